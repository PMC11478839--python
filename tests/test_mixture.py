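"""Tests for mixture mixing rules and chemical potentials."""

import math

import numpy as np
import pytest

from slsorb.constants import R_GAS
from slsorb.errors import DomainError
from slsorb.eos import solve_density
from slsorb.mixture import (
    MixtureState,
    chemical_potential,
    mixing_rules,
    mixture_density,
    solve_mixture,
)


def binary_state(gas, polymer, w_gas, kij=0.0):
    return MixtureState(
        components=(gas, polymer),
        mass_fractions=(w_gas, 1.0 - w_gas),
        kij_matrix=((0.0, kij), (kij, 0.0)),
    )


class TestValidation:
    def test_mass_fractions_must_sum_to_one(self, co2, phbv0):
        with pytest.raises(DomainError):
            MixtureState((co2, phbv0), (0.3, 0.3), ((0.0, 0.0), (0.0, 0.0)))

    def test_negative_mass_fraction_rejected(self, co2, phbv0):
        with pytest.raises(DomainError):
            MixtureState((co2, phbv0), (-0.1, 1.1), ((0.0, 0.0), (0.0, 0.0)))

    def test_kij_symmetry_required(self, co2, phbv0):
        with pytest.raises(DomainError):
            MixtureState((co2, phbv0), (0.1, 0.9), ((0.0, 0.01), (0.02, 0.0)))

    def test_kij_zero_diagonal_required(self, co2, phbv0):
        with pytest.raises(DomainError):
            MixtureState((co2, phbv0), (0.1, 0.9), ((0.1, 0.0), (0.0, 0.0)))


class TestMixingRules:
    def test_single_component_degeneracy(self, co2):
        state = MixtureState((co2,), (1.0,), ((0.0,),))
        assert mixture_density(state, 308.15, 3.0, "vapor") == solve_density(
            co2, 308.15, 3.0, "vapor"
        )
        mixed = mixing_rules((co2,), (1.0,), ((0.0,),))
        assert mixed.Tstar == pytest.approx(co2.Tstar, rel=1e-15)
        assert mixed.pstar == pytest.approx(co2.pstar, rel=1e-15)
        assert mixed.rhostar == pytest.approx(co2.rhostar, rel=1e-15)

    def test_zero_penetrant_boundary(self, co2, phbv0):
        state = binary_state(co2, phbv0, 0.0)
        assert mixture_density(state, 308.15, 0.1, "liquid") == pytest.approx(
            solve_density(phbv0, 308.15, 0.1, "liquid"), rel=1e-14
        )

    def test_harmonic_close_packed_density(self, co2, phbv0):
        w = 0.07
        mixed = mixing_rules(
            (co2, phbv0), (w, 1 - w), ((0.0, 0.0), (0.0, 0.0))
        )
        assert 1.0 / mixed.rhostar == pytest.approx(
            w / co2.rhostar + (1 - w) / phbv0.rhostar, rel=1e-15
        )

    def test_polymer_partial_density_decreases_with_co2(self, co2, phbv8):
        # Swelling: polymer mass per unit mixed-phase volume drops as CO2
        # loads up at fixed (T, p).
        partials = []
        for w in (0.0, 0.02, 0.05, 0.08):
            rho = mixture_density(binary_state(co2, phbv8, w), 308.15, 3.0)
            partials.append(rho * (1.0 - w))
        assert all(a > b for a, b in zip(partials, partials[1:]))


class TestChemicalPotential:
    def test_state_function_property(self, co2, phbv8):
        # Identical composition, T, p -> identical mu, whether the state
        # was pre-solved or solved on the fly.
        state = binary_state(co2, phbv8, 0.04)
        solved = solve_mixture(state, 308.15, 3.0, "liquid")
        mu_direct = chemical_potential(state, 0, 308.15, 3.0, "liquid")
        mu_solved = chemical_potential(solved, 0, 308.15, 3.0)
        assert mu_direct == mu_solved

    def test_pure_fluid_reduction(self, co2):
        from slsorb.eos import mu_pure

        state = MixtureState((co2,), (1.0,), ((0.0,),))
        mu_mix = chemical_potential(state, 0, 308.15, 2.0, phase_hint="vapor")
        mu_p = mu_pure(co2, 308.15, 2.0, phase_hint="vapor")
        assert mu_mix == pytest.approx(mu_p, rel=1e-12)

    def test_dilute_monotonicity(self, co2, phbv8):
        mus = [
            chemical_potential(binary_state(co2, phbv8, w), 0, 308.15, 3.0)
            for w in (1e-4, 1e-3, 1e-2, 3e-2)
        ]
        assert all(a < b for a, b in zip(mus, mus[1:]))

    def test_polymer_component_rejected(self, co2, phbv8):
        with pytest.raises(DomainError):
            chemical_potential(binary_state(co2, phbv8, 0.05), 1, 308.15, 3.0)

    def test_index_out_of_range(self, co2, phbv8):
        with pytest.raises(IndexError):
            chemical_potential(binary_state(co2, phbv8, 0.05), 2, 308.15, 3.0)


def total_gibbs_over_RT(masses, components, kij, T, p):
    """Independent total Gibbs energy of a solved mixture, G/RT.

    Lattice-fluid free energy assembled from scratch (close-packed volume,
    lattice count, mixing entropy); only the mixing rules and density
    solve are shared with the package.  Polymer components contribute no
    molecular translational term (N -> 0).
    """
    masses = np.asarray(masses, dtype=float)
    w = masses / masses.sum()
    mixed = mixing_rules(components, w, kij)
    state = solve_mixture(
        MixtureState(tuple(components), tuple(w), tuple(map(tuple, kij))),
        T, p, "liquid",
    )
    rhotilde = state.rhotilde
    vstar_total = float(np.sum(masses / np.array([c.rhostar for c in components])))
    volume = vstar_total / rhotilde
    moles = np.array(
        [0.0 if c.is_polymer else m / c.molar_mass
         for m, c in zip(masses, components)]
    )
    log_phi = np.log(np.where(mixed.phi > 0.0, mixed.phi, 1.0))
    return (
        -mixed.pstar * vstar_total * rhotilde / (R_GAS * T)
        + p * volume / (R_GAS * T)
        + (volume - vstar_total) / mixed.vstar * math.log1p(-rhotilde)
        + float(np.sum(moles * (math.log(rhotilde) + log_phi)))
    )


class TestThermodynamicConsistency:
    def test_mu_is_derivative_of_total_gibbs(self, co2, ch4, phbv8):
        # mu_i/RT must equal M_i * d(G/RT)/d m_i at fixed T, p and other
        # masses -- the defining property of a chemical potential.
        components = (co2, ch4, phbv8)
        kij = np.array([[0.0, -0.03, -0.002], [-0.03, 0.0, -0.069],
                        [-0.002, -0.069, 0.0]])
        masses = np.array([0.03, 0.005, 0.965])
        T, p = 308.15, 3.0
        w = masses / masses.sum()
        state = MixtureState(components, tuple(w), tuple(map(tuple, kij)))
        for i in (0, 1):
            h = 1e-6
            up, down = masses.copy(), masses.copy()
            up[i] += h
            down[i] -= h
            fd = (
                (total_gibbs_over_RT(up, components, kij, T, p)
                 - total_gibbs_over_RT(down, components, kij, T, p))
                / (2 * h) * components[i].molar_mass
            )
            analytic = chemical_potential(state, i, T, p)
            assert analytic == pytest.approx(fd, rel=1e-6)

    def test_gibbs_duhem(self, co2, ch4):
        # sum_i n_i d(mu_i) = 0 along a composition change at fixed T, p.
        components = (co2, ch4)
        kij = ((0.0, -0.03), (-0.03, 0.0))
        T, p = 300.0, 5.0
        w = np.array([0.6, 0.4])
        delta = 1e-5

        def mus(wvec):
            state = MixtureState(components, tuple(wvec), kij)
            return np.array(
                [chemical_potential(state, i, T, p, "vapor") for i in (0, 1)]
            )

        d_mu = mus(w + [delta, -delta]) - mus(w - [delta, -delta])
        moles = w / np.array([co2.molar_mass, ch4.molar_mass])
        violation = abs(float(moles @ d_mu))
        scale = float(np.abs(moles * d_mu).max())
        assert violation < 1e-6 * max(scale, 1e-12) + 1e-12
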