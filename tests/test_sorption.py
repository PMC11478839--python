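"""Tests for pure- and mixed-gas sorption equilibrium."""

import numpy as np
import pytest
from scipy.optimize import brentq

from slsorb.errors import DomainError
from slsorb.fugacity import GasMixtureSpec, pr_fugacity
from slsorb.reference import T_SORPTION
from slsorb.sorption import (
    CrystallinityContext,
    SorptionSystem,
    amorphous_rescale,
    fit_gas_polymer_kij,
    mixed_vs_ideal_selectivity,
    pure_gas_isotherm,
    sensitivity_sweep,
    solubility_coefficient,
    solubility_selectivity,
    solve_sorption,
)

from conftest import make_system


def pure_concentration_at_fugacity(system, gas_index, f_target_bar):
    """Pure-gas concentration at a matched fugacity (bar)."""
    sub = system.pure_subsystem(gas_index)
    spec = GasMixtureSpec((sub.pr_components[0],), (1.0,), 0.0)

    def mismatch(p):
        return pr_fugacity(spec, sub.temperature, p)[0] * 10.0 - f_target_bar

    p = brentq(mismatch, 1e-8, 5.0)
    return solve_sorption(sub, p).concentrations[0]


class TestValidation:
    def test_needs_polymer_limit(self, co2, ch4):
        with pytest.raises(DomainError):
            SorptionSystem(polymer=co2, gases=(ch4,), kij_gas_polymer=(0.0,))

    def test_kij_band(self, phbv8, co2):
        with pytest.raises(DomainError):
            SorptionSystem(
                polymer=phbv8, gases=(co2,), kij_gas_polymer=(0.5,)
            )

    def test_mole_fractions_checked(self):
        system = make_system(8, ("CO2", "CH4"))
        with pytest.raises(DomainError):
            solve_sorption(system, 1.0, (0.5, 0.6))

    def test_multi_gas_requires_composition(self):
        system = make_system(8, ("CO2", "CH4"))
        with pytest.raises(DomainError):
            solve_sorption(system, 1.0)


class TestSolveSorption:
    def test_zero_pressure_trivial(self):
        system = make_system(8, ("CO2",))
        res = solve_sorption(system, 0.0)
        assert res.concentrations == (0.0,)
        assert res.mixture_density == res.reference_density
        assert res.density_change == 0.0

    def test_equilibrium_residuals(self):
        # The defining condition of the solver, pure and mixed.
        pure = solve_sorption(make_system(8, ("CO2",)), 3.0)
        mixed = solve_sorption(make_system(8, ("CO2", "CH4")), 3.0, (0.2, 0.8))
        for res in (pure, mixed):
            assert max(abs(r) for r in res.mu_residuals) < 1e-8

    def test_isotherm_nonnegative_increasing(self):
        iso = pure_gas_isotherm(
            make_system(8, ("CO2", "CH4")), 0, np.linspace(0.1, 3.0, 8)
        )
        c = iso.concentration.to_numpy()
        assert np.all(c >= 0.0)
        assert np.all(np.diff(c) > 0.0)

    def test_co2_isotherm_convex_in_fugacity(self):
        iso = pure_gas_isotherm(
            make_system(8, ("CO2", "CH4")), 0, np.linspace(0.5, 3.0, 6)
        )
        f = iso.fugacity_bar.to_numpy()
        c = iso.concentration.to_numpy()
        # second divided differences (non-uniform fugacity spacing)
        first = np.diff(c) / np.diff(f)
        assert np.all(np.diff(first) > 0.0)

    def test_swelling_ordering_co2_above_ch4(self):
        for hv in (8, 25):
            sys2 = make_system(hv, ("CO2", "CH4"))
            dc = [
                solve_sorption(sys2.pure_subsystem(i), 3.0).density_change
                for i in (0, 1)
            ]
            assert abs(dc[0]) > abs(dc[1])

    def test_sl_gas_phase_option(self):
        # Both gas-phase references solve and agree in the Henry regime.
        pr_sys = make_system(8, ("CO2",))
        sl_sys = make_system(8, ("CO2",), gas_phase="sl")
        s_pr = solubility_coefficient(solve_sorption(pr_sys, 0.05), 0)
        s_sl = solubility_coefficient(solve_sorption(sl_sys, 0.05), 0)
        assert s_pr == pytest.approx(s_sl, rel=2e-2)


class TestSolubility:
    def test_henry_regime_below_one_bar(self):
        system = make_system(8, ("CO2",))
        s = [
            solubility_coefficient(solve_sorption(system, p), 0)
            for p in (0.02, 0.05, 0.1)
        ]
        assert max(s) / min(s) - 1.0 < 0.01

    def test_doubling_fugacity_doubles_concentration(self):
        system = make_system(8, ("CO2",))
        r1 = solve_sorption(system, 0.04)
        r2 = solve_sorption(system, 0.08)
        ratio = (r2.concentrations[0] / r1.concentrations[0]) / (
            r2.fugacities[0] / r1.fugacities[0]
        )
        assert ratio == pytest.approx(1.0, abs=5e-3)

    def test_one_bar_matches_infinite_dilution(self):
        system = make_system(8, ("CO2",))
        s_1bar = solubility_coefficient(solve_sorption(system, 0.1), 0)
        s_dilute = solubility_coefficient(solve_sorption(system, 0.001), 0)
        assert s_1bar == pytest.approx(s_dilute, rel=2e-2)

    def test_zero_fugacity_rejected(self):
        res = solve_sorption(make_system(8, ("CO2",)), 0.0)
        with pytest.raises(DomainError):
            solubility_coefficient(res, 0)

    def test_selectivity_helpers(self):
        assert solubility_selectivity(1.5, 1.5) == 1.0
        with pytest.raises(DomainError):
            solubility_selectivity(1.0, 0.0)


class TestMixedGas:
    def test_dilute_limit_selectivities_coincide(self):
        table = mixed_vs_ideal_selectivity(
            make_system(8, ("CO2", "CH4")), [0.01], 0.2
        )
        assert abs(table.percent_decrease.iloc[0]) < 1.0

    def test_mixed_below_ideal_and_growing_with_pressure(self):
        table = mixed_vs_ideal_selectivity(
            make_system(8, ("CO2", "CH4")), [1.0, 2.0, 3.0], 0.2
        )
        assert np.all(table.mixed_selectivity < table.ideal_selectivity)
        assert np.all(np.diff(table.percent_decrease) > 0.0)

    def test_co2_competition_at_matched_fugacity(self):
        # CO2 uptake per unit of its own fugacity is reduced by the
        # coabsorbed CH4 at every tested feed composition.
        system = make_system(8, ("CO2", "CH4"))
        for y in (0.2, 0.5, 0.8):
            res = solve_sorption(system, 3.0, (y, 1.0 - y))
            pure = pure_concentration_at_fugacity(system, 0, res.fugacities[0])
            assert res.concentrations[0] < pure

    def test_ch4_swelling_enhancement_at_matched_fugacity(self):
        # For the sparingly soluble gas the CO2-induced swelling outweighs
        # site competition in this formulation: CH4 uptake at matched own
        # fugacity is slightly enhanced, not suppressed.
        system = make_system(8, ("CO2", "CH4"))
        res = solve_sorption(system, 3.0, (0.8, 0.2))
        pure = pure_concentration_at_fugacity(system, 1, res.fugacities[1])
        assert res.concentrations[1] > pure


class TestSensitivity:
    def test_zero_row_reproduces_reference(self):
        system = make_system(100, ("CO2", "CH4"))
        sweep = sensitivity_sweep(
            system, [1.0, 3.0], (0.8, 0.2), kij_values=(-0.01, 0.0, 0.01)
        )
        zero = sweep[sweep.kij == 0.0]
        assert np.allclose(zero.dev_CO2_pct, 0.0)
        assert np.allclose(zero.dev_CH4_pct, 0.0)

    def test_co2_concentration_insensitive_to_kch4(self):
        system = make_system(100, ("CO2", "CH4"))
        sweep = sensitivity_sweep(
            system, [3.0], (0.8, 0.2), kij_values=(-0.05, 0.0)
        )
        dev_from_kch4 = abs(
            sweep[(sweep.varied_gas == "CH4") & (sweep.kij == -0.05)]
            .dev_CO2_pct.iloc[0]
        )
        dev_from_kco2 = abs(
            sweep[(sweep.varied_gas == "CO2") & (sweep.kij == -0.05)]
            .dev_CO2_pct.iloc[0]
        )
        assert dev_from_kch4 < 0.1 * dev_from_kco2


class TestCrystallinity:
    def test_identity(self):
        assert amorphous_rescale(0.7, CrystallinityContext(0.0)) == 0.7

    def test_factor_two(self):
        assert amorphous_rescale(0.7, CrystallinityContext(0.5)) == pytest.approx(1.4)

    def test_hand_case(self):
        assert amorphous_rescale(0.4, CrystallinityContext(0.6)) == pytest.approx(1.0)

    def test_invalid_fraction(self):
        with pytest.raises(DomainError):
            CrystallinityContext(1.0)


class TestKijFit:
    def test_recovery(self):
        system = make_system(8, ("CO2", "CH4"))
        target = system.with_kij(0, -0.02)
        s_obs = solubility_coefficient(
            solve_sorption(target.pure_subsystem(0), 1.0), 0
        )
        fit = fit_gas_polymer_kij(system, 0, [(1.0, s_obs)])
        assert fit.converged
        assert fit.kij == pytest.approx(-0.02, abs=1e-4)

    def test_fixed_point_at_zero(self):
        system = make_system(8, ("CO2", "CH4"), kij=(0.0, 0.0))
        s_obs = solubility_coefficient(
            solve_sorption(system.pure_subsystem(0), 1.0), 0
        )
        fit = fit_gas_polymer_kij(system, 0, [(1.0, s_obs)])
        assert fit.kij == pytest.approx(0.0, abs=1e-4)

    def test_bounds_enforced(self):
        system = make_system(8, ("CO2", "CH4"))
        s_obs = 50.0 * solubility_coefficient(
            solve_sorption(system.pure_subsystem(0), 1.0), 0
        )
        fit = fit_gas_polymer_kij(system, 0, [(1.0, s_obs)])
        assert abs(fit.kij) <= 0.2


class TestReferenceTemperature:
    def test_default_is_35c(self):
        assert make_system(8, ("CO2",)).temperature == T_SORPTION
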