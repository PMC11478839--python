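"""Sanchez-Lacombe mixtures: one-fluid mixing rules and chemical potentials.

Mixing rules
------------
Compositions enter through close-packed volume fractions computed from mass
fractions ``w_i`` and pure close-packed densities::

    phi_i = (w_i / rho*_i) / sum_j (w_j / rho*_j)

The mixture characteristic parameters are::

    1/rho*  = sum_i w_i / rho*_i                      (harmonic in mass)
    p*      = sum_ij phi_i phi_j p*_ij,  p*_ij = (1 - k_ij) sqrt(p*_i p*_j)
    T*      = p* / sum_i (phi_i p*_i / T*_i)
    v*      = R T* / p*

so the close-packed volume per mole of sites, ``v*``, mixes harmonically in
volume fractions.  Each species occupies ``r_i = (M_i/rho*_i)/v*`` sites in
the mixture (infinite for polymers).

Chemical potential
------------------
``chemical_potential`` evaluates the exact composition derivative of the
lattice-fluid Gibbs energy under these mixing rules::

    mu_i/RT = log(rhotilde*phi_i) + 1
              - r_i*[1 + (1 + (1-rhotilde)*(1-a_i)/rhotilde)*log(1-rhotilde)]
              - 2*rhotilde*r_i*v**pbar_i/(R T)

with ``a_i = (p*_i/T*_i)/sum_j phi_j p*_j/T*_j`` and
``pbar_i = sum_j phi_j p*_ij``.  It is equivalent to the multicomponent
generalisation of the Sanchez-Lacombe (1978) binary expression and has been
verified against finite differences of the total Gibbs energy; see
docs/methods.md for the derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .constants import R_GAS
from .errors import DomainError, NoDensityRootError
from .eos import SLParams, find_reduced_roots, solve_density

__all__ = [
    "MixedParams",
    "MixtureState",
    "mixing_rules",
    "solve_mixture",
    "mixture_density",
    "chemical_potential",
]

_MASS_FRACTION_TOL = 1e-8


def _validate_kij(kij_matrix, n):
    kij = np.asarray(kij_matrix, dtype=float)
    if kij.shape != (n, n):
        raise DomainError(f"kij_matrix must be {n}x{n}, got shape {kij.shape}")
    if not np.allclose(kij, kij.T, atol=0.0):
        raise DomainError("kij_matrix must be symmetric")
    if np.any(np.diag(kij) != 0.0):
        raise DomainError("kij_matrix must have a zero diagonal")
    return kij


def _validate_mass_fractions(mass_fractions, n):
    w = np.asarray(mass_fractions, dtype=float)
    if w.shape != (n,):
        raise DomainError(f"expected {n} mass fractions, got shape {w.shape}")
    if np.any(w < 0.0):
        raise DomainError("mass fractions must be nonnegative")
    if abs(w.sum() - 1.0) > _MASS_FRACTION_TOL:
        raise DomainError(f"mass fractions must sum to 1, got {w.sum()!r}")
    return w


@dataclass(frozen=True)
class MixedParams:
    """Mixture characteristic parameters plus per-species bookkeeping."""

    Tstar: float
    pstar: float
    rhostar: float
    vstar: float
    phi: np.ndarray          # close-packed volume fractions
    pij: np.ndarray          # pairwise p*_ij matrix, MPa
    chain_sizes: np.ndarray  # r_i in the mixture (inf for polymers)
    rbar_inv: float          # sum_i phi_i / r_i

    @property
    def rbar(self):
        """Mean chain size; infinite when every species is a polymer."""
        return math.inf if self.rbar_inv == 0.0 else 1.0 / self.rbar_inv


@dataclass(frozen=True)
class MixtureState:
    """Composition (and optionally the solved reduced density) of a mixture.

    ``rhotilde`` is ``None`` until the state has been solved at some
    (T, p); :func:`solve_mixture` returns a copy with it filled in.
    """

    components: Tuple[SLParams, ...]
    mass_fractions: Tuple[float, ...]
    kij_matrix: Tuple[Tuple[float, ...], ...]
    rhotilde: Optional[float] = None

    def __post_init__(self):
        components = tuple(self.components)
        n = len(components)
        if n == 0:
            raise DomainError("mixture needs at least one component")
        w = _validate_mass_fractions(self.mass_fractions, n)
        kij = _validate_kij(self.kij_matrix, n)
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "mass_fractions", tuple(float(x) for x in w))
        object.__setattr__(
            self, "kij_matrix", tuple(tuple(float(x) for x in row) for row in kij)
        )
        if self.rhotilde is not None and not (0.0 < self.rhotilde < 1.0):
            raise DomainError("rhotilde must lie strictly inside (0, 1)")

    def mixed_params(self):
        """Apply the one-fluid mixing rules to this composition."""
        return mixing_rules(self.components, self.mass_fractions, self.kij_matrix)


def mixing_rules(components, mass_fractions, kij_matrix):
    """One-fluid Sanchez-Lacombe mixing rules; see the module docstring.

    Zero-mass-fraction components are retained (their volume fraction is
    zero), so endpoint compositions degenerate exactly to the remaining
    species.
    """
    components = tuple(components)
    n = len(components)
    w = _validate_mass_fractions(mass_fractions, n)
    kij = _validate_kij(kij_matrix, n)

    ps = np.array([c.pstar for c in components])
    Ts = np.array([c.Tstar for c in components])
    rs = np.array([c.rhostar for c in components])
    M = np.array([c.molar_mass for c in components])

    vspec = w / rs                      # close-packed cm3 per g of mixture
    total = vspec.sum()
    if total <= 0.0:
        raise DomainError("at least one mass fraction must be positive")
    phi = vspec / total
    rhostar = 1.0 / total
    pij = np.sqrt(np.outer(ps, ps)) * (1.0 - kij)
    # Exact diagonal: sqrt(p*_i * p*_i) can be off by one ulp, which would
    # break the exact single-component degeneracy.
    np.fill_diagonal(pij, ps)
    pstar = float(phi @ pij @ phi)
    if pstar <= 0.0:
        raise DomainError(f"mixing rules produced nonpositive p* = {pstar!r}")
    Tstar = pstar / float(np.sum(phi * ps / Ts))
    vstar = R_GAS * Tstar / pstar
    with np.errstate(invalid="ignore"):
        chain_sizes = np.where(np.isinf(M), math.inf, (M / rs) / vstar)
    rbar_inv = float(np.sum(np.where(np.isinf(chain_sizes), 0.0, phi / chain_sizes)))
    return MixedParams(
        Tstar=Tstar, pstar=pstar, rhostar=rhostar, vstar=vstar,
        phi=phi, pij=pij, chain_sizes=chain_sizes, rbar_inv=rbar_inv,
    )


def _solve_rhotilde(mixed, T, p, phase_hint):
    Ttilde = T / mixed.Tstar
    ptilde = p / mixed.pstar
    roots = find_reduced_roots(Ttilde, ptilde, mixed.rbar)
    if not roots:
        raise NoDensityRootError(
            f"no mixture density root at T={T} K, p={p} MPa "
            f"(Ttilde={Ttilde:.6g}, ptilde={ptilde:.6g})",
            T=T, p=p, Ttilde=Ttilde, ptilde=ptilde,
        )
    if phase_hint == "vapor":
        return roots[0]
    if phase_hint in (None, "liquid"):
        # Liquid by default: the sorbed polymer phase is always the dense
        # branch; pure-fluid callers wanting Gibbs selection use eos.
        return roots[-1]
    raise DomainError(f"unknown phase_hint {phase_hint!r}")


def solve_mixture(state, T, p, phase_hint="liquid"):
    """Solve the mixture EoS and return the state with ``rhotilde`` set."""
    mixed = state.mixed_params()
    rhotilde = _solve_rhotilde(mixed, T, p, phase_hint)
    return replace(state, rhotilde=rhotilde)


def mixture_density(state, T, p, phase_hint="liquid"):
    """Mixed-phase mass density, g/cm3.

    A single-component state delegates to the pure solver (identical by
    construction); for genuine mixtures the one-fluid parameters are used.
    Uses ``state.rhotilde`` when already solved, else solves at (T, p).
    """
    if len(state.components) == 1:
        return solve_density(state.components[0], T, p, phase_hint)
    mixed = state.mixed_params()
    rhotilde = state.rhotilde
    if rhotilde is None:
        rhotilde = _solve_rhotilde(mixed, T, p, phase_hint)
    return rhotilde * mixed.rhostar


def chemical_potential(state, component_index, T, p, phase_hint="liquid"):
    """Dimensionless chemical potential mu/RT of one component.

    Evaluated at the equilibrium reduced density of the mixed phase at
    (T, p) (or at ``state.rhotilde`` when the state is already solved).
    The component must have a finite chain size and a positive mass
    fraction; for a single-component state the result reduces to the
    pure-fluid expression.

    Raises
    ------
    IndexError
        If ``component_index`` is out of range.
    DomainError
        For polymer (infinite-chain) components, whose molar chemical
        potential diverges, or zero-mass-fraction components.
    """
    n = len(state.components)
    if not (-n <= component_index < n):
        raise IndexError(
            f"component_index {component_index} out of range for {n} components"
        )
    component_index %= n
    mixed = state.mixed_params()
    rhotilde = state.rhotilde
    if rhotilde is None:
        rhotilde = _solve_rhotilde(mixed, T, p, phase_hint)

    ri = mixed.chain_sizes[component_index]
    if math.isinf(ri):
        raise DomainError("chemical_potential diverges for an infinite chain")
    phi_i = mixed.phi[component_index]
    if phi_i <= 0.0:
        raise DomainError("chemical_potential requires a positive mass fraction")

    components = state.components
    ps_over_Ts = np.array([c.pstar / c.Tstar for c in components])
    q = float(mixed.phi @ ps_over_Ts)
    a_i = ps_over_Ts[component_index] / q
    pbar_i = float(mixed.pij[component_index] @ mixed.phi)
    log_one_minus = np.log1p(-rhotilde)
    return float(
        np.log(rhotilde * phi_i)
        + 1.0
        - ri * (1.0 + (1.0 + (1.0 - rhotilde) * (1.0 - a_i) / rhotilde) * log_one_minus)
        - 2.0 * rhotilde * ri * mixed.vstar * pbar_i / (R_GAS * T)
    )
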