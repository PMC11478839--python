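"""Sanchez-Lacombe lattice-fluid equation of state for pure fluids.

The lattice fluid of Sanchez and Lacombe (J. Phys. Chem. 80 (1976) 2352;
Macromolecules 11 (1978) 1145) describes a fluid by three characteristic
parameters: temperature ``T*``, pressure ``p*`` and close-packed mass
density ``rho*``.  In reduced variables ``Ttilde = T/T*``, ``ptilde = p/p*``
and ``rhotilde = rho/rho*`` (the occupied lattice fraction) the equation of
state reads::

    rhotilde**2 + ptilde + Ttilde*(log(1 - rhotilde) + (1 - 1/r)*rhotilde) = 0

where ``r`` is the number of lattice sites occupied by one molecule.  For a
high polymer ``r`` is effectively infinite and the ``1/r`` term vanishes;
that limit is handled analytically throughout so no large-but-finite chain
length is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import R_GAS
from .errors import DomainError, NoDensityRootError

__all__ = [
    "SLParams",
    "ReducedState",
    "eos_residual",
    "find_reduced_roots",
    "solve_reduced_density",
    "solve_density",
    "reduced_state",
    "unreduce",
    "mu_pure",
    "ideal_gas_mu",
]


@dataclass(frozen=True)
class SLParams:
    """Sanchez-Lacombe characteristic parameters for one species.

    Parameters
    ----------
    Tstar : float
        Characteristic temperature, K.
    pstar : float
        Characteristic pressure, MPa.
    rhostar : float
        Close-packed mass density, g/cm3.
    molar_mass : float, optional
        Molar mass in g/mol; ``math.inf`` (the default) marks a high
        polymer and selects the analytic infinite-chain limit.
    label : str, optional
        Human-readable species name.
    """

    Tstar: float
    pstar: float
    rhostar: float
    molar_mass: float = math.inf
    label: str = ""

    def __post_init__(self):
        for name in ("Tstar", "pstar", "rhostar", "molar_mass"):
            value = getattr(self, name)
            if not (value > 0.0):
                raise DomainError(f"SLParams.{name} must be positive, got {value!r}")

    @classmethod
    def polymer(cls, Tstar, pstar, rhostar, label=""):
        """Build parameters for a high polymer (infinite chain)."""
        return cls(Tstar, pstar, rhostar, math.inf, label)

    @property
    def is_polymer(self):
        """True when the species is treated in the infinite-chain limit."""
        return math.isinf(self.molar_mass)

    @property
    def vstar(self):
        """Close-packed volume of one mole of lattice sites, cm3/mol."""
        return R_GAS * self.Tstar / self.pstar

    @property
    def chain_size(self):
        """Number of lattice sites per molecule, r = M p* / (R T* rho*)."""
        if self.is_polymer:
            return math.inf
        return self.molar_mass * self.pstar / (R_GAS * self.Tstar * self.rhostar)


@dataclass(frozen=True)
class ReducedState:
    """Reduced-variable description of a state point."""

    Ttilde: float
    ptilde: float
    rhotilde: float
    r: float

    def __post_init__(self):
        if not (0.0 < self.rhotilde < 1.0):
            raise DomainError(
                f"rhotilde must lie strictly inside (0, 1), got {self.rhotilde!r}"
            )


def _inv_r(r):
    """1/r with the infinite-chain limit mapped to exactly zero."""
    r = float(r)
    if r <= 0.0:
        raise DomainError(f"chain size r must be positive, got {r!r}")
    return 0.0 if math.isinf(r) else 1.0 / r


def eos_residual(rhotilde, Ttilde, ptilde, r=math.inf):
    """Residual of the Sanchez-Lacombe equation of state.

    Returns ``rhotilde**2 + ptilde + Ttilde*(log(1-rhotilde)
    + (1 - 1/r)*rhotilde)``; zero at an equilibrium reduced density.
    Accepts scalars or arrays for ``rhotilde``.

    Raises
    ------
    DomainError
        If any ``rhotilde`` lies outside the open interval (0, 1), or
        ``Ttilde <= 0`` or ``ptilde < 0``.
    """
    rho = np.asarray(rhotilde, dtype=float)
    if np.any(rho <= 0.0) or np.any(rho >= 1.0):
        raise DomainError("rhotilde must lie strictly inside (0, 1)")
    if not (Ttilde > 0.0):
        raise DomainError(f"Ttilde must be positive, got {Ttilde!r}")
    if ptilde < 0.0:
        raise DomainError(f"ptilde must be nonnegative, got {ptilde!r}")
    inv_r = _inv_r(r)
    out = rho * rho + ptilde + Ttilde * (np.log1p(-rho) + (1.0 - inv_r) * rho)
    if np.isscalar(rhotilde):
        return float(out)
    return out


def _gibbs_per_site(rhotilde, Ttilde, ptilde, inv_r):
    """Dimensionless Gibbs energy per lattice site, mu/(r R T).

    Used only to rank coexisting density roots at the same (T, p); valid
    for finite chains and in the polymer limit (``inv_r = 0``).
    """
    rho = rhotilde
    return (
        -rho / Ttilde
        + ptilde / (rho * Ttilde)
        + (1.0 - rho) * np.log1p(-rho) / rho
        + inv_r * np.log(rho)
    )


# Bracketing grid for the root scan: log-spaced through the dilute branch,
# linear through the dense branch up to the log singularity at rhotilde = 1.
_SCAN_GRID = np.concatenate(
    [np.logspace(-12.0, -1.0, 80), np.linspace(0.1, 1.0 - 1e-12, 420)[1:]]
)


def find_reduced_roots(Ttilde, ptilde, r=math.inf):
    """All reduced-density roots of the equation of state at (Ttilde, ptilde).

    Scans a fixed log/linear grid over (1e-12, 1-1e-12) for sign changes
    and polishes each bracket with Brent's method.  Returns roots in
    increasing order (possibly empty).
    """
    inv_r = _inv_r(r)

    def f(rho):
        return rho * rho + ptilde + Ttilde * (np.log1p(-rho) + (1.0 - inv_r) * rho)

    values = f(_SCAN_GRID)
    roots = []
    for lo, hi, flo, fhi in zip(
        _SCAN_GRID[:-1], _SCAN_GRID[1:], values[:-1], values[1:]
    ):
        if flo == 0.0:
            roots.append(float(lo))
        elif np.sign(flo) != np.sign(fhi):
            roots.append(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16))
    if values[-1] == 0.0:
        roots.append(float(_SCAN_GRID[-1]))
    # De-duplicate near-identical roots found at grid nodes.
    out = []
    for root in roots:
        if not out or abs(root - out[-1]) > 1e-12:
            out.append(root)
    return out


def solve_reduced_density(params, T, p, phase_hint=None):
    """Reduced density rhotilde at (T, p) for a pure fluid.

    ``phase_hint`` may be ``"liquid"`` (largest root), ``"vapor"``
    (smallest root) or ``None``, in which case the root with the lowest
    Gibbs energy is returned when several coexist.

    Raises
    ------
    NoDensityRootError
        If no root exists in (0, 1) at the requested state.
    """
    if not (T > 0.0):
        raise DomainError(f"temperature must be positive, got {T!r}")
    if p < 0.0:
        raise DomainError(f"pressure must be nonnegative, got {p!r}")
    Ttilde = T / params.Tstar
    ptilde = p / params.pstar
    r = params.chain_size
    roots = find_reduced_roots(Ttilde, ptilde, r)
    if not roots:
        raise NoDensityRootError(
            f"no density root for {params.label or 'species'} at "
            f"T={T} K, p={p} MPa (Ttilde={Ttilde:.6g}, ptilde={ptilde:.6g})",
            T=T, p=p, Ttilde=Ttilde, ptilde=ptilde,
        )
    if phase_hint == "liquid":
        return roots[-1]
    if phase_hint == "vapor":
        return roots[0]
    if phase_hint is not None:
        raise DomainError(f"unknown phase_hint {phase_hint!r}")
    if len(roots) == 1:
        return roots[0]
    inv_r = _inv_r(r)
    gibbs = [_gibbs_per_site(rho, Ttilde, ptilde, inv_r) for rho in roots]
    return roots[int(np.argmin(gibbs))]


def solve_density(params, T, p, phase_hint=None):
    """Equilibrium mass density rho = rhotilde * rhostar in g/cm3."""
    return solve_reduced_density(params, T, p, phase_hint) * params.rhostar


def reduced_state(params, T, p, phase_hint=None):
    """Solve the EoS and package the result as a :class:`ReducedState`."""
    rhotilde = solve_reduced_density(params, T, p, phase_hint)
    return ReducedState(
        Ttilde=T / params.Tstar,
        ptilde=p / params.pstar,
        rhotilde=rhotilde,
        r=params.chain_size,
    )


def unreduce(params, state):
    """Recover (T, p) in physical units from a :class:`ReducedState`."""
    return state.Ttilde * params.Tstar, state.ptilde * params.pstar


def mu_pure(params, T, p, phase_hint=None, rhotilde=None):
    """Dimensionless chemical potential mu/RT of a pure finite-chain fluid.

    Evaluated at the equilibrium reduced density (or at a caller-supplied
    ``rhotilde`` root).  The polymer limit diverges per mole and is
    rejected.
    """
    if params.is_polymer:
        raise DomainError("mu_pure is undefined in the infinite-chain limit")
    if rhotilde is None:
        rhotilde = solve_reduced_density(params, T, p, phase_hint)
    r = params.chain_size
    Tt = T / params.Tstar
    return (
        np.log(rhotilde)
        + 1.0
        - r * (1.0 + np.log1p(-rhotilde))
        - 2.0 * r * rhotilde / Tt
    )


def ideal_gas_mu(params, T, fugacity):
    """mu/RT of a pure gas in the ideal-gas limit at the given fugacity (MPa).

    Analytic low-density limit of :func:`mu_pure`: as ``p -> 0`` the
    reduced density tends to ``p r v* / (R T)`` and the chemical potential
    to ``log(p r v*/(R T)) + 1 - r``; replacing the pressure with the
    fugacity gives the ideal-gas reference used by the sorption solver.
    """
    if params.is_polymer:
        raise DomainError("ideal_gas_mu is undefined in the infinite-chain limit")
    if not (fugacity > 0.0):
        raise DomainError(f"fugacity must be positive, got {fugacity!r}")
    r = params.chain_size
    return math.log(fugacity * r * params.vstar / (R_GAS * T)) + 1.0 - r
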