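"""Peng-Robinson fugacities for light-gas mixtures.

Standard Peng-Robinson cubic equation of state (Ind. Eng. Chem. Fundam. 15
(1976) 59) with van der Waals one-fluid mixing and a single binary
interaction coefficient, used to map gas-phase pressures to per-component
fugacities.  Only the vapor root is needed for the sub-30-bar, 35 degC
envelope this package targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .constants import R_GAS
from .errors import DomainError, NoDensityRootError

__all__ = [
    "PRComponent",
    "GasMixtureSpec",
    "CO2_PR",
    "CH4_PR",
    "pr_lnphi",
    "pr_fugacity",
]

_SQRT2 = math.sqrt(2.0)
_MOLE_FRACTION_TOL = 1e-8


@dataclass(frozen=True)
class PRComponent:
    """Peng-Robinson critical constants for one gas.

    Tc in K, Pc in MPa, omega dimensionless.
    """

    Tc: float
    Pc: float
    omega: float
    label: str = ""

    def __post_init__(self):
        if not (self.Tc > 0.0 and self.Pc > 0.0):
            raise DomainError("Tc and Pc must be positive")

    def a_b(self, T):
        """Attraction parameter a(T) (MPa cm6/mol2) and covolume b (cm3/mol)."""
        kappa = 0.37464 + 1.54226 * self.omega - 0.26992 * self.omega**2
        alpha = (1.0 + kappa * (1.0 - math.sqrt(T / self.Tc))) ** 2
        a = 0.45724 * R_GAS**2 * self.Tc**2 / self.Pc * alpha
        b = 0.07780 * R_GAS * self.Tc / self.Pc
        return a, b


#: Textbook critical constants, overridable via configuration.
CO2_PR = PRComponent(Tc=304.13, Pc=7.377, omega=0.224, label="CO2")
CH4_PR = PRComponent(Tc=190.56, Pc=4.599, omega=0.011, label="CH4")


@dataclass(frozen=True)
class GasMixtureSpec:
    """A gas mixture for fugacity evaluation.

    ``k_pr`` is the single binary interaction coefficient applied to every
    unlike pair (0.09 for CO2/CH4).
    """

    components: Tuple[PRComponent, ...]
    mole_fractions: Tuple[float, ...]
    k_pr: float = 0.0

    def __post_init__(self):
        components = tuple(self.components)
        y = np.asarray(self.mole_fractions, dtype=float)
        if len(components) == 0:
            raise DomainError("mixture needs at least one component")
        if y.shape != (len(components),):
            raise DomainError("one mole fraction per component is required")
        if np.any(y < 0.0):
            raise DomainError("mole fractions must be nonnegative")
        if abs(y.sum() - 1.0) > _MOLE_FRACTION_TOL:
            raise DomainError(f"mole fractions must sum to 1, got {y.sum()!r}")
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "mole_fractions", tuple(float(v) for v in y))


def _vapor_z(A, B, T, p):
    """Largest real compressibility root of the PR cubic."""
    coeffs = [
        1.0,
        -(1.0 - B),
        A - 2.0 * B - 3.0 * B**2,
        -(A * B - B**2 - B**3),
    ]
    roots = np.roots(coeffs)
    real = roots.real[np.abs(roots.imag) < 1e-10 * max(1.0, np.abs(roots).max())]
    real = real[real > B]
    if real.size == 0:
        raise NoDensityRootError(
            f"no Peng-Robinson vapor root at T={T} K, p={p} MPa", T=T, p=p
        )
    return float(real.max())


def pr_lnphi(mix, T, p):
    """Log fugacity coefficients of every component at (T, p).

    Vapor-root evaluation of the standard Peng-Robinson expression with
    van der Waals mixing.  Returns an array aligned with
    ``mix.components``.
    """
    if not (T > 0.0 and p > 0.0):
        raise DomainError("T and p must be positive")
    comps = mix.components
    n = len(comps)
    y = np.asarray(mix.mole_fractions, dtype=float)
    ab = [c.a_b(T) for c in comps]
    a = np.array([x[0] for x in ab])
    b = np.array([x[1] for x in ab])
    kmat = np.full((n, n), mix.k_pr)
    np.fill_diagonal(kmat, 0.0)
    aij = np.sqrt(np.outer(a, a)) * (1.0 - kmat)
    # Exact diagonal: sqrt(a_i * a_i) can be off by one ulp, which would
    # break the exact pure-component degeneracy of the mixing rules.
    np.fill_diagonal(aij, a)
    a_mix = float(y @ aij @ y)
    b_mix = float(y @ b)
    RT = R_GAS * T
    A = a_mix * p / RT**2
    B = b_mix * p / RT
    Z = _vapor_z(A, B, T, p)
    log_term = math.log((Z + (1.0 + _SQRT2) * B) / (Z + (1.0 - _SQRT2) * B))
    return (
        b / b_mix * (Z - 1.0)
        - math.log(Z - B)
        - A / (2.0 * _SQRT2 * B) * (2.0 * (aij @ y) / a_mix - b / b_mix) * log_term
    )


def pr_fugacity(mix, T, p):
    """Per-component fugacities f_i = phi_i y_i p, in MPa.

    A single-component mixture gives the pure-gas fugacity; at vanishing
    pressure every fugacity coefficient tends to 1.
    """
    y = np.asarray(mix.mole_fractions, dtype=float)
    return np.exp(pr_lnphi(mix, T, p)) * y * p
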