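"""Copolymer characteristic parameters from homopolymer ones.

A statistical copolymer is treated as a pseudo-binary mixture of its two
parent homopolymers: the comonomer mole fraction is converted to a mass
fraction using the repeat-unit molar masses, and the one-fluid mixing rules
of :mod:`slsorb.mixture` (with an adjustable, default-zero interaction
coefficient) yield the copolymer's (T*, p*, rho*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .eos import SLParams
from .mixture import mixing_rules

__all__ = [
    "M_HB",
    "M_HV",
    "CopolymerSpec",
    "mol_to_mass_fraction",
    "copolymer_params",
    "parameter_trend",
]

#: Repeat-unit molar mass of 3-hydroxybutyrate, g/mol.
M_HB = 86.09
#: Repeat-unit molar mass of 3-hydroxyvalerate, g/mol.
M_HV = 100.12


@dataclass(frozen=True)
class CopolymerSpec:
    """Composition of a PHBV-type copolymer.

    Parameters
    ----------
    x_hv : float
        Mole fraction of HV repeat units, in [0, 1].
    m_hb, m_hv : float, optional
        Repeat-unit molar masses, g/mol.
    """

    x_hv: float
    m_hb: float = M_HB
    m_hv: float = M_HV

    def __post_init__(self):
        if not (0.0 <= self.x_hv <= 1.0):
            raise DomainError(f"x_hv must lie in [0, 1], got {self.x_hv!r}")
        if not (self.m_hb > 0.0 and self.m_hv > 0.0):
            raise DomainError("monomer molar masses must be positive")


def mol_to_mass_fraction(spec):
    """HV mass fraction from the HV mole fraction.

    ``w_hv = x m_hv / (x m_hv + (1 - x) m_hb)``; strictly increasing in
    ``x_hv`` with fixed points at 0 and 1.
    """
    num = spec.x_hv * spec.m_hv
    return num / (num + (1.0 - spec.x_hv) * spec.m_hb)


def copolymer_params(hb, hv, spec, kij=0.0):
    """SL parameters of the copolymer described by ``spec``.

    Parameters
    ----------
    hb, hv : SLParams
        Parent homopolymer parameter sets (0 and 100 % HV).
    spec : CopolymerSpec
        Copolymer composition.
    kij : float, optional
        Binary interaction coefficient for the HB/HV pseudo-mixture
        (default 0).

    Returns
    -------
    SLParams
        Polymer-limit parameters.  Endpoint compositions return the
        corresponding homopolymer parameters exactly (with the new label).
    """
    w_hv = mol_to_mass_fraction(spec)
    label = f"copolymer(x_hv={spec.x_hv:g})"
    # Endpoints short-circuit to the parent parameters so the identity is
    # exact in floating point, not merely to rounding of the mixing rules.
    if w_hv == 0.0:
        return SLParams.polymer(hb.Tstar, hb.pstar, hb.rhostar, label)
    if w_hv == 1.0:
        return SLParams.polymer(hv.Tstar, hv.pstar, hv.rhostar, label)
    mixed = mixing_rules(
        (hb, hv), (1.0 - w_hv, w_hv), ((0.0, kij), (kij, 0.0))
    )
    return SLParams.polymer(mixed.Tstar, mixed.pstar, mixed.rhostar, label)


def parameter_trend(hb, hv, x_hv_grid, kij=0.0):
    """Tabulate :func:`copolymer_params` over a composition grid.

    Returns a DataFrame with columns ``x_hv``, ``w_hv``, ``Tstar_K``,
    ``pstar_MPa`` and ``rhostar_g_cm3``.
    """
    x_hv_grid = np.asarray(x_hv_grid, dtype=float)
    if np.any((x_hv_grid < 0.0) | (x_hv_grid > 1.0)):
        raise DomainError("x_hv grid values must lie in [0, 1]")
    rows = []
    for x in x_hv_grid:
        spec = CopolymerSpec(float(x))
        params = copolymer_params(hb, hv, spec, kij)
        rows.append(
            {
                "x_hv": float(x),
                "w_hv": mol_to_mass_fraction(spec),
                "Tstar_K": params.Tstar,
                "pstar_MPa": params.pstar,
                "rhostar_g_cm3": params.rhostar,
            }
        )
    return pd.DataFrame(rows)
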