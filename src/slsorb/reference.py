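"""Published parameter sets used by the default pipeline.

Characteristic Sanchez-Lacombe parameters for PHBV copolymers across the
HV composition range (direct fits at 0, 8, 60 and 100 mol% HV; mixing-rule
estimates at 16, 25, 40 and 80 mol%), lattice-fluid parameters for CO2 and
CH4, Peng-Robinson critical constants, and fitted gas-polymer interaction
coefficients.  All values are exposed so user configurations can override
them.
"""

from __future__ import annotations

from .eos import SLParams
from .fugacity import CH4_PR, CO2_PR

__all__ = [
    "PHBV_PARAMS",
    "PHBV_DIRECT_FIT",
    "GAS_SL",
    "GAS_PR",
    "GAS_POLYMER_KIJ",
    "KIJ_GAS_GAS",
    "K_PR_CO2_CH4",
    "T_SORPTION",
    "phbv",
    "gas",
]

#: SL parameters for PHBV at a given HV mol% (key).  T* K, p* MPa,
#: rho* g/cm3; polymer (infinite-chain) limit throughout.
PHBV_PARAMS = {
    0: SLParams.polymer(859.4, 607.4, 1.226, "PHBV0"),
    8: SLParams.polymer(857.1, 595.8, 1.216, "PHBV8"),
    16: SLParams.polymer(852.5, 588.4, 1.211, "PHBV16"),
    25: SLParams.polymer(848.9, 578.5, 1.203, "PHBV25"),
    40: SLParams.polymer(843.3, 562.9, 1.191, "PHBV40"),
    60: SLParams.polymer(836.4, 546.4, 1.176, "PHBV60"),
    80: SLParams.polymer(830.3, 527.0, 1.161, "PHBV80"),
    100: SLParams.polymer(824.7, 511.5, 1.148, "PHBV100"),
}

#: HV contents whose parameters come from direct PVT fits (the others are
#: mixing-rule estimates from the 0/100 endpoints).
PHBV_DIRECT_FIT = (0, 8, 60, 100)

#: Lattice-fluid parameters of the penetrant gases.
GAS_SL = {
    "CO2": SLParams(300.0, 630.0, 1.515, molar_mass=44.01, label="CO2"),
    "CH4": SLParams(215.0, 250.0, 0.500, molar_mass=16.043, label="CH4"),
}

#: Peng-Robinson critical constants of the penetrant gases.
GAS_PR = {"CO2": CO2_PR, "CH4": CH4_PR}

#: Fitted gas-polymer interaction coefficients, keyed by (gas, HV mol%).
GAS_POLYMER_KIJ = {
    ("CO2", 8): -0.002,
    ("CO2", 25): -0.043,
    ("CH4", 8): -0.069,
    ("CH4", 25): -0.005,
}

#: Lattice-fluid CO2/CH4 interaction coefficient for mixed-gas sorption.
KIJ_GAS_GAS = -0.03

#: Peng-Robinson CO2/CH4 binary coefficient.
K_PR_CO2_CH4 = 0.09

#: Sorption reference temperature, K (35 degC).
T_SORPTION = 308.15


def phbv(hv_mol_percent):
    """SL parameters of PHBV at one of the tabulated HV contents."""
    try:
        return PHBV_PARAMS[int(hv_mol_percent)]
    except KeyError:
        raise KeyError(
            f"no tabulated parameters for {hv_mol_percent} mol% HV; "
            f"available: {sorted(PHBV_PARAMS)}"
        ) from None


def gas(name):
    """SL parameters of a penetrant gas by name ('CO2' or 'CH4')."""
    try:
        return GAS_SL[name]
    except KeyError:
        raise KeyError(f"unknown gas {name!r}; available: {sorted(GAS_SL)}") from None
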