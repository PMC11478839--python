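"""Shared fixtures: reference parameter sets and prebuilt systems."""

import pytest

from slsorb.reference import GAS_POLYMER_KIJ, gas, phbv
from slsorb.sorption import SorptionSystem


@pytest.fixture(scope="session")
def phbv0():
    return phbv(0)


@pytest.fixture(scope="session")
def phbv8():
    return phbv(8)


@pytest.fixture(scope="session")
def phbv25():
    return phbv(25)


@pytest.fixture(scope="session")
def phbv100():
    return phbv(100)


@pytest.fixture(scope="session")
def co2():
    return gas("CO2")


@pytest.fixture(scope="session")
def ch4():
    return gas("CH4")


def make_system(hv, gas_names, kij=None, **kwargs):
    """SorptionSystem for PHBV<hv> with the named gases.

    ``kij=None`` uses the tabulated fitted coefficients (0 when absent).
    """
    gases = tuple(gas(name) for name in gas_names)
    if kij is None:
        kij = tuple(GAS_POLYMER_KIJ.get((name, hv), 0.0) for name in gas_names)
    return SorptionSystem(
        polymer=phbv(hv), gases=gases, kij_gas_polymer=tuple(kij), **kwargs
    )
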