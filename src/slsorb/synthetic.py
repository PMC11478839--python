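"""Synthetic PVT data generation.

Emulates the statistics of a molecular-dynamics PVT campaign — a small
pressure/temperature grid with a few independent replicates and sub-1 %
density scatter — so the fitting stage and the full pipeline can be
exercised without any simulation input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .errors import DomainError
from .eos import solve_density
from .pvtfit import PVT_COLUMNS, PVTDataset

__all__ = ["PVTGridSpec", "generate_pvt"]

DEFAULT_PRESSURES = (0.1, 50.0, 100.0)
DEFAULT_TEMPERATURES = (275.0, 300.0, 325.0, 350.0, 375.0,
                        400.0, 450.0, 500.0, 550.0, 600.0)


@dataclass(frozen=True)
class PVTGridSpec:
    """Grid and noise specification for synthetic PVT generation."""

    pressures: Tuple[float, ...] = DEFAULT_PRESSURES
    temperatures: Tuple[float, ...] = DEFAULT_TEMPERATURES
    replicates: int = 3
    noise_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pressures", tuple(float(p) for p in self.pressures))
        object.__setattr__(
            self, "temperatures", tuple(float(t) for t in self.temperatures)
        )
        if len(self.pressures) == 0 or len(self.temperatures) == 0:
            raise DomainError("pressure and temperature grids must be nonempty")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")
        if self.noise_sigma < 0.0:
            raise DomainError("noise_sigma must be nonnegative")


def generate_pvt(params, grid=PVTGridSpec(), polymer_id="synthetic",
                 hv_mol_percent=0.0):
    """Generate a replicated PVT dataset from known SL parameters.

    The noiseless backbone is the equilibrium liquid density at every
    (T, p) grid state; each replicate observation multiplies it by
    ``1 + noise_sigma * N(0, 1)``.  Fully reproducible from ``grid.seed``:
    the same seed yields a byte-identical dataset and different seeds
    share the same backbone.

    No-root errors from the equation of state propagate with the
    offending state named.
    """
    backbone = {
        (T, p): solve_density(params, T, p, phase_hint="liquid")
        for T in grid.temperatures
        for p in grid.pressures
    }
    rng = np.random.default_rng(grid.seed)
    rows = []
    for replicate in range(1, grid.replicates + 1):
        for T in grid.temperatures:
            for p in grid.pressures:
                rho = backbone[(T, p)]
                if grid.noise_sigma > 0.0:
                    rho = rho * (1.0 + grid.noise_sigma * rng.standard_normal())
                rows.append(
                    {"T_K": T, "p_MPa": p, "rho_g_cm3": rho, "replicate": replicate}
                )
    frame = pd.DataFrame(rows, columns=list(PVT_COLUMNS))
    return PVTDataset(polymer_id, float(hv_mol_percent), frame)
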