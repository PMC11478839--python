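"""Pure- and mixed-gas sorption equilibrium in Sanchez-Lacombe polymers.

Equilibrium condition
---------------------
For each penetrant the lattice-fluid chemical potential in the polymer
mixture at (T, p_total) must equal its chemical potential in the external
gas phase.  The gas-phase reference is, by default, the ideal-gas-anchored
lattice-fluid potential evaluated at the Peng-Robinson fugacity of the
component (``gas_phase="pr"``)::

    mu_i^gas/RT = log(f_i r_i v*_i / (R T)) + 1 - r_i

which ties both phases to the same pure-component lattice parameters while
taking the gas-phase non-ideality from the cubic EoS that also supplies
the fugacities used for solubility coefficients.  Setting
``gas_phase="sl"`` instead evaluates the penetrant potentials in a
lattice-fluid gas mixture at (T, p_total).

Reported quantities
-------------------
Concentrations are cm3(STP) of gas per cm3 of unpenetrated polymer at
(T, 1 bar); solubility coefficients are per bar of fugacity.  The headline
``density_change`` is the percent change of the polymer-partial density
(mass of polymer per unit mixed-phase volume) relative to the unpenetrated
polymer — the quantity that tracks swelling, since the mixed-phase mass
density can rise when a dense penetrant such as CO2 dissolves.  The
mixed-phase mass density is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar, root

from .constants import MPA_TO_BAR, P_REFERENCE, V_STP
from .errors import ConvergenceError, DomainError
from .eos import SLParams, ideal_gas_mu, solve_density
from .fugacity import CH4_PR, CO2_PR, GasMixtureSpec, PRComponent, pr_fugacity
from .mixture import MixtureState, chemical_potential, mixture_density, solve_mixture

__all__ = [
    "SorptionSystem",
    "SorptionResult",
    "CrystallinityContext",
    "KijFitResult",
    "solve_sorption",
    "solubility_coefficient",
    "solubility_selectivity",
    "pure_gas_isotherm",
    "mixed_vs_ideal_selectivity",
    "sensitivity_sweep",
    "amorphous_rescale",
    "fit_gas_polymer_kij",
]

_KIJ_BAND = 0.2
_MU_TOL = 1e-8
_DEFAULT_PR = {"CO2": CO2_PR, "CH4": CH4_PR}


@dataclass(frozen=True)
class SorptionSystem:
    """A polymer, its penetrant gases, and the interaction coefficients.

    Parameters
    ----------
    polymer : SLParams
        Polymer-limit lattice parameters.
    gases : tuple of SLParams
        Penetrant lattice parameters (finite chains).
    kij_gas_polymer : tuple of float
        One lattice-fluid interaction coefficient per gas.
    kij_gas_gas : float
        Lattice-fluid coefficient for every unlike gas pair.
    temperature : float
        Sorption temperature, K.
    pr_components : tuple of PRComponent, optional
        Critical constants per gas; defaults are looked up by gas label.
    k_pr : float
        Peng-Robinson binary coefficient for the gas phase.
    gas_phase : {"pr", "sl"}
        Gas-phase chemical-potential reference (see module docstring).
    """

    polymer: SLParams
    gases: Tuple[SLParams, ...]
    kij_gas_polymer: Tuple[float, ...]
    kij_gas_gas: float = -0.03
    temperature: float = 308.15
    pr_components: Optional[Tuple[PRComponent, ...]] = None
    k_pr: float = 0.09
    gas_phase: str = "pr"

    def __post_init__(self):
        gases = tuple(self.gases)
        if len(gases) == 0:
            raise DomainError("at least one gas is required")
        if not self.polymer.is_polymer:
            raise DomainError("the polymer must use the infinite-chain limit")
        for g in gases:
            if g.is_polymer:
                raise DomainError(f"gas {g.label!r} must have a finite molar mass")
        kij = tuple(float(k) for k in self.kij_gas_polymer)
        if len(kij) != len(gases):
            raise DomainError("one gas-polymer kij per gas is required")
        for k in kij + (float(self.kij_gas_gas),):
            if abs(k) > _KIJ_BAND:
                raise DomainError(f"|kij| must not exceed {_KIJ_BAND}, got {k!r}")
        if self.gas_phase not in ("pr", "sl"):
            raise DomainError(f"unknown gas_phase {self.gas_phase!r}")
        if not (self.temperature > 0.0):
            raise DomainError("temperature must be positive")
        pr = self.pr_components
        if pr is None:
            try:
                pr = tuple(_DEFAULT_PR[g.label] for g in gases)
            except KeyError as exc:
                raise DomainError(
                    f"no default critical constants for gas {exc.args[0]!r}; "
                    "pass pr_components explicitly"
                ) from None
        else:
            pr = tuple(pr)
            if len(pr) != len(gases):
                raise DomainError("one PRComponent per gas is required")
        object.__setattr__(self, "gases", gases)
        object.__setattr__(self, "kij_gas_polymer", kij)
        object.__setattr__(self, "pr_components", pr)

    @property
    def n_gases(self):
        return len(self.gases)

    @property
    def gas_labels(self):
        return tuple(g.label for g in self.gases)

    def with_kij(self, gas_index, value):
        """Copy of the system with one gas-polymer kij replaced."""
        kij = list(self.kij_gas_polymer)
        kij[gas_index] = float(value)
        return replace(self, kij_gas_polymer=tuple(kij))

    def pure_subsystem(self, gas_index):
        """Single-gas system for gas ``gas_index`` keeping its kij."""
        return replace(
            self,
            gases=(self.gases[gas_index],),
            kij_gas_polymer=(self.kij_gas_polymer[gas_index],),
            pr_components=(self.pr_components[gas_index],),
        )

    def kij_matrix(self):
        """Full (gases + polymer) lattice interaction matrix."""
        n = self.n_gases
        kij = np.full((n + 1, n + 1), float(self.kij_gas_gas))
        np.fill_diagonal(kij, 0.0)
        kij[:n, n] = self.kij_gas_polymer
        kij[n, :n] = self.kij_gas_polymer
        return tuple(tuple(row) for row in kij)

    def mixture_state(self, gas_mass_fractions):
        """Polymer-phase :class:`MixtureState` at the given gas loadings."""
        w = np.asarray(gas_mass_fractions, dtype=float)
        if w.shape != (self.n_gases,):
            raise DomainError("one mass fraction per gas is required")
        fractions = tuple(w) + (1.0 - float(w.sum()),)
        return MixtureState(
            components=self.gases + (self.polymer,),
            mass_fractions=fractions,
            kij_matrix=self.kij_matrix(),
        )

    def reference_density(self):
        """Unpenetrated polymer density at (T, 1 bar), g/cm3."""
        return solve_density(self.polymer, self.temperature, P_REFERENCE, "liquid")


@dataclass(frozen=True)
class SorptionResult:
    """Sorption equilibrium at one state point.

    Per-gas arrays are aligned with ``gas_labels``.  ``fugacities`` are in
    bar, ``concentrations`` in cm3(STP)/cm3 of unpenetrated polymer,
    ``density_change`` in percent (polymer-partial basis; see module
    docstring).  ``selectivity`` is S_1/S_2 for two-gas systems at
    positive fugacity, else ``None``.
    """

    temperature: float
    p_total: float
    gas_labels: Tuple[str, ...]
    mole_fractions: Tuple[float, ...]
    fugacities: Tuple[float, ...]
    mass_fractions: Tuple[float, ...]
    concentrations: Tuple[float, ...]
    mixture_density: float
    polymer_partial_density: float
    reference_density: float
    density_change: float
    selectivity: Optional[float]
    mu_residuals: Tuple[float, ...]

    @property
    def solubility_coefficients(self):
        """Per-gas S = c/f in cm3(STP) cm-3 bar-1 (nan at zero fugacity)."""
        return tuple(
            c / f if f > 0.0 else math.nan
            for c, f in zip(self.concentrations, self.fugacities)
        )


@dataclass(frozen=True)
class CrystallinityContext:
    """Crystalline mass fraction of a semicrystalline sample."""

    x_c: float

    def __post_init__(self):
        if not (0.0 <= self.x_c < 1.0):
            raise DomainError(f"x_c must lie in [0, 1), got {self.x_c!r}")


def _gas_phase_targets(system, p_total, y, fugacities):
    """Target mu/RT per gas (nan for absent gases)."""
    T = system.temperature
    targets = np.full(system.n_gases, math.nan)
    active = [i for i, yi in enumerate(y) if yi > 0.0]
    if system.gas_phase == "pr":
        for i in active:
            targets[i] = ideal_gas_mu(system.gases[i], T, fugacities[i])
        return targets
    # Lattice-fluid gas phase at (T, p_total, y): mole -> mass fractions.
    masses = np.array([system.gases[i].molar_mass for i in active])
    ya = np.array([y[i] for i in active])
    w = ya * masses / float(ya @ masses)
    n = len(active)
    kij = np.full((n, n), float(system.kij_gas_gas))
    np.fill_diagonal(kij, 0.0)
    state = MixtureState(
        components=tuple(system.gases[i] for i in active),
        mass_fractions=tuple(w),
        kij_matrix=tuple(tuple(row) for row in kij),
    )
    for slot, i in enumerate(active):
        targets[i] = chemical_potential(state, slot, T, p_total, phase_hint="vapor")
    return targets


def _polymer_phase_mu(system, w_active, active, p_total):
    """mu/RT of the active gases in the polymer phase at loadings w_active."""
    w = np.zeros(system.n_gases)
    w[active] = w_active
    state = solve_mixture(
        system.mixture_state(w), system.temperature, p_total, phase_hint="liquid"
    )
    return np.array(
        [chemical_potential(state, i, system.temperature, p_total) for i in active]
    ), state


def _solve_single(system, active_index, p_total, target, w_start=None):
    """1-D bracketed solve for one dissolved gas; returns its mass fraction."""

    def residual(lw):
        mu, _ = _polymer_phase_mu(system, [math.exp(lw)], [active_index], p_total)
        return mu[0] - target

    lo, hi = math.log(1e-14), math.log(0.75)
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0.0:
        raise ConvergenceError(
            f"single-gas sorption bracket failed at p={p_total} MPa",
            residual=min(abs(flo), abs(fhi)),
        )
    lw = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return math.exp(lw)


def _solve_multi(system, active, p_total, targets, w_start):
    """Newton-type solve in log mass fractions for several dissolved gases."""

    def residuals(x):
        mu, _ = _polymer_phase_mu(system, np.exp(x), active, p_total)
        return mu - targets

    x0 = np.log(np.maximum(w_start, 1e-13))
    sol = root(residuals, x0, method="hybr", tol=1e-13)
    res = residuals(sol.x)
    if np.max(np.abs(res)) > _MU_TOL:
        raise ConvergenceError(
            f"mixed-gas sorption solver residual {np.max(np.abs(res)):.3g} "
            f"exceeds {_MU_TOL} at p={p_total} MPa",
            last_iterate=np.exp(sol.x),
            residual=float(np.max(np.abs(res))),
        )
    return np.exp(sol.x)


def _trivial_result(system, y):
    rho0 = system.reference_density()
    n = system.n_gases
    return SorptionResult(
        temperature=system.temperature,
        p_total=0.0,
        gas_labels=system.gas_labels,
        mole_fractions=tuple(y),
        fugacities=(0.0,) * n,
        mass_fractions=(0.0,) * n,
        concentrations=(0.0,) * n,
        mixture_density=rho0,
        polymer_partial_density=rho0,
        reference_density=rho0,
        density_change=0.0,
        selectivity=None,
        mu_residuals=(0.0,) * n,
    )


def solve_sorption(system, p_total, gas_mole_fractions=None):
    """Sorption equilibrium of ``system`` at total pressure ``p_total`` (MPa).

    ``gas_mole_fractions`` is the external gas-phase composition over the
    system's gases (defaults to pure gas for a single-gas system).  A zero
    total pressure returns the trivial zero-sorption result.

    Raises
    ------
    ConvergenceError
        If the chemical-potential equality cannot be satisfied to 1e-8,
        even after pressure continuation; carries the last iterate.
    """
    n = system.n_gases
    if gas_mole_fractions is None:
        if n != 1:
            raise DomainError("gas_mole_fractions is required for multi-gas systems")
        y = np.array([1.0])
    else:
        y = np.asarray(gas_mole_fractions, dtype=float)
        if y.shape != (n,):
            raise DomainError(f"expected {n} gas mole fractions")
        if np.any(y < 0.0) or abs(y.sum() - 1.0) > 1e-8:
            raise DomainError("gas mole fractions must be nonnegative and sum to 1")
    if p_total < 0.0:
        raise DomainError("p_total must be nonnegative")
    if p_total == 0.0:
        return _trivial_result(system, y)

    T = system.temperature
    spec = GasMixtureSpec(system.pr_components, tuple(y), system.k_pr)
    fug = pr_fugacity(spec, T, p_total)
    targets = _gas_phase_targets(system, p_total, y, fug)
    active = [i for i in range(n) if y[i] > 0.0]

    if len(active) == 1:
        i = active[0]
        w_active = np.array([_solve_single(system, i, p_total, targets[i])])
    else:
        # Start from the pure-gas loadings at the partial fugacities.
        w_start = np.array(
            [
                _solve_single(system, i, p_total, targets[i])
                if np.isfinite(targets[i])
                else 0.0
                for i in active
            ]
        )
        try:
            w_active = _solve_multi(system, active, p_total, targets[active], w_start)
        except ConvergenceError:
            # Pressure continuation from a quarter of the target pressure.
            w_active = w_start
            for frac in (0.25, 0.5, 0.75, 1.0):
                p_step = frac * p_total
                fug_step = pr_fugacity(spec, T, p_step)
                targets_step = _gas_phase_targets(system, p_step, y, fug_step)
                w_active = _solve_multi(
                    system, active, p_step, targets_step[active], w_active
                )

    w = np.zeros(n)
    w[active] = w_active
    state = solve_mixture(system.mixture_state(w), T, p_total, phase_hint="liquid")
    mu_res = np.zeros(n)
    for slot, i in enumerate(active):
        mu_res[i] = chemical_potential(state, i, T, p_total) - targets[i]

    rho_mix = mixture_density(state, T, p_total)
    w_polymer = 1.0 - float(w.sum())
    rho_partial = rho_mix * w_polymer
    rho0 = system.reference_density()
    conc = np.array(
        [
            V_STP * w[i] / (w_polymer * system.gases[i].molar_mass) * rho0
            for i in range(n)
        ]
    )
    fug_bar = fug * MPA_TO_BAR
    selectivity = None
    if n == 2 and all(f > 0.0 for f in fug_bar):
        s = conc / fug_bar
        if s[1] > 0.0:
            selectivity = float(s[0] / s[1])
    return SorptionResult(
        temperature=T,
        p_total=float(p_total),
        gas_labels=system.gas_labels,
        mole_fractions=tuple(float(v) for v in y),
        fugacities=tuple(float(v) for v in fug_bar),
        mass_fractions=tuple(float(v) for v in w),
        concentrations=tuple(float(v) for v in conc),
        mixture_density=float(rho_mix),
        polymer_partial_density=float(rho_partial),
        reference_density=float(rho0),
        density_change=float(100.0 * (rho_partial - rho0) / rho0),
        selectivity=selectivity,
        mu_residuals=tuple(float(v) for v in mu_res),
    )


def solubility_coefficient(result, gas_index):
    """S = c/f for one gas of a :class:`SorptionResult`, per bar.

    Raises
    ------
    DomainError
        At zero fugacity, where S is undefined.
    """
    f = result.fugacities[gas_index]
    if f <= 0.0:
        raise DomainError("solubility coefficient is undefined at zero fugacity")
    return result.concentrations[gas_index] / f


def solubility_selectivity(s_i, s_j):
    """Solubility-selectivity S_i / S_j of two solubility coefficients."""
    if s_j == 0.0:
        raise DomainError("selectivity is undefined for S_j = 0")
    return s_i / s_j


def pure_gas_isotherm(system, gas_index, pressures):
    """Single-gas isotherm table over total pressures (MPa).

    Columns: p_MPa, fugacity_bar, mass_fraction, concentration,
    solubility, mixture_density, density_change_pct.
    """
    sub = system.pure_subsystem(gas_index)
    rows = []
    for p in pressures:
        res = solve_sorption(sub, float(p))
        rows.append(
            {
                "p_MPa": float(p),
                "fugacity_bar": res.fugacities[0],
                "mass_fraction": res.mass_fractions[0],
                "concentration": res.concentrations[0],
                "solubility": res.solubility_coefficients[0],
                "mixture_density": res.mixture_density,
                "density_change_pct": res.density_change,
            }
        )
    return pd.DataFrame(rows)


def mixed_vs_ideal_selectivity(system, pressures, y_first):
    """Ideal vs mixed-gas solubility-selectivity along a pressure grid.

    ``y_first`` is the gas-phase mole fraction of the first gas.  The
    ideal selectivity at each total pressure is the ratio of the pure-gas
    solubility coefficients, each evaluated for the pure gas at that same
    total pressure; the mixed-gas value comes from the binary equilibrium.

    Returns a DataFrame with columns p_MPa, ideal_selectivity,
    mixed_selectivity, percent_decrease.
    """
    if system.n_gases != 2:
        raise DomainError("mixed_vs_ideal_selectivity needs a two-gas system")
    if not (0.0 < y_first < 1.0):
        raise DomainError("y_first must lie strictly inside (0, 1)")
    sub0 = system.pure_subsystem(0)
    sub1 = system.pure_subsystem(1)
    rows = []
    for p in pressures:
        p = float(p)
        r0 = solve_sorption(sub0, p)
        r1 = solve_sorption(sub1, p)
        ideal = solubility_selectivity(
            solubility_coefficient(r0, 0), solubility_coefficient(r1, 0)
        )
        mixed = solve_sorption(system, p, (y_first, 1.0 - y_first)).selectivity
        rows.append(
            {
                "p_MPa": p,
                "ideal_selectivity": ideal,
                "mixed_selectivity": mixed,
                "percent_decrease": 100.0 * (1.0 - mixed / ideal),
            }
        )
    return pd.DataFrame(rows)


def sensitivity_sweep(system, pressures, gas_mole_fractions=None,
                      kij_values=(-0.05, -0.01, 0.0, 0.01, 0.05)):
    """Sensitivity of sorption to the gas-polymer interaction coefficients.

    For each gas in turn, its kij is stepped through ``kij_values`` with
    every other gas-polymer coefficient set to zero, and sorption is
    recomputed over ``pressures`` at the fixed external composition.
    Percent deviations are reported against the all-zero-kij reference at
    the same pressure.

    Returns a long-format DataFrame with columns: varied_gas, kij, p_MPa,
    one ``conc_<label>`` and ``dev_<label>_pct`` pair per gas, and
    ``selectivity`` (two-gas systems).
    """
    n = system.n_gases
    zero = system
    for i in range(n):
        zero = zero.with_kij(i, 0.0)
    baseline = {
        float(p): solve_sorption(zero, float(p), gas_mole_fractions)
        for p in pressures
    }
    rows = []
    labels = system.gas_labels
    for varied in range(n):
        for k in kij_values:
            trial = zero.with_kij(varied, float(k))
            for p in pressures:
                p = float(p)
                res = solve_sorption(trial, p, gas_mole_fractions)
                ref = baseline[p]
                row = {"varied_gas": labels[varied], "kij": float(k), "p_MPa": p}
                for i, lab in enumerate(labels):
                    c, c0 = res.concentrations[i], ref.concentrations[i]
                    row[f"conc_{lab}"] = c
                    row[f"dev_{lab}_pct"] = (
                        100.0 * (c - c0) / c0 if c0 > 0.0 else math.nan
                    )
                if n == 2:
                    row["selectivity"] = res.selectivity
                rows.append(row)
    return pd.DataFrame(rows)


def amorphous_rescale(s_semicrystalline, ctx):
    """Amorphous-phase solubility from the semicrystalline value.

    ``S_am = S_sc / (1 - x_c)`` — sorption is attributed entirely to the
    amorphous fraction.
    """
    if not isinstance(ctx, CrystallinityContext):
        ctx = CrystallinityContext(float(ctx))
    return s_semicrystalline / (1.0 - ctx.x_c)


@dataclass(frozen=True)
class KijFitResult:
    """Outcome of a gas-polymer kij fit."""

    kij: float
    objective: float
    converged: bool


def fit_gas_polymer_kij(system, gas_index, observations, bound=_KIJ_BAND):
    """Fit one gas-polymer kij to observed pure-gas solubility coefficients.

    ``observations`` is a sequence of ``(p_total_MPa, S_obs)`` pairs with
    S in cm3(STP) cm-3 bar-1.  A bounded one-dimensional minimisation of
    the summed squared relative S error is used; the box is ±``bound``.
    """
    obs = [(float(p), float(s)) for p, s in observations]
    if not obs:
        raise DomainError("at least one observation is required")
    if any(s <= 0.0 for _, s in obs):
        raise DomainError("observed solubility coefficients must be positive")
    sub = system.pure_subsystem(gas_index)

    def objective(k):
        trial = sub.with_kij(0, float(k))
        total = 0.0
        for p, s_obs in obs:
            s_pred = solubility_coefficient(solve_sorption(trial, p), 0)
            total += ((s_pred - s_obs) / s_obs) ** 2
        return total

    result = minimize_scalar(
        objective, bounds=(-bound, bound), method="bounded",
        options={"xatol": 1e-9},
    )
    return KijFitResult(
        kij=float(result.x),
        objective=float(result.fun),
        converged=bool(result.success),
    )
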