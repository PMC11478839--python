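"""Fitting Sanchez-Lacombe parameters to PVT data by MAPE minimisation.

The characteristic triple (T*, p*, rho*) of a polymer is regressed against
replicated (T, p, rho) observations by minimising the mean absolute
percentage error of the predicted equilibrium densities.  Two interfaces
are provided:

* :class:`SanchezLacombePVT` — a scikit-learn-style estimator with
  ``fit(X, y)`` / ``predict(X)`` / ``score(X, y)`` and ``get_params`` /
  ``set_params``, where ``X`` is an (n, 2) array of (T in K, p in MPa) and
  ``y`` the densities in g/cm3;
* :func:`fit_sl_params` — a dataset-level wrapper returning a
  :class:`FitResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import DomainError, NoDensityRootError
from .eos import SLParams, solve_density

__all__ = [
    "PVT_COLUMNS",
    "PVTDataset",
    "FitResult",
    "mape",
    "r_squared",
    "SanchezLacombePVT",
    "fit_sl_params",
]

#: Canonical column names of the PVT table dialect.
PVT_COLUMNS = ("T_K", "p_MPa", "rho_g_cm3", "replicate")

DEFAULT_INITIAL = (800.0, 550.0, 1.2)
DEFAULT_BOUNDS = ((300.0, 1500.0), (100.0, 1200.0), (0.8, 1.6))


@dataclass(frozen=True)
class PVTDataset:
    """Replicated PVT observations for one polymer.

    ``data`` holds one row per observation with the columns of
    :data:`PVT_COLUMNS`; replicate ids partition the rows.  At least four
    distinct (T, p) states are required for a parameter fit.
    """

    polymer_id: str
    hv_mol_percent: float
    data: pd.DataFrame

    def __post_init__(self):
        frame = self.data
        missing = [c for c in PVT_COLUMNS if c not in frame.columns]
        if missing:
            raise DomainError(f"PVT data missing columns: {missing}")
        if len(frame) == 0:
            raise DomainError("PVT dataset is empty")
        for col in ("T_K", "p_MPa", "rho_g_cm3"):
            values = frame[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(values)) or np.any(values <= 0.0):
                raise DomainError(f"column {col} must be positive and finite")
        object.__setattr__(self, "data", frame.reset_index(drop=True))

    @property
    def n_points(self):
        return len(self.data)

    def states(self):
        """(n, 2) array of (T, p) observation states."""
        return self.data[["T_K", "p_MPa"]].to_numpy(dtype=float)

    def densities(self):
        """Observed densities, g/cm3."""
        return self.data["rho_g_cm3"].to_numpy(dtype=float)

    def n_distinct_states(self):
        return len(self.data[["T_K", "p_MPa"]].drop_duplicates())

    def replicate_means(self):
        """Dataset averaged over replicates at each (T, p) state."""
        grouped = (
            self.data.groupby(["T_K", "p_MPa"], as_index=False)["rho_g_cm3"]
            .mean()
            .assign(replicate=0)
        )
        return PVTDataset(self.polymer_id, self.hv_mol_percent, grouped[list(PVT_COLUMNS)])


@dataclass(frozen=True)
class FitResult:
    """Outcome of a Sanchez-Lacombe PVT fit."""

    params: SLParams
    mape: float
    r_squared: float
    n_points: int
    converged: bool
    n_iter: int = 0

    def __post_init__(self):
        if self.mape < 0.0:
            raise DomainError("mape must be nonnegative")
        if self.r_squared > 1.0:
            raise DomainError("r_squared cannot exceed 1")


def mape(observed, predicted):
    """Mean absolute percentage error, in percent.

    ``100/N * sum |obs - pred| / |obs|`` over paired values.

    Raises
    ------
    DomainError
        On length mismatch, empty input, or a zero observed value.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DomainError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise DomainError("mape of empty lists is undefined")
    if np.any(obs == 0.0):
        raise DomainError("mape is undefined for zero observed values")
    return float(100.0 * np.mean(np.abs(obs - pred) / np.abs(obs)))


def r_squared(observed, predicted):
    """Coefficient of determination, 1 - SS_res/SS_tot.

    Raises
    ------
    DomainError
        For fewer than two points or a constant observed list.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DomainError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise DomainError("r_squared needs at least two points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("r_squared is undefined for constant observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


class SanchezLacombePVT:
    """Estimator fitting (T*, p*, rho*) to PVT observations.

    A derivative-free simplex search minimises the MAPE between observed
    densities and :func:`slsorb.eos.solve_density` predictions in the
    polymer (infinite-chain) limit.  The fit is deterministic for a given
    dataset, initial guess and solver settings.

    Parameters
    ----------
    initial : tuple of float
        Starting (T* K, p* MPa, rho* g/cm3).
    bounds : tuple of (low, high)
        Box constraints for the three parameters.
    tol : float
        Convergence tolerance on the objective.
    max_iter : int
        Simplex iteration budget; exhaustion is flagged, never silent.

    Attributes (after ``fit``)
    --------------------------
    params_ : SLParams
    mape_ : float            fit MAPE over the training points, percent
    r_squared_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, initial=DEFAULT_INITIAL, bounds=DEFAULT_BOUNDS,
                 tol=1e-10, max_iter=5000):
        self.initial = initial
        self.bounds = bounds
        self.tol = tol
        self.max_iter = max_iter

    # -- scikit-learn estimator plumbing ---------------------------------
    def get_params(self, deep=True):
        return {
            "initial": self.initial,
            "bounds": self.bounds,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- core -------------------------------------------------------------
    @staticmethod
    def _validate_xy(X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise DomainError(f"X must have shape (n, 2) of (T, p), got {X.shape}")
        if y.shape != (X.shape[0],):
            raise DomainError("y must be one density per row of X")
        if np.any(X <= 0.0) or np.any(y <= 0.0):
            raise DomainError("temperatures, pressures and densities must be positive")
        return X, y

    @staticmethod
    def _predict_states(theta, states):
        """Densities at the distinct states for trial parameters theta."""
        params = SLParams.polymer(*theta)
        return np.array(
            [solve_density(params, T, p, phase_hint="liquid") for T, p in states]
        )

    def _objective_factory(self, X, y):
        # Density solves depend only on the distinct (T, p) states, so
        # evaluate each state once per trial point and broadcast back.
        states, inverse = np.unique(X, axis=0, return_inverse=True)

        def objective(theta):
            try:
                pred = self._predict_states(theta, states)[inverse]
            except NoDensityRootError:
                return 1e6
            return mape(y, pred)

        return objective

    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        if len(np.unique(X, axis=0)) < 4:
            raise DomainError("at least 4 distinct (T, p) states are required")
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        x0 = np.clip(np.asarray(self.initial, dtype=float), lo, hi)
        objective = self._objective_factory(X, y)
        result = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={
                "fatol": self.tol,
                "xatol": 1e-8,
                "maxiter": self.max_iter,
                "maxfev": 4 * self.max_iter,
            },
        )
        self.params_ = SLParams.polymer(*result.x)
        predicted = self.predict(X)
        self.mape_ = mape(y, predicted)
        self.r_squared_ = r_squared(y, predicted) if len(y) >= 2 else math.nan
        self.converged_ = bool(result.success)
        self.n_iter_ = int(result.nit)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit(X, y) first")
        states, inverse = np.unique(X, axis=0, return_inverse=True)
        theta = (self.params_.Tstar, self.params_.pstar, self.params_.rhostar)
        return self._predict_states(theta, states)[inverse]

    def score(self, X, y):
        """Coefficient of determination of the prediction."""
        return r_squared(y, self.predict(X))


def fit_sl_params(dataset, initial=None, bounds=DEFAULT_BOUNDS,
                  aggregate="points", tol=1e-10, max_iter=5000):
    """Fit SL parameters to a :class:`PVTDataset` and report diagnostics.

    Parameters
    ----------
    dataset : PVTDataset
    initial : SLParams or tuple, optional
        Starting point; defaults to (800 K, 550 MPa, 1.2 g/cm3).
    bounds : parameter box
    aggregate : {"points", "replicate_means"}
        Fit to every replicate point (default) or to replicate-mean
        densities; diagnostics are reported on the same basis.
    """
    if aggregate == "replicate_means":
        dataset = dataset.replicate_means()
    elif aggregate != "points":
        raise DomainError(f"unknown aggregate mode {aggregate!r}")
    if dataset.n_distinct_states() < 4:
        raise DomainError("at least 4 distinct (T, p) states are required")
    if initial is None:
        initial = DEFAULT_INITIAL
    elif isinstance(initial, SLParams):
        initial = (initial.Tstar, initial.pstar, initial.rhostar)
    estimator = SanchezLacombePVT(
        initial=tuple(initial), bounds=bounds, tol=tol, max_iter=max_iter
    )
    estimator.fit(dataset.states(), dataset.densities())
    return FitResult(
        params=SLParams.polymer(
            estimator.params_.Tstar,
            estimator.params_.pstar,
            estimator.params_.rhostar,
            label=dataset.polymer_id,
        ),
        mape=estimator.mape_,
        r_squared=estimator.r_squared_,
        n_points=dataset.n_points,
        converged=estimator.converged_,
        n_iter=estimator.n_iter_,
    )
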