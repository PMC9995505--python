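"""Meta-model (Model 2): an MLP mapping clock parameters to dispersion.

After the parameter sweep, every grid cell pairs a 4-vector of clock
parameters (attention horizon, hidden size, epochs, Fahlman offset) with
the temporal dispersion coefficient the trained clock produced.  A
feed-forward multilayer perceptron is fitted to that mapping so the
influence of each parameter can be treated as a continuous dimension —
the meta-model can be queried between the simulated grid values.

The hidden architecture is found by a constrained enumeration rather than
an open-ended search: totals of 8-28 hidden neurons, each additional layer
strictly smaller than the one before it and never smaller than 3 neurons.
The candidate minimising training MSE wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.neural_network import MLPRegressor

__all__ = [
    "PARAMETER_COLUMNS",
    "NormalizedGrid",
    "MetaArchitecture",
    "FitMetrics",
    "MetaModel",
    "PredictionResult",
    "normalize_grid",
    "architecture_candidates",
    "train_meta",
    "select_architecture",
    "predict_dispersion",
]

#: Sweep-table columns holding the four clock parameters, in input order.
PARAMETER_COLUMNS: tuple[str, ...] = ("attention", "hidden", "epochs", "offset")


@dataclass(frozen=True)
class NormalizedGrid:
    """Sweep cells with parameters min-max scaled to [0, 1].

    ``X`` has one row per grid cell and one column per clock parameter;
    each column's minimum maps to 0 and maximum to 1.  ``y`` holds the
    paired dispersion coefficients.  The scaling constants are kept so raw
    parameter values can be mapped in (and normalized ones mapped back).
    """

    X: np.ndarray
    y: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    columns: tuple[str, ...] = PARAMETER_COLUMNS

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        return (raw - self.mins) / (self.maxs - self.mins)

    def denormalize(self, scaled: np.ndarray) -> np.ndarray:
        scaled = np.atleast_2d(np.asarray(scaled, dtype=float))
        return scaled * (self.maxs - self.mins) + self.mins


class MetaArchitecture(NamedTuple):
    """Hidden-layer sizes of a candidate meta-MLP."""

    layers: tuple[int, ...]

    @property
    def total_neurons(self) -> int:
        return sum(self.layers)


@dataclass(frozen=True)
class FitMetrics:
    """Training-set goodness of fit of a fitted meta-MLP."""

    r_squared: float
    mse: float
    mae: float
    converged: bool = True


class PredictionResult(NamedTuple):
    """Dispersion prediction plus an extrapolation flag."""

    value: float
    extrapolated: bool


@dataclass
class MetaModel:
    """A fitted meta-MLP together with its input scaling constants."""

    regressor: MLPRegressor
    grid: NormalizedGrid
    architecture: MetaArchitecture
    metrics: FitMetrics

    def predict_normalized(self, X_scaled: np.ndarray) -> np.ndarray:
        return self.regressor.predict(np.atleast_2d(X_scaled))


def normalize_grid(
    table: pd.DataFrame,
    target_column: str = "slope",
    columns: Sequence[str] = PARAMETER_COLUMNS,
) -> NormalizedGrid:
    """Min-max scale the four parameter columns of a sweep table to [0, 1]."""
    missing = [c for c in [*columns, target_column] if c not in table.columns]
    if missing:
        raise ValueError(f"sweep table missing columns: {missing}")
    X_raw = table.loc[:, list(columns)].to_numpy(dtype=float)
    mins = X_raw.min(axis=0)
    maxs = X_raw.max(axis=0)
    constant = [c for c, lo, hi in zip(columns, mins, maxs) if lo == hi]
    if constant:
        raise ValueError(
            f"cannot normalize constant parameter column(s): {constant}"
        )
    X = (X_raw - mins) / (maxs - mins)
    y = table[target_column].to_numpy(dtype=float)
    return NormalizedGrid(X=X, y=y, mins=mins, maxs=maxs, columns=tuple(columns))


def architecture_candidates(
    min_total: int = 8, max_total: int = 28, min_layer: int = 3
) -> list[MetaArchitecture]:
    """Enumerate admissible hidden architectures in a fixed linear order.

    Constraints: total hidden neurons within [min_total, max_total]; each
    successive layer strictly smaller than the previous; no layer below
    ``min_layer`` neurons.  Ordered by depth, then lexicographically by
    layer sizes, so single hidden layers of 8..28 come first.
    """

    def extend(prefix: tuple[int, ...]) -> list[tuple[int, ...]]:
        found = []
        total = sum(prefix)
        upper = (prefix[-1] - 1) if prefix else max_total
        for size in range(min_layer, min(upper, max_total - total) + 1):
            layers = prefix + (size,)
            if sum(layers) >= min_total:
                found.append(layers)
            found.extend(extend(layers))
        return found

    all_layers = extend(())
    all_layers.sort(key=lambda ls: (len(ls), ls))
    return [MetaArchitecture(ls) for ls in all_layers]


def _fit_metrics(reg: MLPRegressor, X: np.ndarray, y: np.ndarray) -> FitMetrics:
    pred = reg.predict(X)
    converged = reg.n_iter_ < reg.max_iter
    return FitMetrics(
        r_squared=float(r2_score(y, pred)),
        mse=float(mean_squared_error(y, pred)),
        mae=float(mean_absolute_error(y, pred)),
        converged=bool(converged),
    )


def train_meta(
    grid: NormalizedGrid,
    arch: MetaArchitecture | Sequence[int],
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
    restarts: int = 3,
    solver: str = "lbfgs",
) -> tuple[MetaModel, FitMetrics]:
    """Fit one candidate architecture; the best of ``restarts`` seeded fits.

    Logistic (sigmoid) hidden units, a linear output unit and bias units in
    every layer.  Training stops on an MSE-change tolerance or the
    iteration cap; non-convergence is recorded in the metrics, not raised.
    """
    if not isinstance(arch, MetaArchitecture):
        arch = MetaArchitecture(tuple(int(n) for n in arch))
    if grid.X.shape[0] == 0:
        raise ValueError("normalized grid is empty")
    best: tuple[MLPRegressor, FitMetrics] | None = None
    for r in range(max(1, restarts)):
        reg = MLPRegressor(
            hidden_layer_sizes=arch.layers,
            activation="logistic",
            solver=solver,
            max_iter=max_iter,
            tol=tol,
            random_state=seed + 1000 * r,
            momentum=0.9,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            reg.fit(grid.X, grid.y)
        metrics = _fit_metrics(reg, grid.X, grid.y)
        if best is None or metrics.mse < best[1].mse:
            best = (reg, metrics)
    reg, metrics = best
    model = MetaModel(regressor=reg, grid=grid, architecture=arch, metrics=metrics)
    return model, metrics


def select_architecture(
    grid: NormalizedGrid,
    candidates: Sequence[MetaArchitecture] | None = None,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
    restarts: int = 3,
) -> MetaModel:
    """Train every candidate with the same seed policy; keep the minimum-MSE
    model.  Ties break toward fewer total hidden neurons, then toward the
    earlier candidate in enumeration order."""
    if candidates is None:
        candidates = architecture_candidates()
    if len(candidates) == 0:
        raise ValueError("no candidate architectures supplied")
    best_model: MetaModel | None = None
    best_key: tuple | None = None
    for order, arch in enumerate(candidates):
        model, metrics = train_meta(
            grid, arch, seed=seed, max_iter=max_iter, tol=tol, restarts=restarts
        )
        key = (metrics.mse, model.architecture.total_neurons, order)
        if best_key is None or key < best_key:
            best_model, best_key = model, key
    return best_model


def predict_dispersion(
    model: MetaModel, params4: Sequence[float]
) -> PredictionResult:
    """Predict the dispersion coefficient for raw parameter values.

    Inputs are normalized with the stored scaling constants before the net
    is evaluated.  Inputs outside the training min-max box are still
    evaluated but flagged as extrapolated.
    """
    raw = np.asarray(params4, dtype=float).reshape(1, -1)
    if raw.shape[1] != model.grid.X.shape[1]:
        raise ValueError(
            f"expected {model.grid.X.shape[1]} parameter values, got {raw.shape[1]}"
        )
    scaled = model.grid.normalize(raw)
    extrapolated = bool((scaled < 0).any() or (scaled > 1).any())
    if extrapolated:
        warnings.warn(
            "parameter values lie outside the training grid; "
            "the meta-model is extrapolating",
            stacklevel=2,
        )
    value = float(model.predict_normalized(scaled)[0])
    return PredictionResult(value=value, extrapolated=extrapolated)
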