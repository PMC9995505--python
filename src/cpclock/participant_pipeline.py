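"""Model 3: from neuropsychological scores to predicted temporal errors.

Two stages in series.  A *prior* MLP maps five participant features (four
neuropsychological scores and age in months, min-max scaled over the
cohort) to the four clock parameters on the normalized [0, 1] scale.  A
*frozen* MLP — the fitted meta-model from the parameter sweep — maps those
four parameters to a temporal dispersion coefficient.  Only the prior
stage trains; gradients flow through the frozen stage but never modify
it.  The training signal is the absolute relative reproduction error of
each retained production, |reproduced - target| / target, after Tukey
1.5-IQR cleaning per age group.

The frozen-through training has no off-the-shelf implementation, so the
composite forward/backward pass is written out explicitly over plain
weight arrays; sklearn-fitted meta models are exported into that form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .meta_mlp import MetaArchitecture, MetaModel, FitMetrics

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "FeedForwardNet",
    "CompositeModel",
    "CleanedTrials",
    "absolute_error",
    "iqr_filter",
    "build_composite",
    "train_composite",
    "search_prior_architecture",
    "prior_architecture_candidates",
]

#: Participant features feeding the prior MLP, in input order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "stm",
    "wm",
    "attention",
    "processing_speed",
    "age_months",
)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class FeedForwardNet:
    """Plain fully-connected net: logistic hidden layers, configurable output.

    ``weights[k]`` has shape (fan_in, fan_out) and ``biases[k]`` shape
    (fan_out,); ``output`` is ``"identity"`` or ``"logistic"``.
    """

    weights: list
    biases: list
    output: str = "identity"

    def __post_init__(self) -> None:
        if self.output not in ("identity", "logistic"):
            raise ValueError("output must be 'identity' or 'logistic'")
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair up")

    @classmethod
    def from_sklearn(cls, model: MetaModel) -> "FeedForwardNet":
        """Export a fitted sklearn meta-MLP into plain arrays."""
        reg = model.regressor
        return cls(
            weights=[w.copy() for w in reg.coefs_],
            biases=[b.copy() for b in reg.intercepts_],
            output="identity",
        )

    @classmethod
    def random(
        cls,
        layer_sizes: Sequence[int],
        rng: np.random.Generator,
        output: str = "identity",
        scale: float = 0.5,
    ) -> "FeedForwardNet":
        sizes = list(layer_sizes)
        weights = [
            rng.uniform(-scale, scale, size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        biases = [rng.uniform(-scale, scale, size=b) for b in sizes[1:]]
        return cls(weights=weights, biases=biases, output=output)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    def forward(self, X: np.ndarray) -> np.ndarray:
        return self.forward_all(X)[-1]

    def forward_all(self, X: np.ndarray) -> list:
        """Activations of every layer, input first; X is (n, fan_in)."""
        acts = [np.atleast_2d(np.asarray(X, dtype=float))]
        n_layers = len(self.weights)
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ W + b
            last = k == n_layers - 1
            if last and self.output == "identity":
                acts.append(z)
            else:
                acts.append(_sigmoid(z))
        return acts

    def backward_input(self, acts: list, grad_out: np.ndarray) -> np.ndarray:
        """Gradient of the loss w.r.t. the net's *input*, weights untouched.

        ``grad_out`` is dLoss/d(output), shape (n, fan_out).
        """
        g = np.atleast_2d(grad_out)
        n_layers = len(self.weights)
        for k in range(n_layers - 1, -1, -1):
            a = acts[k + 1]
            if not (k == n_layers - 1 and self.output == "identity"):
                g = g * a * (1.0 - a)
            g = g @ self.weights[k].T
        return g

    def copy(self) -> "FeedForwardNet":
        return FeedForwardNet(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            output=self.output,
        )


def absolute_error(reproduced_s, target_s, squared: bool = False):
    """Dimensionless reproduction error |reproduced - target| / target.

    The absolute value folds under- and over-estimation together (the bias
    direction is outside the model's scope); ``squared=True`` gives the
    squared relative error instead.
    """
    target = np.asarray(target_s, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target_s must be positive")
    rel = (np.asarray(reproduced_s, dtype=float) - target) / target
    out = rel**2 if squared else np.abs(rel)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CleanedTrials:
    """Result of Tukey 1.5-IQR rejection: fences computed once, applied once."""

    retained: pd.DataFrame
    rejected: pd.DataFrame
    fences: dict

    @property
    def rejection_fraction(self) -> float:
        total = len(self.retained) + len(self.rejected)
        return len(self.rejected) / total if total else 0.0


def iqr_filter(
    trials: pd.DataFrame,
    error_column: str = "error",
    group_column: str = "group",
    k: float = 1.5,
) -> CleanedTrials:
    """Reject trials outside [Q1 - k*IQR, Q3 + k*IQR] per group.

    Quartiles use linear interpolation.  Fences are computed once on the
    incoming data and applied once; they are not re-estimated on the
    retained subset.
    """
    if error_column not in trials.columns or group_column not in trials.columns:
        raise ValueError(f"trials need '{error_column}' and '{group_column}' columns")
    fences = {}
    keep = np.zeros(len(trials), dtype=bool)
    for group, sub in trials.groupby(group_column):
        if len(sub) < 4:
            raise ValueError(
                f"group {group!r} has {len(sub)} trials; need >= 4 for quartiles"
            )
        vals = sub[error_column].to_numpy(dtype=float)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        fences[group] = (float(lo), float(hi))
        keep[trials.index.get_indexer(sub.index)] = (vals >= lo) & (vals <= hi)
    retained = trials.loc[keep].copy()
    rejected = trials.loc[~keep].copy()
    logger.info(
        "IQR filter: rejected %d of %d trials (%.2f%%)",
        len(rejected),
        len(trials),
        100.0 * len(rejected) / max(len(trials), 1),
    )
    return CleanedTrials(retained=retained, rejected=rejected, fences=fences)


@dataclass
class CompositeModel:
    """Serial prior + frozen meta network.

    ``prior`` ends in a logistic layer so its four outputs live on the
    [0, 1] normalized parameter scale the frozen stage was trained on.
    ``feature_mins``/``feature_maxs`` are the cohort min-max constants for
    the five input features.
    """

    prior: FeedForwardNet
    frozen: FeedForwardNet
    feature_mins: np.ndarray | None = None
    feature_maxs: np.ndarray | None = None

    def scale_features(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_mins is None:
            return X
        span = np.where(
            self.feature_maxs > self.feature_mins,
            self.feature_maxs - self.feature_mins,
            1.0,
        )
        return (X - self.feature_mins) / span

    def clock_parameters(self, X: np.ndarray) -> np.ndarray:
        """Normalized 4-parameter vectors inferred for raw feature rows."""
        return self.prior.forward(self.scale_features(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted temporal error for raw feature rows (n, 5) -> (n,)."""
        out = self.frozen.forward(self.clock_parameters(X))
        return out[:, 0]


def prior_architecture_candidates(
    min_total: int = 5, max_total: int = 12, min_layer: int = 3
) -> list[MetaArchitecture]:
    """Prior-MLP hidden architectures: totals 5-12, same layer constraints
    as the meta search (strictly decreasing, >= 3 neurons per layer)."""
    from .meta_mlp import architecture_candidates

    return architecture_candidates(
        min_total=min_total, max_total=max_total, min_layer=min_layer
    )


def build_composite(
    prior_arch: MetaArchitecture | Sequence[int],
    meta_model: MetaModel | FeedForwardNet,
    seed: int = 0,
) -> CompositeModel:
    """Assemble the serial model with a randomly initialised prior stage."""
    if isinstance(prior_arch, MetaArchitecture):
        hidden = prior_arch.layers
    else:
        hidden = tuple(int(n) for n in prior_arch)
    frozen = (
        meta_model
        if isinstance(meta_model, FeedForwardNet)
        else FeedForwardNet.from_sklearn(meta_model)
    )
    n_params = frozen.layer_sizes[0]
    rng = np.random.default_rng(seed)
    prior = FeedForwardNet.random(
        (len(FEATURE_COLUMNS), *hidden, n_params), rng, output="logistic"
    )
    return CompositeModel(prior=prior, frozen=frozen)


@dataclass(frozen=True)
class CompositeFit:
    """Outcome of composite training."""

    model: CompositeModel
    metrics: FitMetrics
    participant_parameters: pd.DataFrame
    mse_history: np.ndarray


def _training_matrix(
    records: pd.DataFrame, trials: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    merged = trials.merge(records, on="participant_id", how="left", validate="m:1")
    missing = merged[list(FEATURE_COLUMNS)].isna().any(axis=1)
    if missing.any():
        bad = merged.loc[missing, "participant_id"].unique()
        raise ValueError(f"missing features for participants: {list(bad)[:5]}")
    X = merged.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = absolute_error(merged["reproduced_s"], merged["target_s"])
    return X, np.asarray(y, dtype=float), merged


def train_composite(
    model: CompositeModel,
    records: pd.DataFrame,
    trials: pd.DataFrame,
    epochs: int = 400,
    learning_rate: float = 0.05,
    momentum: float = 0.9,
    seed: int = 0,
    batch_size: int = 32,
) -> CompositeFit:
    """Fit the prior stage against per-production absolute errors.

    One training sample per retained production.  Mini-batch gradient
    descent with momentum updates only the prior weights; the backward
    pass propagates the squared-error gradient through the frozen stage
    via its stored weights, which are never written to.
    """
    X_raw, y, merged = _training_matrix(records, trials)
    model = CompositeModel(
        prior=model.prior.copy(),
        frozen=model.frozen,  # shared on purpose: the freeze contract
        feature_mins=X_raw.min(axis=0),
        feature_maxs=X_raw.max(axis=0),
    )
    X = model.scale_features(X_raw)
    rng = np.random.default_rng(seed)
    prior = model.prior
    vel_w = [np.zeros_like(w) for w in prior.weights]
    vel_b = [np.zeros_like(b) for b in prior.biases]
    n = X.shape[0]
    mse_history = np.empty(epochs)
    n_prior = len(prior.weights)
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], y[idx]
            prior_acts = prior.forward_all(xb)
            params = prior_acts[-1]
            frozen_acts = model.frozen.forward_all(params)
            pred = frozen_acts[-1][:, 0]
            # d(mean squared error)/d(pred), then through the frozen stage
            g_out = (2.0 * (pred - yb) / len(idx))[:, None]
            g_params = model.frozen.backward_input(frozen_acts, g_out)
            # backprop within the prior (logistic output layer)
            g = g_params
            for k in range(n_prior - 1, -1, -1):
                a = prior_acts[k + 1]
                g = g * a * (1.0 - a)
                gw = prior_acts[k].T @ g
                gb = g.sum(axis=0)
                vel_w[k] = momentum * vel_w[k] - learning_rate * gw
                vel_b[k] = momentum * vel_b[k] - learning_rate * gb
                prior.weights[k] += vel_w[k]
                prior.biases[k] += vel_b[k]
                g = g @ (prior.weights[k] - vel_w[k]).T
        mse_history[epoch] = float(np.mean((model.predict(X_raw) - y) ** 2))
    pred = model.predict(X_raw)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    metrics = FitMetrics(
        r_squared=1.0 - ss_res / ss_tot if ss_tot else 0.0,
        mse=float(np.mean((y - pred) ** 2)),
        mae=float(np.mean(np.abs(y - pred))),
        converged=True,
    )
    per_participant = records.loc[:, ["participant_id"]].copy()
    params = model.clock_parameters(
        records.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    )
    for j, name in enumerate(("attention", "hidden", "epochs", "offset")):
        per_participant[f"param_{name}"] = params[:, j]
    return CompositeFit(
        model=model,
        metrics=metrics,
        participant_parameters=per_participant,
        mse_history=mse_history,
    )


def search_prior_architecture(
    records: pd.DataFrame,
    trials: pd.DataFrame,
    meta_model: MetaModel | FeedForwardNet,
    candidates: Sequence[MetaArchitecture] | None = None,
    seed: int = 0,
    **train_kwargs,
) -> CompositeFit:
    """Enumerate prior architectures; keep the highest-R^2 composite fit."""
    if candidates is None:
        candidates = prior_architecture_candidates()
    if len(candidates) == 0:
        raise ValueError("no candidate architectures supplied")
    best: CompositeFit | None = None
    for arch in candidates:
        composite = build_composite(arch, meta_model, seed=seed)
        fit = train_composite(composite, records, trials, seed=seed, **train_kwargs)
        if best is None or fit.metrics.r_squared > best.metrics.r_squared:
            best = fit
    return best
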