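"""Factorial sweep over the clock's four parameters and its statistics.

The study design crosses five attention horizons, five hidden-layer sizes,
five epoch counts and seven Fahlman offsets into a 5*5*5*7 = 875-cell full
factorial.  Each cell trains one clock, evaluates it to 4096 ms and
records the temporal dispersion coefficient.  The statistics mirror the
study's analysis: marginal means per parameter level, one-way
repeated-measures ANOVAs in which the "subjects" are the crossed
combinations of the other three factors (the design that yields the
printed degrees of freedom, e.g. (4, 696) for memory and (6, 744) for
plasticity), and Bonferroni-corrected paired contrasts.

A full sweep at 100-500 epochs takes hours on one CPU, so the sweep is
resumable: completed cells persisted to CSV are skipped on restart.
Scaled-down grids (fewer epochs) preserve the factorial structure at desk
scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .oscillator_bank import ATTENTION_HORIZONS_MS, OscillatorBank, build_trajectory
from .srn_clock import (
    SRNConfig,
    dispersion_coefficient,
    error_trace,
    init_srn,
    tracked_run,
    train_srn,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SweepGrid",
    "SWEEP_COLUMNS",
    "build_grid",
    "cell_seed",
    "run_sweep",
    "marginal_means",
    "rm_anova",
    "paired_contrasts",
]

SWEEP_COLUMNS: tuple[str, ...] = (
    "attention",
    "hidden",
    "epochs",
    "offset",
    "seed",
    "slope",
    "r2",
)

_PARAM_COLUMNS = ("attention", "hidden", "epochs", "offset")


@dataclass(frozen=True)
class SweepGrid:
    """Level sets of the four-parameter factorial.

    The default levels are the study grid (875 cells).  ``scaled`` builds
    a grid with the epoch levels divided by a factor, keeping the factorial
    structure while shrinking the dominant computational cost.
    """

    attention_levels: tuple[int, ...] = ATTENTION_HORIZONS_MS
    memory_levels: tuple[int, ...] = (8, 16, 32, 64, 128)
    epoch_levels: tuple[int, ...] = (100, 200, 300, 400, 500)
    offset_levels: tuple[float, ...] = (0.01, 0.015, 0.03, 0.06, 0.125, 0.25, 0.5)
    eval_horizon_ms: int = 4096

    def __post_init__(self) -> None:
        for name in ("attention_levels", "memory_levels", "epoch_levels", "offset_levels"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    @property
    def size(self) -> int:
        return (
            len(self.attention_levels)
            * len(self.memory_levels)
            * len(self.epoch_levels)
            * len(self.offset_levels)
        )

    @classmethod
    def study(cls) -> "SweepGrid":
        return cls()

    @classmethod
    def scaled(cls, epoch_divisor: int = 10, **kwargs) -> "SweepGrid":
        base = cls(**kwargs)
        levels = tuple(max(1, e // epoch_divisor) for e in base.epoch_levels)
        return cls(
            attention_levels=base.attention_levels,
            memory_levels=base.memory_levels,
            epoch_levels=levels,
            offset_levels=base.offset_levels,
            eval_horizon_ms=base.eval_horizon_ms,
        )


def cell_seed(base_seed: int, cell_index: int) -> int:
    """Deterministic per-cell seed below 2^31."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(cell_index),))
    return int(ss.generate_state(1)[0] % (2**31))


def build_grid(grid: SweepGrid, base_seed: int = 0) -> list[SRNConfig]:
    """Full factorial in fixed order: attention, memory, epochs, offset
    (offset fastest); one deterministic seed per cell."""
    configs = []
    combos = itertools.product(
        grid.attention_levels, grid.memory_levels, grid.epoch_levels, grid.offset_levels
    )
    for idx, (att, n_h, epochs, offset) in enumerate(combos):
        configs.append(
            SRNConfig(
                hidden_size=int(n_h),
                epochs=int(epochs),
                fahlman_offset=float(offset),
                attention_horizon_ms=int(att),
                eval_horizon_ms=grid.eval_horizon_ms,
                seed=cell_seed(base_seed, idx),
            )
        )
    return configs


def _run_cell(config: SRNConfig, bank: OscillatorBank, datasets: dict) -> tuple[float, float]:
    if config.attention_horizon_ms not in datasets:
        datasets[config.attention_horizon_ms] = build_trajectory(
            bank, config.attention_horizon_ms
        )
    data = datasets[config.attention_horizon_ms]
    weights = init_srn(config)
    weights, _ = train_srn(weights, data, config)
    preds = tracked_run(
        weights, bank, config.eval_horizon_ms, config.output_activation
    )
    trace = error_trace(preds, bank)
    fit = dispersion_coefficient(trace)
    return fit.slope, fit.r_squared


def run_sweep(
    grid: SweepGrid | Sequence[SRNConfig],
    base_seed: int = 0,
    out_csv: str | Path | None = None,
    bank: OscillatorBank | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every grid cell; returns the sweep table.

    If ``out_csv`` exists, cells already recorded there (matched on the
    four parameter values) are skipped and the file is extended in place
    after each cell, making long sweeps resumable.  A cell whose training
    raises is recorded with NaN slope and ``status='failed'`` rather than
    aborting the sweep.
    """
    if bank is None:
        bank = OscillatorBank()
    configs = build_grid(grid, base_seed) if isinstance(grid, SweepGrid) else list(grid)
    done: pd.DataFrame | None = None
    if out_csv is not None and Path(out_csv).exists():
        done = pd.read_csv(out_csv)
        logger.info("resuming sweep: %d cells already recorded", len(done))
    datasets: dict = {}
    rows = [] if done is None else done.to_dict("records")
    seen = {
        (r["attention"], r["hidden"], r["epochs"], r["offset"]) for r in rows
    }
    for i, cfg in enumerate(configs):
        key = (cfg.attention_horizon_ms, cfg.hidden_size, cfg.epochs, cfg.fahlman_offset)
        if key in seen:
            continue
        try:
            slope, r2 = _run_cell(cfg, bank, datasets)
            status = "ok"
        except Exception:  # pragma: no cover - defensive per-cell isolation
            logger.exception("sweep cell %s failed", key)
            slope, r2, status = np.nan, np.nan, "failed"
        rows.append(
            {
                "attention": cfg.attention_horizon_ms,
                "hidden": cfg.hidden_size,
                "epochs": cfg.epochs,
                "offset": cfg.fahlman_offset,
                "seed": cfg.seed,
                "slope": slope,
                "r2": r2,
                "status": status,
            }
        )
        if out_csv is not None:
            pd.DataFrame(rows).to_csv(out_csv, index=False)
        if progress and (i + 1) % 25 == 0:
            logger.info("sweep progress: %d/%d cells", i + 1, len(configs))
    return pd.DataFrame(rows)


_LEVEL_COLUMN = {
    "attention": "attention",
    "memory": "hidden",
    "hidden": "hidden",
    "epochs": "epochs",
    "iteration": "epochs",
    "offset": "offset",
    "plasticity": "offset",
}


def _column_for(parameter: str) -> str:
    try:
        return _LEVEL_COLUMN[parameter]
    except KeyError:
        raise ValueError(
            f"unknown parameter {parameter!r}; expected one of "
            f"{sorted(set(_LEVEL_COLUMN))}"
        ) from None


def marginal_means(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Mean dispersion coefficient per level of one parameter, averaged
    over all combinations of the other three."""
    col = _column_for(parameter)
    out = (
        table.groupby(col)["slope"]
        .agg(mean="mean", n="count")
        .reset_index()
        .rename(columns={col: "level"})
        .sort_values("level", ignore_index=True)
    )
    return out


def _wide_table(table: pd.DataFrame, col: str) -> pd.DataFrame:
    """Subjects-by-levels matrix; subjects are the other-factor combos."""
    others = [c for c in _PARAM_COLUMNS if c != col]
    wide = table.pivot_table(index=others, columns=col, values="slope", aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("unbalanced sweep table: missing cells for some level")
    counts = table.groupby([*others, col]).size()
    if (counts != 1).any():
        raise ValueError("unbalanced sweep table: duplicated cells")
    return wide


def rm_anova(table: pd.DataFrame, parameter: str) -> dict:
    """One-way repeated-measures ANOVA across the parameter's levels.

    Subjects are the crossed combinations of the other three factors, so
    the full study grid yields df = (4, 696) for memory and (6, 744) for
    plasticity.  Returns F, degrees of freedom, p and partial eta squared
    (SS_effect / (SS_effect + SS_error)).
    """
    col = _column_for(parameter)
    wide = _wide_table(table, col)
    data = wide.to_numpy(dtype=float)
    n_subj, k = data.shape
    grand = data.mean()
    ss_effect = n_subj * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subjects
    df1 = k - 1
    df2 = (k - 1) * (n_subj - 1)
    # guard degenerate decompositions against floating-point dust
    eps = 1e-12 * max(ss_total, 1.0)
    if ss_effect <= eps:
        f_stat, p = 0.0, 1.0
    elif ss_error <= eps:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_effect / df1) / (ss_error / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    if ss_effect <= eps:
        eta = 0.0
    else:
        eta = ss_effect / (ss_effect + ss_error)
    return {
        "F": float(f_stat),
        "df1": int(df1),
        "df2": int(df2),
        "p": float(p),
        "partial_eta_squared": float(eta),
    }


def paired_contrasts(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """All pairwise paired t-tests between levels, Bonferroni-corrected
    within the parameter (p capped at 1)."""
    col = _column_for(parameter)
    wide = _wide_table(table, col)
    levels = list(wide.columns)
    n_pairs = len(levels) * (len(levels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(levels, 2):
        x = wide[a].to_numpy(dtype=float)
        y = wide[b].to_numpy(dtype=float)
        diff = x - y
        n = diff.shape[0]
        delta = diff.mean()
        se = diff.std(ddof=1) / np.sqrt(n)
        if se == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(x, y)
            t_stat, p = float(res.statistic), float(res.pvalue)
        ci_half = stats.t.ppf(0.975, n - 1) * se if se > 0 else 0.0
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "delta_mean": float(delta),
                "se": float(se),
                "ci_low": float(delta - ci_half),
                "ci_high": float(delta + ci_half),
                "t": t_stat,
                "p_bonferroni": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows)
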