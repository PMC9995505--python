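"""Bank of formal oscillatory neurons driving the internal-clock network.

The clock's input signal is a bank of 12 sinusoidal oscillators in the low
gamma band (32.9-37.2 Hz), sampled every millisecond.  Each oscillator's
state is mapped onto [0, 1] with 0.5 as the zero crossing: values below 0.5
are "negative" states, values above are "positive" states.  All oscillators
are phase-synchronised at stimulus onset, so the state at t = 0 is exactly
0.5 for every unit.

The supervised task derived from the bank is one-step-ahead prediction:
given the 12 states at millisecond t, predict the states at t + 1.  The
amount of trajectory available for training (the horizon) is the model's
attention parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FREQUENCIES_HZ",
    "ATTENTION_HORIZONS_MS",
    "OscillatorBank",
    "TrajectoryDataset",
    "sinusoid",
    "oscillator_state",
    "build_trajectory",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

#: Oscillator rates in Hz, chosen in the gamma range observed in awake humans.
DEFAULT_FREQUENCIES_HZ: tuple[float, ...] = (
    32.9, 33.2, 33.6, 34.0, 34.3, 34.7, 35.1, 35.5, 35.9, 36.3, 36.8, 37.2,
)

#: Training horizons (ms) used as the attention levels of the sweep grid.
ATTENTION_HORIZONS_MS: tuple[int, ...] = (1024, 1792, 2560, 3328, 4096)


def sinusoid(freq_hz: float, t_ms: np.ndarray) -> np.ndarray:
    """Unit-amplitude waveform mapped onto [0, 1]: 0.5 + 0.5*sin(2*pi*f*t)."""
    return 0.5 + 0.5 * np.sin(2.0 * np.pi * freq_hz * t_ms / 1000.0)


@dataclass(frozen=True)
class OscillatorBank:
    """Twelve synchronised oscillators sampled once per millisecond.

    Parameters
    ----------
    frequencies : sequence of float
        Exactly 12 rates in Hz, strictly increasing.
    sampling_period_ms : float
        Sampling period; the model operates on a 1 ms clock tick.
    waveform : callable ``(freq_hz, t_ms_array) -> states``
        Pluggable waveform; the default sinusoid starts at 0.5 and swings
        symmetrically between the negative (<0.5) and positive (>0.5)
        half-states.
    """

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    sampling_period_ms: float = 1.0
    waveform: Callable[[float, np.ndarray], np.ndarray] = field(
        default=sinusoid, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) != 12:
            raise ValueError(f"expected exactly 12 oscillators, got {len(freqs)}")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("oscillator frequencies must be strictly increasing")
        if self.sampling_period_ms <= 0:
            raise ValueError("sampling period must be positive")

    @property
    def n_oscillators(self) -> int:
        return len(self.frequencies)

    def state(self, t_ms: int | float) -> np.ndarray:
        """State vector of all oscillators at time ``t_ms`` (length 12)."""
        if t_ms < 0:
            raise ValueError(f"t_ms must be non-negative, got {t_ms}")
        t = np.asarray(float(t_ms))
        return np.array([self.waveform(f, t) for f in self.frequencies], dtype=float)

    def states(self, horizon_ms: int) -> np.ndarray:
        """Trajectory matrix of shape ``(horizon_ms + 1, 12)`` for t = 0..horizon."""
        if horizon_ms < 0:
            raise ValueError("horizon_ms must be non-negative")
        t = np.arange(horizon_ms + 1, dtype=float) * self.sampling_period_ms
        cols = [self.waveform(f, t) for f in self.frequencies]
        return np.column_stack(cols)


def oscillator_state(bank: OscillatorBank, t_ms: int | float) -> np.ndarray:
    """Functional alias for :meth:`OscillatorBank.state`."""
    return bank.state(t_ms)


@dataclass(frozen=True)
class TrajectoryDataset:
    """Supervised one-step-ahead dataset: pairs (state(t), state(t+1)).

    ``inputs[k]`` is the bank state at millisecond k and ``targets[k]`` the
    state at k + 1, for k = 0 .. horizon_ms - 1.  The horizon is the
    attention parameter of the clock: a smaller horizon means the network
    sees less of the oscillators' evolution during training.
    """

    inputs: np.ndarray
    targets: np.ndarray
    horizon_ms: int

    def __post_init__(self) -> None:
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must have identical shapes")
        if self.inputs.shape[0] != self.horizon_ms:
            raise ValueError("number of pairs must equal horizon_ms")

    def __len__(self) -> int:
        return self.horizon_ms


def build_trajectory(bank: OscillatorBank, horizon_ms: int) -> TrajectoryDataset:
    """Build the (t -> t+1) training set over ``horizon_ms`` milliseconds.

    Deterministic: the same bank and horizon always yield the identical
    dataset.  The first input row is the all-0.5 synchronised start state.
    """
    horizon_ms = int(horizon_ms)
    if horizon_ms < 1:
        raise ValueError(f"horizon_ms must be >= 1, got {horizon_ms}")
    traj = bank.states(horizon_ms)
    return TrajectoryDataset(
        inputs=traj[:-1].copy(), targets=traj[1:].copy(), horizon_ms=horizon_ms
    )


def write_trajectory_csv(dataset: TrajectoryDataset, path) -> None:
    """Persist a trajectory dataset as CSV with columns t, o1..o12.

    Row t holds the *input* state at millisecond t; a final row holds the
    last target so the full sampled trajectory (t = 0..horizon) round-trips.
    """
    full = np.vstack([dataset.inputs, dataset.targets[-1]])
    df = pd.DataFrame(full, columns=[f"o{i + 1}" for i in range(full.shape[1])])
    df.insert(0, "t", np.arange(full.shape[0]))
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> TrajectoryDataset:
    """Inverse of :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    cols = [f"o{i + 1}" for i in range(12)]
    missing = [c for c in ["t", *cols] if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    full = df[cols].to_numpy(dtype=float)
    return TrajectoryDataset(
        inputs=full[:-1].copy(), targets=full[1:].copy(), horizon_ms=full.shape[0] - 1
    )
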