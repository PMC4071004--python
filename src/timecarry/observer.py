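"""Ideal observer with an adaptive leaky memory prior and uncertainty threshold.

On each stimulus trial the observer draws a noisy percept of the elapsed
duration (Gaussian, SD proportional to duration -- the scalar property),
compares it to a running weighted geometric mean of recently perceived
durations, and responds "long" or "short" only when the difference
exceeds a per-trial uncertainty threshold; otherwise it repeats its
previous response.  Four reduced variants isolate the contribution of
each mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal, stats

from .sequences import TrialSequence

PERCEIVE_FLOOR_MS = 1.0

VARIANTS = (
    "full",
    "unlimited_prior",
    "zero_uncertainty",
    "zero_weighting",
    "memory_based_uncertainty",
)

__all__ = [
    "VARIANTS",
    "ObserverParams",
    "Session",
    "perceive",
    "decay_weights",
    "prior_mean",
    "draw_threshold",
    "decide",
    "simulate_session",
    "prior_trajectory",
    "spectrum_slope",
]


@dataclass(frozen=True)
class ObserverParams:
    """Free parameters of the observer.

    M       memory window, in trials (capacity of the leaky prior)
    theta   uncertainty scale in ms (half-normal per-trial threshold)
    cv      perceptual coefficient of variation (percept SD = cv * t)
    variant one of ``VARIANTS``
    seed    RNG seed for the percept / threshold / fallback draws
    """

    M: int = 13
    theta: float = 49.0
    cv: float = 0.16
    variant: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or int(self.M) != self.M:
            raise ValueError(f"M must be a positive integer, got {self.M}")
        if self.theta < 0:
            raise ValueError(f"theta must be nonnegative, got {self.theta}")
        if not (0 <= self.cv < 1):
            raise ValueError(f"cv must lie in [0, 1), got {self.cv}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")


#: Columns of a session trial table, in storage order.
SESSION_COLUMNS = [
    "trial_index",
    "label",
    "duration_ms",
    "perceived_ms",
    "prior_mean_ms",
    "threshold_ms",
    "response",
    "rt_ms",
    "prior_label",
    "prior_response",
]


@dataclass
class Session:
    """Trial records of one simulated (or synthetic) session.

    ``trials`` is a DataFrame with ``SESSION_COLUMNS``; null trials carry
    NaN durations/percepts and response ``"none"``.  ``params`` records
    provenance (observer parameters or the synthetic preset).
    """

    trials: pd.DataFrame
    params: dict
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def stimulus_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["duration_ms"].notna()]

    @property
    def null_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["duration_ms"].isna()]


def perceive(t: float, cv: float, rng: np.random.Generator) -> float:
    """Noisy percept of duration ``t``: Normal(t, cv*t), floored at 1 ms."""
    if t <= 0:
        raise ValueError(f"duration must be positive, got {t}")
    if cv == 0:
        return float(t)
    draw = rng.normal(t, cv * t)
    return float(max(draw, PERCEIVE_FLOOR_MS))


def decay_weights(M: int, tau: float | None = None) -> np.ndarray:
    """Exponential-decay weights over lags 0..M-1 (most recent first).

    ``w_j`` is proportional to ``exp(-j / tau)`` with decay constant
    ``tau = M`` by default, normalized to sum to one.  Larger windows
    therefore decay more slowly.
    """
    if M < 1:
        raise ValueError(f"M must be at least 1, got {M}")
    if tau is None:
        tau = float(M)
    w = np.exp(-np.arange(M, dtype=float) / tau)
    return w / w.sum()


def prior_mean(memory: np.ndarray, weights: np.ndarray) -> float:
    """Weighted geometric mean of remembered durations.

    ``memory`` is ordered most recent first to match ``weights``.  The
    result is bounded by the memory extremes for any normalized weights.
    """
    memory = np.asarray(memory, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if memory.size == 0:
        raise ValueError("memory buffer is empty; prior undefined")
    if memory.size != weights.size:
        raise ValueError(f"memory length {memory.size} != weights length {weights.size}")
    w = weights / weights.sum()
    return float(np.exp(np.dot(w, np.log(memory))))


def draw_threshold(theta: float, rng: np.random.Generator) -> float:
    """Per-trial effective threshold: |Normal(0, theta)| (half-normal).

    Equivalent to drawing a criterion from Normal(prior mean, theta) and
    taking its absolute distance from the prior mean.
    """
    if theta < 0:
        raise ValueError(f"theta must be nonnegative, got {theta}")
    if theta == 0:
        return 0.0
    return float(abs(rng.normal(0.0, theta)))


def decide(
    perceived: float,
    prior: float,
    threshold: float,
    prev_response: Optional[str],
    rng: np.random.Generator | None = None,
) -> str:
    """Categorize the percept against the prior under uncertainty.

    Responds ideally when |perceived - prior| exceeds the threshold;
    otherwise repeats the previous response (fair coin if there is none).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold}")
    diff = perceived - prior
    if diff > threshold:
        return "long"
    if -diff > threshold:
        return "short"
    if prev_response in ("long", "short"):
        return prev_response
    if rng is None:
        rng = np.random.default_rng()
    return "long" if rng.random() < 0.5 else "short"


class _Memory:
    """Leaky buffer of perceived durations (most recent last)."""

    def __init__(self, capacity: Optional[int], seed_values: list[float]):
        self.capacity = capacity  # None = unlimited
        self.values: list[float] = list(seed_values)

    def push(self, value: float) -> None:
        self.values.append(value)
        if self.capacity is not None and len(self.values) > self.capacity:
            del self.values[0]

    def recent_first(self) -> np.ndarray:
        return np.asarray(self.values[::-1], dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _trial_weights(params: ObserverParams, n: int) -> np.ndarray:
    if params.variant == "zero_weighting":
        return np.full(n, 1.0 / n)
    if params.variant == "unlimited_prior":
        # Window (and hence decay constant) grows with the trials tested.
        tau = float(max(n, 1))
        return decay_weights(n, tau=tau)
    return decay_weights(n, tau=float(params.M))


def _trial_theta(params: ObserverParams, memory: _Memory) -> float:
    if params.variant == "zero_uncertainty":
        return 0.0
    if params.variant == "memory_based_uncertainty":
        # theta tracks the dispersion of remembered intervals (linear ms)
        vals = np.asarray(memory.values, dtype=float)
        if vals.size < 2:
            return 0.0
        return float(np.std(vals, ddof=1))
    return params.theta


def simulate_session(seq: TrialSequence, params: ObserverParams) -> Session:
    """Run the observer through a trial sequence.

    The memory buffer is seeded with three entries at the geometric mean
    of the stimulus set (mirroring the example stimuli shown before a
    session starts).  Null trials leave memory and the previous response
    untouched and produce response ``"none"``.
    """
    rng = np.random.default_rng(params.seed)
    ds = seq.duration_set
    gm = ds.geometric_mean
    capacity = None if params.variant == "unlimited_prior" else params.M
    memory = _Memory(capacity, [gm, gm, gm])

    rows = []
    prev_response: Optional[str] = None
    prev_label: Optional[str] = None
    for i, label in enumerate(seq.labels):
        duration = ds.duration_of(label)
        if duration is None:
            rows.append((i, label, np.nan, np.nan, np.nan, np.nan, "none", np.nan,
                         prev_label, prev_response))
        else:
            percept = perceive(duration, params.cv, rng)
            mem = memory.recent_first()
            weights = _trial_weights(params, len(mem))
            t_bar = prior_mean(mem, weights)
            theta_i = _trial_theta(params, memory)
            threshold = draw_threshold(theta_i, rng)
            response = decide(percept, t_bar, threshold, prev_response, rng)
            rows.append((i, label, duration, percept, t_bar, threshold, response,
                         np.nan, prev_label, prev_response))
            memory.push(percept)
            prev_response = response
        prev_label = label

    trials = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    return Session(
        trials=trials,
        params={
            "kind": "observer",
            "M": params.M,
            "theta": params.theta,
            "cv": params.cv,
            "variant": params.variant,
            "sequence_seed": seq.seed,
            "multiplicity": seq.multiplicity,
        },
        seed=params.seed,
    )


def prior_trajectory(session: Session) -> np.ndarray:
    """Per-stimulus-trial prior mean recorded during simulation."""
    traj = session.stimulus_trials["prior_mean_ms"].to_numpy(dtype=float)
    if np.isnan(traj).any():
        raise ValueError("session has no recorded prior trajectory")
    return traj


def spectrum_slope(trajectory: np.ndarray, nperseg: int = 128) -> float:
    """Log-log slope of the trajectory's Welch power spectrum.

    Returns the least-squares slope of log power against log frequency
    over the nonzero frequencies; ~0 for white noise, increasingly
    negative for 1/f-like drift.  Degenerate (constant) input returns 0.
    """
    x = np.asarray(trajectory, dtype=float)
    if x.size < 64:
        raise ValueError(f"trajectory too short for a spectrum ({x.size} < 64)")
    if np.allclose(x, x[0]):
        return 0.0
    freqs, power = signal.welch(x, nperseg=min(nperseg, x.size))
    keep = (freqs > 0) & (power > 0)
    slope, _, _, _, _ = stats.linregress(np.log(freqs[keep]), np.log(power[keep]))
    return float(slope)
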