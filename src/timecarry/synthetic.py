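"""Synthetic participants: observer-driven responses plus a parametric RT model.

Each synthetic participant draws subject-level observer parameters from
a cohort preset, runs the ideal observer on a freshly generated
counterbalanced sequence, and attaches reaction times from an invented
but explicit generative model:

    rt = base - b_dur * log(duration)
              - drop * 1[duration > BP proxy]
              + b_prior * prior_duration
              + slow * exp(-(log d - log BP proxy)^2 / (2 * 0.25^2))
              + Normal(0, noise_sd),  floored at 150 ms

The log-duration term gives the declining chronometric function, the
prior-duration term the positive RT-by-prior slope, and the optional
boundary-slowing bump (zero in the default presets) concentrates
RT-cutoff removals around the middle durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import ObserverParams, Session, simulate_session
from .sequences import make_duration_set, make_guide, generate_sequence

RT_FLOOR_MS = 150.0
BUMP_LOG_SD = 0.25

__all__ = [
    "RTParams",
    "CohortPreset",
    "AUDITORY_PRESET",
    "VISUAL_PRESET",
    "synth_participant",
    "synth_cohort",
]


@dataclass(frozen=True)
class RTParams:
    """Coefficients of the synthetic reaction-time model (ms units)."""

    base: float = 1250.0
    duration_coef: float = 120.0  # per log-ms
    prior_coef: float = 0.12  # ms per ms of prior duration
    post_bp_drop: float = 60.0
    noise_sd: float = 90.0
    boundary_slow: float = 0.0  # bump height at the BP proxy

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class CohortPreset:
    """Population-level parameters for a synthetic cohort."""

    modality: str
    M_mean: float = 13.0
    theta_mean: float = 49.0
    cv: float = 0.16
    M_sd: float = 4.0
    theta_sd: float = 15.0
    rt_params: RTParams = field(default_factory=RTParams)
    t_min: float = 300.0
    t_max: float = 900.0
    n_levels: int = 7
    multiplicity: int = 8


AUDITORY_PRESET = CohortPreset(modality="auditory", theta_mean=49.0)
VISUAL_PRESET = CohortPreset(modality="visual", theta_mean=84.0)


def _attach_rts(
    session: Session, rt: RTParams, bp_proxy: float, rng: np.random.Generator
) -> Session:
    trials = session.trials.copy()
    stim = trials["duration_ms"].notna()
    d = trials.loc[stim, "duration_ms"].to_numpy(dtype=float)
    # prior duration in ms; null (or first-trial) priors contribute 0
    dur_of = {
        lab: float(trials.loc[trials["label"] == lab, "duration_ms"].iloc[0])
        for lab in trials.loc[stim, "label"].unique()
    }
    prior = np.array(
        [dur_of.get(lab, 0.0) for lab in trials.loc[stim, "prior_label"]],
        dtype=float,
    )
    bump = rt.boundary_slow * np.exp(-((np.log(d) - np.log(bp_proxy)) ** 2) / (2 * BUMP_LOG_SD**2))
    rts = (
        rt.base
        - rt.duration_coef * np.log(d)
        - rt.post_bp_drop * (d > bp_proxy)
        + rt.prior_coef * prior
        + bump
        + (rng.normal(0.0, rt.noise_sd, size=d.size) if rt.noise_sd > 0 else 0.0)
    )
    trials.loc[stim, "rt_ms"] = np.maximum(rts, RT_FLOOR_MS)
    return Session(trials=trials, params=session.params, seed=session.seed)


def synth_participant(preset: CohortPreset, seed: int) -> Session:
    """One synthetic participant session on a fresh counterbalanced sequence.

    Subject-level (M, theta) are drawn from the preset means and
    between-subject SDs, clipped to the canonical fitting ranges
    (M to [1, 30], theta to [1, 150] ms).
    """
    root = np.random.SeedSequence(seed)
    seq_seed, subj_seed, obs_seed, rt_seed = (s.generate_state(1)[0] for s in root.spawn(4))
    subj_rng = np.random.default_rng(subj_seed)

    ds = make_duration_set(preset.t_min, preset.t_max, preset.n_levels)
    n_trials = len(ds.labels) ** 2 * preset.multiplicity
    guide = make_guide(n_trials, seed=int(seq_seed))
    seq = generate_sequence(ds, preset.multiplicity, guide, seed=int(seq_seed))

    M = int(np.clip(round(subj_rng.normal(preset.M_mean, preset.M_sd)), 1, 30))
    theta = float(np.clip(subj_rng.normal(preset.theta_mean, preset.theta_sd), 1.0, 150.0))
    params = ObserverParams(M=M, theta=theta, cv=preset.cv, seed=int(obs_seed))
    session = simulate_session(seq, params)
    session = _attach_rts(
        session, preset.rt_params, bp_proxy=ds.geometric_mean, rng=np.random.default_rng(rt_seed)
    )
    session.params.update(
        {
            "kind": "synthetic",
            "modality": preset.modality,
            "true_M": M,
            "true_theta": theta,
            "true_cv": preset.cv,
            "rt_params": vars(preset.rt_params) | {},
            "seed": int(seed),
        }
    )
    return session


def synth_cohort(
    n: int, preset: CohortPreset, master_seed: int
) -> tuple[list[Session], pd.DataFrame]:
    """``n`` independent synthetic sessions plus a ground-truth manifest.

    The manifest records each subject's generating parameters so
    recovery studies can score fitted values against the truth.
    """
    if n < 1:
        raise ValueError(f"cohort size must be at least 1, got {n}")
    seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(master_seed).spawn(n)]
    sessions = [synth_participant(preset, s) for s in seeds]
    manifest = pd.DataFrame(
        {
            "subject": range(n),
            "seed": seeds,
            "modality": preset.modality,
            "true_M": [s.params["true_M"] for s in sessions],
            "true_theta": [s.params["true_theta"] for s in sessions],
            "true_cv": preset.cv,
            "n_trials": [len(s) for s in sessions],
        }
    )
    return sessions, manifest
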