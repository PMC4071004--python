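"""Carryover analysis: condition splits, bias/slope indices, RT matrices.

A session is segregated two ways: by the response on the preceding
trial (decisional carryover) and by the stimulus presented on the
preceding trial, null included (perceptual carryover).  Two scalar
indices summarize a session:

* decision bias  = BP(prior response long) - BP(prior response short);
  negative values mean the current response is assimilated toward the
  previous response.
* perceptual slope = OLS slope of the per-prior-duration BPs against
  prior duration in ms (null excluded); positive values mean contrast
  away from the previous stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .observer import Session
from .psychometrics import (
    PsychometricFit,
    filter_trials,
    fit_psychometric_trials,
)
from .sequences import NULL_LABEL

__all__ = [
    "CarryoverProfile",
    "split_by_prior_response",
    "split_by_prior_duration",
    "analyze_session",
    "decision_bias_index",
    "perceptual_slope",
    "rt_analyses",
    "cohort_correlations",
    "repetition_check",
    "central_tendency",
]


@dataclass
class CarryoverProfile:
    """All condition fits and carryover indices for one session."""

    fit_full: PsychometricFit
    fit_prior_long: PsychometricFit
    fit_prior_short: PsychometricFit
    fits_prior_duration: dict[str, PsychometricFit]
    decision_bias: float
    perceptual_slope: float
    rt_matrix: Optional[pd.DataFrame] = None
    rt_by_prior: Optional[pd.Series] = None
    rt_prior_slope: float = float("nan")
    excluded: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def n_curves(self) -> int:
        """Psychometric curves produced: full + 2 prior-response + 8 prior-duration."""
        return 1 + 2 + len(self.fits_prior_duration)

    @property
    def session_cv(self) -> float:
        return self.fit_full.cv


def split_by_prior_response(session: Session) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stimulus trials split by the previous trial's response.

    Trials whose previous trial was null, was removed by filtering, or
    produced no short/long response belong to neither subset.
    """
    trials = session.trials
    stim = trials[trials["duration_ms"].notna()]
    if "prior_response_valid" in stim.columns:
        stim = stim[stim["prior_response_valid"]]
    else:
        stim = stim[stim["prior_response"].isin(["short", "long"])]
    prior_long = stim[stim["prior_response"] == "long"]
    prior_short = stim[stim["prior_response"] == "short"]
    return prior_long, prior_short


def split_by_prior_duration(session: Session) -> dict[str, pd.DataFrame]:
    """Stimulus trials split by the previous trial's presented label.

    Assignment uses the presented sequence, so a trial still counts
    toward its prior-duration condition even if the prior trial's
    response was RT-filtered.  Keys follow the duration-set label order
    (null first).
    """
    trials = session.trials
    stim = trials[trials["duration_ms"].notna() & trials["prior_label"].notna()]
    order = [NULL_LABEL] + sorted(
        {lab for lab in stim["prior_label"].unique() if lab != NULL_LABEL}
    )
    return {lab: stim[stim["prior_label"] == lab] for lab in order}


def decision_bias_index(
    fit_prior_long: PsychometricFit, fit_prior_short: PsychometricFit
) -> float:
    """Signed BP difference (prior long - prior short); NaN if either fit failed."""
    if not (fit_prior_long.converged and fit_prior_short.converged):
        return float("nan")
    return float(fit_prior_long.bp - fit_prior_short.bp)


def perceptual_slope(
    fits_prior_duration: dict[str, PsychometricFit],
    duration_of: dict[str, float],
    min_points: int = 5,
) -> float:
    """OLS slope of condition BPs against prior duration (ms, linear scale).

    The null condition is excluded.  Requires at least ``min_points``
    converged duration-prior fits, else NaN.
    """
    xs, ys = [], []
    for lab, fit in fits_prior_duration.items():
        if lab == NULL_LABEL or not fit.converged:
            continue
        xs.append(duration_of[lab])
        ys.append(fit.bp)
    if len(xs) < min_points:
        return float("nan")
    slope, _, _, _, _ = stats.linregress(xs, ys)
    return float(slope)


def rt_analyses(
    session: Session, duration_of: dict[str, float]
) -> tuple[pd.DataFrame, pd.Series, float]:
    """RT cell means (prior x current), marginals by prior, and prior slope.

    Returns an 8x7 matrix of mean RTs indexed by prior label with one
    column per current duration (NaN flags empty cells), the marginal
    mean RT per prior label, and the OLS slope of RT against prior
    duration over the seven duration priors.
    """
    trials = session.trials
    stim = trials[trials["duration_ms"].notna() & trials["rt_ms"].notna()]
    if len(stim) == 0:
        raise ValueError("no reaction times present")
    stim = stim[stim["prior_label"].notna()]
    matrix = stim.pivot_table(
        index="prior_label", columns="duration_ms", values="rt_ms", aggfunc="mean"
    )
    prior_order = [NULL_LABEL] + sorted(
        (lab for lab in duration_of if lab != NULL_LABEL),
        key=lambda lab: duration_of[lab],
    )
    matrix = matrix.reindex(prior_order)
    rt_by_prior = stim.groupby("prior_label")["rt_ms"].mean().reindex(prior_order)

    xs = [duration_of[lab] for lab in prior_order if lab != NULL_LABEL]
    ys = [rt_by_prior.get(lab, np.nan) for lab in prior_order if lab != NULL_LABEL]
    pairs = [(x, y) for x, y in zip(xs, ys) if np.isfinite(y)]
    if len(pairs) >= 2:
        slope, _, _, _, _ = stats.linregress(*zip(*pairs))
    else:
        slope = float("nan")
    return matrix, rt_by_prior, float(slope)


def analyze_session(
    session: Session,
    rt_cutoff: float = 1000.0,
    cv_threshold: float = 1.0,
    min_trials_per_level: int = 4,
    prefiltered: bool = False,
) -> CarryoverProfile:
    """Full carryover analysis of one session (11 psychometric curves).

    Filters trials, fits the full-session curve plus the two
    prior-response and eight prior-duration condition curves, and
    computes both carryover indices.  RT analyses run only when RTs are
    present.  ``excluded`` mirrors the session-level CV >= 1 /
    non-convergence rule.
    """
    filtered = session if prefiltered else filter_trials(session, rt_cutoff)
    trials = filtered.trials

    fit_full = fit_psychometric_trials(trials)
    prior_long, prior_short = split_by_prior_response(filtered)
    fit_long = fit_psychometric_trials(prior_long, min_trials_per_level)
    fit_short = fit_psychometric_trials(prior_short, min_trials_per_level)
    duration_splits = split_by_prior_duration(filtered)
    fits_prior = {
        lab: fit_psychometric_trials(sub, min_trials_per_level)
        for lab, sub in duration_splits.items()
    }

    labels = sorted({lab for lab in trials["label"].unique() if lab != NULL_LABEL})
    duration_of = {
        lab: float(trials.loc[trials["label"] == lab, "duration_ms"].iloc[0])
        for lab in labels
    }

    bias = decision_bias_index(fit_long, fit_short)
    slope = perceptual_slope(fits_prior, duration_of)

    flags = []
    if not fit_full.converged:
        flags.append("full_fit_failed")
    if np.isnan(bias):
        flags.append("decision_bias_undefined")
    if np.isnan(slope):
        flags.append("perceptual_slope_undefined")

    rt_matrix = rt_by_prior = None
    rt_slope = float("nan")
    if trials["rt_ms"].notna().any():
        rt_matrix, rt_by_prior, rt_slope = rt_analyses(filtered, duration_of)

    excluded = (not fit_full.converged) or fit_full.cv >= cv_threshold
    return CarryoverProfile(
        fit_full=fit_full,
        fit_prior_long=fit_long,
        fit_prior_short=fit_short,
        fits_prior_duration=fits_prior,
        decision_bias=bias,
        perceptual_slope=slope,
        rt_matrix=rt_matrix,
        rt_by_prior=rt_by_prior,
        rt_prior_slope=rt_slope,
        excluded=excluded,
        flags=flags,
    )


def cohort_correlations(profiles: list[CarryoverProfile]) -> dict[str, float]:
    """Pearson correlations of (bias, slope) and (bias, session CV).

    Flagged/excluded profiles and profiles with undefined indices are
    dropped; zero-variance inputs yield NaN correlations.
    """
    rows = [
        (p.decision_bias, p.perceptual_slope, p.session_cv)
        for p in profiles
        if not p.excluded
        and np.isfinite(p.decision_bias)
        and np.isfinite(p.perceptual_slope)
        and np.isfinite(p.session_cv)
    ]
    if len(rows) < 3:
        raise ValueError(f"need at least 3 usable profiles, got {len(rows)}")
    bias, slope, cv = map(np.asarray, zip(*rows))

    def _pearson(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y).statistic)

    return {
        "n": len(rows),
        "r_bias_slope": _pearson(bias, slope),
        "r_bias_cv": _pearson(bias, cv),
    }


def repetition_check(
    session: Session, min_trials_per_level: int = 1, prefiltered: bool = False,
    rt_cutoff: float = 1000.0,
) -> dict[str, float]:
    """BP on duration-repeat trials vs prior-null trials for one session.

    Repeat trials are stimulus trials whose prior presented label equals
    the current label; null trials are those preceded by a blank.  NaN
    difference flags a missing/failed condition.
    """
    filtered = session if prefiltered else filter_trials(session, rt_cutoff)
    trials = filtered.trials
    stim = trials[trials["duration_ms"].notna() & trials["prior_label"].notna()]
    repeat = stim[stim["prior_label"] == stim["label"]]
    prior_null = stim[stim["prior_label"] == NULL_LABEL]
    fit_repeat = fit_psychometric_trials(repeat, min_trials_per_level)
    fit_null = fit_psychometric_trials(prior_null, min_trials_per_level)
    diff = (
        fit_repeat.bp - fit_null.bp
        if fit_repeat.converged and fit_null.converged
        else float("nan")
    )
    return {
        "bp_repeat": fit_repeat.bp,
        "bp_null": fit_null.bp,
        "difference": diff,
    }


def central_tendency(session: Session) -> pd.DataFrame:
    """Mean per-trial duration estimate for each stimulus level.

    The estimate on a trial is the percept when it cleared the
    uncertainty threshold and the prior mean otherwise -- the minimal
    estimate consistent with the decision stage.  Regression of the
    means toward the grand mean is the classic central-tendency pattern.
    """
    stim = session.stimulus_trials
    required = ["perceived_ms", "prior_mean_ms", "threshold_ms"]
    if stim[required].isna().any().any():
        raise ValueError("session lacks recorded percepts/priors/thresholds")
    exceeded = (stim["perceived_ms"] - stim["prior_mean_ms"]).abs() > stim["threshold_ms"]
    estimate = np.where(exceeded, stim["perceived_ms"], stim["prior_mean_ms"])
    frame = pd.DataFrame({"duration": stim["duration_ms"].to_numpy(), "estimate": estimate})
    return frame.groupby("duration")["estimate"].agg(["mean", "sem", "count"]).reset_index()
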