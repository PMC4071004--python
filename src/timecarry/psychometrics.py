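"""Session filtering and psychometric / chronometric curve fitting.

Responses are aggregated per duration level and fitted with a
two-parameter logistic by binomial maximum likelihood:

    P(long | t) = 1 / (1 + exp(-(t - mu) / s))

The bisection point (BP) is ``mu``; the difference limen (DL) is half
the distance between the 25% and 75% points, ``s * ln(3)``; the
coefficient of variation (CV) is DL/BP.  Threshold confidence intervals
come from a bias-corrected parametric bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .observer import Session

LN3 = math.log(3.0)

__all__ = [
    "PsychometricFit",
    "filter_trials",
    "aggregate_responses",
    "fit_psychometric",
    "fit_psychometric_trials",
    "bootstrap_thresholds",
    "chronometric",
    "exclude_session",
]


@dataclass
class PsychometricFit:
    """Logistic fit summary for one condition cell."""

    bp: float
    dl: float
    cv: float
    t25: float
    t75: float
    slope: float
    n_per_level: dict[float, int]
    converged: bool
    s: float = float("nan")
    ci_t25: Optional[tuple[float, float]] = None
    ci_t75: Optional[tuple[float, float]] = None

    @classmethod
    def failed(cls, n_per_level: dict[float, int] | None = None) -> "PsychometricFit":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, dict(n_per_level or {}), converged=False)


def filter_trials(session: Session, rt_cutoff: float = 1000.0) -> Session:
    """Drop the first trial and stimulus trials whose RT exceeds the cutoff.

    Null trials are retained as prior-context markers.  A
    ``prior_response_valid`` column marks trials whose preceding trial
    was a surviving stimulus trial with a short/long response, so the
    prior-response split downstream can exclude the rest.  Removal
    counts are recorded in ``session.params["filter_log"]``.
    """
    trials = session.trials.copy()
    has_rt = trials["rt_ms"].notna().any()
    is_stim = trials["duration_ms"].notna()
    rt_removed = is_stim & trials["rt_ms"].notna() & (trials["rt_ms"] > rt_cutoff)

    kept_response = (~rt_removed) & trials["response"].isin(["short", "long"])
    prior_valid = kept_response.shift(1, fill_value=False)
    trials = trials.assign(prior_response_valid=prior_valid)

    keep = ~rt_removed
    keep.iloc[0] = False  # first trial always removed
    filtered = trials[keep].reset_index(drop=True)

    params = dict(session.params)
    params["filter_log"] = {
        "rt_cutoff": rt_cutoff if has_rt else None,
        "n_first_removed": 1,
        "n_rt_removed": int(rt_removed.sum()),
        "rt_removed_by_duration": {
            float(d): int(n)
            for d, n in trials.loc[rt_removed, "duration_ms"].value_counts().items()
        },
    }
    return Session(trials=filtered, params=params, seed=session.seed)


def aggregate_responses(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-duration response counts: columns duration, n_long, n_total."""
    stim = trials[trials["duration_ms"].notna() & trials["response"].isin(["short", "long"])]
    grouped = stim.groupby("duration_ms")["response"].agg(
        n_long=lambda r: int((r == "long").sum()), n_total="size"
    )
    return grouped.reset_index().rename(columns={"duration_ms": "duration"})


def _nll(params: np.ndarray, t: np.ndarray, n_long: np.ndarray, n_total: np.ndarray) -> float:
    mu, log_s = params
    p = expit((t - mu) / math.exp(log_s))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-(n_long * np.log(p) + (n_total - n_long) * np.log(1.0 - p)).sum())


def fit_psychometric(
    durations: np.ndarray,
    n_long: np.ndarray,
    n_total: np.ndarray,
) -> PsychometricFit:
    """Binomial ML logistic fit of P(long) against duration (linear ms).

    Data with responses all on one side of 0.5 cannot anchor the BP and
    are flagged non-converged rather than extrapolated.
    """
    t = np.asarray(durations, dtype=float)
    n_long = np.asarray(n_long, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    order = np.argsort(t)
    t, n_long, n_total = t[order], n_long[order], n_total[order]
    n_per_level = {float(d): int(n) for d, n in zip(t, n_total)}

    if len(t) < 2:
        return PsychometricFit.failed(n_per_level)
    prop = n_long / n_total
    if prop.min() >= 0.5 or prop.max() <= 0.5:
        return PsychometricFit.failed(n_per_level)

    mu0 = None
    for i in range(len(t) - 1):
        lo, hi = prop[i] - 0.5, prop[i + 1] - 0.5
        if lo <= 0 <= hi or lo >= 0 >= hi:
            if prop[i + 1] != prop[i]:
                mu0 = t[i] + (0.5 - prop[i]) * (t[i + 1] - t[i]) / (prop[i + 1] - prop[i])
            else:
                mu0 = 0.5 * (t[i] + t[i + 1])
            break
    if mu0 is None:
        mu0 = float(t[np.argmin(np.abs(prop - 0.5))])
    s0 = max((t[-1] - t[0]) / 8.0, 1e-3)

    best = None
    for start in ((mu0, math.log(s0)), (t.mean(), math.log(s0 * 4))):
        res = optimize.minimize(
            _nll,
            np.asarray(start),
            args=(t, n_long, n_total),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-11, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best.success:
            break
    mu, log_s = best.x
    s = math.exp(log_s)
    if not np.isfinite(mu) or mu <= 0 or mu > 10 * t[-1]:
        return PsychometricFit.failed(n_per_level)

    dl = s * LN3
    return PsychometricFit(
        bp=float(mu),
        dl=float(dl),
        cv=float(dl / mu),
        t25=float(mu - dl),
        t75=float(mu + dl),
        slope=float(1.0 / (4.0 * s)),
        n_per_level=n_per_level,
        converged=bool(best.success),
        s=float(s),
    )


def fit_psychometric_trials(
    trials: pd.DataFrame, min_trials_per_level: int = 1
) -> PsychometricFit:
    """Fit a trial table directly; levels with too few trials are dropped."""
    agg = aggregate_responses(trials)
    agg = agg[agg["n_total"] >= min_trials_per_level]
    if len(agg) < 2:
        return PsychometricFit.failed(
            {float(d): int(n) for d, n in zip(agg["duration"], agg["n_total"])}
        )
    return fit_psychometric(
        agg["duration"].to_numpy(), agg["n_long"].to_numpy(), agg["n_total"].to_numpy()
    )


def bootstrap_thresholds(
    fit: PsychometricFit,
    durations: np.ndarray,
    n_total: np.ndarray,
    n_boot: int = 1999,
    seed: int | None = None,
    min_retained_frac: float = 0.9,
) -> PsychometricFit:
    """Bias-corrected parametric bootstrap CIs for the 25%/75% thresholds.

    Responses are resampled from the fitted curve at the observed trial
    counts, refit, and the bias-corrected percentile interval computed
    for each threshold.  Replicates whose refit fails are dropped; if
    fewer than ``min_retained_frac`` survive, an error is raised.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    if n_boot == 0:
        return fit
    rng = np.random.default_rng(seed)
    t = np.asarray(durations, dtype=float)
    n_total = np.asarray(n_total, dtype=int)
    p_fit = expit((t - fit.bp) / fit.s)

    t25s, t75s = [], []
    for _ in range(n_boot):
        k = rng.binomial(n_total, p_fit)
        refit = fit_psychometric(t, k, n_total)
        if refit.converged:
            t25s.append(refit.t25)
            t75s.append(refit.t75)
    retained = len(t25s) / n_boot
    if retained < min_retained_frac:
        raise RuntimeError(
            f"only {retained:.0%} of bootstrap refits converged (< {min_retained_frac:.0%})"
        )

    def bc_interval(samples: list[float], estimate: float, alpha: float = 0.05):
        arr = np.sort(np.asarray(samples))
        frac_below = np.clip((arr < estimate).mean(), 1e-6, 1 - 1e-6)
        z0 = stats.norm.ppf(frac_below)
        lo = stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2))
        hi = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - alpha / 2))
        return (float(np.quantile(arr, lo)), float(np.quantile(arr, hi)))

    fit.ci_t25 = bc_interval(t25s, fit.t25)
    fit.ci_t75 = bc_interval(t75s, fit.t75)
    return fit


def chronometric(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean RT and s.e. per duration level; NaN rows flag empty levels."""
    stim = trials[trials["duration_ms"].notna()]
    if stim["rt_ms"].notna().sum() == 0:
        raise ValueError("no reaction times present")
    grouped = stim.groupby("duration_ms")["rt_ms"].agg(["mean", "sem", "count"])
    grouped = grouped.rename(columns={"mean": "rt_mean", "sem": "rt_sem", "count": "n"})
    return grouped.reset_index().rename(columns={"duration_ms": "duration"})


def exclude_session(fit: PsychometricFit, cv_threshold: float = 1.0) -> bool:
    """True when the full-session fit fails or its CV is at/above threshold."""
    return (not fit.converged) or fit.cv >= cv_threshold
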