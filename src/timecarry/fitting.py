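"""Monte Carlo parameter grids and RMSE fitting of carryover profiles.

A grid is a set of observer permutations: each entry draws a memory
window M and an uncertainty scale theta (uniformly from their ranges by
default, or exhaustively), simulates a session on a fixed sequence, and
records the session's carryover indices.  A profile is fitted by
finding the grid entry minimizing the RMSE over the standardized
(decision bias, perceptual slope) pair; each component is z-scored by
the grid's own spread so the two incommensurate indices weigh equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .carryover import CarryoverProfile, analyze_session
from .observer import ObserverParams, simulate_session
from .sequences import TrialSequence

DEFAULT_M_RANGE = (1, 30)
DEFAULT_THETA_RANGE = (1.0, 150.0)

__all__ = [
    "GridResult",
    "FitResult",
    "run_grid",
    "fit_session",
    "compare_variants",
]


@dataclass
class GridResult:
    """Observer permutations with their simulated carryover indices."""

    entries: pd.DataFrame  # columns: M, theta, seed, decision_bias, perceptual_slope, session_cv, flagged
    variant: str
    cv: float
    n_curves: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def usable(self) -> pd.DataFrame:
        ok = self.entries[~self.entries["flagged"]]
        return ok[
            np.isfinite(ok["decision_bias"]) & np.isfinite(ok["perceptual_slope"])
        ]


@dataclass
class FitResult:
    """Best grid entry for one profile."""

    best_M: int
    best_theta: float
    rmse: float
    runner_up_gap: float


def run_grid(
    n_perm: int,
    sequence: TrialSequence,
    seed: int = 0,
    M_range: tuple[int, int] = DEFAULT_M_RANGE,
    theta_range: tuple[float, float] = DEFAULT_THETA_RANGE,
    variant: str = "full",
    cv: float = 0.16,
    exhaustive: bool = False,
    rt_cutoff: float = 1000.0,
) -> GridResult:
    """Simulate ``n_perm`` observer permutations and analyze each session.

    Parameters are drawn uniformly (integer steps, matching the 1-trial /
    1-ms grid resolution) unless ``exhaustive`` is set, in which case the
    full M x theta lattice is enumerated and ``n_perm`` ignored.  Each
    permutation runs the complete 11-curve analysis with bootstrap off;
    sessions failing the exclusion rule are flagged, never dropped.
    """
    rng = np.random.default_rng(seed)
    if exhaustive:
        Ms, thetas = np.meshgrid(
            np.arange(M_range[0], M_range[1] + 1),
            np.arange(int(theta_range[0]), int(theta_range[1]) + 1),
        )
        Ms, thetas = Ms.ravel(), thetas.ravel().astype(float)
    else:
        Ms = rng.integers(M_range[0], M_range[1] + 1, size=n_perm)
        thetas = rng.integers(int(theta_range[0]), int(theta_range[1]) + 1, size=n_perm).astype(float)

    rows = []
    n_curves = 0
    for M, theta in zip(Ms, thetas):
        obs_seed = int(rng.integers(0, 2**31))
        params = ObserverParams(M=int(M), theta=float(theta), cv=cv, variant=variant, seed=obs_seed)
        session = simulate_session(sequence, params)
        profile = analyze_session(session, rt_cutoff=rt_cutoff)
        n_curves += profile.n_curves
        rows.append(
            (
                int(M),
                float(theta),
                obs_seed,
                profile.decision_bias,
                profile.perceptual_slope,
                profile.session_cv,
                profile.excluded,
            )
        )
    entries = pd.DataFrame(
        rows,
        columns=["M", "theta", "seed", "decision_bias", "perceptual_slope", "session_cv", "flagged"],
    )
    return GridResult(entries=entries, variant=variant, cv=cv, n_curves=n_curves)


def fit_session(
    profile: CarryoverProfile,
    grid: GridResult,
    scale: tuple[float, float, float, float] | None = None,
) -> FitResult:
    """Grid entry minimizing standardized RMSE to the profile's indices.

    Bias and slope are z-scored against the grid's own distribution
    before the RMSE (or against an explicit ``scale`` of
    ``(bias_mean, bias_sd, slope_mean, slope_sd)`` so several grids can
    be compared on a common footing); ties break toward smaller theta,
    then smaller M.
    """
    if not (np.isfinite(profile.decision_bias) and np.isfinite(profile.perceptual_slope)):
        raise ValueError("profile has undefined carryover indices")
    usable = grid.usable
    if len(usable) == 0:
        raise ValueError("grid has no usable entries")

    b = usable["decision_bias"].to_numpy(dtype=float)
    s = usable["perceptual_slope"].to_numpy(dtype=float)
    if scale is None:
        mu_b, sd_b = float(np.mean(b)), float(np.std(b)) or 1.0
        mu_s, sd_s = float(np.mean(s)), float(np.std(s)) or 1.0
    else:
        mu_b, sd_b, mu_s, sd_s = scale
    zb, zs = (b - mu_b) / sd_b, (s - mu_s) / sd_s
    pb = (profile.decision_bias - mu_b) / sd_b
    ps = (profile.perceptual_slope - mu_s) / sd_s
    rmse = np.sqrt(((zb - pb) ** 2 + (zs - ps) ** 2) / 2.0)

    ranked = usable.assign(rmse=rmse).sort_values(
        ["rmse", "theta", "M"], kind="mergesort"
    )
    best = ranked.iloc[0]
    gap = float(ranked.iloc[1]["rmse"] - best["rmse"]) if len(ranked) > 1 else float("nan")
    return FitResult(
        best_M=int(best["M"]),
        best_theta=float(best["theta"]),
        rmse=float(best["rmse"]),
        runner_up_gap=gap,
    )


def compare_variants(
    profiles: list[CarryoverProfile], grids: dict[str, GridResult]
) -> pd.DataFrame:
    """Fit every profile against every variant grid; summarize RMSE.

    All grids are standardized by the ``full`` grid's index spread (when
    present) so RMSEs are commensurate across variants.  Returns one row
    per variant with the mean RMSE, mean (1 - RMSE) fit-quality score,
    and the fraction of profiles for which that variant beats the
    ``full`` grid (NaN for ``full`` itself).
    """
    if not grids:
        raise ValueError("no grids supplied")
    scale = None
    if "full" in grids:
        ref = grids["full"].usable
        scale = (
            float(ref["decision_bias"].mean()),
            float(ref["decision_bias"].std(ddof=0)) or 1.0,
            float(ref["perceptual_slope"].mean()),
            float(ref["perceptual_slope"].std(ddof=0)) or 1.0,
        )
    per_variant = {}
    for name, grid in grids.items():
        per_variant[name] = np.array(
            [fit_session(p, grid, scale=scale).rmse for p in profiles], dtype=float
        )
    rows = []
    full = per_variant.get("full")
    for name, rmses in per_variant.items():
        beats_full = float("nan")
        if full is not None and name != "full":
            beats_full = float(np.mean(rmses < full))
        rows.append(
            {
                "variant": name,
                "mean_rmse": float(np.mean(rmses)),
                "mean_score": float(np.mean(1.0 - rmses)),
                "frac_beats_full": beats_full,
                "n_profiles": len(rmses),
            }
        )
    return pd.DataFrame(rows)
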