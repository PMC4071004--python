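"""Configuration, session CSV round-tripping, and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting
from .carryover import CarryoverProfile, analyze_session
from .observer import SESSION_COLUMNS, ObserverParams, Session, simulate_session
from .psychometrics import PsychometricFit, bootstrap_thresholds
from .sequences import make_duration_set, make_guide, generate_sequence

logger = logging.getLogger("timecarry")

REQUIRED_SESSION_COLUMNS = ["trial_index", "label", "duration_ms", "response"]

__all__ = [
    "RunConfig",
    "read_session",
    "write_session",
    "write_sequence",
    "profile_to_dict",
    "fit_to_dict",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """All pipeline settings; defaults mirror the canonical task design."""

    t_min: float = 300.0
    t_max: float = 900.0
    n_levels: int = 7
    multiplicity: int = 8
    M: int = 13
    theta: float = 49.0
    cv: float = 0.16
    variant: str = "full"
    rt_cutoff: float = 1000.0
    n_bootstrap: int = 1999
    exclusion_cv: float = 1.0
    M_range: tuple[int, int] = (1, 30)
    theta_range: tuple[float, float] = (1.0, 150.0)
    n_perm: int = 500
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("M_range", "theta_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["M_range"] = list(d["M_range"])
        d["theta_range"] = list(d["theta_range"])
        return d

    def seeds(self) -> dict[str, int]:
        """Named substreams derived from the master seed, in stable order."""
        names = ("sequence", "observer", "bootstrap", "cohort", "grid")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to CSV (empty fields on null trials) plus provenance.

    Provenance (params, seed) goes to a sidecar ``<path>.meta.json`` so
    the CSV stays a plain trial table.
    """
    path = Path(path)
    session.trials.to_csv(path, index=False, columns=SESSION_COLUMNS)
    meta = {"params": _jsonable(session.params), "seed": session.seed}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path) -> Session:
    """Read a session CSV written by :func:`write_session`.

    Malformed rows (non-numeric durations/RTs) and missing required
    columns raise errors naming the offending column and line.
    """
    path = Path(path)
    # keep_default_na=False so the literal label "null" survives; only
    # genuinely empty fields become missing values
    trials = pd.read_csv(
        path,
        dtype={"label": str, "response": str, "prior_label": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in REQUIRED_SESSION_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("duration_ms", "perceived_ms", "prior_mean_ms", "threshold_ms", "rt_ms"):
        if col in trials.columns:
            try:
                trials[col] = pd.to_numeric(trials[col])
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(trials[col], errors="coerce").isna() & trials[col].notna()
                line = int(trials.index[bad][0]) + 2  # 1-based, after header
                raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}") from exc
    for col in SESSION_COLUMNS:
        if col not in trials.columns:
            trials[col] = np.nan
    trials = trials[SESSION_COLUMNS]

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    params, seed = {}, -1
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        params, seed = meta.get("params", {}), meta.get("seed", -1)
    return Session(trials=trials, params=params, seed=seed)


def write_sequence(seq, path: str | Path, plain: bool = False) -> None:
    """Export a trial sequence as CSV (or one label per line)."""
    path = Path(path)
    if plain:
        path.write_text("\n".join(seq.labels) + "\n")
        return
    rows = []
    for i, (lab, dur) in enumerate(zip(seq.labels, seq.durations_ms())):
        rows.append({"trial_index": i, "label": lab, "duration_ms": "" if dur is None else dur})
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    return obj


def fit_to_dict(fit: PsychometricFit) -> dict:
    d = dataclasses.asdict(fit)
    d["n_per_level"] = {str(k): v for k, v in d["n_per_level"].items()}
    return _jsonable(d)


def profile_to_dict(profile: CarryoverProfile) -> dict:
    return _jsonable(
        {
            "decision_bias": profile.decision_bias,
            "perceptual_slope": profile.perceptual_slope,
            "session_cv": profile.session_cv,
            "excluded": profile.excluded,
            "flags": profile.flags,
            "n_curves": profile.n_curves,
            "fit_full": fit_to_dict(profile.fit_full),
            "fit_prior_long": fit_to_dict(profile.fit_prior_long),
            "fit_prior_short": fit_to_dict(profile.fit_prior_short),
            "fits_prior_duration": {
                lab: fit_to_dict(f) for lab, f in profile.fits_prior_duration.items()
            },
            "rt_prior_slope": profile.rt_prior_slope,
            "rt_by_prior": None
            if profile.rt_by_prior is None
            else {str(k): _jsonable(v) for k, v in profile.rt_by_prior.items()},
            "rt_matrix": None
            if profile.rt_matrix is None
            else _jsonable(profile.rt_matrix.values.tolist()),
        }
    )


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Sequence -> session -> fits -> carryover profile -> grid -> fit.

    Writes every artifact under ``outdir`` and returns their paths.
    Deterministic for a fixed config (all randomness flows from the
    master seed through named substreams).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds()
    artifacts: dict[str, Path] = {}

    import contextlib
    import hashlib

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]

    @contextlib.contextmanager
    def stage(name: str):
        try:
            yield
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed (config {config_hash}): {exc}"
            ) from exc

    with stage("sequence"):
        ds = make_duration_set(config.t_min, config.t_max, config.n_levels)
        n_trials = len(ds.labels) ** 2 * config.multiplicity
        guide = make_guide(n_trials, seed=seeds["sequence"])
        seq = generate_sequence(ds, config.multiplicity, guide, seed=seeds["sequence"])
        artifacts["sequence"] = outdir / "sequence.csv"
        write_sequence(seq, artifacts["sequence"])

    with stage("simulate"):
        params = ObserverParams(
            M=config.M, theta=config.theta, cv=config.cv, variant=config.variant,
            seed=seeds["observer"],
        )
        session = simulate_session(seq, params)
        artifacts["session"] = outdir / "session.csv"
        write_session(session, artifacts["session"])

    with stage("analyze"):
        profile = analyze_session(
            session, rt_cutoff=config.rt_cutoff, cv_threshold=config.exclusion_cv
        )
        logger.info(
            "session analyzed: bias=%.2f ms slope=%.4f cv=%.4f excluded=%s",
            profile.decision_bias, profile.perceptual_slope, profile.session_cv, profile.excluded,
        )
        if config.n_bootstrap > 0 and profile.fit_full.converged:
            from .psychometrics import aggregate_responses, filter_trials

            agg = aggregate_responses(filter_trials(session, config.rt_cutoff).trials)
            bootstrap_thresholds(
                profile.fit_full,
                agg["duration"].to_numpy(),
                agg["n_total"].to_numpy(),
                n_boot=config.n_bootstrap,
                seed=seeds["bootstrap"],
            )
        artifacts["profile"] = outdir / "profile.json"
        artifacts["profile"].write_text(json.dumps(profile_to_dict(profile), indent=1))

    with stage("grid"):
        grid = fitting.run_grid(
            config.n_perm,
            seq,
            seed=seeds["grid"],
            M_range=config.M_range,
            theta_range=config.theta_range,
            cv=config.cv,
            rt_cutoff=config.rt_cutoff,
        )
        artifacts["grid"] = outdir / "grid.json"
        artifacts["grid"].write_text(
            json.dumps(
                {
                    "variant": grid.variant,
                    "cv": grid.cv,
                    "n_curves": grid.n_curves,
                    "entries": _jsonable(grid.entries.to_dict(orient="records")),
                },
                indent=1,
            )
        )

    with stage("fit"):
        result = fitting.fit_session(profile, grid)
        artifacts["fit"] = outdir / "fit.json"
        artifacts["fit"].write_text(json.dumps(dataclasses.asdict(result), indent=1))

    artifacts["config"] = outdir / "config.json"
    artifacts["config"].write_text(json.dumps(config.to_dict(), indent=1))
    return artifacts
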