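import numpy as np
import pytest

from timecarry.carryover import (
    analyze_session,
    central_tendency,
    cohort_correlations,
    decision_bias_index,
    perceptual_slope,
    repetition_check,
    rt_analyses,
    split_by_prior_duration,
    split_by_prior_response,
)
from timecarry.observer import ObserverParams, Session, simulate_session
from timecarry.psychometrics import PsychometricFit, filter_trials
from timecarry.sequences import NULL_LABEL


def make_fit(bp, converged=True):
    dl = 60.0
    return PsychometricFit(bp, dl, dl / bp, bp - dl, bp + dl, 0.01, {}, converged, s=dl)


@pytest.fixture(scope="module")
def filtered_session(default_session):
    return filter_trials(default_session)


class TestSplits:
    def test_prior_response_subsets_partition(self, filtered_session):
        prior_long, prior_short = split_by_prior_response(filtered_session)
        stim = filtered_session.trials[filtered_session.trials["duration_ms"].notna()]
        excluded = stim[~stim["prior_response_valid"]]
        assert len(prior_long) + len(prior_short) + len(excluded) == len(stim)
        assert len(stim) == 447  # 448 stimulus trials minus the removed first trial

    def test_prior_duration_counterbalance(self, default_session):
        splits = split_by_prior_duration(default_session)
        assert set(splits) == {NULL_LABEL} | {f"d{i}" for i in range(1, 8)}
        deficits = 0
        for sub in splits.values():
            counts = sub.groupby("duration_ms").size()
            assert len(counts) == 7
            deficits += int((8 - counts).sum())
            assert counts.min() >= 7
        assert deficits <= 1  # only the first trial (undefined prior) is lost

    def test_prior_null_subset_size(self, filtered_session):
        splits = split_by_prior_duration(filtered_session)
        # 64 null trials precede 64 successors; ~1/8 of those are null themselves
        assert 50 <= len(splits[NULL_LABEL]) <= 60

    def test_all_long_responses_leave_short_subset_empty(self, filtered_session):
        sess = Session(filtered_session.trials.copy(), {}, 0)
        stim = sess.trials["duration_ms"].notna()
        sess.trials.loc[stim, "response"] = "long"
        sess.trials.loc[stim, "prior_response"] = "long"
        prior_long, prior_short = split_by_prior_response(sess)
        assert len(prior_short) == 0


class TestIndices:
    def test_identical_fits_give_zero_bias(self):
        assert decision_bias_index(make_fit(500), make_fit(500)) == 0.0

    def test_missing_fit_gives_nan(self):
        assert np.isnan(decision_bias_index(make_fit(500), make_fit(500, converged=False)))

    def test_constant_bps_give_zero_slope(self):
        durs = {f"d{i}": d for i, d in enumerate(np.geomspace(300, 900, 7), start=1)}
        fits = {lab: make_fit(500) for lab in durs}
        fits[NULL_LABEL] = make_fit(480)
        assert perceptual_slope(fits, durs) == pytest.approx(0.0, abs=1e-12)

    def test_identity_bps_give_unit_slope(self):
        durs = {f"d{i}": d for i, d in enumerate(np.geomspace(300, 900, 7), start=1)}
        fits = {lab: make_fit(d) for lab, d in durs.items()}
        assert perceptual_slope(fits, durs) == pytest.approx(1.0)

    def test_too_few_points_gives_nan(self):
        durs = {f"d{i}": d for i, d in enumerate(np.geomspace(300, 900, 7), start=1)}
        fits = {lab: make_fit(d, converged=(i < 4)) for i, (lab, d) in enumerate(durs.items())}
        assert np.isnan(perceptual_slope(fits, durs))

    def test_null_condition_excluded_from_slope(self):
        durs = {f"d{i}": d for i, d in enumerate(np.geomspace(300, 900, 7), start=1)}
        fits = {lab: make_fit(500) for lab in durs}
        fits[NULL_LABEL] = make_fit(5000)  # wild null BP must not matter
        assert perceptual_slope(fits, durs) == pytest.approx(0.0, abs=1e-12)


class TestAnalyzeSession:
    def test_eleven_curves(self, default_session):
        profile = analyze_session(default_session)
        assert profile.n_curves == 11
        assert len(profile.fits_prior_duration) == 8

    def test_full_model_upper_left_quadrant_exists(self, default_sequence):
        # simultaneous assimilative bias and contrastive slope for some seeds
        found = False
        for seed in range(15):
            sess = simulate_session(
                default_sequence, ObserverParams(M=13, theta=49, cv=0.16, seed=seed)
            )
            p = analyze_session(sess)
            if p.decision_bias < 0 and p.perceptual_slope > 0:
                found = True
                break
        assert found

    def test_theta84_bias_negative_majority(self, default_sequence):
        signs = []
        for seed in range(10):
            sess = simulate_session(
                default_sequence, ObserverParams(M=13, theta=84, cv=0.16, seed=100 + seed)
            )
            signs.append(analyze_session(sess).decision_bias < 0)
        assert np.mean(signs) > 0.5


class TestRTAnalyses:
    def _with_rts(self, session, rts):
        sess = Session(session.trials.copy(), dict(session.params), 0)
        stim = sess.trials["duration_ms"].notna()
        sess.trials.loc[stim, "rt_ms"] = rts
        return sess

    def _duration_of(self, session):
        stim = session.trials[session.trials["duration_ms"].notna()]
        return {
            lab: float(stim.loc[stim["label"] == lab, "duration_ms"].iloc[0])
            for lab in stim["label"].unique()
        }

    def test_constant_rts_flat(self, default_session):
        sess = self._with_rts(default_session, 500.0)
        matrix, by_prior, slope = rt_analyses(sess, self._duration_of(sess))
        assert np.allclose(matrix.to_numpy()[np.isfinite(matrix.to_numpy())], 500.0)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_prior_duration_effect_recovered(self, default_session):
        sess = Session(default_session.trials.copy(), dict(default_session.params), 0)
        stim = sess.trials["duration_ms"].notna()
        dur_of = self._duration_of(sess)
        prior_ms = sess.trials["prior_label"].map(lambda l: dur_of.get(l, 0.0))
        sess.trials.loc[stim, "rt_ms"] = 400.0 + 0.2 * prior_ms[stim]
        _, _, slope = rt_analyses(sess, dur_of)
        assert slope == pytest.approx(0.2, rel=1e-6)

    def test_no_rts_raises(self, default_session):
        with pytest.raises(ValueError):
            rt_analyses(default_session, self._duration_of(default_session))

    def test_empty_cells_are_nan(self, default_session):
        sess = self._with_rts(default_session, 500.0)
        # drop every trial whose prior was null: that matrix row must be NaN
        keep = sess.trials["prior_label"] != NULL_LABEL
        sess = Session(sess.trials[keep], {}, 0)
        matrix, _, _ = rt_analyses(sess, self._duration_of(sess))
        assert matrix.loc[NULL_LABEL].isna().all()


class TestCohortCorrelations:
    def _profile(self, bias, slope, cv):
        from timecarry.carryover import CarryoverProfile

        fit = make_fit(500)
        fit.cv = cv
        return CarryoverProfile(
            fit_full=fit,
            fit_prior_long=make_fit(500 + bias / 2),
            fit_prior_short=make_fit(500 - bias / 2),
            fits_prior_duration={},
            decision_bias=bias,
            perceptual_slope=slope,
            excluded=False,
        )

    def test_requires_three_profiles(self):
        with pytest.raises(ValueError):
            cohort_correlations([self._profile(0, 0, 0.2)] * 2)

    def test_zero_variance_flagged_nan(self):
        out = cohort_correlations([self._profile(-10, 0.1, 0.2)] * 5)
        assert np.isnan(out["r_bias_slope"])

    def test_known_correlation_sign(self, rng):
        profiles = []
        for _ in range(50):
            bias = rng.normal(-50, 30)
            profiles.append(self._profile(bias, -0.001 * bias + rng.normal(0, 0.01), 0.2 - 0.0005 * bias))
        out = cohort_correlations(profiles)
        assert out["r_bias_slope"] < 0  # constructed anti-correlation
        assert out["r_bias_cv"] < 0


class TestRepetitionCheck:
    def test_identical_conditions_zero(self, default_session):
        out = repetition_check(default_session)
        assert np.isfinite(out["difference"]) or np.isnan(out["difference"])

    def test_missing_condition_flagged(self, default_session):
        sess = Session(
            default_session.trials[default_session.trials["prior_label"] != NULL_LABEL],
            {},
            0,
        )
        out = repetition_check(sess, prefiltered=True)
        assert np.isnan(out["difference"])


class TestCentralTendency:
    def test_estimates_regress_toward_mean(self, default_sequence):
        # aggregate across sessions: the single-session effect at the
        # extremes is smaller than percept sampling noise
        per_level = {}
        for seed in range(25):
            sess = simulate_session(
                default_sequence, ObserverParams(M=13, theta=150.0, cv=0.16, seed=seed)
            )
            table = central_tendency(sess)
            for d, m in zip(table["duration"], table["mean"]):
                per_level.setdefault(float(d), []).append(m)
        means = {d: np.mean(v) for d, v in per_level.items()}
        xs = np.array(sorted(means))
        ys = np.array([means[x] for x in xs])
        assert means[300.0] > 300.0  # short durations overestimated
        assert means[900.0] < 900.0  # long durations underestimated
        assert np.polyfit(xs, ys, 1)[0] < 1.0  # regression toward the mean

    def test_requires_recorded_internals(self, default_session):
        sess = Session(default_session.trials.copy(), {}, 0)
        sess.trials["threshold_ms"] = np.nan
        with pytest.raises(ValueError):
            central_tendency(sess)
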