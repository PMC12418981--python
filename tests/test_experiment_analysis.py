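import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pflow.experiment_analysis import (
    ANCHOR_HIGH,
    ANCHOR_LOW,
    ObserverModel,
    RatingScale,
    SessionRecord,
    StimulusSpec,
    TrialRecord,
    analyze_cohort,
    apply_scale_expansion,
    bonferroni_alpha,
    compute_check_variables,
    expected_rating,
    make_design,
    measurement_stimuli,
    mixed_anova,
    moving_window_rms,
    rating_error,
    simulate_cohort,
    simulate_observer,
    summarize_participant,
    tukey_posthoc,
)


def _trial(block, idx, stim, actual, rt=5.0):
    return TrialRecord(participant_id="p0", block=block, trial_index=idx,
                       stimulus=stim, actual_rating=actual, rt=rt)


def _session_trials(errors_by_block, stimuli, orders):
    """Build TrialRecords from per-block error lists and stimulus orders."""
    trials = []
    idx = 0
    for b, (errs, order) in enumerate(zip(errors_by_block, orders), start=1):
        for e, si in zip(errs, order):
            st_ = stimuli[si]
            idx += 1
            trials.append(_trial(b, idx, st_, st_.expected_rating + e))
    return trials


class TestExpectedRating:
    def test_anchor_viscosities(self):
        assert expected_rating(ANCHOR_LOW[0]) == pytest.approx(10.0)
        assert expected_rating(ANCHOR_HIGH[0]) == pytest.approx(80.0)

    def test_log_midpoint(self):
        mid = math.sqrt(ANCHOR_LOW[0] * ANCHOR_HIGH[0])
        assert expected_rating(mid) == pytest.approx(45.0)

    def test_nonpositive_viscosity(self):
        with pytest.raises(ValueError):
            expected_rating(0.0)

    @given(st.floats(min_value=-6, max_value=3))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing(self, log10v):
        v = 10.0**log10v
        assert expected_rating(v * 1.01) > expected_rating(v)

    def test_measurement_set_spans_5_to_95(self):
        stims = measurement_stimuli("pflow")
        exp = [s.expected_rating for s in stims]
        assert exp[0] == pytest.approx(5.0, abs=0.05)
        assert exp[-1] == pytest.approx(95.0, abs=0.05)
        assert np.allclose(np.diff(exp), 10.0, atol=0.02)


class TestScaleExpansion:
    def test_lower_extreme_expands_down(self):
        scale = apply_scale_expansion(RatingScale(0, 100), 0.0)
        assert (scale.lower, scale.upper) == (-10.0, 100.0)

    def test_interior_rating_unchanged(self):
        scale = apply_scale_expansion(RatingScale(0, 100), 50.0)
        assert (scale.lower, scale.upper) == (0.0, 100.0)

    def test_repeat_expansion(self):
        scale = apply_scale_expansion(RatingScale(-10, 100), -10.0)
        assert scale.lower == -20.0

    def test_upper_extreme(self):
        scale = apply_scale_expansion(RatingScale(0, 100), 100.0)
        assert scale.upper == 110.0

    def test_out_of_bounds_rating_rejected(self):
        with pytest.raises(ValueError):
            apply_scale_expansion(RatingScale(0, 100), 101.0)


class TestRatingError:
    def test_subtraction(self):
        stim = StimulusSpec("s", 1.0, "pflow", expected_rating=45.0)
        assert rating_error(_trial(1, 1, stim, 60.0)) == pytest.approx(15.0)
        assert rating_error(_trial(1, 2, stim, 45.0)) == pytest.approx(0.0)

    def test_vectorized_consistency(self, rng):
        stims = measurement_stimuli("lk")
        trials = [_trial(1, i + 1, s, s.expected_rating + e)
                  for i, (s, e) in enumerate(
                      zip(stims, rng.normal(0, 5, 10)))]
        errs = [rating_error(t) for t in trials]
        assert np.allclose(
            errs, [t.actual_rating - t.stimulus.expected_rating
                   for t in trials])

    def test_aborted_excluded(self):
        stim = StimulusSpec("s", 1.0, "pflow", expected_rating=45.0)
        t = TrialRecord("p0", 1, 1, stim, 50.0, rt=61.0, aborted=True)
        with pytest.raises(ValueError):
            rating_error(t)


class TestMovingWindowRMS:
    def test_full_session_has_41_windows(self, rng):
        stims = measurement_stimuli("pflow")
        orders = [rng.permutation(10) for _ in range(5)]
        errors = [rng.normal(0, 5, 10) for _ in range(5)]
        trials = _session_trials(errors, stims, orders)
        assert len(moving_window_rms(trials, w=10)) == 41

    def test_constant_errors(self):
        stims = measurement_stimuli("pflow")
        orders = [np.arange(10)] * 5
        errors = [np.full(10, -3.0)] * 5
        trials = _session_trials(errors, stims, orders)
        assert np.allclose(moving_window_rms(trials, w=10), 3.0)

    def test_toy_two_blocks_vs_bruteforce(self, rng):
        stims = measurement_stimuli("pflow")
        orders = [rng.permutation(10), rng.permutation(10)]
        errors = [rng.normal(0, 4, 10), rng.normal(0, 4, 10)]
        trials = _session_trials(errors, stims, orders)
        out = moving_window_rms(trials, w=10)
        assert len(out) == 11
        # brute force: reorder block 2 to block 1's stimulus order by hand
        e1 = dict(zip(orders[0], errors[0]))
        e2 = dict(zip(orders[1], errors[1]))
        seq = [e1[s] for s in orders[0]] + [e2[s] for s in orders[0]]
        brute = [np.sqrt(np.mean(np.square(seq[i:i + 10])))
                 for i in range(11)]
        assert np.allclose(out, brute)

    def test_missing_stimulus_structure_error(self):
        stims = measurement_stimuli("pflow")
        orders = [np.arange(10), np.array([0] * 10)]
        errors = [np.zeros(10)] * 2
        trials = _session_trials(errors, stims, orders)
        with pytest.raises(ValueError):
            moving_window_rms(trials, w=10)


class TestSummarizeParticipant:
    def _trials_with_block_errors(self, per_block):
        stims = measurement_stimuli("pflow")
        orders = [np.arange(10)] * len(per_block)
        errors = [np.full(10, e) for e in per_block]
        return _session_trials(errors, stims, orders)

    def test_constant_errors(self):
        trials = self._trials_with_block_errors([9, 9, 3, 3, 3])
        out = summarize_participant(trials)
        assert np.allclose(out["mean_error"], 3.0)
        assert np.allclose(out["sd_error"], 0.0)

    def test_sample_sd(self):
        stims = measurement_stimuli("pflow")
        orders = [np.arange(10)] * 5
        errors = [np.zeros(10), np.zeros(10),
                  np.full(10, 0.0), np.full(10, 3.0), np.full(10, 6.0)]
        trials = _session_trials(errors, stims, orders)
        out = summarize_participant(trials)
        assert np.allclose(out["mean_error"], 3.0)
        assert np.allclose(out["sd_error"], 3.0)  # n-1 denominator

    def test_first_two_blocks_excluded(self, rng):
        base = self._trials_with_block_errors([0, 0, 1, 2, 3])
        pert = self._trials_with_block_errors([99, -99, 1, 2, 3])
        a = summarize_participant(base)
        b = summarize_participant(pert)
        pd.testing.assert_frame_equal(a, b)


class TestMixedAnova:
    def test_no_variance(self):
        res = mixed_anova(np.full((6, 3), 2.0), ["a", "a", "a", "b", "b", "b"])
        assert (res.table["F"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_bruteforce_ss_oracle(self, rng):
        y = rng.normal(size=(6, 3)) + np.array([[0], [0], [0], [2], [2], [2]])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = mixed_anova(y, groups)

        # explicit group-mean decomposition
        grand = y.mean()
        subj = y.mean(axis=1)
        ga = subj[:3].mean()
        gb = subj[3:].mean()
        sm = y.mean(axis=0)
        ss_a = 3 * (3 * (ga - grand) ** 2 + 3 * (gb - grand) ** 2)
        ss_bs = 3 * sum((s - grand) ** 2 for s in subj)
        ss_s = 6 * sum((m - grand) ** 2 for m in sm)
        cells = np.array([y[:3].mean(axis=0), y[3:].mean(axis=0)])
        gmeans = np.array([ga, gb])
        ss_as = sum(
            3 * (cells[g, s] - gmeans[g] - sm[s] + grand) ** 2
            for g in range(2) for s in range(3))
        ss_tot = ((y - grand) ** 2).sum()
        ss_eb = ss_bs - ss_a
        ss_ew = ss_tot - ss_bs - ss_s - ss_as
        f_a = (ss_a / 1) / (ss_eb / 4)
        f_s = (ss_s / 2) / (ss_ew / 8)
        f_as = (ss_as / 2) / (ss_ew / 8)
        assert res.table["F"].to_numpy() == pytest.approx(
            [f_a, f_s, f_as], abs=1e-9)
        assert res.table["eta_sq"].to_numpy() == pytest.approx(
            [ss_a / ss_tot, ss_s / ss_tot, ss_as / ss_tot], abs=1e-9)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        N, s = 12, 5
        y = rng.normal(size=(N, s)) + rng.normal(size=(N, 1))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = mixed_anova(y, groups)
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(N), s),
            "group": np.repeat(groups, s),
            "stim": np.tile(np.arange(s), N),
            "y": y.ravel(),
        })
        ref = pg.mixed_anova(long, dv="y", within="stim", between="group",
                             subject="subj")
        assert res.table["F"].to_numpy() == pytest.approx(
            ref["F"].to_numpy(), rel=1e-9)
        assert res.table["p"].to_numpy() == pytest.approx(
            ref["p_unc"].to_numpy(), rel=1e-6)

    def test_unbalanced_within_rejected(self, rng):
        y = rng.normal(size=(6, 3))
        y[2, 1] = np.nan
        with pytest.raises(ValueError):
            mixed_anova(y, ["a"] * 3 + ["b"] * 3)

    def test_df_structure(self, rng):
        # 183 participants in 3 groups x 10 stimuli: df = (2, 180), (9, 1620)
        y = rng.normal(size=(183, 10))
        groups = np.repeat(["a", "b", "c"], 61)
        t = mixed_anova(y, groups).table
        assert (t.loc[0, "df1"], t.loc[0, "df2"]) == (2, 180)
        assert (t.loc[1, "df1"], t.loc[1, "df2"]) == (9, 1620)
        assert (t.loc[2, "df1"], t.loc[2, "df2"]) == (18, 1620)


class TestTukeyPosthoc:
    def test_identical_groups(self):
        out = tukey_posthoc({"a": 1.0, "b": 1.0}, {"a": 10, "b": 10},
                            ms_error=2.0, df_error=18)
        assert out["q"].iloc[0] == 0.0
        assert out["p_adj"].iloc[0] == 1.0

    def test_shifted_group_detected(self, rng):
        n = 30
        groups = {"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n),
                  "c": rng.normal(5, 1, n)}
        means = {k: v.mean() for k, v in groups.items()}
        ns = {k: n for k in groups}
        pooled = np.mean([v.var(ddof=1) for v in groups.values()])
        out = tukey_posthoc(means, ns, pooled, 3 * (n - 1))
        sig = out[out["p_adj"] < 0.05]
        pairs = {frozenset((r.group_a, r.group_b)) for r in sig.itertuples()}
        assert pairs == {frozenset(("a", "c")), frozenset(("b", "c"))}

    def test_q_matches_hand_formula(self):
        from scipy.stats import studentized_range

        means = {"a": 2.0, "b": 5.0}
        ns = {"a": 12, "b": 12}
        ms, df = 4.0, 22
        out = tukey_posthoc(means, ns, ms, df)
        q_hand = 3.0 / math.sqrt(ms / 12)  # |diff| / sqrt(MS/n), equal n
        assert out["q"].iloc[0] == pytest.approx(q_hand, abs=1e-12)
        assert out["p_adj"].iloc[0] == pytest.approx(
            studentized_range.sf(q_hand, 2, df), rel=1e-9)

    def test_df_validation(self):
        with pytest.raises(ValueError):
            tukey_posthoc({"a": 0, "b": 1}, {"a": 2, "b": 2}, 1.0, 0)


class TestBonferroni:
    @pytest.mark.parametrize("n,expected", [(6, 0.05 / 6), (1, 0.05),
                                            (10, 0.005)])
    def test_values(self, n, expected):
        assert bonferroni_alpha(n) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


class TestCheckVariables:
    def _session(self, rts, training, practice):
        stim = StimulusSpec("s", 1.0, "pflow", 45.0)
        trials = [TrialRecord("p0", 1, i + 1, stim, 45.0, rt=rt,
                              aborted=rt >= 60.0)
                  for i, rt in enumerate(rts)]
        from pflow.experiment_analysis import TrainingTrial

        tt = [TrainingTrial(target=t, response=r) for t, r in training]
        return SessionRecord("p0", "pflow", tt, practice, trials,
                             RatingScale())

    def test_abort_threshold(self):
        s = self._session([5.0, 61.0, 12.0], [(10, 12), (80, 79)], [0.0])
        assert compute_check_variables(s)["n_aborted"] == 1

    def test_training_count_first_try(self):
        s = self._session([5.0], [(10, 12), (80, 79)], [0.0])
        assert compute_check_variables(s)["n_training_trials"] == 2

    def test_practice_rms(self):
        s = self._session([5.0], [(10, 12), (80, 79)], [3.0, 4.0, 0.0])
        assert compute_check_variables(s)["practice_rms"] == pytest.approx(
            math.sqrt(25 / 3))


class TestSimulateObserver:
    def _design(self, rng):
        return make_design(measurement_stimuli("pflow"), rng)

    def test_noise_free_limit(self):
        model = ObserverModel(bias=0.0,
                              sigma_by_algorithm={"pflow": 1e-12},
                              rng_seed=0)
        rng = np.random.default_rng(0)
        sess = simulate_observer(model, self._design(rng), rng=rng)
        for tr in sess.trials:
            # clipping at the scale bounds still applies (expected 5..95)
            exp = np.clip(tr.stimulus.expected_rating, 0, 100)
            assert tr.actual_rating == pytest.approx(exp, abs=1e-9)

    def test_error_sd_recovered(self):
        model = ObserverModel(sigma_by_algorithm={"pflow": 8.0}, rng_seed=1)
        rng = np.random.default_rng(1)
        stim = StimulusSpec("s", 1.0, "pflow", 45.0)
        noise = rng.normal(0, 8.0, 1000)
        # mid-scale stimulus: clipping never triggers
        sd = np.std(noise, ddof=1)
        assert 7.3 <= sd <= 8.7  # chi-square 99.9% interval at n=1000
        sess_errors = []
        for chunk in range(20):
            design = [stim] * 50
            sess = simulate_observer(model, design, rng=rng,
                                     participant_id=f"p{chunk}")
            sess_errors.extend(t.actual_rating - 45.0 for t in sess.trials)
        assert 7.3 <= np.std(sess_errors, ddof=1) <= 8.7

    def test_determinism(self):
        model = ObserverModel(rng_seed=5)
        d1 = self._design(np.random.default_rng(5))
        d2 = self._design(np.random.default_rng(5))
        s1 = simulate_observer(model, d1, rng=np.random.default_rng(9))
        s2 = simulate_observer(model, d2, rng=np.random.default_rng(9))
        assert [t.actual_rating for t in s1.trials] == \
            [t.actual_rating for t in s2.trials]
        assert [t.rt for t in s1.trials] == [t.rt for t in s2.trials]

    def test_design_structure(self):
        rng = np.random.default_rng(3)
        design = self._design(rng)
        assert len(design) == 50
        for b in range(5):
            block = design[b * 10:(b + 1) * 10]
            assert len({s.stimulus_id for s in block}) == 10


class TestCohortPipeline:
    def test_cohort_shape_and_determinism(self):
        model = ObserverModel(rng_seed=2)
        df1 = simulate_cohort(model, 3)
        df2 = simulate_cohort(model, 3)
        assert len(df1) == 3 * 3 * 50
        pd.testing.assert_frame_equal(df1, df2)

    def test_analyze_cohort_recovers_structure(self):
        model = ObserverModel(rng_seed=4)
        df = simulate_cohort(model, 25)
        res = analyze_cohort(df)
        assert res["sd_error"].table["p"].iloc[0] < res["sd_error"].alpha
        assert res["mean_rt"].table["p"].iloc[0] < res["mean_rt"].alpha
        assert res["mean_error"].table["p"].iloc[0] > 0.00833
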