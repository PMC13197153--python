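"""Choice-predictivity AUC, the decision-time rule, and the psychometric fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazedyn import decision_timing as dt


def pairwise_auc(left, right):
    """O(n*m) concordant-pair oracle: P(right > left) + half ties."""
    left, right = np.asarray(left), np.asarray(right)
    wins = sum((r > l) + 0.5 * (r == l) for l in left for r in right)
    return wins / (len(left) * len(right))


class TestAUC:
    def test_perfect_separation(self):
        assert dt.auc_at_time([-10, -8, -9], [5, 6, 7]) == 1.0

    def test_identical_samples_are_chance(self):
        assert dt.auc_at_time([1.0, 2.0], [1.0, 2.0]) == 0.5

    def test_three_of_four_concordant(self):
        assert dt.auc_at_time([-1, 2], [0, 3]) == 0.75

    def test_empty_class_rejected(self):
        with pytest.raises(dt.UndefinedAUCError):
            dt.auc_at_time([], [1.0])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_rank_method_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_l, n_r = rng.integers(1, 40, size=2)
        # heavy ties: half the draws from a small integer lattice
        left = np.where(rng.random(n_l) < 0.5,
                        rng.integers(-3, 4, n_l), rng.normal(0, 2, n_l))
        right = np.where(rng.random(n_r) < 0.5,
                         rng.integers(-3, 4, n_r), rng.normal(0, 2, n_r))
        assert dt.auc_at_time(left, right) == pytest.approx(
            pairwise_auc(left, right), abs=1e-12)

    def test_agrees_with_sklearn_roc_auc(self):
        """Independent cross-check against a reference ROC implementation."""
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(8)
        for _ in range(25):
            left = rng.normal(-1, 2, int(rng.integers(3, 40)))
            right = rng.normal(1, 2, int(rng.integers(3, 40)))
            y = np.r_[np.zeros(len(left)), np.ones(len(right))]
            scores = np.r_[left, right]
            assert dt.auc_at_time(left, right) == pytest.approx(
                roc_auc_score(y, scores), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_label_swap_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        left, right = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        assert dt.auc_at_time(left, right) == pytest.approx(
            1.0 - dt.auc_at_time(right, left), abs=1e-12)


class TestAUCCurve:
    def test_zero_noise_curve_steps_from_chance_to_one(self):
        """All trials turning at 300 ms, no noise or onset bias: chance
        before the turn, perfect separation once headings diverge."""
        from gazedyn import bias_report, synthdata
        cfg = synthdata.GeneratorConfig(
            n_trials=40, seed=3, heading_noise_sd=0.0, onset_heading_sd=0.0,
            onset_choice_bias=0.0, switch_bias=0.0, drift_speed=0.0,
            turn_time_sd=0.0, turn_time_mean=300.0)
        s = synthdata.generate_session(cfg)
        from gazedyn import io_model
        trials, _ = io_model.build_trials(s.pose, None, s.events,
                                          cfg.monitor_xy)
        curve = dt.auc_curve(trials, "heading")
        before = curve.auc[(curve.t_ms >= 0) & (curve.t_ms < 300)]
        after = curve.auc[(curve.t_ms > 320) & (curve.t_ms < 600)]
        np.testing.assert_allclose(before, 0.5)
        np.testing.assert_allclose(after, 1.0)

    def test_mirrored_signals_and_labels_leave_curve_unchanged(
            self, small_session):
        from gazedyn import io_model
        s = small_session
        trials, _ = io_model.build_trials(s.pose, None, s.events,
                                          s.config.monitor_xy)
        mirrored = []
        for tr in trials:
            h = io_model.HeadingTrace(tr.heading.t_ms, -tr.heading.heading_deg,
                                      tr.heading.valid)
            mirrored.append(io_model.TrialRecord(
                tr.trial_id, tr.session_id, tr.onset_ms, tr.display_ms,
                tr.condition, "L" if tr.choice == "R" else "R", tr.correct,
                None if tr.prev_choice is None else
                ("L" if tr.prev_choice == "R" else "R"), h))
        c1 = dt.auc_curve(trials, "heading")
        c2 = dt.auc_curve(mirrored, "heading")
        np.testing.assert_allclose(c1.auc, c2.auc, atol=1e-12)


class TestDecisionTime:
    def test_two_consecutive_rule_on_stated_sequence(self):
        """[0.80, 0.90, 0.85, 0.89, 0.91] at 12.5 ms/frame: the first
        qualifying pair is frames 4-5, so decision time is 37.5 ms."""
        curve = dt.AUCCurve(t_ms=np.arange(5) * 12.5,
                            auc=np.array([0.80, 0.90, 0.85, 0.89, 0.91]),
                            n_left=np.full(5, 10), n_right=np.full(5, 10))
        timing = dt.decision_time(curve)
        assert timing.decision_ms == pytest.approx(37.5)
        assert timing.status == "ok"

    def test_following_frame_variant(self):
        curve = dt.AUCCurve(t_ms=np.arange(5) * 12.5,
                            auc=np.array([0.80, 0.90, 0.85, 0.89, 0.91]),
                            n_left=np.full(5, 10), n_right=np.full(5, 10))
        timing = dt.decision_time(curve, report_following_frame=True)
        assert timing.decision_ms == pytest.approx(50.0)

    def test_never_crossing_reports_not_reached(self):
        curve = dt.AUCCurve(t_ms=np.arange(8) * 12.5,
                            auc=np.full(8, 0.6),
                            n_left=np.full(8, 10), n_right=np.full(8, 10))
        timing = dt.decision_time(curve)
        assert timing.decision_ms is None
        assert timing.status == "not_reached"

    def test_exactly_criterion_does_not_qualify(self):
        """The crossing is strict: AUC == 0.875 never starts a run."""
        curve = dt.AUCCurve(t_ms=np.arange(4) * 12.5,
                            auc=np.array([0.875, 0.875, 0.9, 0.9]),
                            n_left=np.full(4, 10), n_right=np.full(4, 10))
        assert dt.decision_time(curve).decision_ms == pytest.approx(25.0)

    def test_undefined_bins_cannot_start_a_run(self):
        curve = dt.AUCCurve(t_ms=np.arange(5) * 12.5,
                            auc=np.array([np.nan, 0.9, np.nan, 0.9, 0.9]),
                            n_left=np.full(5, 10), n_right=np.full(5, 10))
        assert dt.decision_time(curve).decision_ms == pytest.approx(37.5)

    def test_window_is_twice_time_to_95(self):
        auc = np.array([0.5, 0.9, 0.9, 0.96, 0.97])
        curve = dt.AUCCurve(t_ms=np.arange(5) * 12.5, auc=auc,
                            n_left=np.full(5, 10), n_right=np.full(5, 10))
        timing = dt.decision_time(curve)
        assert timing.t95_ms == pytest.approx(37.5)
        assert timing.window_ms == pytest.approx(75.0)

    def test_pointwise_dominance_gives_earlier_decision(self):
        rng = np.random.default_rng(5)
        base = np.clip(np.linspace(0.5, 0.99, 30)
                       + rng.normal(0, 0.02, 30), 0, 1)
        better = np.clip(base + 0.03, 0, 1)
        mk = lambda a: dt.AUCCurve(np.arange(30) * 12.5, a,
                                   np.full(30, 9), np.full(30, 9))
        ta = dt.decision_time(mk(better)).decision_ms
        tb = dt.decision_time(mk(base)).decision_ms
        assert ta is not None and tb is not None and ta <= tb


class TestPsychometric:
    def test_exact_hit(self):
        table = pd.DataFrame({
            "session": [0] * 3,
            "duration_ms": [100, 300, 500],
            "prop_correct": [0.70, 0.82, 0.90]})
        res = dt.psychometric_criterion(table)
        assert res.criterion_ms == pytest.approx(300.0)
        assert res.flagged is None

    def test_linear_interpolation(self):
        table = pd.DataFrame({
            "session": [0, 0],
            "duration_ms": [100, 500],
            "prop_correct": [0.70, 0.90]})
        res = dt.psychometric_criterion(table)
        assert res.criterion_ms == pytest.approx(340.0)

    def test_never_reaching_level_is_flagged(self):
        table = pd.DataFrame({
            "session": [0, 0, 0],
            "duration_ms": [100, 300, 500],
            "prop_correct": [0.80, 0.75, 0.70]})
        res = dt.psychometric_criterion(table)
        assert res.criterion_ms is None
        assert res.flagged == "not_reached"

    def test_single_duration_rejected(self):
        table = pd.DataFrame({"session": [0], "duration_ms": [300],
                              "prop_correct": [0.9]})
        with pytest.raises(ValueError):
            dt.psychometric_criterion(table)

    def test_sessions_averaged_before_interpolation(self):
        table = pd.DataFrame({
            "session": [0, 1, 0, 1],
            "duration_ms": [100, 100, 500, 500],
            "prop_correct": [0.6, 0.8, 0.86, 0.94]})
        res = dt.psychometric_criterion(table)
        # means 0.70 and 0.90 -> same as the two-point interpolation
        assert res.criterion_ms == pytest.approx(340.0)


class TestRankSum:
    def test_identical_samples_p_one(self):
        with pytest.warns(RuntimeWarning):
            rep = dt.compare_accuracy([3, 3, 3], [3, 3, 3])
        assert rep.p_value == 1.0

    def test_exact_small_sample_p(self):
        """Fully separated n=3 vs n=3: the most extreme of the 20 splits on
        either side, exact two-sided p = 0.1."""
        rep = dt.compare_accuracy([1, 2, 3], [10, 11, 12])
        assert rep.p_value == pytest.approx(0.1)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_statistic_is_u_count(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.integers(0, 6, 8).astype(float), rng.integers(0, 6, 6).astype(float)
        if np.all(np.concatenate([a, b]) == a[0]):
            return
        rep = dt.compare_accuracy(a, b)
        u = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert rep.statistic == pytest.approx(u)
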