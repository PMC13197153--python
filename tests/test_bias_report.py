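"""Onset/history bias tables, grouped summaries, mirror symmetry, report."""

import numpy as np
import pytest

from gazedyn import bias_report, io_model, synthdata


def _trials(cfg):
    s = synthdata.generate_session(cfg)
    trials, _ = io_model.build_trials(s.pose, s.eye, s.events, cfg.monitor_xy)
    return trials


def mirror_session(session):
    """Global left/right reflection at the raw-data level: pose x-coordinates
    reflected about the monitor's vertical axis, pupil displacement negated,
    choice labels swapped."""
    cfg = session.config
    mx = cfg.monitor_xy[0]
    pose_df = session.pose.data.copy()
    for lm in io_model.HEAD_LANDMARKS:
        pose_df[f"{lm}_x"] = 2 * mx - pose_df[f"{lm}_x"]
    pose = io_model.PoseTrack(pose_df, frame_rate=cfg.frame_rate_head)
    eye_df = session.eye.data.copy()
    eye_df["pupil_x"] = 2 * eye_df["eye_x"] - eye_df["pupil_x"]
    eye = io_model.EyeTrack(eye_df, frame_rate=cfg.frame_rate_eye)
    events = session.events.copy()
    swap = {"L": "R", "R": "L", "": ""}
    events["choice"] = events["choice"].map(swap)
    events["prev_choice"] = events["prev_choice"].map(swap)
    return pose, eye, events


class TestOnsetBias:
    def test_generator_bias_detected(self):
        cfg = synthdata.GeneratorConfig(n_trials=600, seed=31,
                                        onset_choice_bias=2.0, switch_bias=0.0)
        row = bias_report.onset_bias(_trials(cfg), "heading")
        assert row.p_value < 0.05
        assert row.effect > 0  # rightward choices start right of leftward

    def test_unbiased_generator_usually_non_significant(self):
        hits = 0
        for seed in range(12):
            cfg = synthdata.GeneratorConfig(
                n_trials=200, seed=100 + seed, onset_choice_bias=0.0,
                switch_bias=0.0, drift_speed=0.0)
            row = bias_report.onset_bias(_trials(cfg), "heading")
            hits += row.p_value < 0.05
        assert hits <= 3  # ~5% expected under the null

    def test_small_group_comparison_skipped(self):
        cfg = synthdata.GeneratorConfig(n_trials=30, seed=33)
        trials = _trials(cfg)
        one_sided = [tr for tr in trials if tr.choice == "R"] + \
            [tr for tr in trials if tr.choice == "L"][:1]
        row = bias_report.onset_bias(one_sided, "heading")
        assert row.p_value is None and row.note is not None


class TestHistoryBias:
    def test_switch_offset_detected_with_positive_index(self):
        cfg = synthdata.GeneratorConfig(n_trials=600, seed=34,
                                        onset_choice_bias=0.0, switch_bias=1.5)
        row = bias_report.history_bias(_trials(cfg), "heading")
        assert row.p_value < 0.05
        assert row.switch_index > 0

    def test_first_trial_excluded(self):
        cfg = synthdata.GeneratorConfig(n_trials=40, seed=35)
        trials = _trials(cfg)
        row = bias_report.history_bias(trials, "heading")
        assert row.n_left + row.n_right == len(trials) - 1

    def test_two_trial_input_degenerate(self):
        cfg = synthdata.GeneratorConfig(n_trials=10, seed=36)
        trials = _trials(cfg)[:2]
        row = bias_report.history_bias(trials, "heading")
        assert row.p_value is None


class TestMirrorSymmetry:
    def test_reflection_negates_effects_and_preserves_p(self, small_session):
        cfg = small_session.config
        res = bias_report.run_pipeline(small_session.pose, small_session.eye,
                                       small_session.events, cfg.monitor_xy)
        pose_m, eye_m, events_m = mirror_session(small_session)
        res_m = bias_report.run_pipeline(pose_m, eye_m, events_m,
                                         cfg.monitor_xy)
        for a, b in zip(res.bias_rows, res_m.bias_rows):
            # group summaries negate and swap sides; the R-L difference and
            # the p-value are invariant under the full reflection
            assert b.mean_left == pytest.approx(-a.mean_right, abs=1e-9)
            assert b.mean_right == pytest.approx(-a.mean_left, abs=1e-9)
            assert b.median_left == pytest.approx(-a.median_right, abs=1e-9)
            assert b.effect == pytest.approx(a.effect, abs=1e-9)
            assert b.p_value == pytest.approx(a.p_value, abs=1e-9)
        np.testing.assert_allclose(res.heading_curve.auc,
                                   res_m.heading_curve.auc, atol=1e-9)
        assert res_m.timing.decision_ms == res.timing.decision_ms
        # per-trial turning times are sign-invariant
        taus = {f.trial_id: f.tau_ms for f in res.fits if f.valid}
        taus_m = {f.trial_id: f.tau_ms for f in res_m.fits if f.valid}
        assert taus == pytest.approx(taus_m)


class TestGroupedSummary:
    def test_noiseless_port_angles_at_late_times(self):
        cfg = synthdata.GeneratorConfig(
            n_trials=40, seed=37, heading_noise_sd=0.0, onset_heading_sd=0.0,
            onset_choice_bias=0.0, switch_bias=0.0, drift_speed=0.0,
            turn_time_sd=0.0, turn_time_mean=200.0, ramp_speed=150.0)
        s = synthdata.generate_session(cfg)
        trials, _ = io_model.build_trials(s.pose, None, s.events,
                                          cfg.monitor_xy)
        from gazedyn import decision_timing, turning
        curve = decision_timing.auc_curve(trials, "heading")
        timing = decision_timing.decision_time(curve)
        fits = turning.fit_trials(trials, window_ms=timing.window_ms)
        table = bias_report.grouped_position_summary(trials, fits, timing)
        head = table[table.signal == "heading"].set_index("choice")
        # noiseless construction: heading equals the (zero) onset level at
        # the breakpoint itself and has split by the criterion crossing
        assert head.loc["L", "turning_mean"] == pytest.approx(0.0, abs=1e-9)
        assert head.loc["R", "turning_mean"] == pytest.approx(0.0, abs=1e-9)
        assert head.loc["L", "decision_mean"] < 0 < head.loc["R", "decision_mean"]

    def test_left_group_below_right_group(self, small_pipeline):
        table = small_pipeline.grouped_summary
        head = table[table.signal == "heading"].set_index("choice")
        for col in ("decision_mean", "turning_mean"):
            assert head.loc["L", col] < 0 < head.loc["R", col]

    def test_heading_only_summary_without_eye(self, small_session):
        s = small_session
        res = bias_report.run_pipeline(s.pose, None, s.events,
                                       s.config.monitor_xy)
        assert set(res.grouped_summary.signal) == {"heading"}


class TestReport:
    def test_report_deterministic_and_serialisable(self, small_pipeline):
        import json
        d1 = bias_report.build_report(small_pipeline)
        d2 = bias_report.build_report(small_pipeline)
        assert json.dumps(d1, sort_keys=True) == json.dumps(d2, sort_keys=True)

    def test_heading_only_report_marks_saccades_absent(self, small_session):
        s = small_session
        res = bias_report.run_pipeline(s.pose, None, s.events,
                                       s.config.monitor_xy)
        doc = bias_report.build_report(res)
        assert doc["saccades"] == "absent"
        assert doc["auc"]["eye"] == "absent"
        assert bias_report.report_summary_text(doc)  # renders without error

    def test_timing_ordering_matches_construction(self, small_pipeline):
        doc = bias_report.build_report(small_pipeline)
        t = doc["timing"]
        assert t["decision_ms"] <= t["mean_turning_ms"]
        assert t["mean_turning_ms"] < t["mean_turning_ms"] + \
            t["saccade_lag_mean_ms"]

    def test_trial_time_comparison_section(self, small_pipeline):
        rng = np.random.default_rng(0)
        doc = bias_report.build_report(
            small_pipeline,
            trial_times_with=rng.normal(6.4, 1.0, 40),
            trial_times_without=rng.normal(4.8, 1.0, 40))
        cmp = doc["behavior"]["trial_time_comparison"]
        assert cmp["p_value"] < 0.01
        assert cmp["mean_with_s"] > cmp["mean_without_s"]
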