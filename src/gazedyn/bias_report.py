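"""Onset-heading/eye decision biases, stay-switch analyses, grouped summaries,
and the session-level report tying all analysis stages together.

The onset-bias analysis asks whether the signal value at the stimulus-onset
frame differs between trials ending in left versus right choices; the
history-bias analysis groups the same onset values by the *previous* trial's
choice instead, with a switch index positive when onset heading points away
from the previously chosen side.  Comparisons default to the Wilcoxon
rank-sum test (the distributions need not be Gaussian); an unpaired t test
is available via ``test="t"``.  Horizontal eye position is normalized per
trial to its mean value in the pre-onset baseline before any eye bias
statistic is computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import decision_timing, io_model, saccades as sacc_mod, turning
from .io_model import TrialRecord


@dataclass
class BiasRow:
    """One grouped comparison of onset signal values."""

    signal: str                  # "heading" | "eye"
    grouping: str                # "choice" | "prev_choice"
    n_left: int
    n_right: int
    mean_left: float
    mean_right: float
    sd_left: float
    sd_right: float
    median_left: float
    median_right: float
    effect: float                # mean_right - mean_left
    statistic: float | None
    p_value: float | None
    test: str
    switch_index: float | None = None   # prev-choice grouping only
    note: str | None = None


def _onset_values(trials: list[TrialRecord], signal: str) -> dict[int, float]:
    """Signal value at the frame nearest t=0 (within half a frame period).

    Trials whose onset frame is masked (or missing) are excluded.  Eye
    values are normalized per trial to the mean valid pre-onset value.
    """
    out: dict[int, float] = {}
    for tr in trials:
        if signal == "heading":
            t, v = tr.heading.t_ms, tr.heading.values()
        else:
            if tr.eye is None:
                continue
            t, v = tr.eye.t_ms, tr.eye.values()
        if len(t) < 2:
            continue
        period = float(np.median(np.diff(t)))
        j = int(np.argmin(np.abs(t)))
        if abs(t[j]) > period / 2 or np.isnan(v[j]):
            continue
        val = v[j]
        if signal == "eye":
            pre = v[(t < 0) & ~np.isnan(v)]
            if len(pre) == 0:
                continue
            val = val - float(pre.mean())
        out[tr.trial_id] = float(val)
    return out


def _two_group_test(a: np.ndarray, b: np.ndarray, test: str):
    if test == "ranksum":
        rep = decision_timing.compare_accuracy(a, b)
        return rep.statistic, rep.p_value
    if test == "t":
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def onset_bias(trials: list[TrialRecord], signal: str = "heading",
               test: str = "ranksum") -> BiasRow:
    """Onset signal values grouped by the current trial's choice."""
    vals = _onset_values(trials, signal)
    by = {tr.trial_id: tr.choice for tr in trials}
    left = np.array([v for tid, v in vals.items() if by.get(tid) == "L"])
    right = np.array([v for tid, v in vals.items() if by.get(tid) == "R"])
    return _make_row(signal, "choice", left, right, test)


def history_bias(trials: list[TrialRecord], signal: str = "heading",
                 test: str = "ranksum") -> BiasRow:
    """Onset signal values grouped by the previous trial's choice.

    Trials without a previous-choice label (the first of each session) are
    excluded.  The switch index is mean(after-L) - mean(after-R): positive
    when onset heading points away from the previously chosen side.
    """
    vals = _onset_values(trials, signal)
    by = {tr.trial_id: tr.prev_choice for tr in trials
          if tr.prev_choice is not None}
    post_l = np.array([v for tid, v in vals.items() if by.get(tid) == "L"])
    post_r = np.array([v for tid, v in vals.items() if by.get(tid) == "R"])
    row = _make_row(signal, "prev_choice", post_l, post_r, test)
    if row.p_value is not None:
        row.switch_index = row.mean_left - row.mean_right
    return row


def _make_row(signal, grouping, left, right, test) -> BiasRow:
    def _stats(x):
        if len(x) == 0:
            return np.nan, np.nan, np.nan
        return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 \
            else 0.0, float(np.median(x))
    ml, sl, medl = _stats(left)
    mr, sr, medr = _stats(right)
    if len(left) < 2 or len(right) < 2:
        return BiasRow(signal, grouping, len(left), len(right), ml, mr,
                       sl, sr, medl, medr, effect=mr - ml, statistic=None,
                       p_value=None, test=test,
                       note="group with n<2; comparison skipped")
    stat, p = _two_group_test(left, right, test)
    return BiasRow(signal, grouping, len(left), len(right), ml, mr, sl, sr,
                   medl, medr, effect=mr - ml, statistic=stat, p_value=p,
                   test=test)


# ---------------------------------------------------------------------------
# grouped summaries at decision and turning times


def grouped_position_summary(
    trials: list[TrialRecord],
    fits: list[turning.TurningFit],
    timing: decision_timing.DecisionTiming,
) -> pd.DataFrame:
    """Mean +/- SD of heading (and eye, if present) per choice group at the
    stimulus-onset frame, the dataset decision-time frame, and each trial's
    own turning-time frame."""
    tau = {f.trial_id: f.tau_ms for f in fits if f.valid and f.tau_ms is not None}
    rows = []
    have_eye = any(tr.eye is not None for tr in trials)
    signals = ["heading"] + (["eye"] if have_eye else [])
    for signal in signals:
        onset_vals = _onset_values(trials, signal)
        for choice in ("L", "R"):
            sub = [tr for tr in trials if tr.choice == choice]
            at_onset = [onset_vals[tr.trial_id] for tr in sub
                        if tr.trial_id in onset_vals]
            at_dec = _values_at(sub, signal, lambda tr: timing.decision_ms)
            at_turn = _values_at(sub, signal, lambda tr: tau.get(tr.trial_id))
            rows.append({
                "signal": signal, "choice": choice, "n": len(sub),
                "onset_mean": _m(at_onset), "onset_sd": _s(at_onset),
                "decision_mean": _m(at_dec), "decision_sd": _s(at_dec),
                "turning_mean": _m(at_turn), "turning_sd": _s(at_turn),
            })
    return pd.DataFrame(rows)


def _values_at(trials, signal, when) -> list[float]:
    out = []
    for tr in trials:
        t_target = when(tr)
        if t_target is None:
            continue
        if signal == "heading":
            t, v = tr.heading.t_ms, tr.heading.values()
        else:
            if tr.eye is None:
                continue
            t, v = tr.eye.t_ms, tr.eye.values()
            pre = v[(t < 0) & ~np.isnan(v)]
            if len(pre) == 0:
                continue
            v = v - float(pre.mean())
        if len(t) < 2:
            continue
        period = float(np.median(np.diff(t)))
        j = int(np.argmin(np.abs(t - t_target)))
        if abs(t[j] - t_target) > period / 2 or np.isnan(v[j]):
            continue
        out.append(float(v[j]))
    return out


def _m(x):
    return float(np.mean(x)) if len(x) else np.nan


def _s(x):
    return float(np.std(x, ddof=1)) if len(x) > 1 else np.nan


# ---------------------------------------------------------------------------
# pipeline + report


@dataclass
class PipelineResult:
    """All computed outputs for one dataset."""

    n_trials: int
    n_excluded_no_choice: int
    accuracy: float
    heading_curve: decision_timing.AUCCurve
    timing: decision_timing.DecisionTiming
    eye_curve: decision_timing.AUCCurve | None
    fits: list[turning.TurningFit]
    turning_report: turning.OneSampleTReport | None
    events_saccades: list[sacc_mod.SaccadeEvent]
    n_saccade_trials_dropped: int
    main_sequence: sacc_mod.MainSequenceQC | None
    largest: sacc_mod.LargestSaccadeReport | None
    bias_rows: list[BiasRow]
    grouped_summary: pd.DataFrame | None
    thresholds: dict = field(default_factory=dict)


def run_pipeline(
    pose: io_model.PoseTrack,
    eye: io_model.EyeTrack | None,
    events: pd.DataFrame,
    monitor_xy,
    session_id: str = "session",
    likelihood_threshold: float = io_model.DEFAULT_LIKELIHOOD_THRESHOLD,
    criterion: float = decision_timing.DECISION_CRITERION,
    correct_only: bool = False,
    test: str = "ranksum",
    fallback_window_ms: float = 1000.0,
) -> PipelineResult:
    """Full analysis: likelihood filtering, trial assembly, AUC/decision
    timing, per-trial bilinear turning fits, saccade detection and
    largest-saccade analysis, and bias tables.

    When the AUC never reaches 0.95 the analysis window falls back to
    ``fallback_window_ms`` so the per-trial stages still run (flagged in
    the report).
    """
    pose = io_model.filter_by_likelihood(pose, likelihood_threshold)
    if eye is not None:
        eye = io_model.filter_by_likelihood(eye, likelihood_threshold)
    trials, excluded = io_model.build_trials(pose, eye, events, monitor_xy,
                                             session_id=session_id)
    if not trials:
        raise ValueError("no completed trials")
    curve = decision_timing.auc_curve(trials, "heading",
                                      correct_only=correct_only)
    timing = decision_timing.decision_time(curve, criterion=criterion)
    window = timing.window_ms if timing.window_ms else fallback_window_ms
    fits = turning.fit_trials(trials, window_ms=window)
    turning_rep = None
    if timing.decision_ms is not None:
        try:
            turning_rep = turning.turning_vs_decision(fits, timing.decision_ms)
        except ValueError:
            turning_rep = None
    eye_curve = None
    events_sacc: list[sacc_mod.SaccadeEvent] = []
    dropped = 0
    ms_qc = None
    largest = None
    if eye is not None and any(tr.eye is not None for tr in trials):
        try:
            eye_curve = decision_timing.auc_curve(trials, "eye",
                                                  correct_only=correct_only)
        except ValueError:
            eye_curve = None
        events_sacc, dropped = sacc_mod.detect_session_saccades(
            trials, window_ms=window)
        ms_qc = sacc_mod.main_sequence_qc(events_sacc)
        largest = sacc_mod.largest_saccade_analysis(trials, events_sacc, fits)
    bias_rows = [onset_bias(trials, "heading", test=test),
                 history_bias(trials, "heading", test=test)]
    if eye is not None and any(tr.eye is not None for tr in trials):
        bias_rows += [onset_bias(trials, "eye", test=test),
                      history_bias(trials, "eye", test=test)]
    grouped = grouped_position_summary(trials, fits, timing)
    accuracy = float(np.mean([tr.correct for tr in trials]))
    return PipelineResult(
        n_trials=len(trials), n_excluded_no_choice=excluded,
        accuracy=accuracy, heading_curve=curve, timing=timing,
        eye_curve=eye_curve, fits=fits, turning_report=turning_rep,
        events_saccades=events_sacc, n_saccade_trials_dropped=dropped,
        main_sequence=ms_qc, largest=largest, bias_rows=bias_rows,
        grouped_summary=grouped,
        thresholds={
            "likelihood_threshold": likelihood_threshold,
            "auc_criterion": criterion,
            "window_criterion": decision_timing.WINDOW_CRITERION,
            "velocity_threshold": sacc_mod.VELOCITY_THRESHOLD,
            "accel_threshold": sacc_mod.ACCEL_THRESHOLD,
            "amplitude_threshold": sacc_mod.AMPLITUDE_THRESHOLD,
            "vmax": sacc_mod.VMAX,
            "bias_test": test,
            "correct_only": correct_only,
        },
    )


def build_report(result: PipelineResult,
                 trial_times_with=None, trial_times_without=None) -> dict:
    """Assemble the session-level report as one JSON-serialisable document.

    Optional total-trial-time distributions with/without the eye-tracking
    apparatus are compared by rank-sum test when both are given; missing
    stages are marked absent, and the report is produced regardless.
    """
    timing = result.timing
    doc: dict = {
        "behavior": {
            "n_trials": result.n_trials,
            "n_excluded_no_choice": result.n_excluded_no_choice,
            "accuracy_pct": 100.0 * result.accuracy,
        },
        "timing": {
            "decision_ms": timing.decision_ms,
            "t95_ms": timing.t95_ms,
            "window_ms": timing.window_ms,
            "criterion": timing.criterion,
            "status": timing.status,
            "mean_turning_ms": None,
            "sd_turning_ms": None,
            "turning_vs_decision_t": None,
            "turning_vs_decision_p": None,
            "saccade_lag_mean_ms": None,
            "saccade_lag_p": None,
        },
        "auc": {
            "heading": result.heading_curve.to_frame().to_dict("list"),
            "eye": (result.eye_curve.to_frame().to_dict("list")
                    if result.eye_curve is not None else "absent"),
        },
        "bias": [vars(r) for r in result.bias_rows],
        "grouped_summary": (result.grouped_summary.to_dict("records")
                            if result.grouped_summary is not None else "absent"),
        "saccades": "absent",
        "thresholds": result.thresholds,
    }
    if result.turning_report is not None:
        tr = result.turning_report
        doc["timing"].update({
            "mean_turning_ms": tr.mean_tau_ms, "sd_turning_ms": tr.sd_tau_ms,
            "turning_vs_decision_t": tr.t_statistic,
            "turning_vs_decision_p": tr.p_value, "n_turning": tr.n,
        })
    if result.main_sequence is not None:
        ms = result.main_sequence
        sec = {
            "n_events": len(result.events_saccades),
            "n_retained": ms.n_retained, "n_excluded_fast": ms.n_excluded,
            "excluded_fraction": ms.excluded_fraction,
            "main_sequence_slope": ms.slope, "main_sequence_r": ms.r,
            "n_trials_dropped_tracking": result.n_saccade_trials_dropped,
        }
        if result.largest is not None:
            lg = result.largest
            sec.update({
                "largest_saccade_auc": lg.auc,
                "n_trials_with_saccade": lg.n_trials_with_saccade,
                "count_correct_mean": lg.count_correct_mean,
                "count_incorrect_mean": lg.count_incorrect_mean,
                "count_p": (lg.count_ranksum.p_value
                            if lg.count_ranksum else None),
            })
            doc["timing"].update({
                "saccade_lag_mean_ms": lg.lag_mean_ms,
                "saccade_lag_sd_ms": lg.lag_sd_ms,
                "saccade_lag_t": lg.paired_t,
                "saccade_lag_p": lg.paired_p,
                "n_saccade_paired": lg.n_paired,
            })
        doc["saccades"] = sec
    if trial_times_with is not None and trial_times_without is not None:
        try:
            rep = decision_timing.compare_accuracy(trial_times_without,
                                                   trial_times_with)
            doc["behavior"]["trial_time_comparison"] = {
                "mean_without_s": float(np.mean(trial_times_without)),
                "mean_with_s": float(np.mean(trial_times_with)),
                "statistic": rep.statistic, "p_value": rep.p_value,
            }
        except ValueError as exc:
            doc["behavior"]["trial_time_comparison"] = f"absent ({exc})"
    return _json_safe(doc)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def report_summary_text(doc: dict) -> str:
    """Short human-readable synopsis of a report document."""
    b, t = doc["behavior"], doc["timing"]
    lines = [
        f"trials analyzed: {b['n_trials']} "
        f"(excluded without choice: {b['n_excluded_no_choice']})",
        f"accuracy: {b['accuracy_pct']:.1f}%",
        f"decision time: {_fmt(t['decision_ms'])} ms "
        f"(AUC > {t['criterion']}, status {t['status']})",
        f"time to AUC 0.95: {_fmt(t['t95_ms'])} ms; "
        f"analysis window: {_fmt(t['window_ms'])} ms",
        f"turning time: {_fmt(t['mean_turning_ms'])} +/- "
        f"{_fmt(t['sd_turning_ms'])} ms "
        f"(vs decision: p = {_fmt(t['turning_vs_decision_p'])})",
    ]
    if doc["saccades"] != "absent":
        s = doc["saccades"]
        lines += [
            f"saccades: {s['n_retained']} retained, "
            f"{s['n_excluded_fast']} excluded >200 deg/s; "
            f"main sequence slope {_fmt(s['main_sequence_slope'])} "
            f"(r = {_fmt(s['main_sequence_r'])})",
            f"largest-saccade AUC: {_fmt(s.get('largest_saccade_auc'))}; "
            f"onset lag vs turning: {_fmt(t['saccade_lag_mean_ms'])} ms "
            f"(p = {_fmt(t['saccade_lag_p'])})",
        ]
    for r in doc["bias"]:
        if r["p_value"] is None:
            continue
        lines.append(
            f"{r['signal']} onset by {r['grouping']}: effect "
            f"{r['effect']:+.2f} deg, p = {r['p_value']:.3g}")
    return "\n".join(lines)


def _fmt(x):
    return "n/a" if x is None else f"{x:.4g}"


def write_report(doc: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(report_summary_text(doc) + "\n")
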