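"""Velocity/acceleration-threshold saccade detection and largest-saccade analysis.

Velocity and acceleration of horizontal eye position are computed with a
five-video-frame smoothed differentiator (62.5 ms at 80 Hz),

    v_n = (e_{n+2} + e_{n+1} - e_{n-1} - e_{n-2}) / (6 dt),

the acceleration being the same operator applied to the velocity.  Maximal
runs of frames with speed above 30 deg/s are candidate saccade periods; a
period is a saccade iff its peak absolute acceleration exceeds 2,000 deg/s^2
and the distance between the eye positions at its beginning and end exceeds
0.5 deg.  Events whose peak speed exceeds 200 deg/s fall off the linear
amplitude/peak-velocity main sequence and are excluded (and counted).
Saccade onset is the time of the first frame of the marked period; mean
pupil size is averaged over the period's frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decision_timing import RankSumReport, auc_at_time, compare_accuracy

VELOCITY_THRESHOLD = 30.0      # deg/s, speed
ACCEL_THRESHOLD = 2000.0       # deg/s^2, peak within period
AMPLITUDE_THRESHOLD = 0.5      # deg, endpoint-to-endpoint
VMAX = 200.0                   # deg/s, main-sequence exclusion
#: trials with at least this fraction of masked frames in the analysis
#: window are dropped from saccade statistics
MAX_MASKED_FRACTION = 0.2


@dataclass
class SaccadeEvent:
    trial_id: int
    onset_ms: float
    offset_ms: float
    amplitude_deg: float        # |position end - position start|
    distance_deg: float         # signed; negative = leftward
    peak_velocity: float        # deg/s
    peak_accel: float           # deg/s^2
    pupil_mean: float
    retained: bool              # False iff peak velocity > VMAX


@dataclass
class MainSequenceQC:
    slope: float | None         # (deg/s) per deg, OLS on retained events
    intercept: float | None
    r: float | None
    n_retained: int
    n_excluded: int             # peak velocity > VMAX
    excluded_fraction: float
    note: str | None = None


@dataclass
class LargestSaccadeReport:
    auc: float | None                     # signed distance vs choice
    n_trials_with_saccade: int
    lag_mean_ms: float | None             # largest-saccade onset - turning time
    lag_sd_ms: float | None
    paired_t: float | None
    paired_p: float | None
    n_paired: int
    count_correct_mean: float | None
    count_incorrect_mean: float | None
    count_ranksum: RankSumReport | None
    largest_by_trial: pd.DataFrame | None = None


def velocity_acceleration(eye_deg, dt_s: float, valid=None):
    """Five-sample smoothed first and second derivatives of eye position.

    Returns (v, a) in deg/s and deg/s^2, NaN at the two-frame margins and
    wherever the five-frame window touches a masked frame.
    """
    e = np.asarray(eye_deg, dtype=float)
    if valid is not None:
        e = np.where(np.asarray(valid, dtype=bool), e, np.nan)
    v = _five_point(e, dt_s)
    # the centred kernel skips the middle sample; a masked centre still
    # invalidates its window
    v[np.isnan(e)] = np.nan
    a = _five_point(v, dt_s)
    return v, a


def _five_point(x: np.ndarray, dt_s: float) -> np.ndarray:
    out = np.full_like(x, np.nan, dtype=float)
    if len(x) >= 5:
        out[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
    return out


def detect_saccades(
    t_ms,
    eye_deg,
    pupil_px=None,
    valid=None,
    dt_s: float | None = None,
    trial_id: int = -1,
    v_threshold: float = VELOCITY_THRESHOLD,
    a_threshold: float = ACCEL_THRESHOLD,
    amp_threshold: float = AMPLITUDE_THRESHOLD,
    v_max: float = VMAX,
) -> list[SaccadeEvent]:
    """Detect saccades in one horizontal eye-position trace.

    Candidate periods are maximal runs of frames with speed strictly above
    ``v_threshold`` (NaN velocity breaks a run; runs separated by a single
    sub-threshold frame are not merged).  A period becomes an event iff its
    peak absolute acceleration exceeds ``a_threshold`` and its
    endpoint-to-endpoint amplitude exceeds ``amp_threshold``.  Events with
    peak speed above ``v_max`` are returned with ``retained=False``.
    """
    t = np.asarray(t_ms, dtype=float)
    e = np.asarray(eye_deg, dtype=float)
    if dt_s is None:
        dt_s = float(np.median(np.diff(t))) / 1000.0
    v, a = velocity_acceleration(e, dt_s, valid=valid)
    fast = np.abs(v) > v_threshold  # NaN -> False
    events: list[SaccadeEvent] = []
    n = len(fast)
    i = 0
    while i < n:
        if not fast[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and fast[j + 1]:
            j += 1
        seg_a = a[i:j + 1]
        peak_a = np.nanmax(np.abs(seg_a)) if np.any(~np.isnan(seg_a)) else np.nan
        dist = e[j] - e[i]
        amp = abs(dist)
        peak_v = float(np.max(np.abs(v[i:j + 1])))
        if (not np.isnan(peak_a) and peak_a > a_threshold
                and amp > amp_threshold):
            pupil = np.nan
            if pupil_px is not None:
                seg_p = np.asarray(pupil_px, dtype=float)[i:j + 1]
                if np.any(~np.isnan(seg_p)):
                    pupil = float(np.nanmean(seg_p))
            events.append(SaccadeEvent(
                trial_id=trial_id,
                onset_ms=float(t[i]), offset_ms=float(t[j]),
                amplitude_deg=float(amp), distance_deg=float(dist),
                peak_velocity=peak_v, peak_accel=float(peak_a),
                pupil_mean=pupil, retained=bool(peak_v <= v_max),
            ))
        i = j + 1
    return events


def detect_session_saccades(
    trials,
    window_ms: float,
    max_masked_fraction: float = MAX_MASKED_FRACTION,
    **kwargs,
) -> tuple[list[SaccadeEvent], int]:
    """Detect saccades within the analysis window of every trial with eye data.

    Trials whose window has at least ``max_masked_fraction`` masked eye
    frames are dropped from saccade statistics; the count of dropped trials
    is returned alongside the events.
    """
    events: list[SaccadeEvent] = []
    dropped = 0
    for tr in trials:
        if tr.eye is None:
            continue
        sel = (tr.eye.t_ms >= 0) & (tr.eye.t_ms <= window_ms)
        if not np.any(sel):
            continue
        if np.mean(~tr.eye.valid[sel]) >= max_masked_fraction:
            dropped += 1
            continue
        events.extend(detect_saccades(
            tr.eye.t_ms[sel], tr.eye.eye_deg[sel],
            pupil_px=tr.eye.pupil_px[sel], valid=tr.eye.valid[sel],
            trial_id=tr.trial_id, **kwargs,
        ))
    return events, dropped


def main_sequence_qc(events: list[SaccadeEvent]) -> MainSequenceQC:
    """OLS line through (amplitude, peak velocity) of retained events."""
    retained = [ev for ev in events if ev.retained]
    n_exc = sum(1 for ev in events if not ev.retained)
    frac = n_exc / len(events) if events else 0.0
    if len(retained) < 3:
        return MainSequenceQC(None, None, None, len(retained), n_exc, frac,
                              note="fewer than 3 retained events; QC skipped")
    amp = np.array([ev.amplitude_deg for ev in retained])
    vel = np.array([ev.peak_velocity for ev in retained])
    res = stats.linregress(amp, vel)
    return MainSequenceQC(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), n_retained=len(retained), n_excluded=n_exc,
        excluded_fraction=frac,
    )


def largest_saccade_analysis(
    trials,
    events: list[SaccadeEvent],
    turning_fits=None,
) -> LargestSaccadeReport:
    """Largest-saccade predictivity and timing relative to head turning.

    Per trial the largest saccade maximises the absolute signed horizontal
    distance among retained events.  Reports (i) the AUC of signed distance
    for predicting choice, (ii) a paired two-sided t test of largest-saccade
    onset against the trial's turning time, and (iii) the rank-sum
    comparison of saccade counts on correct versus incorrect trials.
    """
    by_trial: dict[int, list[SaccadeEvent]] = {}
    for ev in events:
        if ev.retained:
            by_trial.setdefault(ev.trial_id, []).append(ev)
    trial_map = {tr.trial_id: tr for tr in trials}
    tau_map = {}
    if turning_fits is not None:
        tau_map = {f.trial_id: f.tau_ms for f in turning_fits
                   if f.valid and f.tau_ms is not None}
    rows = []
    for tid, evs in by_trial.items():
        if tid not in trial_map:
            continue
        largest = max(evs, key=lambda ev: abs(ev.distance_deg))
        rows.append({
            "trial_id": tid,
            "distance_deg": largest.distance_deg,
            "onset_ms": largest.onset_ms,
            "choice": trial_map[tid].choice,
            "tau_ms": tau_map.get(tid, np.nan),
        })
    largest_df = pd.DataFrame(rows) if rows else None
    auc = None
    if largest_df is not None:
        lv = largest_df.loc[largest_df.choice == "L", "distance_deg"]
        rv = largest_df.loc[largest_df.choice == "R", "distance_deg"]
        if len(lv) and len(rv):
            auc = auc_at_time(lv, rv)
    lag_mean = lag_sd = t_stat = p_val = None
    n_paired = 0
    if largest_df is not None:
        paired = largest_df.dropna(subset=["tau_ms"])
        n_paired = len(paired)
        if n_paired >= 2:
            lags = (paired["onset_ms"] - paired["tau_ms"]).to_numpy()
            lag_mean = float(lags.mean())
            lag_sd = float(lags.std(ddof=1))
            res = stats.ttest_rel(paired["onset_ms"], paired["tau_ms"])
            t_stat, p_val = float(res.statistic), float(res.pvalue)
    # saccade counts per trial, correct vs incorrect
    counts = {tr.trial_id: 0 for tr in trials if tr.eye is not None}
    for ev in events:
        if ev.retained and ev.trial_id in counts:
            counts[ev.trial_id] += 1
    corr = np.array([counts[tr.trial_id] for tr in trials
                     if tr.eye is not None and tr.correct], dtype=float)
    incorr = np.array([counts[tr.trial_id] for tr in trials
                       if tr.eye is not None and not tr.correct], dtype=float)
    count_report = None
    if len(corr) >= 2 and len(incorr) >= 2:
        count_report = compare_accuracy(corr, incorr)
    return LargestSaccadeReport(
        auc=auc,
        n_trials_with_saccade=0 if largest_df is None else len(largest_df),
        lag_mean_ms=lag_mean, lag_sd_ms=lag_sd,
        paired_t=t_stat, paired_p=p_val, n_paired=n_paired,
        count_correct_mean=float(corr.mean()) if len(corr) else None,
        count_incorrect_mean=float(incorr.mean()) if len(incorr) else None,
        count_ranksum=count_report,
        largest_by_trial=largest_df,
    )


def events_to_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": ev.trial_id, "onset_ms": ev.onset_ms,
        "offset_ms": ev.offset_ms, "amp_deg": ev.amplitude_deg,
        "dist_deg": ev.distance_deg, "vpeak": ev.peak_velocity,
        "apeak": ev.peak_accel, "pupil_mean": ev.pupil_mean,
        "retained": ev.retained,
    } for ev in events])
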