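"""Choice-predictivity AUC curves, decision time and the psychometric criterion.

At each video frame after stimulus onset, the signed signal values (heading
or horizontal eye position; rightward positive) across trials are scored by
how well they separate eventual right from left choices, summarised as the
area under the empirical ROC curve over all possible cut points.  AUC is
computed by the rank (Mann-Whitney) identity

    AUC = P(score_right > score_left) + 1/2 P(tie),

with rightward choice as the positive class.  The dataset decision time is
the first frame of the earliest run of two consecutive frames whose AUC
exceeds the criterion (default 0.875); the analysis window used by the
turning and saccade stages is twice the time for the AUC to reach 0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import TrialRecord

DECISION_CRITERION = 0.875
WINDOW_CRITERION = 0.95


class UndefinedAUCError(ValueError):
    """AUC requested with an empty class."""


@dataclass
class AUCCurve:
    """Choice-predictivity AUC as a function of time from stimulus onset."""

    t_ms: np.ndarray       # one bin per video frame, strictly increasing
    auc: np.ndarray        # NaN where undefined (fewer than 2 per class)
    n_left: np.ndarray
    n_right: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t_ms, "auc": self.auc,
            "n_left": self.n_left, "n_right": self.n_right,
        })


@dataclass
class DecisionTiming:
    """Criterion crossings of an AUC curve and the derived analysis window."""

    decision_ms: float | None
    t95_ms: float | None
    window_ms: float | None       # = 2 x t95
    criterion: float
    status: str                   # "ok" | "not_reached"


@dataclass
class PsychometricResult:
    """Proportion correct vs display duration and the 0.82-criterion duration."""

    durations_ms: np.ndarray
    proportion: np.ndarray        # mean across sessions
    sem: np.ndarray
    criterion_ms: float | None
    criterion_level: float
    flagged: str | None           # None | "not_reached" | "extrapolated"


@dataclass
class RankSumReport:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    note: str | None = None


# ---------------------------------------------------------------------------


def auc_at_time(values_left, values_right) -> float:
    """AUC for predicting rightward choice from signed signal values.

    Rank-based Mann-Whitney formulation with midranks for ties; equals the
    area under the empirical ROC curve over all cut points, and equals the
    fraction of (left, right) trial pairs in which the right-choice value
    is larger (ties counted half).
    """
    left = np.asarray(values_left, dtype=float)
    right = np.asarray(values_right, dtype=float)
    left = left[~np.isnan(left)]
    right = right[~np.isnan(right)]
    if len(left) == 0 or len(right) == 0:
        raise UndefinedAUCError("both choice classes must be non-empty")
    pooled = np.concatenate([left, right])
    ranks = stats.rankdata(pooled)
    r_right = ranks[len(left):].sum()
    n_l, n_r = len(left), len(right)
    u_right = r_right - n_r * (n_r + 1) / 2.0
    return float(u_right / (n_l * n_r))


def auc_curve(
    trials: list[TrialRecord],
    signal: str = "heading",
    correct_only: bool = False,
    min_per_class: int = 2,
) -> AUCCurve:
    """Frame-resolved choice-predictivity curve for ``signal``.

    ``signal`` is ``"heading"`` (head-camera grid) or ``"eye"`` (eye-camera
    grid).  Each post-onset frame time pools the signal values of all
    included trials at that frame, dropping masked frames; bins where either
    class has fewer than ``min_per_class`` values are undefined (NaN).
    """
    vals, t_grid, choices = _signal_matrix(trials, signal, correct_only)
    if vals is None:
        raise ValueError("no trials with the requested signal")
    is_right = choices == "R"
    if is_right.all() or (~is_right).all():
        raise ValueError("need trials of both choices")
    n_bins = vals.shape[1]
    auc = np.full(n_bins, np.nan)
    n_l = np.zeros(n_bins, dtype=int)
    n_r = np.zeros(n_bins, dtype=int)
    for j in range(n_bins):
        col = vals[:, j]
        lv = col[~is_right & ~np.isnan(col)]
        rv = col[is_right & ~np.isnan(col)]
        n_l[j], n_r[j] = len(lv), len(rv)
        if len(lv) >= min_per_class and len(rv) >= min_per_class:
            auc[j] = auc_at_time(lv, rv)
    return AUCCurve(t_ms=t_grid, auc=auc, n_left=n_l, n_right=n_r)


def _signal_matrix(trials, signal, correct_only):
    """Stack per-trial post-onset signal values on a common frame grid.

    Frame index k = round(t / period) on the signal's native camera grid;
    returns (matrix [n_trials x n_bins], bin times, choices).
    """
    use = [t for t in trials if (not correct_only or t.correct)]
    if signal == "heading":
        tv = [(t.heading.t_ms, t.heading.values()) for t in use]
    elif signal == "eye":
        tv = [(t.eye.t_ms, t.eye.values()) for t in use if t.eye is not None]
        use = [t for t in use if t.eye is not None]
    else:
        raise ValueError(f"unknown signal {signal!r}")
    if not tv:
        return None, None, None
    periods = [np.median(np.diff(t)) for t, _ in tv if len(t) > 1]
    period = float(np.median(periods))
    if not all(np.isclose(p, period, rtol=0.02) for p in periods):
        raise ValueError("trials are not on a common time grid")
    k_max = 0
    for t, _ in tv:
        post = t[t >= -period / 2]
        if len(post):
            k_max = max(k_max, int(round(post[-1] / period)))
    mat = np.full((len(use), k_max + 1), np.nan)
    for i, (t, v) in enumerate(tv):
        k = np.round(t / period).astype(int)
        sel = (k >= 0) & (k <= k_max) & np.isclose(t, k * period, atol=period / 4)
        mat[i, k[sel]] = v[sel]
    t_grid = np.arange(k_max + 1) * period
    choices = np.array([t.choice for t in use])
    return mat, t_grid, choices


def decision_time(
    curve: AUCCurve,
    criterion: float = DECISION_CRITERION,
    consecutive: int = 2,
    window_criterion: float = WINDOW_CRITERION,
    report_following_frame: bool = False,
) -> DecisionTiming:
    """Decision time by criterion crossing of an AUC curve.

    Decision time is the timestamp of the FIRST frame of the earliest run of
    ``consecutive`` frames all with AUC strictly above ``criterion``
    (undefined bins cannot start or continue a run).  Setting
    ``report_following_frame`` reports the frame after the qualifying run
    instead.  The time to reach ``window_criterion`` (default 0.95) uses a
    single-frame crossing, and the analysis window is twice that time.
    """
    d_ms = _first_crossing(curve, criterion, consecutive, report_following_frame)
    t95 = _first_crossing(curve, window_criterion, 1, False)
    status = "ok" if d_ms is not None else "not_reached"
    return DecisionTiming(
        decision_ms=d_ms,
        t95_ms=t95,
        window_ms=None if t95 is None else 2.0 * t95,
        criterion=criterion,
        status=status,
    )


def _first_crossing(curve, criterion, consecutive, following):
    above = curve.auc > criterion  # NaN compares False
    run = 0
    for j, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= consecutive:
            start = j - consecutive + 1
            idx = j + 1 if following else start
            if idx >= len(curve.t_ms):
                idx = len(curve.t_ms) - 1
            return float(curve.t_ms[idx])
    return None


def psychometric_criterion(
    session_table: pd.DataFrame,
    level: float = 0.82,
) -> PsychometricResult:
    """Criterion display duration from per-session psychometric data.

    ``session_table`` has columns ``session``, ``duration_ms``,
    ``prop_correct``.  The mean proportion-correct curve across sessions is
    linearly interpolated at ``level`` (first upward crossing); a curve that
    never reaches the level is flagged with no value.
    """
    required = {"duration_ms", "prop_correct"}
    if not required <= set(session_table.columns):
        raise ValueError(f"session table needs columns {sorted(required)}")
    grp = session_table.groupby("duration_ms")["prop_correct"]
    mean = grp.mean()
    sem = grp.sem().fillna(0.0)
    durations = mean.index.to_numpy(dtype=float)
    if len(durations) < 2:
        raise ValueError("need at least two distinct display durations")
    props = mean.to_numpy(dtype=float)
    crit = None
    flagged: str | None = "not_reached"
    for i in range(len(durations)):
        if props[i] >= level:
            if i == 0:
                crit, flagged = float(durations[0]), "extrapolated" \
                    if props[0] > level else None
                if props[0] == level:
                    flagged = None
                break
            x0, x1 = durations[i - 1], durations[i]
            y0, y1 = props[i - 1], props[i]
            crit = float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))
            flagged = None
            break
    return PsychometricResult(
        durations_ms=durations,
        proportion=props,
        sem=sem.to_numpy(dtype=float),
        criterion_ms=crit,
        criterion_level=level,
        flagged=flagged,
    )


def compare_accuracy(dist_a, dist_b) -> RankSumReport:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with tie correction.

    Used for comparisons between distributions of accuracy, trial time, or
    any per-session/per-trial scalar that need not be Gaussian.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must have at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("degenerate all-equal samples; p set to 1",
                      RuntimeWarning, stacklevel=2)
        return RankSumReport(statistic=len(a) * len(b) / 2.0, p_value=1.0,
                             n_a=len(a), n_b=len(b), note="degenerate")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankSumReport(statistic=float(res.statistic),
                         p_value=float(res.pvalue), n_a=len(a), n_b=len(b))
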