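"""Per-trial head-turning time via a continuous two-segment linear fit.

Within the analysis window (stimulus onset to twice the time for heading
choice-predictivity to reach AUC 0.95), each trial's heading-vs-time curve
is fit with a bilinear function: two straight lines constrained to meet at a
breakpoint.  The breakpoint minimising the least-squares error, searched
over interior frame times, is the trial's turning time -- the moment the
head turns away from the monitor toward a reward port.  Turning times are
compared to the dataset decision time with a one-sample t test, since the
decision time is a single value per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: single-line SSE / bilinear SSE below this flags "no clear turn"
LOW_CONTRAST_RATIO = 1.05
#: candidate breakpoints stay this many frames away from each window edge
EDGE_MARGIN = 2


@dataclass
class TurningFit:
    """Result of the bilinear fit for one trial."""

    trial_id: int
    tau_ms: float | None          # breakpoint = turning time
    slope1: float                 # deg/ms before the turn
    intercept1: float
    slope2: float                 # deg/ms after the turn
    intercept2: float
    sse: float
    sse_line: float               # best single-line SSE (nested model)
    valid: bool
    low_contrast: bool            # SSE ratio < LOW_CONTRAST_RATIO

    @property
    def contrast_ratio(self) -> float:
        if self.sse <= 0:
            return np.inf if self.sse_line > 0 else 1.0
        return self.sse_line / self.sse


@dataclass
class OneSampleTReport:
    mean_tau_ms: float
    sd_tau_ms: float
    decision_ms: float
    t_statistic: float | None
    df: int
    p_value: float | None
    n: int
    note: str | None = None


def _hinge_design(t: np.ndarray, c: float) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t, np.maximum(t - c, 0.0)])


def fit_bilinear(
    t_ms,
    heading_deg,
    valid=None,
    trial_id: int = -1,
    min_frames: int = 5,
) -> TurningFit:
    """Continuous two-segment least-squares fit to one heading trace.

    The breakpoint is searched over interior frame times (at least
    :data:`EDGE_MARGIN` frames from each edge of the window); for each
    candidate the model ``y = b0 + b1 t + b2 max(t - c, 0)`` is solved in
    closed form, and the candidate with minimal SSE wins, ties broken toward
    the earliest.  Masked frames are omitted from the least squares.  Traces
    with fewer than ``min_frames`` valid frames yield an invalid fit.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(heading_deg, dtype=float)
    if valid is None:
        valid = ~np.isnan(y)
    else:
        valid = np.asarray(valid, dtype=bool) & ~np.isnan(y)
    t, y = t[valid], y[valid]
    if len(t) < min_frames:
        return TurningFit(trial_id, None, np.nan, np.nan, np.nan, np.nan,
                          np.nan, np.nan, valid=False, low_contrast=False)
    # best single line (nested model, for the turn-contrast flag)
    X1 = np.column_stack([np.ones_like(t), t])
    coef1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse_line = float(np.sum((y - X1 @ coef1) ** 2))
    candidates = t[EDGE_MARGIN:len(t) - EDGE_MARGIN]
    if len(candidates) == 0:
        return TurningFit(trial_id, None, np.nan, np.nan, np.nan, np.nan,
                          np.nan, sse_line, valid=False, low_contrast=False)
    best_sse = np.inf
    best_c = None
    best_beta = None
    for c in candidates:
        X = _hinge_design(t, c)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ beta) ** 2))
        if sse < best_sse - 1e-12:
            best_sse, best_c, best_beta = sse, float(c), beta
    b0, b1, b2 = best_beta
    ratio = sse_line / best_sse if best_sse > 0 else (
        np.inf if sse_line > 0 else 1.0)
    return TurningFit(
        trial_id=trial_id,
        tau_ms=best_c,
        slope1=float(b1),
        intercept1=float(b0),
        slope2=float(b1 + b2),
        intercept2=float(b0 - b2 * best_c),
        sse=best_sse,
        sse_line=sse_line,
        valid=True,
        low_contrast=bool(ratio < LOW_CONTRAST_RATIO),
    )


def fit_trials(trials, window_ms: float, min_frames: int = 5) -> list[TurningFit]:
    """Bilinear fit for every trial's heading within [0, window_ms].

    Trials whose post-onset frames share one grid and have no masked frames
    are solved in a single batched pass (one least-squares solve per
    candidate breakpoint for all trials simultaneously); the rest fall back
    to the per-trial path.
    """
    prepared = []
    for tr in trials:
        sel = (tr.heading.t_ms >= 0) & (tr.heading.t_ms <= window_ms)
        prepared.append((tr.trial_id, tr.heading.t_ms[sel],
                         tr.heading.values()[sel]))
    # batch trials with identical, fully valid grids
    fits: dict[int, TurningFit] = {}
    groups: dict[tuple, list[int]] = {}
    for i, (tid, t, y) in enumerate(prepared):
        if len(t) >= min_frames and not np.any(np.isnan(y)):
            groups.setdefault((len(t), round(float(t[0]), 6),
                               round(float(t[-1]), 6)), []).append(i)
        else:
            fits[i] = fit_bilinear(t, y, trial_id=tid, min_frames=min_frames)
    for idxs in groups.values():
        t = prepared[idxs[0]][1]
        Y = np.column_stack([prepared[i][2] for i in idxs])
        ids = [prepared[i][0] for i in idxs]
        for i, fit in zip(idxs, _batch_bilinear(t, Y, ids)):
            fits[i] = fit
    return [fits[i] for i in range(len(prepared))]


def _batch_bilinear(t: np.ndarray, Y: np.ndarray, ids) -> list[TurningFit]:
    """Solve the bilinear fit for many trials sharing a common grid."""
    n, m = Y.shape  # frames x trials
    X1 = np.column_stack([np.ones_like(t), t])
    coef1, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    sse_line = np.sum((Y - X1 @ coef1) ** 2, axis=0)
    candidates = t[EDGE_MARGIN:n - EDGE_MARGIN]
    sse_all = np.empty((len(candidates), m))
    betas = np.empty((len(candidates), 3, m))
    for k, c in enumerate(candidates):
        X = _hinge_design(t, c)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        betas[k] = beta
        sse_all[k] = np.sum((Y - X @ beta) ** 2, axis=0)
    # earliest candidate within numerical tolerance of the minimum
    min_sse = sse_all.min(axis=0)
    first = np.argmax(sse_all <= min_sse + 1e-12, axis=0)
    out = []
    for j in range(m):
        k = first[j]
        b0, b1, b2 = betas[k, :, j]
        c = float(candidates[k])
        sse = float(sse_all[k, j])
        sl = float(sse_line[j])
        ratio = sl / sse if sse > 0 else (np.inf if sl > 0 else 1.0)
        out.append(TurningFit(
            trial_id=ids[j], tau_ms=c,
            slope1=float(b1), intercept1=float(b0),
            slope2=float(b1 + b2), intercept2=float(b0 - b2 * c),
            sse=sse, sse_line=sl, valid=True,
            low_contrast=bool(ratio < LOW_CONTRAST_RATIO),
        ))
    return out


def turning_vs_decision(fits: list[TurningFit], decision_ms: float) -> OneSampleTReport:
    """One-sample two-sided t test of turning times against the decision time."""
    taus = np.array([f.tau_ms for f in fits if f.valid and f.tau_ms is not None])
    if len(taus) < 2:
        raise ValueError("need at least 2 valid turning fits")
    mean = float(taus.mean())
    sd = float(taus.std(ddof=1))
    if sd == 0.0:
        diff = mean - decision_ms
        return OneSampleTReport(
            mean_tau_ms=mean, sd_tau_ms=0.0, decision_ms=decision_ms,
            t_statistic=None, df=len(taus) - 1,
            p_value=1.0 if diff == 0 else 0.0, n=len(taus),
            note="zero variance; exact comparison reported without t",
        )
    res = stats.ttest_1samp(taus, popmean=decision_ms)
    return OneSampleTReport(
        mean_tau_ms=mean, sd_tau_ms=sd, decision_ms=decision_ms,
        t_statistic=float(res.statistic), df=len(taus) - 1,
        p_value=float(res.pvalue), n=len(taus),
    )


def fits_to_frame(fits: list[TurningFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": f.trial_id, "tau_ms": f.tau_ms,
        "slope1": f.slope1, "slope2": f.slope2,
        "sse": f.sse, "sse_line": f.sse_line,
        "flag": "low_contrast" if f.low_contrast else
                ("invalid" if not f.valid else "ok"),
    } for f in fits])
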