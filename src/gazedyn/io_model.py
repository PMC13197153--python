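"""Reading pose/eye/event tables and deriving heading, eye-position and gaze traces.

The overhead camera yields markerless-pose tables in the DeepLabCut CSV
dialect (three header rows: scorer / bodyparts / coords, with x, y,
likelihood columns per landmark).  Head direction is the signed angle at the
neck between the neck-to-nose line and the neck-to-monitor-center line;
negative angles point left of the monitor center, positive right.  The
head-mounted eye camera yields pupil- and eyelid-ellipse parameters per
frame, from which horizontal eye-in-head position is derived under a
spherical-eye model whose radius is half the eyelid-ellipse major axis.

Frames in which any required landmark falls below a tracking-likelihood
threshold are masked out, never interpolated; all downstream statistics skip
masked frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HEAD_LANDMARKS = ("nose", "neck_center", "neck_left", "neck_right")
#: landmarks whose likelihood gates frame validity (nose + neck markers)
REQUIRED_HEAD_LANDMARKS = ("nose", "neck_center", "neck_left", "neck_right")
EYE_MARKERS = ("pupil", "eye")

DEFAULT_LIKELIHOOD_THRESHOLD = 0.9


class FormatError(ValueError):
    """A table does not conform to the expected dialect/schema."""


class DataError(ValueError):
    """A table is well-formed but its contents violate an invariant."""


class AlignmentError(ValueError):
    """Event timestamps cannot be aligned with the recorded streams."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class PoseTrack:
    """Per-frame overhead-camera landmark coordinates with likelihoods.

    ``data`` holds one row per frame with columns ``<landmark>_x``,
    ``<landmark>_y``, ``<landmark>_likelihood`` for each of
    :data:`HEAD_LANDMARKS`, plus ``timestamp_ms``.  ``valid`` is the
    likelihood mask (True = retained frame).
    """

    data: pd.DataFrame
    frame_rate: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ts = np.asarray(self.data["timestamp_ms"], dtype=float)
        if len(ts) > 1:
            dt = np.diff(ts)
            if np.any(dt <= 0):
                raise DataError("pose timestamps must be strictly increasing")
            period = 1000.0 / self.frame_rate
            if not np.allclose(dt, period, rtol=0.01):
                raise DataError(
                    f"frame period inconsistent with {self.frame_rate} Hz"
                )
        if self.valid is None:
            self.valid = np.ones(len(self.data), dtype=bool)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps_ms(self) -> np.ndarray:
        return np.asarray(self.data["timestamp_ms"], dtype=float)


@dataclass
class EyeTrack:
    """Per-frame pupil/eyelid ellipse parameters from the eye camera.

    Columns: ``timestamp_ms``, ``pupil_x``, ``pupil_y``, ``pupil_major``,
    ``pupil_minor``, ``eye_x``, ``eye_y``, ``eye_major``,
    ``pupil_likelihood``, ``eye_likelihood``.
    """

    data: pd.DataFrame
    frame_rate: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ts = np.asarray(self.data["timestamp_ms"], dtype=float)
        if len(ts) > 1 and np.any(np.diff(ts) <= 0):
            raise DataError("eye timestamps must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(len(self.data), dtype=bool)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps_ms(self) -> np.ndarray:
        return np.asarray(self.data["timestamp_ms"], dtype=float)


@dataclass
class HeadingTrace:
    """Heading angle vs time for one trial, t=0 at stimulus onset."""

    t_ms: np.ndarray          # relative to stimulus onset
    heading_deg: np.ndarray   # signed, negative = left of monitor center
    valid: np.ndarray

    def values(self) -> np.ndarray:
        out = np.array(self.heading_deg, dtype=float)
        out[~self.valid] = np.nan
        return out


@dataclass
class EyeTrace:
    """Horizontal eye-in-head position and pupil size for one trial."""

    t_ms: np.ndarray
    eye_deg: np.ndarray       # signed, negative = left
    pupil_px: np.ndarray
    valid: np.ndarray

    def values(self) -> np.ndarray:
        out = np.array(self.eye_deg, dtype=float)
        out[~self.valid] = np.nan
        return out


@dataclass
class TrialRecord:
    """One completed trial: events plus time-aligned heading/eye segments."""

    trial_id: int
    session_id: str
    onset_ms: float
    display_ms: float
    condition: str
    choice: str                    # 'L' or 'R'
    correct: bool
    prev_choice: str | None        # None on the first trial of a session
    heading: HeadingTrace
    eye: EyeTrace | None = None
    #: eye trace resampled onto the head-frame grid (nearest neighbour)
    eye_on_head_grid: np.ndarray | None = None

    @property
    def gaze_deg(self) -> np.ndarray | None:
        """Gaze trajectory g = heading + eye, on the head-frame grid.

        Defined only at frames where both parent traces are valid; NaN
        elsewhere.
        """
        if self.eye_on_head_grid is None:
            return None
        return self.heading.values() + self.eye_on_head_grid


# ---------------------------------------------------------------------------
# DeepLabCut-dialect I/O


def read_pose_csv(path, frame_rate: float, scorer: str | None = None) -> PoseTrack:
    """Read a DeepLabCut-dialect pose CSV into a :class:`PoseTrack`.

    The dialect has three header rows (scorer / bodyparts / coords) and an
    index column of frame numbers.  Timestamps are reconstructed from the
    frame index and ``frame_rate`` (Hz) since the dialect carries none.

    Raises :class:`FormatError` if a required landmark column is missing.
    """
    try:
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse pose CSV {path}: {exc}") from exc
    bodyparts = {c[1] for c in raw.columns}
    for lm in REQUIRED_HEAD_LANDMARKS:
        if lm not in bodyparts:
            raise FormatError(f"pose CSV missing bodypart column: {lm!r}")
    cols: dict[str, np.ndarray] = {}
    for lm in HEAD_LANDMARKS:
        for coord in ("x", "y", "likelihood"):
            sub = [c for c in raw.columns if c[1] == lm and c[2] == coord]
            if not sub:
                raise FormatError(f"pose CSV missing {coord} for {lm!r}")
            vals = pd.to_numeric(raw[sub[0]], errors="coerce")
            bad = np.nonzero(vals.isna().to_numpy())[0]
            if bad.size:
                # +4: 3 header rows + 1-based line numbering
                lines = ", ".join(str(i + 4) for i in bad[:5])
                raise DataError(
                    f"malformed values for {lm}/{coord} at line(s) {lines}"
                )
            cols[f"{lm}_{coord}"] = vals.to_numpy(dtype=float)
    n = len(raw)
    cols["timestamp_ms"] = np.asarray(raw.index, dtype=float) * 1000.0 / frame_rate
    return PoseTrack(pd.DataFrame(cols), frame_rate=frame_rate)


def write_pose_csv(track: PoseTrack, path, scorer: str = "gazedyn") -> None:
    """Write a :class:`PoseTrack` in the DeepLabCut CSV dialect."""
    columns = pd.MultiIndex.from_tuples(
        [(scorer, lm, coord) for lm in HEAD_LANDMARKS
         for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    out = pd.DataFrame(
        {(scorer, lm, coord): track.data[f"{lm}_{coord}"]
         for lm in HEAD_LANDMARKS for coord in ("x", "y", "likelihood")},
    )
    out.columns = columns
    out.index.name = None
    out.to_csv(path)


def read_eye_csv(path, frame_rate: float = 80.0) -> EyeTrack:
    """Read a tidy eye-camera CSV (frame, timestamp_ms, ellipse params)."""
    raw = pd.read_csv(path)
    required = [
        "timestamp_ms", "pupil_x", "pupil_y", "pupil_major", "pupil_minor",
        "eye_x", "eye_y", "eye_major", "pupil_likelihood", "eye_likelihood",
    ]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"eye CSV missing column(s): {missing}")
    return EyeTrack(raw[required].astype(float), frame_rate=frame_rate)


def write_eye_csv(track: EyeTrack, path) -> None:
    out = track.data.copy()
    out.insert(0, "frame", np.arange(len(out)))
    out.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    """Read a trial-event table (trial_id, t_onset_ms, display_ms, condition,
    choice, correct, prev_choice)."""
    raw = pd.read_csv(path, dtype={"choice": str, "prev_choice": str})
    required = ["trial_id", "t_onset_ms", "display_ms", "condition",
                "choice", "correct"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"events CSV missing column(s): {missing}")
    if "prev_choice" not in raw.columns:
        raw["prev_choice"] = [None] + list(raw["choice"][:-1])
    return raw


# ---------------------------------------------------------------------------
# likelihood filtering


def filter_by_likelihood(track, threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD):
    """Mask frames whose tracking likelihood falls below ``threshold``.

    A frame is invalid iff ANY required landmark's likelihood is strictly
    below the threshold.  Returns a copy with an updated validity mask; no
    interpolation is performed.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if isinstance(track, PoseTrack):
        like_cols = [f"{lm}_likelihood" for lm in REQUIRED_HEAD_LANDMARKS]
    elif isinstance(track, EyeTrack):
        like_cols = ["pupil_likelihood", "eye_likelihood"]
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported track type {type(track)!r}")
    like = track.data[like_cols].to_numpy(dtype=float)
    valid = np.all(like >= threshold, axis=1)
    return replace(track, data=track.data, valid=valid)


# ---------------------------------------------------------------------------
# geometry


def heading_angle(nose_xy, neck_xy, monitor_xy) -> float:
    """Signed heading angle (degrees) at the neck.

    The angle between the neck-to-monitor-center ray and the neck-to-nose
    ray, in (-180, 180].  The overhead camera's image y-axis points down;
    with the monitor at the top of the image, a nose rotated toward the
    animal's right (image +x) gives a positive angle, so rightward port
    choices end at positive heading.
    """
    nose = np.asarray(nose_xy, dtype=float)
    neck = np.asarray(neck_xy, dtype=float)
    mon = np.asarray(monitor_xy, dtype=float)
    v_mon = mon - neck
    v_nose = nose - neck
    if np.allclose(v_mon, 0) or np.allclose(v_nose, 0):
        raise ValueError("undefined heading: coincident landmark points")
    cross = v_mon[0] * v_nose[1] - v_mon[1] * v_nose[0]
    dot = float(v_mon @ v_nose)
    ang = math.degrees(math.atan2(cross, dot))
    if ang <= -180.0:  # map (-180, 180]
        ang += 360.0
    return ang


def heading_trace(pose: PoseTrack, monitor_xy) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised heading angle for every frame of ``pose``.

    Returns (heading_deg, valid); masked frames carry NaN.
    """
    nx = pose.data["nose_x"].to_numpy(float)
    ny = pose.data["nose_y"].to_numpy(float)
    cx = pose.data["neck_center_x"].to_numpy(float)
    cy = pose.data["neck_center_y"].to_numpy(float)
    mx, my = float(monitor_xy[0]), float(monitor_xy[1])
    v1x, v1y = mx - cx, my - cy
    v2x, v2y = nx - cx, ny - cy
    cross = v1x * v2y - v1y * v2x
    dot = v1x * v2x + v1y * v2y
    ang = np.degrees(np.arctan2(cross, dot))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    valid = pose.valid & ((np.abs(v1x) + np.abs(v1y)) > 0) \
        & ((np.abs(v2x) + np.abs(v2y)) > 0)
    out = np.where(valid, ang, np.nan)
    return out, valid


def eye_angle(pupil_x, eye_x, eye_major, pupil_major=None):
    """Horizontal eye-in-head angle (degrees) under a spherical-eye model.

    The eyeball diameter is approximated by the eyelid-ellipse major axis;
    the horizontal angle is ``arcsin(dx / r)`` with ``dx`` the horizontal
    pupil-center displacement from the eye-ellipse center and ``r`` half the
    major axis.  Displacements beyond the radius are clipped to +/-90 deg and
    flagged.  Negative = leftward.  Returns ``(angle_deg, pupil_size,
    clipped)``; pupil size is the pupil-ellipse major axis.
    """
    eye_major = np.asarray(eye_major, dtype=float)
    if np.any(eye_major <= 0):
        raise ValueError("eye major axis must be positive")
    dx = np.asarray(pupil_x, dtype=float) - np.asarray(eye_x, dtype=float)
    ratio = dx / (eye_major / 2.0)
    clipped = np.abs(ratio) > 1.0
    ang = np.degrees(np.arcsin(np.clip(ratio, -1.0, 1.0)))
    size = None if pupil_major is None else np.asarray(pupil_major, dtype=float)
    return ang, size, clipped


def eye_trace(track: EyeTrack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame horizontal eye angle and pupil size for a whole track."""
    ang, size, _clipped = eye_angle(
        track.data["pupil_x"].to_numpy(float),
        track.data["eye_x"].to_numpy(float),
        track.data["eye_major"].to_numpy(float),
        track.data["pupil_major"].to_numpy(float),
    )
    ang = np.where(track.valid, ang, np.nan)
    return ang, size, track.valid.copy()


# ---------------------------------------------------------------------------
# trial assembly


def build_trials(
    pose: PoseTrack,
    eye: EyeTrack | None,
    events: pd.DataFrame,
    monitor_xy,
    session_id: str = "session",
    window_ms: float | None = None,
    pre_ms: float = 500.0,
) -> tuple[list[TrialRecord], int]:
    """Assemble time-aligned :class:`TrialRecord` objects.

    Every trial's traces are re-referenced to stimulus onset (t=0) and carry
    a ``pre_ms`` pre-onset baseline.  Segments are disjoint: each trial ends
    where the next trial's baseline begins.  The eye trace is resampled onto
    the head-frame grid by nearest neighbour within half a head-frame period
    for gaze composition.  Trials without a recorded choice are excluded and
    counted; the second return value is the number excluded.

    ``window_ms`` further limits each trial's segment length after onset.
    """
    head_deg, head_valid = heading_trace(pose, monitor_xy)
    head_ts = pose.timestamps_ms
    head_period = 1000.0 / pose.frame_rate
    if eye is not None:
        e_deg, e_size, e_valid = eye_trace(eye)
        eye_ts = eye.timestamps_ms
    trials: list[TrialRecord] = []
    excluded = 0
    onsets = events["t_onset_ms"].to_numpy(float)
    for i, row in events.reset_index(drop=True).iterrows():
        choice = row["choice"]
        if not isinstance(choice, str) or choice not in ("L", "R"):
            excluded += 1
            continue
        onset = float(row["t_onset_ms"])
        if onset < head_ts[0] - head_period or onset > head_ts[-1]:
            raise AlignmentError(
                f"trial {row['trial_id']} onset {onset} ms outside recording span"
            )
        t_end = (onsets[i + 1] - pre_ms) if i + 1 < len(onsets) \
            else head_ts[-1] + head_period
        if window_ms is not None:
            t_end = min(t_end, onset + window_ms + head_period / 2)
        t_start = onset - pre_ms - head_period / 2
        lo = int(np.searchsorted(head_ts, t_start, side="left"))
        hi = int(np.searchsorted(head_ts, t_end, side="left"))
        h = HeadingTrace(
            t_ms=head_ts[lo:hi] - onset,
            heading_deg=head_deg[lo:hi],
            valid=head_valid[lo:hi],
        )
        etrace = None
        eye_on_grid = None
        if eye is not None:
            elo = int(np.searchsorted(eye_ts, t_start, side="left"))
            ehi = int(np.searchsorted(eye_ts, t_end, side="left"))
            etrace = EyeTrace(
                t_ms=eye_ts[elo:ehi] - onset,
                eye_deg=e_deg[elo:ehi],
                pupil_px=e_size[elo:ehi],
                valid=e_valid[elo:ehi],
            )
            eye_on_grid = _nearest_resample(
                etrace.t_ms, etrace.values(), h.t_ms, head_period / 2
            )
        prev = row.get("prev_choice")
        if not isinstance(prev, str) or prev not in ("L", "R"):
            prev = None
        trials.append(
            TrialRecord(
                trial_id=int(row["trial_id"]),
                session_id=session_id,
                onset_ms=onset,
                display_ms=float(row["display_ms"]),
                condition=str(row["condition"]),
                choice=choice,
                correct=bool(row["correct"]),
                prev_choice=prev,
                heading=h,
                eye=etrace,
                eye_on_head_grid=eye_on_grid,
            )
        )
    return trials, excluded


def _nearest_resample(src_t, src_v, dst_t, tol_ms) -> np.ndarray:
    """Nearest-neighbour resampling of ``src`` onto ``dst_t`` within ``tol_ms``."""
    out = np.full(len(dst_t), np.nan)
    if len(src_t) == 0:
        return out
    idx = np.searchsorted(src_t, dst_t)
    idx = np.clip(idx, 1, len(src_t) - 1) if len(src_t) > 1 else np.zeros(
        len(dst_t), dtype=int)
    if len(src_t) > 1:
        left = src_t[idx - 1]
        right = src_t[idx]
        pick = np.where(np.abs(dst_t - left) <= np.abs(right - dst_t),
                        idx - 1, idx)
    else:
        pick = idx
    dist = np.abs(src_t[pick] - dst_t)
    ok = dist <= tol_ms
    out[ok] = src_v[pick[ok]]
    return out


def trials_to_tidy(trials: list[TrialRecord]) -> pd.DataFrame:
    """Per-trial tidy table (trial_id, t_ms, heading_deg, eye_deg, gaze_deg, valid)."""
    rows = []
    for tr in trials:
        gaze = tr.gaze_deg
        eye = tr.eye_on_head_grid
        for j, t in enumerate(tr.heading.t_ms):
            rows.append({
                "trial_id": tr.trial_id,
                "t_ms": t,
                "heading_deg": tr.heading.heading_deg[j]
                if tr.heading.valid[j] else np.nan,
                "eye_deg": np.nan if eye is None else eye[j],
                "gaze_deg": np.nan if gaze is None else gaze[j],
                "valid": bool(tr.heading.valid[j]),
            })
    return pd.DataFrame(rows)
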