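"""Synthetic sessions with the statistical structure of the freely moving
two-alternative forced-choice paradigm, plus ground-truth labels.

Each trial emulates an animal running a corridor toward a monitor, viewing a
brief stimulus, and turning toward the left or right reward port (about
+/-30 deg from the monitor center as seen from the midline):

* heading starts near-flat at a small onset value (optionally biased toward
  the eventual choice and away from the previous choice), drifts slowly
  toward the choice from stimulus onset, then ramps linearly toward the
  signed port angle from the trial's true turning time onward, clamped at
  the port angle, with white frame noise -- an exactly two-segment profile
  inside the analysis window, so the bilinear turning fit is well-posed by
  construction;
* the horizontal eye trace is fixational noise plus injected saccades whose
  position profile is a raised-cosine step; one large choice-directed
  saccade lags the turning time by a configurable latency, an optional
  counter-directed compensatory saccade follows it, and a few smaller
  saccades of random direction are scattered through the trial;
* overhead-camera pose landmarks (nose, neck markers) are back-computed so
  that the heading geometry of :mod:`gazedyn.io_model` reproduces the
  intended heading angle exactly, and pupil/eyelid ellipses are
  back-computed so the spherical-eye mapping reproduces the intended eye
  angle.

The head and eye cameras run on independent clocks (70 or 80 Hz vs 80 Hz)
whose grids share t=0 at each stimulus onset; trial slots are multiples of
100 ms so onsets land on both grids.

Saccade peak velocities are calibrated against the five-frame smoothed
differentiator used by the detector: for a raised-cosine step spanning N
frames, the measured peak velocity is a fixed multiple kappa(N) of the
amplitude, so the generator picks the N whose kappa is closest to the
requested main-sequence slope and records the effective slope it actually
synthesises.  At 80 Hz this double-smoothed kernel also caps the measurable
peak acceleration at a few hundred (deg/s^2) per degree of amplitude, so
the 2,000 deg/s^2 detection threshold implies an amplitude floor of roughly
5 deg (see :func:`detection_floor`); the generator injects saccades above
that floor, as the retained saccades of any real session at these
thresholds necessarily were.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io_model
from .io_model import EyeTrack, PoseTrack

#: trial slots are multiples of this so onsets land on the 70 and 80 Hz grids
_SLOT_QUANTUM_MS = 100.0


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic session generator.

    Timing defaults follow the recorded behaviour of ferrets in this
    paradigm: per-trial turning times near 300 +/- 110 ms after stimulus
    onset, onset-heading spread of ~4 deg with ~1.5 deg choice- and
    history-dependent offsets, ports at +/-30 deg, and the largest
    choice-directed saccade lagging the head turn by ~+40 +/- 150 ms.
    """

    n_trials: int = 600
    frame_rate_head: float = 80.0     # Hz; 70 or 80
    frame_rate_eye: float = 80.0      # Hz
    accuracy: float = 0.75            # P(choice == correct side)
    turn_time_mean: float = 300.0     # ms after stimulus onset
    turn_time_sd: float = 110.0       # ms
    port_angle: float = 30.0          # deg, asymptotic heading magnitude
    ramp_speed: float = 45.0          # deg/s of the post-turn heading ramp
    drift_speed: float = 8.0          # deg/s pre-turn drift toward choice
    heading_noise_sd: float = 2.0     # deg per frame
    onset_heading_sd: float = 4.0     # deg
    onset_choice_bias: float = 0.75   # deg toward the eventual choice
    switch_bias: float = 0.75         # deg away from previous choice (offset
                                      # mode) OR P(correct side flips)
                                      # (sequence mode)
    switch_mode: str = "offset"       # "offset" | "sequence"
    saccade_lag_mean: float = 40.0    # ms, largest-saccade onset - turn time
    saccade_lag_sd: float = 150.0     # ms
    saccade_amplitude_mean: float = 7.0   # deg, largest saccade
    saccade_amplitude_sd: float = 1.2     # deg
    main_sequence_slope: float = 20.0     # (deg/s) per deg of amplitude
    eye_noise_sd: float = 0.1         # deg per eye frame
    compensatory_fraction: float = 0.5    # P(counter-saccade after largest)
    extra_saccade_rate: float = 1.0   # mean count of small extra saccades
    oversize_fraction: float = 0.0    # P(largest saccade exceeds 200 deg/s)
    wander_prob: float = 0.0          # P(premature turn + reorient excursion)
    pupil_baseline: float = 40.0      # px
    pupil_sd: float = 2.0             # px
    dropout_fraction: float = 0.0     # P(frame marked low-likelihood)
    baseline_ms: float = 500.0        # pre-onset capture per trial
    post_ms: float = 1500.0           # post-onset capture per trial
    display_ms: float = 400.0         # stimulus display duration (events)
    condition: str = "contrast"
    monitor_xy: tuple = (400.0, 100.0)    # overhead-camera pixels
    neck_xy: tuple = (400.0, 500.0)
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate_head <= 0 or self.frame_rate_eye <= 0:
            raise ValueError("frame rates must be positive")
        for name in ("accuracy", "compensatory_fraction", "oversize_fraction",
                     "wander_prob", "dropout_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.switch_mode not in ("offset", "sequence"):
            raise ValueError(f"unknown switch_mode {self.switch_mode!r}")
        if self.switch_mode == "sequence" and not 0.0 <= self.switch_bias <= 1.0:
            raise ValueError("sequence-mode switch_bias must be a probability")
        if self.turn_time_mean <= 0:
            raise ValueError("turn_time_mean must be positive")
        for name in ("n_trials", "port_angle", "ramp_speed",
                     "saccade_amplitude_mean", "main_sequence_slope",
                     "pupil_baseline", "baseline_ms", "post_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.drift_speed < 0:
            raise ValueError("drift_speed must be non-negative")
        if self.ramp_speed <= self.drift_speed:
            raise ValueError("ramp_speed must exceed drift_speed")
        for name in ("turn_time_sd", "heading_noise_sd", "onset_heading_sd",
                     "saccade_lag_sd", "saccade_amplitude_sd", "eye_noise_sd",
                     "pupil_sd", "extra_saccade_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.switch_mode == "offset" and self.switch_bias < 0:
            raise ValueError("offset-mode switch_bias must be non-negative")


@dataclass
class InjectedSaccade:
    onset_ms: float       # relative to stimulus onset
    amplitude_deg: float
    direction: int        # +1 right, -1 left
    kind: str             # "largest" | "compensatory" | "extra"


@dataclass
class TrialTruth:
    trial_id: int
    choice: str
    correct_side: str
    correct: bool
    prev_choice: str | None
    turn_time_ms: float               # true breakpoint of the heading ramp
    onset_heading_mean: float
    largest_onset_ms: float | None
    largest_amplitude_deg: float | None
    saccades: list[InjectedSaccade] = field(default_factory=list)


@dataclass
class GroundTruth:
    trials: list[TrialTruth]
    effective_main_sequence_slope: float   # kappa(N), see module docstring
    saccade_n_frames: int
    config: GeneratorConfig

    def to_json(self, path) -> None:
        payload = {
            "effective_main_sequence_slope": self.effective_main_sequence_slope,
            "saccade_n_frames": self.saccade_n_frames,
            "config": asdict(self.config),
            "trials": [asdict(t) for t in self.trials],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = GeneratorConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in payload["config"].items()
        })
        trials = []
        for t in payload["trials"]:
            sacc = [InjectedSaccade(**s) for s in t.pop("saccades")]
            trials.append(TrialTruth(**t, saccades=sacc))
        return cls(trials=trials,
                   effective_main_sequence_slope=payload[
                       "effective_main_sequence_slope"],
                   saccade_n_frames=payload["saccade_n_frames"], config=cfg)


@dataclass
class SyntheticSession:
    pose: PoseTrack
    eye: EyeTrack
    events: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# saccade waveform calibration


def raised_cosine_step(n_frames: int) -> np.ndarray:
    """Unit-amplitude raised-cosine position step sampled at n_frames+1 points."""
    k = np.arange(n_frames + 1)
    return (1.0 - np.cos(np.pi * k / n_frames)) / 2.0


def kernel_peak_ratio(n_frames: int, dt_s: float) -> float:
    """Peak velocity per unit amplitude as measured by the five-frame kernel."""
    pad = 10
    trace = np.zeros(2 * pad + n_frames + 1)
    trace[pad:pad + n_frames + 1] = raised_cosine_step(n_frames)
    trace[pad + n_frames + 1:] = 1.0
    v = (trace[4:] + trace[3:-1] - trace[1:-3] - trace[:-4]) / (6.0 * dt_s)
    return float(np.max(np.abs(v)))


def calibrate_saccade_duration(slope: float, dt_s: float,
                               n_min: int = 3, n_max: int = 12):
    """Pick the step duration whose measured main-sequence slope is closest
    to the requested one; returns (n_frames, effective_slope)."""
    best = None
    for n in range(n_min, n_max + 1):
        kappa = kernel_peak_ratio(n, dt_s)
        if best is None or abs(kappa - slope) < abs(best[1] - slope):
            best = (n, kappa)
    return best


def kernel_peak_accel_ratio(n_frames: int, dt_s: float) -> float:
    """Peak |acceleration| per unit amplitude through the five-frame kernel
    applied twice (position -> velocity -> acceleration)."""
    pad = 10
    trace = np.zeros(2 * pad + n_frames + 1)
    trace[pad:pad + n_frames + 1] = raised_cosine_step(n_frames)
    trace[pad + n_frames + 1:] = 1.0
    v = (trace[4:] + trace[3:-1] - trace[1:-3] - trace[:-4]) / (6.0 * dt_s)
    a = (v[4:] + v[3:-1] - v[1:-3] - v[:-4]) / (6.0 * dt_s)
    return float(np.max(np.abs(a)))


def detection_floor(n_frames: int, dt_s: float,
                    v_threshold: float = 30.0,
                    a_threshold: float = 2000.0,
                    amp_threshold: float = 0.5) -> float:
    """Smallest amplitude whose raised-cosine step clears all three
    detection thresholds through the smoothed differentiators.

    At 80 Hz the acceleration threshold dominates: the double-smoothed
    kernel caps peak acceleration at a few hundred (deg/s^2) per degree of
    amplitude, so saccades below roughly 5 deg cannot be detected at these
    thresholds regardless of their true kinematics.
    """
    return max(v_threshold / kernel_peak_ratio(n_frames, dt_s),
               a_threshold / kernel_peak_accel_ratio(n_frames, dt_s),
               amp_threshold)


# ---------------------------------------------------------------------------
# generation


def generate_session(config: GeneratorConfig) -> SyntheticSession:
    """Generate one synthetic session; bit-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    head_period = 1000.0 / config.frame_rate_head
    eye_period = 1000.0 / config.frame_rate_eye
    slot = _SLOT_QUANTUM_MS * np.ceil(
        (config.baseline_ms + config.post_ms) / _SLOT_QUANTUM_MS)
    n = config.n_trials

    # --- trial-level draws -------------------------------------------------
    choices = np.empty(n, dtype="U1")
    correct_sides = np.empty(n, dtype="U1")
    prev = None
    for i in range(n):
        if config.switch_mode == "sequence" and prev is not None:
            flip = rng.random() < config.switch_bias
            correct_sides[i] = ("L" if prev == "R" else "R") if flip else prev
        else:
            correct_sides[i] = "R" if rng.random() < 0.5 else "L"
        is_correct = rng.random() < config.accuracy
        if is_correct:
            choices[i] = correct_sides[i]
        else:
            choices[i] = "L" if correct_sides[i] == "R" else "R"
        prev = choices[i]
    correct = choices == correct_sides
    prev_choices = np.concatenate([[""], choices[:-1]])
    sign = np.where(choices == "R", 1.0, -1.0)
    prev_sign = np.where(prev_choices == "R", 1.0,
                         np.where(prev_choices == "L", -1.0, 0.0))

    tau_lo = 5 * head_period
    tau_hi = config.post_ms - 300.0
    taus = _truncated_normal(rng, config.turn_time_mean, config.turn_time_sd,
                             tau_lo, tau_hi, n)
    # snap turning times to the head-frame grid so the bilinear breakpoint
    # search (which runs on frame times) is well-posed
    taus = np.round(taus / head_period) * head_period

    mu0 = sign * config.onset_choice_bias
    if config.switch_mode == "offset":
        mu0 = mu0 - prev_sign * config.switch_bias
    h0 = mu0 + rng.normal(0.0, config.onset_heading_sd, size=n)

    # --- heading on the head-camera grid -----------------------------------
    n_head = int(round(n * slot / head_period))
    t_head = np.arange(n_head) * head_period
    trial_idx = np.minimum((t_head // slot).astype(int), n - 1)
    t_rel = t_head - (trial_idx * slot + config.baseline_ms)
    # two-segment profile from stimulus onset: slow decision-related drift
    # toward the choice until the turning time, then the port-ward ramp
    drift = (config.drift_speed / 1000.0) * np.clip(
        np.minimum(t_rel, taus[trial_idx]), 0.0, None)
    ramp = (config.ramp_speed / 1000.0) * np.clip(
        t_rel - taus[trial_idx], 0.0, None)
    heading = h0[trial_idx] + sign[trial_idx] * (drift + ramp)
    heading = np.where(sign[trial_idx] > 0,
                       np.minimum(heading, config.port_angle),
                       np.maximum(heading, -config.port_angle))
    if config.wander_prob > 0:
        heading = _add_wander(rng, config, heading, t_rel, trial_idx, sign, taus)
    heading = heading + rng.normal(0.0, config.heading_noise_sd, size=n_head)

    pose = _pose_from_heading(rng, config, t_head, heading)

    # --- eye trace on the eye-camera grid -----------------------------------
    n_frames_sacc, eff_slope = calibrate_saccade_duration(
        config.main_sequence_slope, eye_period / 1000.0)
    template = raised_cosine_step(n_frames_sacc)
    n_eye = int(round(n * slot / eye_period))
    t_eye = np.arange(n_eye) * eye_period
    eye = rng.normal(0.0, config.eye_noise_sd, size=n_eye) \
        if config.eye_noise_sd > 0 else np.zeros(n_eye)
    pupil = config.pupil_baseline + rng.normal(0.0, config.pupil_sd, size=n_eye)

    truths: list[TrialTruth] = []
    step_delta = np.zeros(n_eye + 1)  # cumulative post-saccade offsets
    min_gap = n_frames_sacc + 4  # frames between saccade onsets
    for i in range(n):
        onset_global = i * slot + config.baseline_ms
        saccs: list[InjectedSaccade] = []
        # largest, choice-directed saccade at turn time + lag
        lag = _truncated_normal(
            rng, config.saccade_lag_mean, config.saccade_lag_sd,
            2 * eye_period - taus[i],
            config.post_ms - taus[i] - (n_frames_sacc + 20) * eye_period, 1)[0]
        big_onset = taus[i] + lag
        # every injected saccade sits above the kernel/threshold detection
        # floor (the real detector could not have retained smaller ones),
        # and the largest outranks the others by a fixed amplitude margin
        amp_floor = detection_floor(n_frames_sacc, eye_period / 1000.0)
        amp_hi = 0.99 * 200.0 / eff_slope
        margin = 0.6
        if rng.random() < config.oversize_fraction:
            amp_big = 1.25 * 200.0 / eff_slope
        else:
            amp_big = _truncated_normal(
                rng, config.saccade_amplitude_mean,
                config.saccade_amplitude_sd,
                min(1.25 * amp_floor, amp_hi - 0.1), amp_hi, 1)[0]
        saccs.append(InjectedSaccade(big_onset, amp_big, int(sign[i]),
                                     "largest"))
        small_lo = 1.1 * amp_floor
        small_hi = min(amp_big, amp_hi) - margin
        if rng.random() < config.compensatory_fraction and small_hi > small_lo:
            comp_onset = big_onset + (n_frames_sacc + 8) * eye_period
            amp_c = float(np.clip(0.65 * amp_big, small_lo, small_hi))
            # leave room for the full step plus the kernel's 2-frame margin
            if comp_onset < config.post_ms - (n_frames_sacc + 5) * eye_period:
                saccs.append(InjectedSaccade(comp_onset, amp_c,
                                             -int(sign[i]), "compensatory"))
        n_extra = rng.poisson(config.extra_saccade_rate)
        for _ in range(n_extra):
            if small_hi <= small_lo:
                break
            for _attempt in range(20):
                t0 = rng.uniform(
                    -config.baseline_ms + 2 * eye_period,
                    config.post_ms - (n_frames_sacc + 5) * eye_period)
                if all(abs(t0 - s.onset_ms) > min_gap * eye_period
                       for s in saccs):
                    break
            else:
                continue
            amp_e = rng.uniform(small_lo, small_hi)
            direction = 1 if rng.random() < 0.5 else -1
            saccs.append(InjectedSaccade(float(t0), amp_e, direction, "extra"))
        # inject (snap onsets to the eye grid); the post-saccade offset is
        # accumulated separately and applied once by cumulative sum
        for s in saccs:
            k0 = int(round((onset_global + s.onset_ms) / eye_period))
            s.onset_ms = k0 * eye_period - onset_global
            k1 = min(k0 + n_frames_sacc + 1, n_eye)
            if k0 < 0 or k0 >= n_eye:
                continue
            eye[k0:k1] += template[:k1 - k0] * s.amplitude_deg * s.direction
            if k1 - k0 > n_frames_sacc:
                step_delta[k1] += s.amplitude_deg * s.direction
        big = saccs[0]
        truths.append(TrialTruth(
            trial_id=i, choice=str(choices[i]), correct_side=str(correct_sides[i]),
            correct=bool(correct[i]),
            prev_choice=str(prev_choices[i]) if prev_choices[i] else None,
            turn_time_ms=float(taus[i]), onset_heading_mean=float(mu0[i]),
            largest_onset_ms=float(big.onset_ms),
            largest_amplitude_deg=float(big.amplitude_deg),
            saccades=saccs,
        ))

    eye = eye + np.cumsum(step_delta[:-1])
    # keep each trial's eye trace centred: subtract the cumulative offset at
    # the start of each trial slot so amplitudes stay within the arcsin model
    slot_starts = (np.arange(n) * slot / eye_period).astype(int)
    offsets = eye[slot_starts]
    eye = eye - np.repeat(offsets, np.diff(
        np.append(slot_starts, n_eye)))

    eye_track = _eye_track_from_angle(rng, config, t_eye, eye, pupil)

    events = pd.DataFrame({
        "trial_id": np.arange(n),
        "t_onset_ms": np.arange(n) * slot + config.baseline_ms,
        "display_ms": np.full(n, config.display_ms),
        "condition": [config.condition] * n,
        "choice": choices,
        "correct": correct,
        "prev_choice": [p if p else "" for p in prev_choices],
    })
    truth = GroundTruth(trials=truths,
                        effective_main_sequence_slope=eff_slope,
                        saccade_n_frames=n_frames_sacc, config=config)
    return SyntheticSession(pose=pose, eye=eye_track, events=events,
                            truth=truth, config=config)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (mild truncation expected)."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _add_wander(rng, config, heading, t_rel, trial_idx, sign, taus):
    """Premature turn toward the wrong side followed by reorienting:
    a triangular excursion between onset and the true turning time."""
    n = len(taus)
    wander = rng.random(n) < config.wander_prob
    amp = rng.uniform(5.0, 12.0, size=n)
    for i in np.nonzero(wander)[0]:
        if taus[i] < 150.0:
            continue
        sel = trial_idx == i
        tr = t_rel[sel]
        peak = taus[i] / 2.0
        bump = np.clip(1.0 - np.abs(tr - peak) / peak, 0.0, None)
        heading[sel] = heading[sel] - sign[i] * amp[i] * bump
    return heading


def _pose_from_heading(rng, config, t_head, heading) -> PoseTrack:
    """Back-compute overhead-camera landmarks from the intended heading.

    With the monitor straight 'up' in the image from a fixed neck point,
    the nose sits at neck + L*(sin(theta), -cos(theta)) in image (y-down)
    coordinates, which the heading geometry inverts exactly.
    """
    theta = np.radians(heading)
    nx, ny = config.neck_xy
    snout = 60.0   # px neck-to-nose
    half_neck = 15.0
    facing = np.stack([np.sin(theta), -np.cos(theta)], axis=1)
    perp = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    nose = np.array([nx, ny]) + snout * facing
    left = np.array([nx, ny]) - half_neck * perp
    right = np.array([nx, ny]) + half_neck * perp
    m = len(t_head)
    like = np.ones(m)
    if config.dropout_fraction > 0:
        like[rng.random(m) < config.dropout_fraction] = 0.5
    data = pd.DataFrame({
        "nose_x": nose[:, 0], "nose_y": nose[:, 1], "nose_likelihood": like,
        "neck_center_x": np.full(m, nx), "neck_center_y": np.full(m, ny),
        "neck_center_likelihood": np.ones(m),
        "neck_left_x": left[:, 0], "neck_left_y": left[:, 1],
        "neck_left_likelihood": np.ones(m),
        "neck_right_x": right[:, 0], "neck_right_y": right[:, 1],
        "neck_right_likelihood": np.ones(m),
        "timestamp_ms": t_head,
    })
    return PoseTrack(data, frame_rate=config.frame_rate_head)


def _eye_track_from_angle(rng, config, t_eye, eye_deg, pupil_px) -> EyeTrack:
    """Back-compute pupil/eyelid ellipses from the intended eye angle."""
    eye_major = 100.0  # px; eyeball radius 50 px
    ex, ey = 200.0, 200.0
    dx = (eye_major / 2.0) * np.sin(np.radians(np.clip(eye_deg, -90, 90)))
    m = len(t_eye)
    like = np.ones(m)
    if config.dropout_fraction > 0:
        like[rng.random(m) < config.dropout_fraction] = 0.5
    data = pd.DataFrame({
        "timestamp_ms": t_eye,
        "pupil_x": ex + dx, "pupil_y": np.full(m, ey),
        "pupil_major": pupil_px, "pupil_minor": pupil_px * 0.95,
        "eye_x": np.full(m, ex), "eye_y": np.full(m, ey),
        "eye_major": np.full(m, eye_major),
        "pupil_likelihood": like, "eye_likelihood": np.ones(m),
    })
    return EyeTrack(data, frame_rate=config.frame_rate_eye)


# ---------------------------------------------------------------------------
# disk I/O


def write_session(session: SyntheticSession, outdir) -> None:
    """Write pose (DeepLabCut dialect), eye, events, ground truth and metadata."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_model.write_pose_csv(session.pose, out / "pose.csv")
    io_model.write_eye_csv(session.eye, out / "eye.csv")
    session.events.to_csv(out / "events.csv", index=False)
    session.truth.to_json(out / "ground_truth.json")
    meta = {
        "frame_rate_head": session.config.frame_rate_head,
        "frame_rate_eye": session.config.frame_rate_eye,
        "monitor_xy": list(session.config.monitor_xy),
        "seed": session.config.seed,
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_session(indir):
    """Read back a written session as (pose, eye, events, meta)."""
    from pathlib import Path
    ind = Path(indir)
    with open(ind / "meta.json") as fh:
        meta = json.load(fh)
    pose = io_model.read_pose_csv(ind / "pose.csv",
                                  frame_rate=meta["frame_rate_head"])
    eye = io_model.read_eye_csv(ind / "eye.csv",
                                frame_rate=meta["frame_rate_eye"])
    events = io_model.read_events_csv(ind / "events.csv")
    return pose, eye, events, meta
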