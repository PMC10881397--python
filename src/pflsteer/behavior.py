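"""Ball-kinematics preprocessing and behavioral analysis.

Covers: FicTrac-style position-to-velocity preprocessing, cue-position to
head-direction conversion, sliding-window goal direction / consistency,
segmentation of paths into straight-walking epochs, classification of cue
jumps as corrected/uncorrected, behavior-conditioned binning, and
event-triggered averaging across flies.

Speeds are thresholded in ball radians/s: cumulative speed =
|forward| + |sideways| + |rotational| before unit conversion; a fly below
0.67 rad/s is treated as immobile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .circular import wrap_deg, circ_mean, circ_dist_signed

__all__ = [
    "BALL_RADIUS_MM",
    "SPEED_THRESHOLD_RAD_S",
    "VELOCITY_CLIP_RAD_S",
    "KinematicsTrace",
    "Segment",
    "JumpEvent",
    "preprocess_kinematics",
    "cue_to_heading",
    "sliding_goal_consistency",
    "segment_path",
    "classify_jump",
    "bin_signal_by_behavior",
    "event_triggered_average",
]

BALL_RADIUS_MM = 4.5  # 9-mm-diameter spherical treadmill
SPEED_THRESHOLD_RAD_S = 0.67  # cumulative-speed mobility threshold
VELOCITY_CLIP_RAD_S = 20.0  # artefactually large velocities are clipped here


@dataclass
class KinematicsTrace:
    """Preprocessed locomotion at 60 Hz.

    forward/sideways in mm/s, rotational in deg/s, cumulative_speed in ball
    rad/s (|forward| + |sideways| + |rotational| before unit conversion).
    ``heading`` (degrees, cue convention) may be attached separately.
    """

    time: np.ndarray
    forward: np.ndarray
    sideways: np.ndarray
    rotational: np.ndarray
    cumulative_speed: np.ndarray
    mobile: np.ndarray
    heading: np.ndarray | None = None
    sample_rate: float = 60.0

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class Segment:
    """Straight-walking epoch [start_idx, end_idx) with its inferred goal."""

    start_idx: int
    end_idx: int
    theta_g: float
    rho: float
    valid: bool
    reason: str = ""


@dataclass
class JumpEvent:
    """A cue jump and its classification."""

    time: float
    magnitude: float
    pre_theta_mean: float = float("nan")
    pre_rho: float = float("nan")
    corrected: bool | None = None
    high_rho: bool | None = None
    excluded: bool = False
    reason: str = ""


def _odd_window(n_samples: int) -> int:
    return max(3, n_samples | 1)


def _loess_smooth(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Local quadratic regression smoothing (Savitzky-Golay)."""
    w = _odd_window(window_samples)
    if w >= len(x):
        w = _odd_window(len(x) - 2)
    if w < 5:
        return x.copy()
    return _sig.savgol_filter(x, w, polyorder=2, mode="interp")


def preprocess_kinematics(
    positions: pd.DataFrame,
    sample_rate: float,
    ball_diameter_mm: float = 2 * BALL_RADIUS_MM,
    butter_corner: float = 0.003,
    corner_is_normalized: bool = True,
    clip_rad_s: float = VELOCITY_CLIP_RAD_S,
    loess_window_s: float = 0.033,
    out_rate: float = 60.0,
) -> KinematicsTrace:
    """Convert cumulative ball-position channels into calibrated velocities.

    ``positions`` must hold monotonic ``time_s`` plus cumulative angular
    positions (radians, as decoded from the tracker's voltage output) in
    columns ``forward``, ``sideways``, ``yaw``.  Pipeline: unwrap ->
    second-order Butterworth low-pass (corner as a fraction of Nyquist by
    default) -> gradient -> clip at 20 rad/s -> local quadratic smoothing
    over 33 ms -> resample to 60 Hz -> convert forward/sideways to mm/s via
    the ball radius and yaw to deg/s.
    """
    required = {"time_s", "forward", "sideways", "yaw"}
    missing = required - set(positions.columns)
    if missing:
        raise ValueError(f"kinematics table missing columns: {sorted(missing)}")
    t = positions["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotonic time column")
    if sample_rate < out_rate:
        raise ValueError(f"sample_rate must be >= {out_rate} Hz")
    wn = butter_corner if corner_is_normalized else butter_corner / (sample_rate / 2.0)
    b, a = _sig.butter(2, wn)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(t) <= padlen:
        raise ValueError("trace too short for the low-pass filter")
    radius = ball_diameter_mm / 2.0

    t_out = np.arange(t[0], t[-1] + 0.5 / out_rate, 1.0 / out_rate)
    t_out = t_out[t_out <= t[-1] + 1e-9]
    vels = {}
    for col in ("forward", "sideways", "yaw"):
        pos = np.unwrap(positions[col].to_numpy(dtype=float))
        pos = _sig.filtfilt(b, a, pos)
        vel = np.gradient(pos, t)
        vel = np.clip(vel, -clip_rad_s, clip_rad_s)
        vel = _loess_smooth(vel, int(round(loess_window_s * sample_rate)))
        vels[col] = np.interp(t_out, t, vel)
    fwd, side, yaw = vels["forward"], vels["sideways"], vels["yaw"]
    cum = np.abs(fwd) + np.abs(side) + np.abs(yaw)  # rad/s, ball frame
    return KinematicsTrace(
        time=t_out,
        forward=fwd * radius,
        sideways=side * radius,
        rotational=np.rad2deg(yaw),
        cumulative_speed=cum,
        mobile=cum > SPEED_THRESHOLD_RAD_S,
        sample_rate=out_rate,
    )


def cue_to_heading(
    cue_deg: np.ndarray,
    yaw_gain: float = 0.7,
    sample_rate: float = 60.0,
    smooth_window_s: float = 0.05,
    clamp: bool = True,
) -> np.ndarray:
    """Convert cue azimuth (degrees on the arena, positive clockwise of the
    fly's front) into head direction.

    Convention: 0 deg when the fly directly faces the cue; +90 when the fly
    is 90 deg clockwise of the cue (so heading = -cue azimuth).  The trace
    is lightly smoothed and by default values beyond +/-180 are clamped to
    +/-180 (set ``clamp=False`` to wrap instead).  ``yaw_gain`` documents
    the closed-loop gain relating ball yaw to cue displacement; it does not
    rescale the cue positions, which are already in arena coordinates.
    """
    if yaw_gain <= 0:
        raise ValueError("yaw gain must be positive")
    heading = -np.asarray(cue_deg, dtype=float)
    if smooth_window_s > 0 and heading.size >= 7:
        heading = _loess_smooth(heading, int(round(smooth_window_s * sample_rate)))
    if clamp:
        return np.clip(heading, -180.0, 180.0)
    return wrap_deg(heading)


def sliding_goal_consistency(
    heading: np.ndarray,
    cumulative_speed: np.ndarray,
    sample_rate: float,
    jump_times: np.ndarray | None = None,
    window_s: float = 30.0,
    speed_thresh: float = SPEED_THRESHOLD_RAD_S,
    post_jump_excl_s: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample goal direction theta_g and consistency rho over a centered
    sliding window.

    Samples where the fly is essentially standing still (cumulative speed
    below ``speed_thresh`` rad/s) and samples within ``post_jump_excl_s``
    seconds after a cue jump are excluded from the window sums; a window
    with no qualifying samples yields NaN.
    """
    th = wrap_deg(np.asarray(heading, dtype=float))
    speed = np.asarray(cumulative_speed, dtype=float)
    n = th.size
    if speed.size != n:
        raise ValueError("heading and speed lengths differ")
    half = int(round(window_s * sample_rate / 2.0))
    if 2 * half >= n:
        raise ValueError("window longer than the trace")
    qualify = speed > speed_thresh
    if jump_times is not None:
        t = np.arange(n) / sample_rate
        for jt in np.asarray(jump_times, dtype=float):
            qualify &= ~((t >= jt) & (t < jt + post_jump_excl_s))
    rad = np.deg2rad(th)
    c = np.where(qualify, np.cos(rad), 0.0)
    s = np.where(qualify, np.sin(rad), 0.0)
    cc = np.concatenate([[0.0], np.cumsum(c)])
    cs = np.concatenate([[0.0], np.cumsum(s)])
    cn = np.concatenate([[0], np.cumsum(qualify.astype(int))])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    nw = cn[hi] - cn[lo]
    empty = nw == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mc = (cc[hi] - cc[lo]) / np.where(empty, 1, nw)
        ms = (cs[hi] - cs[lo]) / np.where(empty, 1, nw)
        rho = np.minimum(np.hypot(mc, ms), 1.0)
        theta_g = wrap_deg(np.rad2deg(np.arctan2(ms, mc)))
    rho[empty] = np.nan
    theta_g = np.where(empty, np.nan, theta_g)
    return theta_g, rho


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def segment_path(
    rho: np.ndarray,
    heading: np.ndarray,
    cumulative_speed: np.ndarray,
    sample_rate: float,
    rho_thresh: float = 0.88,
    min_dip_s: float = 0.5,
    min_active_s: float = 2.0,
    speed_thresh: float = SPEED_THRESHOLD_RAD_S,
) -> list[Segment]:
    """Divide a path into straight-walking segments at dips of rho below
    ``rho_thresh``.

    Dips shorter than ``min_dip_s`` do not break a segment.  Per segment the
    goal is the circular mean of heading over mobile samples and rho is the
    mean of the rho series.  Segments are invalid when rho equals 1 (frozen
    cue) or when the fly was never mobile for ``min_active_s`` contiguous
    seconds.
    """
    rho = np.asarray(rho, dtype=float)
    th = np.asarray(heading, dtype=float)
    speed = np.asarray(cumulative_speed, dtype=float)
    if not (rho.size == th.size == speed.size):
        raise ValueError("series lengths differ")
    above = np.where(np.isnan(rho), False, rho >= rho_thresh)
    min_dip = int(round(min_dip_s * sample_rate))
    runs = _runs(above)
    # lump runs separated by brief dips
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and (start - merged[-1][1]) < min_dip:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    segments: list[Segment] = []
    min_active = int(round(min_active_s * sample_rate))
    for start, end in merged:
        seg_rho = float(np.nanmean(rho[start:end]))
        mobile = speed[start:end] > speed_thresh
        active_ok = any((e - s) >= min_active for s, e in _runs(mobile))
        valid, reason = True, ""
        theta_g = float("nan")
        if seg_rho >= 1.0 - 1e-12:
            valid, reason = False, "rho_equals_1"
        elif not active_ok:
            valid, reason = False, "inactive"
        if np.any(mobile):
            theta_g = circ_mean(th[start:end][mobile])
        elif valid:
            valid, reason = False, "inactive"
        segments.append(
            Segment(
                start_idx=start,
                end_idx=end,
                theta_g=theta_g,
                rho=seg_rho,
                valid=valid,
                reason=reason,
            )
        )
    return segments


def classify_jump(
    heading: np.ndarray,
    cumulative_speed: np.ndarray,
    rho: np.ndarray,
    sample_rate: float,
    jump: JumpEvent,
    pre_s: float = 15.0,
    return_s: float = 10.0,
    return_tol_90: float = 30.0,
    return_tol_180: float = 60.0,
    rho_thresh: float = 0.88,
    min_mobile_s: float = 1.0,
    speed_thresh: float = SPEED_THRESHOLD_RAD_S,
    fast: bool = False,
) -> JumpEvent:
    """Classify a cue jump as corrected/uncorrected and high/low rho.

    A jump is excluded when the fly was essentially immobile before it
    (cumulative speed never above threshold for ``min_mobile_s`` contiguous
    seconds in the ``pre_s`` window) or when flanking data are missing.
    ``corrected`` means heading returned to within 30 deg (90-deg jumps) or
    60 deg (180-deg jumps) of its pre-jump mean within ``return_s``;
    ``fast=True`` selects the alternate rapid-response criterion
    (40 / 75 deg within 4 s).  ``high_rho`` means the mean pre-jump rho over
    mobile samples reached ``rho_thresh``.
    """
    th = np.asarray(heading, dtype=float)
    speed = np.asarray(cumulative_speed, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n = th.size
    if abs(jump.magnitude) not in (90.0, 180.0):
        raise ValueError(f"jump magnitude must be +/-90 or 180, got {jump.magnitude}")
    if fast:
        return_s = 4.0
        tol = 40.0 if abs(jump.magnitude) == 90.0 else 75.0
    else:
        tol = return_tol_90 if abs(jump.magnitude) == 90.0 else return_tol_180
    j = int(round(jump.time * sample_rate))
    pre_n = int(round(pre_s * sample_rate))
    post_n = int(round(return_s * sample_rate))
    if j - pre_n < 0 or j + post_n > n:
        jump.excluded, jump.reason = True, "insufficient_flanking_data"
        return jump
    pre = slice(j - pre_n, j)
    mobile_pre = speed[pre] > speed_thresh
    min_mobile = int(round(min_mobile_s * sample_rate))
    if not any((e - s) >= min_mobile for s, e in _runs(mobile_pre)):
        jump.excluded, jump.reason = True, "immobile_pre_jump"
        return jump
    jump.pre_theta_mean = circ_mean(th[pre][mobile_pre])
    pre_rho = rho[pre][mobile_pre]
    jump.pre_rho = float(np.nanmean(pre_rho)) if np.any(np.isfinite(pre_rho)) else float("nan")
    post = th[j : j + post_n]
    dist = np.abs(circ_dist_signed(post, jump.pre_theta_mean))
    jump.corrected = bool(np.any(dist <= tol))
    jump.high_rho = bool(np.isfinite(jump.pre_rho) and jump.pre_rho >= rho_thresh)
    jump.excluded = False
    return jump


_BIN_WIDTHS = {"rotational": 10.0, "forward": 1.0, "error": 10.0}


def bin_signal_by_behavior(
    signal: np.ndarray,
    conditioning: np.ndarray,
    kind: str,
    bin_width: float | None = None,
    mobile: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean of ``signal`` within bins of a behavioral conditioning variable.

    Default widths: 10 deg/s for rotational velocity, 1 mm/s for forward
    velocity, 10 deg for directional error (error values are wrapped; error
    bins tile (-180, 180]).  Immobile samples are dropped when a ``mobile``
    mask is supplied.  Returns bin_center, mean, n (empty bins omitted).
    """
    sig = np.asarray(signal, dtype=float)
    cond = np.asarray(conditioning, dtype=float)
    if sig.shape != cond.shape:
        raise ValueError("signal and conditioning series lengths differ")
    if kind not in _BIN_WIDTHS:
        raise ValueError(f"kind must be one of {sorted(_BIN_WIDTHS)}")
    width = bin_width if bin_width is not None else _BIN_WIDTHS[kind]
    ok = np.isfinite(sig) & np.isfinite(cond)
    if mobile is not None:
        ok &= np.asarray(mobile, dtype=bool)
    sig, cond = sig[ok], cond[ok]
    if kind == "error":
        cond = wrap_deg(cond)
        edges = np.arange(-180.0, 180.0 + width, width)
    else:
        lo = np.floor(cond.min() / width) * width
        hi = np.ceil(cond.max() / width) * width
        if hi <= lo:
            hi = lo + width
        edges = np.arange(lo, hi + width / 2.0, width)
    idx = np.clip(np.digitize(cond, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if np.any(sel):
            rows.append((edges[b] + width / 2.0, float(sig[sel].mean()), int(sel.sum())))
    return pd.DataFrame(rows, columns=["bin_center", "mean", "n"])


def event_triggered_average(
    signals: dict,
    events: pd.DataFrame,
    sample_rate: float,
    window_s: float = 10.0,
    min_reps: int = 4,
) -> dict:
    """Event-triggered averages, hierarchically: fly means first, then the
    grand mean and s.e.m. across flies.

    ``signals`` maps fly_id -> 1-D signal array (uniformly sampled at
    ``sample_rate``); ``events`` has columns fly_id, time_s and optionally
    ``group`` (e.g. stimulus pulse duration).  Flies contributing fewer than
    ``min_reps`` usable events to a group are excluded from that group;
    events whose +/-window exceeds the trace are skipped with a warning.
    Returns {group: DataFrame(lag_s, mean, sem, n_flies)}.
    """
    if "group" not in events.columns:
        events = events.assign(group="all")
    half = int(round(window_s * sample_rate))
    lags = np.arange(-half, half + 1) / sample_rate
    out = {}
    for group, ev_g in events.groupby("group"):
        fly_means = []
        for fly, ev_f in ev_g.groupby("fly_id"):
            sig = np.asarray(signals[fly], dtype=float)
            snips = []
            for t0 in ev_f["time_s"]:
                c = int(round(t0 * sample_rate))
                if c - half < 0 or c + half + 1 > sig.size:
                    warnings.warn(
                        f"event at {t0:.2f}s for fly {fly!r} exceeds trace bounds; skipped"
                    )
                    continue
                snips.append(sig[c - half : c + half + 1])
            if len(snips) >= min_reps:
                fly_means.append(np.mean(snips, axis=0))
        if not fly_means:
            continue
        arr = np.asarray(fly_means)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
        out[group] = pd.DataFrame(
            {"lag_s": lags, "mean": arr.mean(axis=0), "sem": sem, "n_flies": arr.shape[0]}
        )
    return out
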