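"""Calcium-imaging analysis: robust z-scoring of ROI fluorescence,
per-timepoint sinusoid ("bump") fitting across brain space, bump-phase /
heading coupling, lateral-accessory-lobe sum and difference readouts, and
neural inference of the goal direction from bump-amplitude modulation.

Brain-space convention: ROI angular coordinates are uniformly spaced over
(-180, 180], +180 = rightmost ROI, -180 = leftmost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .circular import wrap_deg, circ_dist_signed

__all__ = [
    "ROI_COUNTS",
    "ADJ_R2_THRESHOLD",
    "RoiTimeSeries",
    "BumpFit",
    "GoalInference",
    "roi_angles_deg",
    "robust_zscore",
    "zscore_dff",
    "fit_bump",
    "fit_bump_series",
    "phase_heading_coupling",
    "lal_sum_and_diff",
    "infer_goal_from_amplitude",
    "error_binned_profiles",
]

#: ROI counts per imaged region: 10 protocerebral-bridge glomeruli, 9
#: fan-shaped-body columns, 2 lateral accessory lobes (right, left).
ROI_COUNTS = {"PB": 10, "FB": 9, "LAL": 2}

#: Sinusoid fits with adjusted r^2 below this are flagged invalid.
ADJ_R2_THRESHOLD = 0.1


@dataclass
class RoiTimeSeries:
    """ROI x time fluorescence with optional derived dF/F and z-scored layers."""

    region: str | None
    values: np.ndarray  # (n_rois, n_frames) raw fluorescence
    frame_rate: float
    dff: np.ndarray | None = None
    zscored: np.ndarray | None = None
    excluded_rois: np.ndarray | None = None  # boolean mask of degenerate ROIs

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if self.region is not None:
            expected = ROI_COUNTS.get(self.region)
            if expected is None:
                raise ValueError(f"unknown region {self.region!r}")
            if self.values.shape[0] != expected:
                raise ValueError(
                    f"region {self.region} expects {expected} ROIs, "
                    f"got {self.values.shape[0]}"
                )

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.frame_rate


@dataclass(frozen=True)
class BumpFit:
    """One-timepoint sinusoid fit a*sin(x - u) + c across brain space.

    ``phase`` is the brain-space position of the sinusoid's peak in degrees
    (+180 = rightmost).  Negative fitted amplitudes are folded to positive
    by a 180-degree phase flip.  ``valid`` requires adjusted r^2 >= 0.1.
    """

    amplitude: float
    phase: float
    offset: float
    adj_r2: float
    valid: bool


@dataclass(frozen=True)
class GoalInference:
    """Neurally inferred goal: heading bin with the smaller bump amplitude in
    the opposing-bin pair with the largest amplitude difference."""

    theta_g: float
    amplitude_range: float
    reliable: bool


def roi_angles_deg(n: int) -> np.ndarray:
    """Angular ROI centers uniformly spaced over (-180, 180], leftmost ROI
    first (most negative), rightmost last (most positive)."""
    if n < 1:
        raise ValueError("need at least one ROI")
    return -180.0 + 360.0 * (np.arange(n) + 0.5) / n


def robust_zscore(x: np.ndarray) -> np.ndarray:
    """Median/MAD z-score: (x - median) / MAD with MAD = median(|x - median|).

    Raises ``ValueError`` when MAD is zero (degenerate trace).
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("MAD is zero; z-score undefined")
    return (x - med) / mad


def zscore_dff(raw: RoiTimeSeries, baseline_quantile: float = 0.10) -> RoiTimeSeries:
    """Compute dF/F and robust z-scored layers for each ROI.

    Baseline F0 is the mean of the bottom ``baseline_quantile`` of the raw
    fluorescence values over the whole trial (per ROI);
    dF/F = (F - F0) / F0.  The z layer applies the median/MAD z-score to the
    dF/F trace.  ROIs with zero MAD are flagged in ``excluded_rois`` (their
    z rows are NaN) with a warning; a non-positive F0 raises ``ValueError``.
    """
    F = raw.values
    if F.shape[1] == 0:
        raise ValueError("empty trial")
    n_low = max(1, int(np.ceil(baseline_quantile * F.shape[1])))
    dff = np.empty_like(F)
    z = np.full_like(F, np.nan)
    excluded = np.zeros(F.shape[0], dtype=bool)
    for i in range(F.shape[0]):
        f0 = np.sort(F[i])[:n_low].mean()
        if f0 <= 0:
            raise ValueError(f"non-positive baseline fluorescence in ROI {i}")
        dff[i] = (F[i] - f0) / f0
        try:
            z[i] = robust_zscore(dff[i])
        except ValueError:
            excluded[i] = True
            warnings.warn(f"ROI {i} has zero MAD; excluded from z-scored layer")
    raw.dff = dff
    raw.zscored = z
    raw.excluded_rois = excluded
    return raw


def fit_bump(profile: np.ndarray, roi_angles: np.ndarray) -> BumpFit:
    """Least-squares sinusoid fit over one full cycle of brain space.

    Fits a*sin(x - u) + c on a sin/cos basis (closed form, deterministic).
    The reported ``phase`` is the peak position wrap(u + 90).  Adjusted r^2
    uses the three-parameter small-sample correction
    1 - (1 - r^2)(n - 1)/(n - 3).
    """
    y = np.asarray(profile, dtype=float).ravel()
    x = np.asarray(roi_angles, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("profile and roi_angles lengths differ")
    if y.size < 4:
        raise ValueError("need at least 4 ROIs to fit a 3-parameter sinusoid")
    xr = np.deg2rad(x)
    X = np.column_stack([np.sin(xr), np.cos(xr), np.ones_like(xr)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    p, q, c = coef
    a = float(np.hypot(p, q))
    u = float(np.rad2deg(np.arctan2(-q, p)))
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    n = y.size
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 3)
    phase = wrap_deg(u + 90.0) if a > 1e-10 else float("nan")
    return BumpFit(
        amplitude=a,
        phase=phase,
        offset=float(c),
        adj_r2=adj_r2,
        valid=bool(adj_r2 >= ADJ_R2_THRESHOLD),
    )


def fit_bump_series(zscored: np.ndarray, roi_angles: np.ndarray | None = None) -> pd.DataFrame:
    """Fit a bump independently at every timepoint of an ROI x time array.

    Returns a frame with columns amplitude, phase_deg, offset, adj_r2, valid.
    """
    z = np.atleast_2d(np.asarray(zscored, dtype=float))
    angles = roi_angles_deg(z.shape[0]) if roi_angles is None else np.asarray(roi_angles)
    rows = []
    for t in range(z.shape[1]):
        y = z[:, t]
        if not np.all(np.isfinite(y)):
            rows.append((np.nan, np.nan, np.nan, np.nan, False))
            continue
        fit = fit_bump(y, angles)
        rows.append((fit.amplitude, fit.phase, fit.offset, fit.adj_r2, fit.valid))
    return pd.DataFrame(
        rows, columns=["amplitude", "phase_deg", "offset", "adj_r2", "valid"]
    )


@dataclass(frozen=True)
class PhaseCoupling:
    pairs: pd.DataFrame  # columns d_phase_deg, d_theta_deg
    r: float
    p_value: float
    slope: float
    intercept: float


def phase_heading_coupling(
    phases: np.ndarray,
    heading: np.ndarray,
    frame_rate: float,
    valid: np.ndarray | None = None,
    mobile: np.ndarray | None = None,
    bin_s: float = 1.5,
    lag_s: float = 0.2,
) -> PhaseCoupling:
    """Relate start-to-end changes in bump phase to changes in head direction
    within non-overlapping bins.

    ``lag_s`` shifts the heading earlier so phase changes are compared with
    the heading changes that preceded them (bump phase lags heading).
    Differences are shortest-arc; positive = clockwise.  Bins whose
    endpoints are invalid fits or immobile samples are dropped; fewer than
    3 usable bins raises ``ValueError``.
    """
    phases = np.asarray(phases, dtype=float)
    heading = np.asarray(heading, dtype=float)
    if phases.shape != heading.shape:
        raise ValueError("phase and heading series lengths differ")
    n = phases.size
    ok = np.isfinite(phases) & np.isfinite(heading)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    if mobile is not None:
        ok &= np.asarray(mobile, dtype=bool)
    lag = int(round(lag_s * frame_rate))
    width = max(2, int(round(bin_s * frame_rate)))
    d_phase, d_theta = [], []
    for start in range(lag, n - width, width):
        end = start + width
        hs, he = start - lag, end - lag
        if not (ok[start] and ok[end] and ok[hs] and ok[he]):
            continue
        d_phase.append(circ_dist_signed(phases[end], phases[start]))
        d_theta.append(circ_dist_signed(heading[he], heading[hs]))
    if len(d_phase) < 3:
        raise ValueError("fewer than 3 usable bins for phase-heading coupling")
    d_phase = np.asarray(d_phase)
    d_theta = np.asarray(d_theta)
    r, p = _stats.pearsonr(d_theta, d_phase)
    slope, intercept = np.polyfit(d_theta, d_phase, 1)
    return PhaseCoupling(
        pairs=pd.DataFrame({"d_theta_deg": d_theta, "d_phase_deg": d_phase}),
        r=float(r),
        p_value=float(p),
        slope=float(slope),
        intercept=float(intercept),
    )


def lal_sum_and_diff(
    lal: RoiTimeSeries,
    conditioning: np.ndarray,
    kind: str,
    segments=None,
    mobile: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned right+left and right-left lateral-accessory-lobe activity.

    Row 0 of ``lal.values`` (or its z layer when present) is the right LAL,
    row 1 the left.  Binning is delegated to
    :func:`pflsteer.behavior.bin_signal_by_behavior`; when ``segments`` is
    given, binning is done per segment and averaged across segments.
    Returns a frame with bin_center, lal_sum, lal_diff, n.
    """
    from .behavior import bin_signal_by_behavior

    if lal.region != "LAL":
        raise ValueError("lal_sum_and_diff requires a LAL (2-ROI) series")
    data = lal.zscored if lal.zscored is not None else lal.values
    right, left = data[0], data[1]
    cond = np.asarray(conditioning, dtype=float)
    if cond.size != right.size:
        raise ValueError("conditioning series length mismatch")

    def _bin(sl) -> pd.DataFrame:
        m = None if mobile is None else np.asarray(mobile, dtype=bool)[sl]
        br = bin_signal_by_behavior(right[sl], cond[sl], kind, mobile=m)
        bl = bin_signal_by_behavior(left[sl], cond[sl], kind, mobile=m)
        merged = br.merge(bl, on="bin_center", suffixes=("_r", "_l"))
        return pd.DataFrame(
            {
                "bin_center": merged["bin_center"],
                "lal_sum": merged["mean_r"] + merged["mean_l"],
                "lal_diff": merged["mean_r"] - merged["mean_l"],
                "n": np.minimum(merged["n_r"], merged["n_l"]),
            }
        )

    if segments is None:
        return _bin(slice(None))
    frames = [
        _bin(slice(s.start_idx, s.end_idx)) for s in segments if getattr(s, "valid", True)
    ]
    if not frames:
        raise ValueError("no valid segments to bin")
    allf = pd.concat(frames)
    out = allf.groupby("bin_center", as_index=False).agg(
        lal_sum=("lal_sum", "mean"), lal_diff=("lal_diff", "mean"), n=("n", "sum")
    )
    return out


def infer_goal_from_amplitude(
    amplitudes: np.ndarray,
    heading: np.ndarray,
    theta_bin: float = 5.0,
    min_range: float = 0.1,
) -> GoalInference:
    """Infer the goal direction from head-direction-binned bump amplitude.

    Bump amplitudes are grouped by heading in ``theta_bin``-degree bins; the
    opposing-bin pair (180 degrees apart) with the largest amplitude
    difference is found and the goal is the heading of the bin with the
    *smaller* amplitude (the model places the bump-amplitude minimum at the
    goal).  ``amplitude_range`` is max - min of the binned amplitudes.
    """
    amp = np.asarray(amplitudes, dtype=float)
    th = wrap_deg(np.asarray(heading, dtype=float))
    ok = np.isfinite(amp) & np.isfinite(th)
    amp, th = amp[ok], th[ok]
    n_bins = int(round(360.0 / theta_bin))
    if n_bins % 2:
        raise ValueError("theta_bin must divide 360 into an even number of bins")
    edges = -180.0 + theta_bin * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(th, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            means[b] = amp[sel].mean()
    half = n_bins // 2
    best_diff, best_goal = -np.inf, None
    for b in range(half):
        o = b + half
        if np.isfinite(means[b]) and np.isfinite(means[o]):
            diff = abs(means[b] - means[o])
            if diff > best_diff:
                best_diff = diff
                smaller = b if means[b] <= means[o] else o
                best_goal = edges[smaller] + theta_bin / 2.0
    if best_goal is None:
        raise ValueError("no opposing bin pairs covered; cannot infer goal")
    occupied = means[np.isfinite(means)]
    amp_range = float(occupied.max() - occupied.min())
    return GoalInference(
        theta_g=wrap_deg(best_goal),
        amplitude_range=amp_range,
        reliable=bool(amp_range > min_range),
    )


def error_binned_profiles(
    zscored: np.ndarray,
    heading: np.ndarray,
    theta_g: float,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Mean z-scored activity of each ROI within directional-error bins.

    The circle of error values theta - theta_g is divided into ``n_bins``
    equal bins centered on 0, +/-90, 180 (for the default 4 x 90 deg).
    Returns a frame indexed by ROI with one column per bin center; empty
    bins give NaN columns.
    """
    z = np.atleast_2d(np.asarray(zscored, dtype=float))
    err = wrap_deg(np.asarray(heading, dtype=float) - theta_g)
    width = 360.0 / n_bins
    # shift so bins are centered on 0, width, 2*width, ...
    shifted = np.mod(err + width / 2.0, 360.0)
    idx = np.clip((shifted // width).astype(int), 0, n_bins - 1)
    centers = [wrap_deg(b * width) for b in range(n_bins)]
    cols = {}
    for b in range(n_bins):
        sel = idx == b
        cols[centers[b]] = z[:, sel].mean(axis=1) if np.any(sel) else np.full(z.shape[0], np.nan)
    out = pd.DataFrame(cols)
    out.index.name = "roi"
    return out
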