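"""Membrane-potential analysis for PFL2/PFL3 whole-cell recordings.

Baseline extraction (spike removal), spike and IPSP event detection,
head-direction tuning curves and preferred direction, goal-offset tuning
analysis, jump-evoked membrane-potential statistics (Brown-Forsythe
variance comparison), and the lag correlation between membrane-potential
changes and rotational speed.

All traces are assumed resampled to 1 kHz, liquid-junction corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as _stats

from .circular import wrap_deg, circ_dist_signed

__all__ = [
    "LIQUID_JUNCTION_MV",
    "VmTrace",
    "IpspEvent",
    "TuningCurve",
    "baseline_vm",
    "detect_spikes",
    "detect_ipsps",
    "preferred_direction_tuning",
    "ipsp_jump_response",
    "tuning_by_goal_offset",
    "brown_forsythe",
    "jump_dvm_stats",
    "unbalanced_two_factor_anova",
    "dvm_speed_lag_correlation",
]

LIQUID_JUNCTION_MV = -13.0  # applied at load time by the io layer


@dataclass
class VmTrace:
    """Membrane potential at 1 kHz with derived baseline and spike times."""

    time: np.ndarray
    vm: np.ndarray  # mV, liquid-junction corrected
    cell_type: str = "PFL2"  # PFL2 | PFL3R | PFL3L
    sample_rate: float = 1000.0
    baseline: np.ndarray | None = None
    spike_times: np.ndarray | None = None


@dataclass(frozen=True)
class IpspEvent:
    """A detected inhibitory postsynaptic potential."""

    time: float  # s, at the negative peak of the detrended trace
    derivative_peak: float  # mV/ms, signed (negative)
    detrended_peak: float  # mV, signed (negative)


@dataclass
class TuningCurve:
    """Binned head-direction tuning with preferred direction and amplitude."""

    bin_centers: np.ndarray
    values: np.ndarray
    n_per_bin: np.ndarray
    preferred: float
    amplitude: float


def _scaled_mad(x: np.ndarray) -> float:
    """Robust sigma estimate: 1.4826 * median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _medfilt_odd(x: np.ndarray, window_samples: int) -> np.ndarray:
    from scipy.ndimage import median_filter

    k = max(3, window_samples | 1)
    return median_filter(x, size=k, mode="nearest")


def _loess(x: np.ndarray, window_samples: int) -> np.ndarray:
    w = max(5, window_samples | 1)
    if w >= len(x):
        raise ValueError("trace shorter than the smoothing window")
    return _sig.savgol_filter(x, w, polyorder=2, mode="interp")


def baseline_vm(
    vm: np.ndarray,
    sample_rate: float = 1000.0,
    median_window_s: float = 0.05,
    smooth_window_s: float = 0.02,
) -> np.ndarray:
    """Spike-free baseline membrane potential: 50 ms median filter followed
    by light local-regression smoothing over 20 ms."""
    vm = np.asarray(vm, dtype=float)
    mw = int(round(median_window_s * sample_rate))
    if len(vm) <= max(3, mw | 1):
        raise ValueError("trace shorter than the median-filter window")
    filt = _medfilt_odd(vm, mw)
    return _loess(filt, int(round(smooth_window_s * sample_rate)))


def detect_spikes(
    vm: np.ndarray,
    sample_rate: float = 1000.0,
    threshold_sd: float = 4.0,
    refractory_s: float = 0.002,
    rate_window_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect spikes as positive peaks of the high-pass residual
    (vm - baseline) above ``threshold_sd`` robust standard deviations, with
    a 2 ms refractory period.  Returns (spike_times_s, firing_rate_hz) where
    the rate is a 100 ms boxcar of the spike train.
    """
    vm = np.asarray(vm, dtype=float)
    resid = vm - baseline_vm(vm, sample_rate)
    sigma = _scaled_mad(resid)
    if sigma == 0:
        return np.array([]), np.zeros_like(vm)
    peaks, _ = _sig.find_peaks(
        resid,
        height=threshold_sd * sigma,
        distance=max(1, int(round(refractory_s * sample_rate))),
    )
    train = np.zeros_like(vm)
    train[peaks] = 1.0
    w = max(1, int(round(rate_window_s * sample_rate)))
    rate = np.convolve(train, np.ones(w) / w, mode="same") * sample_rate
    return peaks / sample_rate, rate


from functools import lru_cache


@lru_cache(maxsize=8)
def _ipsp_noise_gains(
    median_w: int, smooth_w: int, detrend_w: int, sample_rate: float
) -> tuple[float, float]:
    """Noise gain of the IPSP pipeline: robust SD of the derivative and of
    the detrended trace when the input is unit-SD white noise.  Depends only
    on the filter windows, so it is computed once on a fixed reference
    trace."""
    rng = np.random.default_rng(12345)
    x = rng.standard_normal(int(30 * sample_rate))
    filt = _loess(_medfilt_odd(x, median_w), smooth_w)
    deriv = np.gradient(filt) * sample_rate / 1000.0
    detr = filt - _medfilt_odd(filt, detrend_w)
    return _scaled_mad(deriv), _scaled_mad(detr)


def detect_ipsps(
    vm: np.ndarray,
    sample_rate: float = 1000.0,
    quiescent_mask: np.ndarray | None = None,
    median_window_s: float = 0.025,
    smooth_window_s: float = 0.02,
    detrend_window_s: float = 0.5,
    min_separation_s: float = 0.02,
    coincidence_s: float = 0.03,
    threshold_sd: float = 3.0,
) -> list[IpspEvent]:
    """Detect IPSPs from coincident negative peaks in the derivative and the
    detrended membrane potential.

    The trace is spike-filtered (25 ms median filter, 20 ms smoothing); its
    derivative's negative peaks mark rapid hyperpolarizations, and negative
    peaks of the detrended trace (minus a 500 ms median filter) mark the
    troughs.  An IPSP is scored at a trough preceded by a derivative peak
    within 30 ms.  Peaks are at least 20 ms apart; per-cell thresholds
    default to ``threshold_sd`` robust SDs of each signal during quiescence.
    """
    vm = np.asarray(vm, dtype=float)
    if quiescent_mask is not None:
        quiescent_mask = np.asarray(quiescent_mask, dtype=bool)
        if not np.any(quiescent_mask):
            raise ValueError("no quiescent samples available for IPSP analysis")
    else:
        quiescent_mask = np.ones(vm.size, dtype=bool)
    mw = int(round(median_window_s * sample_rate))
    sw = int(round(smooth_window_s * sample_rate))
    dw = int(round(detrend_window_s * sample_rate))
    filt = _loess(_medfilt_odd(vm, mw), sw)
    deriv = np.gradient(filt) * sample_rate / 1000.0  # mV per ms
    detrended = filt - _medfilt_odd(filt, dw)
    dist = max(1, int(round(min_separation_s * sample_rate)))
    # per-cell noise floor, robust to the events themselves: raw noise SD
    # from successive differences, scaled by the pipeline's fixed noise gain
    diffs = np.diff(vm[quiescent_mask])
    sigma_raw = _scaled_mad(diffs) / np.sqrt(2.0)
    gain_d, gain_a = _ipsp_noise_gains(mw, sw, dw, sample_rate)
    # floor at a fraction of the signal range so a noiseless trace does not
    # admit filter-ringing artefacts
    thr_d = max(threshold_sd * gain_d * sigma_raw, 0.15 * np.max(np.abs(deriv), initial=0.0))
    thr_a = max(threshold_sd * gain_a * sigma_raw, 0.15 * np.max(np.abs(detrended), initial=0.0))
    d_peaks, _ = _sig.find_peaks(-deriv, height=thr_d, distance=dist)
    a_peaks, _ = _sig.find_peaks(-detrended, height=thr_a, distance=dist)
    win = int(round(coincidence_s * sample_rate))
    events: list[IpspEvent] = []
    last_t = -np.inf
    d_iter = 0
    for ap in a_peaks:
        if not quiescent_mask[ap]:
            continue
        # any derivative peak within the 30 ms before the trough?
        while d_iter < len(d_peaks) and d_peaks[d_iter] < ap - win:
            d_iter += 1
        j = d_iter
        hit = False
        while j < len(d_peaks) and d_peaks[j] <= ap:
            hit = True
            dp = d_peaks[j]
            j += 1
        if not hit:
            continue
        t = ap / sample_rate
        if t - last_t < min_separation_s:
            continue
        last_t = t
        events.append(
            IpspEvent(time=t, derivative_peak=float(deriv[dp]), detrended_peak=float(detrended[ap]))
        )
    return events


def preferred_direction_tuning(
    values: np.ndarray,
    heading: np.ndarray,
    bin_deg: float = 20.0,
) -> TuningCurve:
    """Head-direction tuning: binned means of membrane potential (or firing
    rate) in ``bin_deg`` bins tiling (-180, 180].

    The preferred direction theta_p is the bin center with the maximum mean
    (ties break toward the smallest bin index) and the tuning amplitude is
    max - min of the binned means.  Sparse coverage (fewer than half the
    bins occupied) only warns.
    """
    v = np.asarray(values, dtype=float)
    th = wrap_deg(np.asarray(heading, dtype=float))
    if v.shape != th.shape:
        raise ValueError("values and heading lengths differ")
    ok = np.isfinite(v) & np.isfinite(th)
    v, th = v[ok], th[ok]
    n_bins = int(round(360.0 / bin_deg))
    edges = -180.0 + bin_deg * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(th, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = v[sel].mean()
    occupied = np.isfinite(means)
    if occupied.sum() < n_bins / 2:
        warnings.warn(
            f"sparse head-direction coverage: {occupied.sum()}/{n_bins} bins occupied "
            f"(per-bin n: {counts.tolist()})"
        )
    if not np.any(occupied):
        raise ValueError("no heading coverage; tuning curve undefined")
    centers = edges[:-1] + bin_deg / 2.0
    best = int(np.nanargmax(means))  # nanargmax returns the first (smallest) index on ties
    amplitude = float(np.nanmax(means) - np.nanmin(means))
    return TuningCurve(
        bin_centers=centers,
        values=means,
        n_per_bin=counts,
        preferred=float(centers[best]),
        amplitude=amplitude,
    )


@dataclass(frozen=True)
class JumpIpspResult:
    pairs: pd.DataFrame  # d_abs_dist_deg, d_freq_hz per jump
    r: float
    p_value: float
    slope: float
    intercept: float


def ipsp_jump_response(
    event_times: np.ndarray,
    jump_times: np.ndarray,
    heading: np.ndarray,
    theta_p: float,
    sample_rate: float = 1000.0,
    window_s: float = 5.0,
    immobile_mask: np.ndarray | None = None,
) -> JumpIpspResult:
    """Relate jump-evoked changes in IPSP frequency to the change in angular
    distance between head direction and the cell's preferred direction.

    For each jump with the fly immobile throughout the +/-``window_s``
    epoch: delta frequency = (events in the 5 s after - before) / window;
    delta distance = |theta_post - theta_p| - |theta_pre - theta_p| using
    mean headings over the flanking windows.  Returns per-jump pairs with a
    Pearson correlation and least-squares line.
    """
    ev = np.sort(np.asarray(event_times, dtype=float))
    th = np.asarray(heading, dtype=float)
    n = th.size
    w = int(round(window_s * sample_rate))
    rows = []
    for jt in np.asarray(jump_times, dtype=float):
        j = int(round(jt * sample_rate))
        if j - w < 0 or j + w > n:
            continue
        if immobile_mask is not None and not np.all(immobile_mask[j - w : j + w]):
            continue
        pre_f = np.sum((ev >= jt - window_s) & (ev < jt)) / window_s
        post_f = np.sum((ev >= jt) & (ev < jt + window_s)) / window_s
        pre_th = np.mean(th[j - w : j])
        post_th = np.mean(th[j : j + w])
        d_dist = abs(circ_dist_signed(post_th, theta_p)) - abs(circ_dist_signed(pre_th, theta_p))
        rows.append((d_dist, post_f - pre_f))
    if len(rows) < 3:
        raise ValueError("fewer than 3 qualifying jumps for IPSP analysis")
    pairs = pd.DataFrame(rows, columns=["d_abs_dist_deg", "d_freq_hz"])
    r, p = _stats.pearsonr(pairs["d_abs_dist_deg"], pairs["d_freq_hz"])
    slope, intercept = np.polyfit(pairs["d_abs_dist_deg"], pairs["d_freq_hz"], 1)
    return JumpIpspResult(pairs=pairs, r=float(r), p_value=float(p),
                          slope=float(slope), intercept=float(intercept))


def tuning_by_goal_offset(
    cells: list[dict],
    offset_bin_deg: float = 72.0,
    tuning_bin_deg: float = 20.0,
    rho_min: float = 0.7,
    subtract_min: bool = True,
) -> dict:
    """Average head-direction tuning curves within bins of goal offset
    (theta_g - theta_p).

    ``cells`` holds one record per segment per cell with keys ``values``
    (Vm or rate), ``heading``, ``theta_g``, ``theta_p``, ``rho`` and
    optionally ``cell_type`` ('PFL3L' records have the left-right order of
    the offset bins reversed, i.e. their offsets are negated, so they pool
    with PFL3R).  Only segments with rho >= ``rho_min`` are used.  Curves
    are computed against heading relative to theta_p, optionally
    min-subtracted, then averaged per offset bin.  Returns
    {offset_bin_center: DataFrame(rel_heading_deg, mean, sem, n_curves)}.
    """
    n_off = int(round(360.0 / offset_bin_deg))
    off_edges = -180.0 + offset_bin_deg * np.arange(n_off + 1)
    off_centers = off_edges[:-1] + offset_bin_deg / 2.0
    n_tb = int(round(360.0 / tuning_bin_deg))
    rel_centers = -180.0 + tuning_bin_deg * (np.arange(n_tb) + 0.5)
    curves: dict[int, list[np.ndarray]] = {b: [] for b in range(n_off)}
    for rec in cells:
        if rec.get("rho", 1.0) < rho_min:
            continue
        offset = circ_dist_signed(rec["theta_g"], rec["theta_p"])
        if rec.get("cell_type") == "PFL3L":
            offset = wrap_deg(-offset)
        b = int(np.clip(np.digitize(offset, off_edges) - 1, 0, n_off - 1))
        rel = wrap_deg(np.asarray(rec["heading"], dtype=float) - rec["theta_p"])
        tc = preferred_direction_tuning(rec["values"], rel, bin_deg=tuning_bin_deg)
        vals = tc.values.copy()
        if subtract_min:
            vals = vals - np.nanmin(vals)
        curves[b].append(vals)
    out = {}
    for b in range(n_off):
        if not curves[b]:
            continue
        arr = np.asarray(curves[b])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(arr, axis=0)
            n_eff = np.sum(np.isfinite(arr), axis=0)
            sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
        out[float(off_centers[b])] = pd.DataFrame(
            {"rel_heading_deg": rel_centers, "mean": mean, "sem": sem,
             "n_curves": len(curves[b])}
        )
    return out


def brown_forsythe(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Brown-Forsythe test of equal variances: an ANOVA F on
    absolute deviations from each group's median."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("each group needs at least 2 observations")
    stat, p = _stats.levene(x, y, center="median")
    return float(stat), float(p)


@dataclass(frozen=True)
class JumpDvmStats:
    dvm_corrected_high: np.ndarray
    dvm_uncorrected_low: np.ndarray
    statistic: float
    p_value: float


def jump_dvm_stats(
    vm: np.ndarray,
    jumps,
    sample_rate: float = 1000.0,
    pre_post_s: float = 1.0,
) -> JumpDvmStats:
    """Jump-evoked membrane-potential change (mean over 1 s after minus 1 s
    before) compared between 'corrected, high rho' and 'uncorrected, low
    rho' jumps with a Brown-Forsythe variance test."""
    vm = np.asarray(vm, dtype=float)
    w = int(round(pre_post_s * sample_rate))
    g1, g2 = [], []
    for jp in jumps:
        if getattr(jp, "excluded", False):
            continue
        j = int(round(jp.time * sample_rate))
        if j - w < 0 or j + w > vm.size:
            continue
        dvm = float(np.mean(vm[j : j + w]) - np.mean(vm[j - w : j]))
        if jp.corrected and jp.high_rho:
            g1.append(dvm)
        elif (not jp.corrected) and (not jp.high_rho):
            g2.append(dvm)
    if min(len(g1), len(g2)) < 2:
        raise ValueError("need at least 2 jumps in each classification group")
    stat, p = brown_forsythe(g1, g2)
    return JumpDvmStats(
        dvm_corrected_high=np.asarray(g1),
        dvm_uncorrected_low=np.asarray(g2),
        statistic=stat,
        p_value=p,
    )


def unbalanced_two_factor_anova(
    y: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
) -> pd.DataFrame:
    """Unbalanced two-factor ANOVA (type-III sums of squares) on categorical
    factors, e.g. head-direction change group and fly identity."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "a": pd.Categorical(factor_a), "b": pd.Categorical(factor_b)})
    fit = smf.ols("y ~ C(a, Sum) + C(b, Sum)", data=df).fit()
    return sm.stats.anova_lm(fit, typ=3)


def dvm_speed_lag_correlation(
    vm: np.ndarray,
    rotational_speed: np.ndarray,
    jump_times: np.ndarray,
    sample_rate: float = 1000.0,
    window_s: float = 4.0,
    max_lag_s: float = 1.0,
    lag_step_s: float = 0.01,
) -> pd.DataFrame:
    """Correlation between |delta Vm| after a jump and lagged rotational
    speed, per lag, averaged over jumps.

    |delta Vm|(t) is the absolute deviation of the post-jump membrane
    potential from its pre-jump 4 s mean.  Positive lags shift the speed
    later, so a peak at a positive lag means membrane-potential changes
    precede steering.  Returns DataFrame(lag_s, mean_r, sem_r) over the
    inclusive lag grid (+/-``max_lag_s`` stepped by ``lag_step_s``).
    """
    vm = np.asarray(vm, dtype=float)
    sp = np.asarray(rotational_speed, dtype=float)
    if vm.shape != sp.shape:
        raise ValueError("vm and speed series lengths differ")
    w = int(round(window_s * sample_rate))
    lag_n = int(round(max_lag_s / lag_step_s))
    lag_samples = (np.arange(-lag_n, lag_n + 1) * lag_step_s * sample_rate).round().astype(int)
    per_jump = []
    for jt in np.asarray(jump_times, dtype=float):
        j = int(round(jt * sample_rate))
        if j - w < 0 or j + w + lag_samples.max() > vm.size or j + lag_samples.min() < 0:
            continue
        pre_mean = np.mean(vm[j - w : j])
        dvm = np.abs(vm[j : j + w] - pre_mean)
        rs = np.empty(lag_samples.size)
        for i, L in enumerate(lag_samples):
            seg = sp[j + L : j + L + w]
            if np.std(seg) == 0 or np.std(dvm) == 0:
                rs[i] = np.nan
            else:
                rs[i] = np.corrcoef(dvm, seg)[0, 1]
        per_jump.append(rs)
    if not per_jump:
        raise ValueError("no qualifying jumps for the lag-correlation analysis")
    arr = np.asarray(per_jump)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = np.nanmean(arr, axis=0)
        n_eff = np.sum(np.isfinite(arr), axis=0)
        sem_r = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    return pd.DataFrame(
        {"lag_s": np.arange(-lag_n, lag_n + 1) * lag_step_s, "mean_r": mean_r, "sem_r": sem_r}
    )
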