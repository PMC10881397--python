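"""Network model of the head-direction-to-steering transformation.

Three output populations of the fly central complex (PFL2, PFL3R, PFL3L)
each receive a phase-shifted copy of the sinusoidal head-direction
representation (shifts +180, +67.5 and -67.5 degrees respectively) plus a
shared sinusoidal goal input.  Each unit sums its two inputs, the sum is
scaled by a factor ``S`` and passed through a calibrated exponential linear
unit (ELU).  Summed population activity converges onto descending neurons:
the *direct* pathway PFL3 -> DNa02 and the *indirect* pathway
PFL2/PFL3 -> DNa03 -> DNa02.  The right-left DNa02 difference is the
rotational-velocity command; feeding it back onto head direction closes the
loop and steers the simulated fly toward its goal.

Because PFL2 projects bilaterally it cannot steer through a linear readout
(its contribution cancels in the right-left difference); it acts by pushing
DNa03 up the expansive part of the nonlinearity, boosting steering gain
selectively around the anti-goal.

Population sums feeding descending neurons are normalized to the biological
cell count (12 cells per population in the hemibrain connectome):
``Sigma = n_cells * mean(unit rates)``.  This keeps the relative synaptic
weights (1 : 4 : 12) meaningful and makes all population-level curves
invariant to the number of model units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .circular import wrap_deg, circ_consistency
from .imaging import fit_bump, roi_angles_deg

__all__ = [
    "ModelParams",
    "PopulationActivity",
    "SimulationResult",
    "NetworkCalibration",
    "preferred_direction_grid",
    "head_input",
    "goal_input",
    "elu_activation",
    "pfl_rates",
    "descending_outputs",
    "steering_drive",
    "calibrate_steering_gain",
    "generate_noise",
    "simulate_closed_loop",
    "scale_sweep",
    "open_loop_profiles",
]

_ELU_LO = float(np.expm1(-1.0))  # ELU(-1), lower bound of the output range


@dataclass
class ModelParams:
    """Parameters of the steering network.

    Weights follow connectome synapse-count ratios: PFL3->DNa02 and
    PFL3->DNa03 weigh 1, PFL2->DNa03 weighs 4, DNa03->DNa02 weighs 12.
    ``steering_gain`` (deg/s per unit of DNa02 right-left difference) is not
    constrained by the biology; ``None`` requests auto-calibration such that
    the peak noise-free open-loop drive at S = 1 is
    ``target_peak_drive`` deg/s for the configured pathway set.
    """

    n_units: int = 1000
    shift_pfl3: float = 67.5
    shift_pfl2: float = 180.0
    goal_amplitude: float = 1.0
    scale: float = 1.0
    theta0: float = 0.0
    w_p3_d2: float = 1.0
    w_p3_d3: float = 1.0
    w_p2_d3: float = 4.0
    w_d3_d2: float = 12.0
    steering_gain: float | None = None
    target_peak_drive: float = 200.0
    dt: float = 0.1
    duration: float = 100.0
    noise_sd: float = 10.0
    noise_cutoff_hz: float = 2.0
    seed: int = 0
    n_cells: int = 12
    pathways: str = "both"  # "both" | "direct" | "indirect"
    activation: str = "elu"  # "elu" | "relu" | "sigmoid" | "identity"

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise ValueError("n_units must be >= 3")
        if min(self.w_p3_d2, self.w_p3_d3, self.w_p2_d3, self.w_d3_d2) < 0:
            raise ValueError("weights must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.goal_amplitude < 0:
            raise ValueError("goal amplitude A must be non-negative")
        if self.scale < 0:
            raise ValueError("scale S must be non-negative")
        if self.pathways not in ("both", "direct", "indirect"):
            raise ValueError(f"unknown pathways setting: {self.pathways!r}")
        if self.activation not in ("elu", "relu", "sigmoid", "identity"):
            raise ValueError(f"unknown activation: {self.activation!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls(**json.loads(text))


@dataclass
class PopulationActivity:
    """Unit rates of the PFL populations and scalar descending-neuron rates.

    All rates lie in [0, 1] after the calibrated activation rescaling.
    """

    pfl2: np.ndarray
    pfl3r: np.ndarray
    pfl3l: np.ndarray
    dna03r: float | None = None
    dna03l: float | None = None
    dna02r: float | None = None
    dna02l: float | None = None


@dataclass
class SimulationResult:
    """Closed-loop run: heading trace, directional error, steering command
    components, per-step PFL2 bump amplitude and the run's heading
    consistency rho (mean resultant length of theta over the full run)."""

    time: np.ndarray
    theta: np.ndarray
    error: np.ndarray
    dna02_diff: np.ndarray
    pfl2_bump_amplitude: np.ndarray
    noise_trace: np.ndarray
    rho: float
    params: ModelParams

    def to_frame(self) -> pd.DataFrame:
        n = len(self.theta)
        return pd.DataFrame(
            {
                "time_s": self.time,
                "theta_deg": self.theta,
                "error_deg": self.error,
                "dna02_diff": np.append(self.dna02_diff, np.nan)[:n]
                if len(self.dna02_diff) < n
                else self.dna02_diff,
                "pfl2_amp": np.append(self.pfl2_bump_amplitude, np.nan)[:n]
                if len(self.pfl2_bump_amplitude) < n
                else self.pfl2_bump_amplitude,
                "noise": np.append(self.noise_trace, np.nan)[:n]
                if len(self.noise_trace) < n
                else self.noise_trace,
            }
        )


def preferred_direction_grid(n_units: int) -> np.ndarray:
    """Preferred head directions of ``n_units`` units, uniformly tiling 360 deg."""
    if n_units < 1:
        raise ValueError("need at least one unit")
    return np.arange(n_units) * (360.0 / n_units)


def head_input(theta: float, theta0: float, shift: float, h: np.ndarray) -> np.ndarray:
    """Per-unit head-direction input cos(theta - theta0 - h + shift)."""
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        raise ValueError("empty preferred-direction grid")
    return np.cos(np.deg2rad(theta - theta0 - h + shift))


def goal_input(theta_g: float, theta0: float, A: float, h: np.ndarray) -> np.ndarray:
    """Per-unit goal input A * cos(theta_g - theta0 - h)."""
    if A < 0:
        raise ValueError("goal amplitude A must be non-negative")
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        raise ValueError("empty preferred-direction grid")
    return A * np.cos(np.deg2rad(theta_g - theta0 - h))


def elu_activation(M, calibration: tuple[float, float]):
    """Calibrated ELU: affinely map ``M`` from the ensemble range
    ``calibration = (min, max)`` onto [-1, 1], apply ELU (identity for
    x >= 0, exp(x) - 1 below), then affinely rescale the ELU output range
    [ELU(-1), ELU(1)] onto [0, 1]."""
    lo, hi = float(calibration[0]), float(calibration[1])
    if not hi > lo:
        raise ValueError("degenerate activation calibration (min >= max)")
    x = (2.0 * (np.asarray(M, dtype=float) - lo) / (hi - lo)) - 1.0
    y = np.where(x >= 0, x, np.expm1(np.minimum(x, 0.0)))
    out = (y - _ELU_LO) / (1.0 - _ELU_LO)
    return out if np.ndim(M) else float(out)


def _relu_activation(M, calibration):
    lo, hi = calibration
    x = (2.0 * (np.asarray(M, dtype=float) - lo) / (hi - lo)) - 1.0
    out = np.maximum(x, 0.0)
    return out if np.ndim(M) else float(out)


def _sigmoid_activation(M, calibration):
    # logistic with half-maximum in the upper part of the calibrated range,
    # so it is expansive (convex) over most of the operating range like the
    # ELU; a logistic centered at the midpoint would be odd and would erase
    # amplitude information from population sums
    lo, hi = calibration
    x = (2.0 * (np.asarray(M, dtype=float) - lo) / (hi - lo)) - 1.0
    c, g = 0.5, 4.0
    y = 1.0 / (1.0 + np.exp(-g * (x - c)))
    y0 = 1.0 / (1.0 + np.exp(g * (1.0 + c)))
    y1 = 1.0 / (1.0 + np.exp(-g * (1.0 - c)))
    out = (y - y0) / (y1 - y0)
    return out if np.ndim(M) else float(out)


def _identity_activation(M, calibration):
    return M


_ACTIVATIONS: dict[str, Callable] = {
    "elu": elu_activation,
    "relu": _relu_activation,
    "sigmoid": _sigmoid_activation,
    "identity": _identity_activation,
}


@dataclass
class NetworkCalibration:
    """Pre-activation input ranges (min, max) per stage, computed over the
    network's "lifetime" ensemble: all head directions theta and goal
    directions theta_g on a 1-degree grid, crossed with every scale value S
    configured for the run, and all unit indices.

    For PFL cells the head and goal cosine terms vary independently over the
    (theta, theta_g) product grid, so the ensemble extrema separate into a
    per-unit sum of the two terms' extrema (computed exactly, no product
    grid needed).  For the descending neurons the summed-input extrema are
    evaluated on an explicit grid of directional error; summed activity over
    a uniform preferred-direction grid depends on theta and theta_g only
    through their difference.
    """

    pfl: tuple[float, float]
    dna03: tuple[float, float]
    dna02: tuple[float, float]

    @classmethod
    def from_params(
        cls,
        params: ModelParams,
        s_ensemble: Sequence[float] | None = None,
        grid_step: float = 1.0,
    ) -> "NetworkCalibration":
        s_vals = np.asarray(
            [params.scale] if s_ensemble is None else list(s_ensemble), dtype=float
        )
        if s_vals.size == 0:
            raise ValueError("empty S ensemble")
        h = preferred_direction_grid(params.n_units)
        thetas = np.arange(-180.0, 180.0, grid_step)
        A = params.goal_amplitude

        # --- PFL stage (theta and theta_g independent => extrema separate) ---
        # per-unit head-term extrema over the theta grid are the same for any
        # constant shift modulo grid alignment; evaluate explicitly.
        head = np.cos(np.deg2rad(thetas[:, None] - params.theta0 - h[None, :]))
        goal = A * head  # same functional form, scaled by A
        base_min = head.min(axis=0) + goal.min(axis=0)
        base_max = head.max(axis=0) + goal.max(axis=0)
        cand = np.concatenate(
            [np.outer(s_vals, base_min).ravel(), np.outer(s_vals, base_max).ravel()]
        )
        pfl = (float(cand.min()), float(cand.max()))

        f = _ACTIVATIONS[params.activation]

        # --- descending stages: scan directional error on the grid ---
        d3_lo, d3_hi = np.inf, -np.inf
        d2_lo, d2_hi = np.inf, -np.inf
        for S in s_vals:
            s2, s3r, s3l = _summed_pfl_curves(params, pfl, thetas, S=S)
            in3r = params.w_p3_d3 * s3r + params.w_p2_d3 * s2
            in3l = params.w_p3_d3 * s3l + params.w_p2_d3 * s2
            d3_lo = min(d3_lo, in3r.min(), in3l.min())
            d3_hi = max(d3_hi, in3r.max(), in3l.max())
        dna03 = (float(d3_lo), float(d3_hi))
        for S in s_vals:
            s2, s3r, s3l = _summed_pfl_curves(params, pfl, thetas, S=S)
            d3r = f(params.w_p3_d3 * s3r + params.w_p2_d3 * s2, dna03)
            d3l = f(params.w_p3_d3 * s3l + params.w_p2_d3 * s2, dna03)
            in2r = params.w_p3_d2 * s3r + params.w_d3_d2 * np.asarray(d3r)
            in2l = params.w_p3_d2 * s3l + params.w_d3_d2 * np.asarray(d3l)
            d2_lo = min(d2_lo, in2r.min(), in2l.min())
            d2_hi = max(d2_hi, in2r.max(), in2l.max())
        dna02 = (float(d2_lo), float(d2_hi))
        return cls(pfl=pfl, dna03=dna03, dna02=dna02)


def _summed_pfl_curves(
    params: ModelParams,
    pfl_calib: tuple[float, float],
    errors: np.ndarray,
    S: float | None = None,
):
    """Normalized population sums (SigmaPFL2, SigmaPFL3R, SigmaPFL3L) as a
    function of directional error, vectorized over an error grid."""
    S = params.scale if S is None else S
    h = preferred_direction_grid(params.n_units)
    f = _ACTIVATIONS[params.activation]
    # theta = error, theta_g = 0, theta0 = 0: population sums over a uniform
    # grid depend only on error (and the per-unit profile only shifts with
    # theta0, leaving sums unchanged).
    err = np.asarray(errors, dtype=float)[:, None]
    goal = params.goal_amplitude * np.cos(np.deg2rad(-h[None, :]))
    out = []
    for shift in (params.shift_pfl2, params.shift_pfl3, -params.shift_pfl3):
        head = np.cos(np.deg2rad(err - h[None, :] + shift))
        rates = np.asarray(f(S * (head + goal), pfl_calib))
        out.append(params.n_cells * rates.mean(axis=1))
    return tuple(out)  # (sigma_pfl2, sigma_pfl3r, sigma_pfl3l)


def pfl_rates(
    theta: float,
    theta_g: float,
    params: ModelParams,
    calibration: NetworkCalibration,
) -> PopulationActivity:
    """Unit rates of the three PFL populations at one (theta, theta_g)."""
    h = preferred_direction_grid(params.n_units)
    f = _ACTIVATIONS[params.activation]
    goal = goal_input(theta_g, params.theta0, params.goal_amplitude, h)
    S = params.scale
    pfl2 = f(S * (head_input(theta, params.theta0, params.shift_pfl2, h) + goal), calibration.pfl)
    pfl3r = f(S * (head_input(theta, params.theta0, params.shift_pfl3, h) + goal), calibration.pfl)
    pfl3l = f(S * (head_input(theta, params.theta0, -params.shift_pfl3, h) + goal), calibration.pfl)
    return PopulationActivity(pfl2=np.asarray(pfl2), pfl3r=np.asarray(pfl3r), pfl3l=np.asarray(pfl3l))


def descending_outputs(
    activity: PopulationActivity,
    params: ModelParams,
    calibration: NetworkCalibration,
) -> PopulationActivity:
    """Fill DNa03 and DNa02 rates from the PFL rates.

    DNa03 sums PFL3 (same side) and PFL2 (bilateral, identical weights on R
    and L); DNa02 sums PFL3 (direct pathway) and DNa03 (indirect pathway).
    ``params.pathways`` zeroes the omitted pathway's input at the DNa02
    summation while keeping the calibrated activation fixed.
    """
    f = _ACTIVATIONS[params.activation]
    nc = params.n_cells
    s2 = nc * float(np.mean(activity.pfl2))
    s3r = nc * float(np.mean(activity.pfl3r))
    s3l = nc * float(np.mean(activity.pfl3l))
    d3r = float(f(params.w_p3_d3 * s3r + params.w_p2_d3 * s2, calibration.dna03))
    d3l = float(f(params.w_p3_d3 * s3l + params.w_p2_d3 * s2, calibration.dna03))
    direct_r = params.w_p3_d2 * s3r if params.pathways in ("both", "direct") else 0.0
    direct_l = params.w_p3_d2 * s3l if params.pathways in ("both", "direct") else 0.0
    indir_r = params.w_d3_d2 * d3r if params.pathways in ("both", "indirect") else 0.0
    indir_l = params.w_d3_d2 * d3l if params.pathways in ("both", "indirect") else 0.0
    activity.dna03r, activity.dna03l = d3r, d3l
    activity.dna02r = float(f(direct_r + indir_r, calibration.dna02))
    activity.dna02l = float(f(direct_l + indir_l, calibration.dna02))
    return activity


def steering_drive(
    activity: PopulationActivity,
    params: ModelParams,
    epsilon: float = 0.0,
    steering_gain: float | None = None,
) -> float:
    """Rotational-velocity command k * (DNa02R - DNa02L) + epsilon, in deg/s.

    Positive = clockwise (rightward) turning.
    """
    if activity.dna02r is None or activity.dna02l is None:
        raise ValueError("descending outputs not populated")
    k = steering_gain if steering_gain is not None else params.steering_gain
    if k is None:
        raise ValueError("steering gain not set; call calibrate_steering_gain")
    return k * (activity.dna02r - activity.dna02l) + epsilon


def calibrate_steering_gain(
    params: ModelParams,
    calibration: NetworkCalibration | None = None,
    grid_step: float = 1.0,
) -> float:
    """Gain k such that the peak noise-free open-loop |drive| at S = 1 equals
    ``params.target_peak_drive`` deg/s for the configured pathway set."""
    p1 = replace(params, scale=1.0, steering_gain=1.0)
    calib = calibration or NetworkCalibration.from_params(p1)
    prof = open_loop_profiles(p1, np.arange(-180.0, 180.0, grid_step), calibration=calib)
    col = {"both": "drive_full", "direct": "drive_direct", "indirect": "drive_indirect"}[
        params.pathways
    ]
    peak = float(np.max(np.abs(prof[col].to_numpy())))
    if peak <= 0:
        raise ValueError("degenerate network: zero open-loop drive everywhere")
    return params.target_peak_drive / peak


def generate_noise(
    seed: int,
    sd: float = 10.0,
    cutoff_hz: float = 2.0,
    dt: float = 0.1,
    duration: float = 100.0,
) -> np.ndarray:
    """Frozen steering-noise sample: Gaussian draws low-pass filtered at
    ``cutoff_hz`` (second-order Butterworth, forward-backward / zero phase)
    and rescaled so the sample standard deviation equals ``sd`` exactly.

    The trace is the per-update angular perturbation epsilon(t) in degrees
    (added to each heading update, not scaled by dt), standing in for
    neural noise and unmodeled steering influences.  The same seed always
    yields the identical trace.
    """
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    n = int(round(duration / dt)) + 1
    if sd == 0:
        return np.zeros(n)
    b, a = _sig.butter(2, cutoff_hz, fs=1.0 / dt)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if n <= padlen:
        raise ValueError(
            f"duration too short for the noise filter ({n} samples <= padlen {padlen})"
        )
    rng = np.random.default_rng(seed)
    eps = _sig.filtfilt(b, a, rng.standard_normal(n))
    return eps * (sd / eps.std())


def simulate_closed_loop(
    params: ModelParams,
    theta_init: float,
    theta_g: float = 0.0,
    calibration: NetworkCalibration | None = None,
    noise: np.ndarray | None = None,
    jump_schedule: Sequence[tuple[float, float]] | None = None,
) -> SimulationResult:
    """Forward-Euler closed-loop steering simulation.

    theta(t+dt) = wrap(theta(t) + dt * k * (DNa02R - DNa02L) + eps(t)),
    where eps is the frozen noise sample in degrees per update.
    ``jump_schedule`` is a list of (time_s, magnitude_deg) pairs applied as
    instantaneous offsets to theta, emulating cue jumps.  Raises a
    ``FloatingPointError`` naming the step index if the state diverges.
    """
    if calibration is None:
        # include S=1 in the ensemble when the gain must be auto-calibrated
        ens = sorted({params.scale, 1.0}) if params.steering_gain is None else None
        calibration = NetworkCalibration.from_params(params, s_ensemble=ens)
    calib = calibration
    k = params.steering_gain
    if k is None:
        k = calibrate_steering_gain(params, calibration=calib)
    n_steps = int(round(params.duration / params.dt))
    if noise is None:
        noise = generate_noise(
            params.seed, params.noise_sd, params.noise_cutoff_hz, params.dt, params.duration
        )
    if len(noise) < n_steps:
        raise ValueError("noise trace shorter than the simulation")
    jumps = sorted(jump_schedule or [])
    jump_idx = 0

    time = np.arange(n_steps + 1) * params.dt
    theta = np.empty(n_steps + 1)
    dna02_diff = np.empty(n_steps)
    pfl2_amp = np.empty(n_steps)
    theta[0] = wrap_deg(theta_init)
    h = preferred_direction_grid(params.n_units)
    angles = roi_angles_deg(params.n_units)

    for t in range(n_steps):
        while jump_idx < len(jumps) and jumps[jump_idx][0] <= time[t] + 1e-9:
            theta[t] = wrap_deg(theta[t] + jumps[jump_idx][1])
            jump_idx += 1
        act = pfl_rates(theta[t], theta_g, params, calib)
        descending_outputs(act, params, calib)
        dna02_diff[t] = act.dna02r - act.dna02l
        pfl2_amp[t] = fit_bump(act.pfl2, angles).amplitude
        nxt = theta[t] + params.dt * k * dna02_diff[t] + noise[t]
        if not np.isfinite(nxt):
            raise FloatingPointError(f"simulation diverged at step {t}")
        theta[t + 1] = wrap_deg(nxt)

    error = wrap_deg(theta - theta_g)
    rho = circ_consistency(theta)
    return SimulationResult(
        time=time,
        theta=theta,
        error=error,
        dna02_diff=dna02_diff,
        pfl2_bump_amplitude=pfl2_amp,
        noise_trace=np.asarray(noise)[: n_steps],
        rho=rho,
        params=params,
    )


def scale_sweep(
    params: ModelParams,
    s_values: Sequence[float],
    n_seeds: int,
    error_bin_deg: float = 10.0,
) -> pd.DataFrame:
    """Sweep the input-scale factor S over repeated noisy closed-loop runs.

    For each (S, seed): run ``params.duration`` seconds of simulated time,
    compute the heading consistency rho = 1 - circular variance of theta,
    and the PFL2 bump-amplitude range = max - min of the error-binned mean
    bump amplitude.  Returns a tidy frame (S, seed, rho, bump_amplitude_range).
    """
    s_values = list(s_values)
    if not s_values:
        raise ValueError("empty S_values")
    calib = NetworkCalibration.from_params(params, s_ensemble=sorted(set(s_values + [1.0])))
    k = params.steering_gain
    if k is None:
        k = calibrate_steering_gain(params, calibration=calib)
    rows = []
    # seed-matched across S: run j uses the same frozen noise sample for
    # every value of S
    for S in s_values:
        p = replace(params, scale=S, steering_gain=k)
        for i in range(n_seeds):
            seed = (params.seed * 100003 + i * 7919) % (2**31 - 1)
            noise = generate_noise(seed, p.noise_sd, p.noise_cutoff_hz, p.dt, p.duration)
            res = simulate_closed_loop(
                p, theta_init=0.0, theta_g=0.0, calibration=calib, noise=noise
            )
            err = res.error[:-1]
            amp = res.pfl2_bump_amplitude
            bins = np.arange(-180.0, 180.0 + error_bin_deg, error_bin_deg)
            which = np.digitize(err, bins) - 1
            means = [amp[which == b].mean() for b in range(len(bins) - 1) if np.any(which == b)]
            amp_range = float(np.max(means) - np.min(means)) if means else 0.0
            rows.append(
                {"S": S, "seed": seed, "rho": res.rho, "bump_amplitude_range": amp_range}
            )
    return pd.DataFrame(rows)


def open_loop_profiles(
    params: ModelParams,
    error_grid: np.ndarray,
    calibration: NetworkCalibration | None = None,
) -> pd.DataFrame:
    """Deterministic open-loop curves versus directional error.

    Columns: summed PFL3R / PFL3L activity and their difference, summed PFL2
    activity, PFL2 bump amplitude, and the drive produced by the direct
    pathway alone, the indirect pathway alone, and both (per-pathway curves
    zero the other pathway's input at the DNa02 summation, keeping the
    calibrated activation fixed).  Drives are in units of the DNa02
    right-left difference; multiply by the steering gain for deg/s.
    """
    err = np.asarray(error_grid, dtype=float)
    calib = calibration or NetworkCalibration.from_params(params)
    f = _ACTIVATIONS[params.activation]
    s2, s3r, s3l = _summed_pfl_curves(params, calib.pfl, err)
    d3r = np.asarray(f(params.w_p3_d3 * s3r + params.w_p2_d3 * s2, calib.dna03))
    d3l = np.asarray(f(params.w_p3_d3 * s3l + params.w_p2_d3 * s2, calib.dna03))

    def drive(direct: bool, indirect: bool) -> np.ndarray:
        r = (params.w_p3_d2 * s3r if direct else 0.0) + (params.w_d3_d2 * d3r if indirect else 0.0)
        l = (params.w_p3_d2 * s3l if direct else 0.0) + (params.w_d3_d2 * d3l if indirect else 0.0)
        return np.asarray(f(r, calib.dna02)) - np.asarray(f(l, calib.dna02))

    # per-error PFL2 bump amplitude from the unit-rate profile
    h_angles = roi_angles_deg(params.n_units)
    amps = np.empty(err.size)
    for i, e in enumerate(err):
        act = pfl_rates(float(e), 0.0, params, calib)
        amps[i] = fit_bump(act.pfl2, h_angles).amplitude
    return pd.DataFrame(
        {
            "error_deg": err,
            "sum_pfl3r": s3r,
            "sum_pfl3l": s3l,
            "pfl3_diff": s3r - s3l,
            "sum_pfl2": s2,
            "pfl2_amp": amps,
            "drive_direct": drive(True, False),
            "drive_indirect": drive(False, True),
            "drive_full": drive(True, True),
        }
    )
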