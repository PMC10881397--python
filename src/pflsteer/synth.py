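"""Synthetic trial generators with recorded ground truth.

These emulate the statistical structure of closed-loop virtual-reality fly
experiments: heading traces with goal fixation and periodic cue jumps
(+90 / 180 / -90 degrees every 60 s, closed-loop yaw gain 0.7), sinusoidal
calcium bumps with controlled amplitude and phase, and membrane potential
with cosine head-direction tuning, spikes and rate-modulated IPSPs.  Every
generator is seed-deterministic and returns the ground truth needed to
score parameter-recovery tests.

Two behavior modes are provided: a *model-driven* mode that runs the
steering network in closed loop (so behavioral recovery is linked to the
model's scale parameter S), and a *scripted* mode using a mean-reverting
angular process toward the goal, which exercises the behavior pipeline
without depending on the network model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circular import wrap_deg, circ_dist_signed
from .behavior import KinematicsTrace, BALL_RADIUS_MM
from .imaging import RoiTimeSeries, ROI_COUNTS, roi_angles_deg
from . import model as _model

__all__ = ["SynthTrialSpec", "GroundTruth", "synth_behavior", "synth_calcium", "synth_vm"]

YAW_GAIN = 0.7  # closed-loop gain: cue displacement = 0.7 x ball yaw displacement


@dataclass
class SynthTrialSpec:
    """Conditions of a synthetic closed-loop trial.

    Defaults reproduce the experimental protocol: 600 s trials with a cue
    jump every 60 s cycling +90, 180, -90 degrees.  ``fixation_mode`` is
    "scripted" (mean-reverting heading, reversion rate ``kappa`` per second)
    or "model" (network closed loop at scale ``S``).
    """

    duration_s: float = 600.0
    jump_period_s: float = 60.0
    jump_sequence: tuple = (90.0, 180.0, -90.0)
    goal_schedule: tuple = ((0.0, 0.0),)  # (start_s, theta_g)
    fixation_mode: str = "scripted"
    kappa: float = 1.5  # scripted-mode reversion rate, 1/s
    heading_noise_step: float = 3.0  # scripted-mode per-sample noise, deg
    S: float = 0.8  # model-mode input scale
    immobility_bouts: tuple = ()  # ((start_s, end_s), ...)
    sample_rate: float = 60.0
    yaw_gain: float = YAW_GAIN
    forward_mean_mm_s: float = 8.0
    forward_sd_mm_s: float = 3.0
    sideways_sd_mm_s: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixation_mode not in ("scripted", "model"):
            raise ValueError(f"unknown fixation mode {self.fixation_mode!r}")
        for t0, _g in self.goal_schedule:
            if t0 < 0 or t0 > self.duration_s:
                raise ValueError("goal schedule entry outside trial")

    def jump_times(self) -> np.ndarray:
        times = np.arange(self.jump_period_s, self.duration_s, self.jump_period_s)
        return times

    def jump_magnitudes(self) -> np.ndarray:
        times = self.jump_times()
        seq = np.asarray(self.jump_sequence, dtype=float)
        return seq[np.arange(times.size) % seq.size]


@dataclass
class GroundTruth:
    """Everything needed to score recovery tests against a generated trial."""

    theta_g: np.ndarray | None = None  # per-sample goal direction, deg
    jump_times: np.ndarray | None = None
    jump_magnitudes: np.ndarray | None = None
    will_correct: np.ndarray | None = None  # per-jump expectation
    rho_regime: str = ""  # "high" | "low"
    bump_amplitude: np.ndarray | None = None
    bump_phase: np.ndarray | None = None
    amplitude_range: float | None = None
    ipsp_times: np.ndarray | None = None
    spike_times: np.ndarray | None = None
    theta_p: float | None = None
    seed: int = 0

    def to_jsonable(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}


def _goal_at(spec: SynthTrialSpec, t: np.ndarray) -> np.ndarray:
    goals = sorted(spec.goal_schedule)
    out = np.full(t.size, goals[0][1], dtype=float)
    for start, g in goals:
        out[t >= start] = g
    return out


def synth_behavior(spec: SynthTrialSpec):
    """Generate a closed-loop behavioral trial.

    Returns ``(trace, trial, truth)`` where ``trace`` is a
    :class:`~pflsteer.behavior.KinematicsTrace` carrying heading, ``trial``
    is a JSON-ready descriptor (jump schedule + arena parameters) and
    ``truth`` records the goal schedule and per-jump expectations.

    Cue jumps appear as instantaneous heading discontinuities of exactly
    the jump magnitude.  The recorded rotational (ball yaw) velocity is the
    smooth part of the heading derivative divided by the closed-loop yaw
    gain; the cue trace is the negated heading, so the generated files obey
    cue displacement = yaw_gain x ball yaw displacement.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs)) + 1
    t = np.arange(n) / fs
    theta_g = _goal_at(spec, t)
    jt = spec.jump_times()
    jm = spec.jump_magnitudes()
    jump_idx = np.round(jt * fs).astype(int)

    immobile = np.zeros(n, dtype=bool)
    for b0, b1 in spec.immobility_bouts:
        immobile[(t >= b0) & (t < b1)] = True

    if spec.fixation_mode == "scripted":
        theta_smooth = np.empty(n)  # continuous part (no jump steps)
        offset = 0.0  # accumulated jump offsets
        theta_smooth[0] = theta_g[0]
        dt = 1.0 / fs
        jmap = dict(zip(jump_idx, jm))
        for i in range(1, n):
            if i in jmap:
                offset += jmap[i]
            cur = theta_smooth[i - 1]
            if immobile[i - 1]:
                step = 0.0
            else:
                err = circ_dist_signed(cur + offset, theta_g[i - 1])
                step = -spec.kappa * err * dt + spec.heading_noise_step * rng.standard_normal()
            theta_smooth[i] = cur + step
        # ball yaw velocity: the cue (hence heading) moves yaw_gain times
        # the ball's yaw displacement
        rot_deg_s = np.gradient(theta_smooth) * fs / spec.yaw_gain
        cum_offsets = np.zeros(n)
        for idx, mag in zip(jump_idx, jm):
            cum_offsets[idx:] += mag
        heading = wrap_deg(theta_smooth + cum_offsets)
        will_correct = np.full(jt.size, spec.kappa > 0.2)
    else:
        p = _model.ModelParams(scale=spec.S, seed=spec.seed,
                               duration=spec.duration_s, dt=0.1)
        schedule = list(zip(jt.tolist(), jm.tolist()))
        res = _model.simulate_closed_loop(
            p, theta_init=theta_g[0], theta_g=float(theta_g[0]), jump_schedule=schedule
        )
        # split the 10 Hz trace into a continuous part plus jump steps,
        # upsample the continuous part to 60 Hz, re-apply the steps exactly
        d = circ_dist_signed(res.theta[1:], res.theta[:-1])
        step_idx = np.round(jt / p.dt).astype(int)
        for si, mag in zip(step_idx, jm):
            if si - 1 < d.size:
                d[si - 1] -= mag
        smooth10 = np.concatenate([[res.theta[0]], res.theta[0] + np.cumsum(d)])
        theta_smooth = np.interp(t, res.time, smooth10)
        rot_deg_s = np.gradient(theta_smooth) * fs / spec.yaw_gain
        cum_offsets = np.zeros(n)
        for idx, mag in zip(jump_idx, jm):
            cum_offsets[idx:] += mag
        heading = wrap_deg(theta_smooth + cum_offsets)
        immobile[:] = False
        will_correct = np.full(jt.size, spec.S >= 0.5)

    forward = spec.forward_mean_mm_s + spec.forward_sd_mm_s * _lowpass_noise(rng, n)
    sideways = spec.sideways_sd_mm_s * _lowpass_noise(rng, n)
    forward[immobile] = 0.0
    sideways[immobile] = 0.0
    rot = rot_deg_s.copy()
    rot[immobile] = 0.0
    cum = (np.abs(forward) + np.abs(sideways)) / BALL_RADIUS_MM + np.abs(np.deg2rad(rot))

    trace = KinematicsTrace(
        time=t,
        forward=forward,
        sideways=sideways,
        rotational=rot,
        cumulative_speed=cum,
        mobile=cum > 0.67,
        heading=heading,
        sample_rate=fs,
    )
    trial = {
        "schema_version": 1,
        "trial_id": f"synth-{spec.fixation_mode}-{spec.seed}",
        "jump_times_s": jt.tolist(),
        "jump_magnitudes_deg": jm.tolist(),
        "arena": {"yaw_gain": spec.yaw_gain, "cue_convention": "heading = -cue azimuth"},
        "sample_rate_hz": fs,
        "seed": spec.seed,
    }
    truth = GroundTruth(
        theta_g=theta_g,
        jump_times=jt,
        jump_magnitudes=jm,
        will_correct=will_correct,
        rho_regime="high" if (spec.kappa > 0.2 if spec.fixation_mode == "scripted" else spec.S >= 0.5) else "low",
        seed=spec.seed,
    )
    return trace, trial, truth


def _lowpass_noise(rng: np.random.Generator, n: int, alpha: float = 0.05) -> np.ndarray:
    """Unit-variance AR(1)-smoothed Gaussian noise."""
    w = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = w[0]
    for i in range(1, n):
        out[i] = (1 - alpha) * out[i - 1] + alpha * w[i]
    sd = out.std()
    return out / sd if sd > 0 else out


def synth_calcium(
    heading: np.ndarray,
    theta_g: float,
    region: str = "PB",
    amplitude_law: str = "pfl2",
    noise_sd: float = 0.2,
    seed: int = 0,
    behavior_rate: float = 60.0,
    frame_rate: float = 7.0,
    amp_base: float = 0.5,
    amp_gain: float = 2.0,
    offset: float = 0.5,
    phase0: float = 0.0,
    phase_lag_s: float = 0.0,
):
    """Generate an ROI time series with a sinusoidal activity bump.

    The bump phase is locked to heading and moves *opposite* to the turning
    direction (phase = phase0 - heading).  ``amplitude_law`` controls the
    bump amplitude: "pfl2" = base + gain*(1 - cos(theta - theta_g))/2
    (minimal at the goal), "pfl3" the reverse (maximal at the goal),
    "constant" = base.  Values are produced directly in z-scored dF/F units
    with additive Gaussian noise (sd ``noise_sd``); a positive affine raw
    layer is attached for file round-trips.  Returns (RoiTimeSeries, GroundTruth).
    """
    rng = np.random.default_rng(seed)
    heading = np.asarray(heading, dtype=float)
    n_frames = int(np.floor((heading.size - 1) / behavior_rate * frame_rate)) + 1
    ft = np.arange(n_frames) / frame_rate
    idx = np.clip(np.round((ft - phase_lag_s) * behavior_rate).astype(int), 0, heading.size - 1)
    th = heading[idx]
    if region not in ROI_COUNTS:
        raise ValueError(f"unknown region {region!r}")
    n_roi = ROI_COUNTS[region]
    angles = roi_angles_deg(n_roi)

    err = wrap_deg(th - theta_g)
    if amplitude_law == "pfl2":
        amp = amp_base + amp_gain * (1.0 - np.cos(np.deg2rad(err))) / 2.0
    elif amplitude_law == "pfl3":
        amp = amp_base + amp_gain * (1.0 + np.cos(np.deg2rad(err))) / 2.0
    elif amplitude_law == "constant":
        amp = np.full(th.size, amp_base)
    else:
        raise ValueError(f"unknown amplitude law {amplitude_law!r}")
    phase = wrap_deg(phase0 - th)
    u = np.deg2rad(phase - 90.0)  # peak of sin(x - u) sits at u + 90
    x = np.deg2rad(angles)[:, None]
    z = amp[None, :] * np.sin(x - u[None, :]) + offset
    z = z + noise_sd * rng.standard_normal(z.shape)
    raw = 150.0 + 40.0 * z  # positive raw-fluorescence layer for io round-trips
    series = RoiTimeSeries(region=region, values=raw, frame_rate=frame_rate)
    series.zscored = z
    truth = GroundTruth(
        bump_amplitude=amp,
        bump_phase=phase,
        amplitude_range=float(amp.max() - amp.min()),
        theta_g=np.full(th.size, theta_g),
        seed=seed,
    )
    return series, truth


def synth_vm(
    heading: np.ndarray,
    theta_p: float,
    tuning_amplitude: float = 10.0,
    ipsp_rate_law: str = "cosine",
    seed: int = 0,
    behavior_rate: float = 60.0,
    sample_rate: float = 1000.0,
    rest_mv: float = -55.0,
    goal_bias_mv: float = 0.0,
    noise_sd_mv: float = 0.0,
    ipsp_rate_hz: float = 8.0,
    ipsp_tau_s: float = 0.015,
    ipsp_amp_range_mv: tuple = (0.5, 2.0),
    spike_rate_max_hz: float = 0.0,
):
    """Generate a 1 kHz membrane-potential trace with cosine head-direction
    tuning, optional IPSP bombardment and spikes.

    vm = rest + (tuning_amplitude/2) * cos(theta - theta_p) + goal bias
    + IPSP kernels + noise.  IPSPs are an inhomogeneous Poisson train
    ("cosine": rate = rate_hz * (1 + cos(theta - theta_p)); "uniform":
    constant; "none") with an instantaneous-drop, exponential-recovery
    kernel (tau 15 ms, amplitudes uniform in ``ipsp_amp_range_mv``).
    Spikes (if ``spike_rate_max_hz`` > 0) are Poisson with a rate that is a
    softplus function of the subthreshold depolarization, rendered as brief
    2 ms depolarizing templates.  Returns (VmTrace-compatible dict fields,
    GroundTruth) as ``(time, vm, truth)``.
    """
    from .ephys import VmTrace

    rng = np.random.default_rng(seed)
    heading = np.asarray(heading, dtype=float)
    dur = (heading.size - 1) / behavior_rate
    n = int(round(dur * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    th = heading[np.clip(np.round(t * behavior_rate).astype(int), 0, heading.size - 1)]
    tune = (tuning_amplitude / 2.0) * np.cos(np.deg2rad(th - theta_p))
    vm = rest_mv + tune + goal_bias_mv

    if ipsp_rate_law == "cosine":
        rate = ipsp_rate_hz * (1.0 + np.cos(np.deg2rad(th - theta_p)))
    elif ipsp_rate_law == "uniform":
        rate = np.full(n, ipsp_rate_hz)
    elif ipsp_rate_law == "none":
        rate = np.zeros(n)
    else:
        raise ValueError(f"unknown IPSP rate law {ipsp_rate_law!r}")
    p_event = rate / sample_rate
    events = np.flatnonzero(rng.random(n) < p_event)
    # enforce a refractory spacing slightly above the detector's 20 ms
    kept = []
    last = -np.inf
    for e in events:
        if (e - last) / sample_rate >= 0.025:
            kept.append(e)
            last = e
    events = np.asarray(kept, dtype=int)
    kernel_len = int(round(8 * ipsp_tau_s * sample_rate))
    kernel_t = np.arange(kernel_len) / sample_rate
    base_kernel = -np.exp(-kernel_t / ipsp_tau_s)
    for e in events:
        a = rng.uniform(*ipsp_amp_range_mv)
        stop = min(n, e + kernel_len)
        vm[e:stop] += a * base_kernel[: stop - e]

    spike_times = np.array([])
    if spike_rate_max_hz > 0:
        drive = (vm - rest_mv) / max(tuning_amplitude / 2.0, 1e-9)
        srate = spike_rate_max_hz * np.log1p(np.exp(2.0 * drive)) / np.log1p(np.e ** 2.0)
        sp = np.flatnonzero(rng.random(n) < srate / sample_rate)
        sp = sp[np.concatenate([[True], np.diff(sp) > int(0.005 * sample_rate)])] if sp.size else sp
        for s in sp:
            stop = min(n, s + 2)
            vm[s:stop] += np.array([30.0, 10.0])[: stop - s]
        spike_times = sp / sample_rate

    if noise_sd_mv > 0:
        vm = vm + noise_sd_mv * rng.standard_normal(n)

    trace = VmTrace(time=t, vm=vm, sample_rate=sample_rate)
    truth = GroundTruth(
        ipsp_times=events / sample_rate,
        spike_times=spike_times,
        theta_p=theta_p,
        seed=seed,
    )
    return trace, truth
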