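"""Trial file formats, validation and the batch pipeline runner.

All time series are CSV with units encoded in the headers (``_deg``,
``_mm_s``, ``_deg_s``, ``_mV``, ``_s``); all metadata is JSON.  A trial
directory holds a ``trial.json`` descriptor plus the channel CSVs it
declares; generated trials also carry ``ground_truth.json``.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import KinematicsTrace

__all__ = [
    "SCHEMA_VERSION",
    "FormatError",
    "AlignmentError",
    "TrialDescriptor",
    "write_trial",
    "read_trial",
    "run_pipeline",
    "PIPELINE_STAGES",
]

SCHEMA_VERSION = 1

KINEMATICS_COLUMNS = [
    "time_s",
    "forward_mm_s",
    "sideways_mm_s",
    "rotational_deg_s",
    "cumulative_speed_rad_s",
    "heading_deg",
    "cue_deg",
]


class FormatError(ValueError):
    """A file does not match its declared schema."""


class AlignmentError(ValueError):
    """Channel lengths or sample rates disagree with the descriptor."""


@dataclass
class TrialDescriptor:
    trial_id: str
    jump_times_s: list
    jump_magnitudes_deg: list
    arena: dict
    channels: dict  # name -> {"file":..., "rate_hz":..., "n_rows":..., ...}
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialDescriptor":
        required = ["trial_id", "jump_times_s", "jump_magnitudes_deg", "arena", "channels"]
        for k in required:
            if k not in d:
                raise FormatError(f"trial descriptor missing field '{k}'")
        if not isinstance(d["arena"], dict) or "yaw_gain" not in d["arena"]:
            raise FormatError("trial descriptor missing field 'arena.yaw_gain'")
        return cls(
            trial_id=d["trial_id"],
            jump_times_s=list(d["jump_times_s"]),
            jump_magnitudes_deg=list(d["jump_magnitudes_deg"]),
            arena=d["arena"],
            channels=d["channels"],
            seed=int(d.get("seed", 0)),
            schema_version=int(d.get("schema_version", SCHEMA_VERSION)),
        )


def write_trial(
    outdir,
    trial: dict,
    trace: KinematicsTrace | None = None,
    roi: dict | None = None,
    vm=None,
    truth=None,
) -> Path:
    """Write a trial directory (kinematics, ROI and Vm CSVs + JSON metadata)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    channels: dict = {}
    if trace is not None:
        cue = -trace.heading if trace.heading is not None else np.full(len(trace), np.nan)
        df = pd.DataFrame(
            {
                "time_s": trace.time,
                "forward_mm_s": trace.forward,
                "sideways_mm_s": trace.sideways,
                "rotational_deg_s": trace.rotational,
                "cumulative_speed_rad_s": trace.cumulative_speed,
                "heading_deg": trace.heading
                if trace.heading is not None
                else np.full(len(trace), np.nan),
                "cue_deg": cue,
            }
        )
        df.to_csv(out / "kinematics.csv", index=False)
        channels["kinematics"] = {
            "file": "kinematics.csv",
            "rate_hz": trace.sample_rate,
            "n_rows": len(df),
        }
    for region, series in (roi or {}).items():
        name = f"roi_{region.lower()}.csv"
        cols = {"time_s": series.time}
        layer = series.zscored if series.zscored is not None else series.values
        for i in range(series.n_rois):
            cols[f"roi_{i + 1:02d}"] = layer[i]
        pd.DataFrame(cols).to_csv(out / name, index=False)
        channels[f"roi_{region.lower()}"] = {
            "file": name,
            "rate_hz": series.frame_rate,
            "n_rois": series.n_rois,
            "n_rows": layer.shape[1],
            "layer": "zscored" if series.zscored is not None else "raw",
        }
    if vm is not None:
        pd.DataFrame({"time_s": vm.time, "vm_mV": vm.vm}).to_csv(out / "vm.csv", index=False)
        channels["vm"] = {"file": "vm.csv", "rate_hz": vm.sample_rate, "n_rows": len(vm.vm)}
    desc = dict(trial)
    desc.setdefault("schema_version", SCHEMA_VERSION)
    desc["channels"] = channels
    (out / "trial.json").write_text(json.dumps(desc, indent=2))
    if truth is not None:
        payload = truth.to_jsonable() if hasattr(truth, "to_jsonable") else truth
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    return out


def read_trial(path) -> dict:
    """Load and validate a trial directory.

    Returns {"descriptor": TrialDescriptor, "kinematics": DataFrame | None,
    "roi": {region: DataFrame}, "vm": DataFrame | None}.  Raises
    :class:`FormatError` naming the offending field/column and
    :class:`AlignmentError` on declared-vs-actual length mismatches.
    """
    p = Path(path)
    trial_json = p / "trial.json" if p.is_dir() else p
    base = trial_json.parent
    try:
        desc_raw = json.loads(trial_json.read_text())
    except FileNotFoundError:
        raise FormatError(f"missing trial descriptor {trial_json}")
    desc = TrialDescriptor.from_dict(desc_raw)
    out: dict = {"descriptor": desc, "kinematics": None, "roi": {}, "vm": None}
    for name, ch in desc.channels.items():
        df = pd.read_csv(base / ch["file"])
        if "n_rows" in ch and len(df) != ch["n_rows"]:
            raise AlignmentError(
                f"channel '{name}': descriptor declares {ch['n_rows']} rows, file has {len(df)}"
            )
        if name == "kinematics":
            for col in KINEMATICS_COLUMNS:
                if col not in df.columns:
                    raise FormatError(f"kinematics file missing column '{col}'")
            out["kinematics"] = df
        elif name.startswith("roi_"):
            expected = [f"roi_{i + 1:02d}" for i in range(ch["n_rois"])]
            for col in ["time_s"] + expected:
                if col not in df.columns:
                    raise FormatError(f"{name} file missing column '{col}'")
            out["roi"][name[4:].upper()] = df
        elif name == "vm":
            for col in ("time_s", "vm_mV"):
                if col not in df.columns:
                    raise FormatError(f"vm file missing column '{col}'")
            out["vm"] = df
    return out


PIPELINE_STAGES = ("synth", "behavior", "imaging", "ephys")


def run_pipeline(config: dict, outdir, dry_run: bool = False) -> Path:
    """Run the configured analysis stages over a trial directory.

    ``config`` keys: ``stages`` (subset of synth/behavior/imaging/ephys),
    ``seed``, ``trial_dir`` (input; created by the synth stage when absent)
    and optional stage parameter overrides.  Writes per-stage CSV outputs, a
    ``manifest.json`` (package version, config hash, seeds) and a
    ``pipeline.log`` with per-stage timing and exclusion counts.  Outputs
    are deterministic for a given config.
    """
    from . import behavior as B
    from . import imaging as IM
    from . import ephys as E
    from . import synth as SY

    stages = list(config.get("stages", ("behavior",)))
    for st in stages:
        if st not in PIPELINE_STAGES:
            raise ValueError(f"unknown stage '{st}'; valid stages: {', '.join(PIPELINE_STAGES)}")
    out = Path(outdir)
    if dry_run:
        if "trial_dir" in config:
            read_trial(config["trial_dir"])
        return out
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{_time.strftime('%H:%M:%S')}] {msg}")

    trial_dir = config.get("trial_dir")
    try:
        if "synth" in stages:
            t0 = _time.perf_counter()
            spec = SY.SynthTrialSpec(seed=seed, **config.get("synth", {}))
            trace, trial, truth = SY.synth_behavior(spec)
            roi = {}
            if config.get("synth_calcium", True):
                series, _ct = SY.synth_calcium(
                    trace.heading, float(truth.theta_g[0]), seed=seed + 1
                )
                roi["PB"] = series
            vm = None
            if config.get("synth_vm", False):
                vm, _vt = SY.synth_vm(trace.heading, theta_p=40.0, seed=seed + 2)
            trial_dir = out / "trial"
            write_trial(trial_dir, trial, trace=trace, roi=roi, vm=vm, truth=truth)
            log(f"synth: wrote {trial_dir} in {_time.perf_counter() - t0:.2f}s")
        if trial_dir is None:
            raise ValueError("no trial_dir configured and no synth stage requested")
        data = read_trial(trial_dir)
        desc = data["descriptor"]
        kin = data["kinematics"]
        fs = desc.channels["kinematics"]["rate_hz"] if kin is not None else 60.0

        if "behavior" in stages:
            t0 = _time.perf_counter()
            heading = kin["heading_deg"].to_numpy()
            speed = kin["cumulative_speed_rad_s"].to_numpy()
            theta_g, rho = B.sliding_goal_consistency(
                heading, speed, fs, jump_times=np.asarray(desc.jump_times_s)
            )
            segs = B.segment_path(rho, heading, speed, fs)
            seg_df = pd.DataFrame(
                [
                    {
                        "start_idx": s.start_idx,
                        "end_idx": s.end_idx,
                        "theta_g_deg": s.theta_g,
                        "rho": s.rho,
                        "valid": s.valid,
                        "reason": s.reason,
                    }
                    for s in segs
                ]
            )
            seg_df.to_csv(out / "segments.csv", index=False)
            jumps = []
            for jt, jm in zip(desc.jump_times_s, desc.jump_magnitudes_deg):
                jp = B.classify_jump(heading, speed, rho, fs, B.JumpEvent(time=jt, magnitude=jm))
                jumps.append(jp.__dict__)
            jdf = pd.DataFrame(jumps)
            jdf.to_csv(out / "jumps.csv", index=False)
            n_excl = int(jdf["excluded"].sum()) if len(jdf) else 0
            log(
                f"behavior: {len(segs)} segments, {len(jumps)} jumps "
                f"({n_excl} excluded) in {_time.perf_counter() - t0:.2f}s"
            )
        if "imaging" in stages and data["roi"]:
            t0 = _time.perf_counter()
            for region, df in data["roi"].items():
                ch = desc.channels[f"roi_{region.lower()}"]
                z = df[[c for c in df.columns if c.startswith("roi_")]].to_numpy().T
                fits = IM.fit_bump_series(z)
                fits.insert(0, "time_s", df["time_s"])
                fits.to_csv(out / f"bump_fits_{region.lower()}.csv", index=False)
                if kin is not None and region in ("PB", "FB"):
                    frame_rate = ch["rate_hz"]
                    idx = np.clip(
                        np.round(df["time_s"].to_numpy() * fs).astype(int), 0, len(kin) - 1
                    )
                    th = kin["heading_deg"].to_numpy()[idx]
                    goal = IM.infer_goal_from_amplitude(fits["amplitude"].to_numpy(), th)
                    prof = IM.error_binned_profiles(z, th, goal.theta_g)
                    prof.to_csv(out / f"error_profiles_{region.lower()}.csv")
                    (out / f"goal_{region.lower()}.json").write_text(
                        json.dumps(
                            {
                                "theta_g_neural_deg": goal.theta_g,
                                "amplitude_range": goal.amplitude_range,
                                "reliable": goal.reliable,
                            },
                            indent=2,
                        )
                    )
            log(f"imaging: {len(data['roi'])} region(s) in {_time.perf_counter() - t0:.2f}s")
        if "ephys" in stages and data["vm"] is not None:
            t0 = _time.perf_counter()
            vm = data["vm"]["vm_mV"].to_numpy()
            vfs = desc.channels["vm"]["rate_hz"]
            base = E.baseline_vm(vm, vfs)
            spike_times, rate = E.detect_spikes(vm, vfs)
            if kin is not None:
                idx = np.clip(
                    np.round(data["vm"]["time_s"].to_numpy() * fs).astype(int), 0, len(kin) - 1
                )
                th = kin["heading_deg"].to_numpy()[idx]
                tc = E.preferred_direction_tuning(base, th)
                pd.DataFrame(
                    {
                        "bin_center_deg": tc.bin_centers,
                        "mean_mV": tc.values,
                        "n": tc.n_per_bin,
                    }
                ).to_csv(out / "vm_tuning.csv", index=False)
                (out / "ephys_summary.json").write_text(
                    json.dumps(
                        {
                            "theta_p_deg": tc.preferred,
                            "tuning_amplitude_mV": tc.amplitude,
                            "n_spikes": int(len(spike_times)),
                        },
                        indent=2,
                    )
                )
            log(f"ephys: {len(spike_times)} spikes in {_time.perf_counter() - t0:.2f}s")
    except Exception:
        (out / "FAILED").write_text("pipeline stage failed; partial results preserved\n")
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        raise
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config_hash": cfg_hash,
                "seed": seed,
                "stages": stages,
                "config": {k: v for k, v in config.items() if k != "trial_dir"}
                | {"trial_dir": str(trial_dir)},
            },
            indent=2,
            default=str,
        )
    )
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return out
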