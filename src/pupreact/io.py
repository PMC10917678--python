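"""File interchange: CSV trial tables and trajectories, TIFF stacks.

Formats follow the lab-bench conventions the assays produce: one CSV row
per trial or per video frame, multi-page grayscale TIFF for videos,
multi-channel TIFF with a JSON sidecar (voxel sizes, channel names) for
confocal stacks.  Output directories carry a manifest recording the
generating spec hash and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .arena import ArenaGeometry, Trajectory
from .ppi import StartleSession, StartleTrial
from .puncta import ConfocalStack
from .reactivity import PuffSession, PuffTrial
from .tracking import FrameStack, TimeSeriesTrace


# ---- traces ---------------------------------------------------------------

def write_trace_csv(trace: TimeSeriesTrace, path: str | Path) -> None:
    df = pd.DataFrame({
        "frame_index": np.arange(trace.values.size),
        "time_s": np.arange(trace.values.size) / trace.sampling_rate,
        f"displacement_{trace.units}": trace.values,
        "valid": trace.valid.astype(int)})
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path, sampling_rate: float,
                   onset_index: int, units: str = "px") -> TimeSeriesTrace:
    df = pd.read_csv(path)
    col = next(c for c in df.columns if c.startswith("displacement"))
    return TimeSeriesTrace(values=df[col].to_numpy(),
                           sampling_rate=sampling_rate,
                           onset_index=onset_index, units=units,
                           valid=df["valid"].to_numpy().astype(bool))


# ---- air-puff trial tables ------------------------------------------------

def puff_sessions_to_frame(sessions: list[PuffSession]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for phase, trials in (("ramp", s.ramp_trials),
                              ("repeated", s.repeated_trials)):
            for k, t in enumerate(trials):
                rows.append({"animal": s.animal_id, "genotype": s.genotype,
                             "phase": phase, "trial_index": k,
                             "intensity_psi": t.intensity, "peak_px": t.peak,
                             "baseline_px": t.baseline_movement,
                             "fell_over": int(t.fell_over)})
    return pd.DataFrame(rows)


def write_puff_csv(sessions: list[PuffSession], path: str | Path) -> None:
    puff_sessions_to_frame(sessions).to_csv(path, index=False)


def read_puff_csv(path: str | Path, **session_kwargs) -> list[PuffSession]:
    df = pd.read_csv(path)
    sessions = []
    for (animal, genotype), sub in df.groupby(["animal", "genotype"], sort=False):
        def trials(phase: str) -> list[PuffTrial]:
            p = sub[sub.phase == phase].sort_values("trial_index")
            return [PuffTrial(intensity=r.intensity_psi, peak=r.peak_px,
                              baseline_movement=r.baseline_px,
                              fell_over=bool(r.fell_over))
                    for r in p.itertuples()]
        sessions.append(PuffSession(animal_id=str(animal),
                                    genotype=str(genotype),
                                    ramp_trials=trials("ramp"),
                                    repeated_trials=trials("repeated"),
                                    **session_kwargs))
    return sessions


# ---- startle trial tables -------------------------------------------------

def write_startle_csv(sessions: list[StartleSession], path: str | Path) -> None:
    rows = [{"animal": s.animal_id, "genotype": s.genotype,
             "trial_type": t.trial_type, "isi_ms": t.isi_ms,
             "response_mv": t.response, "block": t.block}
            for s in sessions for t in s.trials]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_startle_csv(path: str | Path) -> list[StartleSession]:
    df = pd.read_csv(path)
    out = []
    for (animal, genotype), sub in df.groupby(["animal", "genotype"], sort=False):
        trials = [StartleTrial(trial_type=r.trial_type,
                               response=r.response_mv,
                               isi_ms=None if pd.isna(r.isi_ms) else r.isi_ms,
                               block=r.block)
                  for r in sub.itertuples()]
        out.append(StartleSession(animal_id=str(animal),
                                  genotype=str(genotype), trials=trials))
    return out


# ---- trajectories ---------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"time_s": traj.t, "x_cm": traj.x,
                  "y_cm": traj.y}).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, frame_rate: float,
                        arena: ArenaGeometry) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(t=df["time_s"].to_numpy(), x=df["x_cm"].to_numpy(),
                      y=df["y_cm"].to_numpy(), frame_rate=frame_rate,
                      arena=arena)


def write_geometry_json(arena: ArenaGeometry, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(arena), indent=2))


def read_geometry_json(path: str | Path) -> ArenaGeometry:
    return ArenaGeometry(**json.loads(Path(path).read_text()))


# ---- videos and confocal stacks ------------------------------------------

def write_video_tiff(stack: FrameStack, path: str | Path) -> None:
    """Multi-page grayscale TIFF, frame axis first."""
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")


def read_video_tiff(path: str | Path, fps: float) -> FrameStack:
    return FrameStack(frames=tifffile.imread(path).astype(float), fps=fps)


def write_confocal_tiff(stack: ConfocalStack, path: str | Path) -> None:
    """Channel-first TIFF plus a JSON sidecar with names and voxel sizes."""
    path = Path(path)
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {"channels": names, "voxel_size_um": list(stack.voxel_size)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_confocal_tiff(path: str | Path) -> ConfocalStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    channels = {n: data[i] for i, n in enumerate(sidecar["channels"])}
    return ConfocalStack(channels=channels,
                         voxel_size=tuple(sidecar["voxel_size_um"]))


# ---- manifests ------------------------------------------------------------

def spec_hash(spec) -> str:
    """Stable hash of a generator spec dataclass."""
    payload = json.dumps(dataclasses.asdict(spec), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(directory: str | Path, spec) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"spec_type": type(spec).__name__,
                "spec_hash": spec_hash(spec),
                "seed": getattr(spec, "seed", None),
                "spec": dataclasses.asdict(spec)}
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, default=str))
    return out
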