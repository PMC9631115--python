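"""On-disk formats: session directories, Phy-style unit directories, SVD stores.

Sessions are written as a plain-text trial table (CSV) plus an NPZ file for
the wheel trace and a JSON sidecar with the delay grid and metadata, so
real task logs can be mapped onto the same schema.  Units use the NPY
layout produced by spike-sorting pipelines (one array per quantity).
Frame stacks go to multi-page TIFF with a JSON sidecar of frame times and
illumination labels; SVD components to HDF5.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import UnitRecord
from .synth.session import DelayGrid, SessionRecord, TrialRecord
from .wheel import WheelTrace
from .widefield import FrameStack, SVDComponents

__all__ = [
    "save_session",
    "load_session",
    "save_units",
    "load_units",
    "save_frame_stack",
    "load_frame_stack",
    "save_svd",
    "load_svd",
]


# ---------------------------------------------------------------------------
# sessions


def save_session(session: SessionRecord, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    session.trials_frame().to_csv(directory / "trials.csv", index=False)
    np.savez(
        directory / "wheel.npz",
        t0=session.wheel.t0,
        dt=session.wheel.dt,
        position=session.wheel.position,
        velocity=session.wheel.velocity,
    )
    sidecar = {
        "delay_grid": asdict(session.delay_grid),
        "movement_threshold": session.movement_threshold,
        "metadata": session.metadata,
    }
    (directory / "session.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_session(directory) -> SessionRecord:
    directory = Path(directory)
    trials_df = pd.read_csv(directory / "trials.csv")
    wheel_npz = np.load(directory / "wheel.npz")
    sidecar = json.loads((directory / "session.json").read_text())
    wheel = WheelTrace(
        t0=float(wheel_npz["t0"]),
        dt=float(wheel_npz["dt"]),
        position=wheel_npz["position"],
        velocity=wheel_npz["velocity"],
    )
    trials = [
        TrialRecord(
            index=int(row["index"]),
            prev_outcome_time=float(row["prev_outcome_time"]),
            iti=float(row["iti"]),
            quiescence=float(row["quiescence"]),
            stim_onset=float(row["stim_onset"]),
            first_move=float(row["first_move"]),
            outcome=str(row["outcome"]),
        )
        for _, row in trials_df.iterrows()
    ]
    return SessionRecord(
        trials=trials,
        wheel=wheel,
        delay_grid=DelayGrid(**sidecar["delay_grid"]),
        movement_threshold=float(sidecar["movement_threshold"]),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# units (Phy-style directory)


def save_units(units: list[UnitRecord], directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spike_times = np.concatenate([u.spike_times for u in units]) if units else np.empty(0)
    clusters = (
        np.concatenate([np.full(u.spike_times.size, u.unit_id) for u in units])
        if units
        else np.empty(0, dtype=int)
    )
    amplitudes = np.concatenate([u.amplitudes for u in units]) if units else np.empty(0)
    order = np.argsort(spike_times, kind="stable")
    np.save(directory / "spike_times.npy", spike_times[order])
    np.save(directory / "spike_clusters.npy", clusters[order].astype(np.int64))
    np.save(directory / "amplitudes.npy", amplitudes[order])
    np.save(directory / "templates.npy", np.stack([u.template for u in units]))
    np.save(directory / "peak_channels.npy", np.array([u.peak_channel for u in units]))
    np.save(directory / "channel_positions.npy", units[0].channel_positions)
    np.save(directory / "cluster_ids.npy", np.array([u.unit_id for u in units]))
    (directory / "params.json").write_text(
        json.dumps({"sample_rate": units[0].sample_rate})
    )
    return directory


def load_units(directory) -> list[UnitRecord]:
    directory = Path(directory)
    spike_times = np.load(directory / "spike_times.npy")
    clusters = np.load(directory / "spike_clusters.npy")
    amplitudes = np.load(directory / "amplitudes.npy")
    templates = np.load(directory / "templates.npy")
    peak_channels = np.load(directory / "peak_channels.npy")
    positions = np.load(directory / "channel_positions.npy")
    cluster_ids = np.load(directory / "cluster_ids.npy")
    sample_rate = json.loads((directory / "params.json").read_text())["sample_rate"]
    units = []
    for i, cid in enumerate(cluster_ids):
        sel = clusters == cid
        units.append(
            UnitRecord(
                spike_times=spike_times[sel],
                amplitudes=amplitudes[sel],
                template=templates[i],
                sample_rate=sample_rate,
                peak_channel=int(peak_channels[i]),
                channel_positions=positions,
                unit_id=int(cid),
            )
        )
    return units


# ---------------------------------------------------------------------------
# frame stacks and SVD components


def save_frame_stack(stack: FrameStack, path) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))
    sidecar = {
        "frame_times": stack.frame_times.tolist(),
        "illumination": [str(x) for x in stack.illumination],
        "um_per_pixel": stack.um_per_pixel,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def load_frame_stack(path) -> FrameStack:
    import tifffile

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return FrameStack(
        frames=tifffile.imread(path),
        frame_times=np.array(sidecar["frame_times"]),
        illumination=np.array(sidecar["illumination"]),
        um_per_pixel=sidecar.get("um_per_pixel", 20.6),
    )


def save_svd(components: SVDComponents, path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("U", data=components.U)
        f.create_dataset("SV", data=components.sv)
        f.create_dataset("S", data=components.singular_values)
        if components.shape is not None:
            f.attrs["rows"], f.attrs["cols"] = components.shape
        if components.frame_times is not None:
            f.create_dataset("frame_times", data=components.frame_times)
    return path


def load_svd(path) -> SVDComponents:
    import h5py

    with h5py.File(path, "r") as f:
        shape = (int(f.attrs["rows"]), int(f.attrs["cols"])) if "rows" in f.attrs else None
        frame_times = f["frame_times"][:] if "frame_times" in f else None
        return SVDComponents(
            U=f["U"][:],
            sv=f["SV"][:],
            singular_values=f["S"][:],
            shape=shape,
            frame_times=frame_times,
        )
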