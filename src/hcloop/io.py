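"""File formats consumed and produced by the analyses.

Neutral plain-text/TIFF formats only: sweeps as one-column CSV plus a JSON
sidecar with acquisition metadata, tracking logs and Barnes event logs as
CSV, object/arena layouts and ROI polygons as JSON (or YAML for configs),
presynaptic count tables as CSV, and single-channel TIFF images.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .anatomy import InputCountTable
from .behavior import BarnesLog, ObjectSpec, TrackingSession
from .ephys import StimulusEvent, Sweep

__all__ = [
    "write_sweep", "read_sweep",
    "write_tracking", "read_tracking",
    "write_objects", "read_objects",
    "write_barnes_log", "read_barnes_log",
    "write_input_counts", "read_input_counts",
    "write_image", "read_image",
    "write_polygons", "read_polygons",
    "load_config", "dump_config",
]


def write_sweep(sweep: Sweep, csv_path) -> None:
    """One sweep: samples as single-column CSV + JSON metadata sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"sample": sweep.samples}).to_csv(csv_path, index=False)
    meta = {
        "sampling_interval": sweep.sampling_interval,
        "clamp_mode": sweep.clamp_mode,
        "holding": sweep.holding,
        "stimulus": {
            "onset": sweep.stimulus.onset,
            "duration": sweep.stimulus.duration,
            "modality": sweep.stimulus.modality,
            "intensity": sweep.stimulus.intensity,
        },
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_sweep(csv_path) -> Sweep:
    csv_path = Path(csv_path)
    samples = pd.read_csv(csv_path)["sample"].to_numpy()
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    stim = StimulusEvent(**meta["stimulus"])
    return Sweep(
        samples=samples,
        stimulus=stim,
        sampling_interval=meta["sampling_interval"],
        clamp_mode=meta["clamp_mode"],
        holding=meta["holding"],
    )


def write_tracking(session: TrackingSession, path) -> None:
    pd.DataFrame(
        {"t": session.t, "x": session.x, "y": session.y, "heading": session.heading}
    ).to_csv(path, index=False)


def read_tracking(path, frame_rate: float = 20.0) -> TrackingSession:
    df = pd.read_csv(path)
    return TrackingSession(
        t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
        heading=df["heading"].to_numpy(), frame_rate=frame_rate,
    )


def write_objects(objects: list[ObjectSpec], path) -> None:
    payload = [
        {"id": o.id, "x": o.x, "y": o.y, "radius": o.radius, "status": o.status}
        for o in objects
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_objects(path) -> list[ObjectSpec]:
    return [ObjectSpec(**d) for d in json.loads(Path(path).read_text())]


def write_barnes_log(log: BarnesLog, path) -> None:
    pd.DataFrame(
        [{"t": t, "hole_id": h, "entered": e} for t, h, e in log.events]
    ).to_csv(path, index=False)


def read_barnes_log(path, escape_hole: int, trial_cap: float = 180.0) -> BarnesLog:
    df = pd.read_csv(path)
    events = [
        (float(r.t), int(r.hole_id), bool(r.entered)) for r in df.itertuples()
    ]
    return BarnesLog(events=events, escape_hole=escape_hole, trial_cap=trial_cap)


def write_input_counts(counts: dict, path, starter_region: str | None = None) -> None:
    df = pd.DataFrame({"region": list(counts), "count": list(counts.values())})
    df["is_starter_region"] = df["region"] == starter_region
    df.to_csv(path, index=False)


def read_input_counts(path) -> InputCountTable:
    df = pd.read_csv(path)
    starter = None
    if "is_starter_region" in df.columns and df["is_starter_region"].any():
        starter = str(df.loc[df["is_starter_region"], "region"].iloc[0])
    counts = dict(zip(df["region"], df["count"].astype(int)))
    return InputCountTable(counts=counts, starter_region=starter)


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_polygons(polygons: dict, path) -> None:
    payload = {k: np.asarray(v).tolist() for k, v in polygons.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_polygons(path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


def load_config(path) -> dict:
    """A YAML or JSON mapping of parameter overrides."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def dump_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, default=str))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
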