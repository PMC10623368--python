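"""File-format helpers: CSV traces/series, TIFF silhouettes, HDF5 geometry."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .synth import (
    BubbleGeometrySequence,
    GridSpec,
    HydrophoneTrace,
    LaserPulse,
    RadiusTimeSeries,
    SilhouetteImage,
)

__all__ = [
    "pulse_to_csv",
    "series_to_csv",
    "series_from_csv",
    "trace_to_csv",
    "trace_from_csv",
    "geometry_to_hdf5",
    "geometry_from_hdf5",
    "silhouette_to_tiff",
    "metrics_to_json",
]


def pulse_to_csv(pulse: LaserPulse, path: str | Path) -> None:
    pd.DataFrame({"time_s": pulse.times, "power_W": pulse.power}).to_csv(
        path, index=False
    )


def series_to_csv(series: RadiusTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": series.times, "Re_m": series.Re})
    df.to_csv(path, index=False)
    evpath = Path(path).with_suffix(".events.json")
    with open(evpath, "w") as fh:
        json.dump(series.events, fh, indent=2)


def series_from_csv(path: str | Path) -> RadiusTimeSeries:
    df = pd.read_csv(path)
    evpath = Path(path).with_suffix(".events.json")
    events = {}
    if evpath.exists():
        with open(evpath) as fh:
            events = json.load(fh)
    return RadiusTimeSeries(
        times=df["time_s"].to_numpy(), Re=df["Re_m"].to_numpy(), events=events
    )


def trace_to_csv(trace: HydrophoneTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "pressure_Pa": trace.pressure})
    df.attrs["sensor_distance_m"] = trace.sensor_distance
    df.to_csv(path, index=False)
    with open(Path(path).with_suffix(".meta.json"), "w") as fh:
        json.dump(
            {"sensor_distance_m": trace.sensor_distance, "noise_rms_Pa": trace.noise_rms},
            fh,
        )


def trace_from_csv(path: str | Path, sensor_distance: float | None = None) -> HydrophoneTrace:
    df = pd.read_csv(path)
    meta_path = Path(path).with_suffix(".meta.json")
    noise = 0.0
    if sensor_distance is None:
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = json.load(fh)
            sensor_distance = meta["sensor_distance_m"]
            noise = meta.get("noise_rms_Pa", 0.0)
        else:
            raise ValueError("sensor_distance required (no sidecar metadata found)")
    return HydrophoneTrace(
        times=df["time_s"].to_numpy(),
        pressure=df["pressure_Pa"].to_numpy(),
        sensor_distance=sensor_distance,
        noise_rms=noise,
    )


def geometry_to_hdf5(geom: BubbleGeometrySequence, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=geom.masks, compression="gzip")
        f.attrs["segment_duration_s"] = geom.segment_duration
        f.attrs["SD_m"] = geom.SD
        f.attrs["contact_segment"] = geom.contact_segment
        g = geom.grid
        f.attrs["grid"] = (g.nr, g.nz, g.dr, g.dz, g.z0)


def geometry_from_hdf5(path: str | Path) -> BubbleGeometrySequence:
    with h5py.File(path, "r") as f:
        masks = f["masks"][...]
        nr, nz, dr, dz, z0 = f.attrs["grid"]
        return BubbleGeometrySequence(
            segment_duration=float(f.attrs["segment_duration_s"]),
            masks=masks.astype(bool),
            grid=GridSpec(int(nr), int(nz), float(dr), float(dz), float(z0)),
            SD=float(f.attrs["SD_m"]),
            contact_segment=int(f.attrs["contact_segment"]),
        )


def silhouette_to_tiff(sil: SilhouetteImage, path: str | Path) -> None:
    tifffile.imwrite(path, sil.image.astype(np.float32))


def metrics_to_json(obj, path: str | Path) -> None:
    from dataclasses import asdict, is_dataclass

    def default(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
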