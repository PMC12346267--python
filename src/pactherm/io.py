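"""File formats: HDF5 RF containers, YAML configs, TIFF images, JSON tables.

The RF container layout is
    /rf            (n_elements, n_samples, n_frames) float
    /frame_time    (n_frames,) seconds-or-minutes timestamps
    /truth/delta_t (n_frames, rows, cols)   optional ground truth
with geometry and calibration stored as root attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import tifffile
import yaml

from .forward import RFFrame, RFSeries
from .geometry import build_geometry
from .phantom import GrueneisenCalibration

__all__ = [
    "write_rf_series",
    "read_rf_series",
    "write_image_tiff",
    "read_image_tiff",
    "load_config",
    "write_json",
]


def write_rf_series(path, series: RFSeries, calibration: GrueneisenCalibration | None = None,
                    truth_delta_t: np.ndarray | None = None,
                    truth_times: np.ndarray | None = None,
                    roi: np.ndarray | None = None) -> None:
    frames = series.frames
    if not frames:
        raise ValueError("empty RF series")
    geometry = frames[0].geometry
    rf = np.stack([f.samples for f in frames], axis=-1)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rf", data=rf, compression="gzip", compression_opts=4)
        fh.create_dataset("frame_time", data=np.asarray(series.frame_times))
        if geometry is not None:
            for key, val in geometry.to_dict().items():
                fh.attrs[f"geometry/{key}"] = val
        if calibration is not None:
            for key, val in calibration.to_dict().items():
                fh.attrs[f"calibration/{key}"] = val
        if truth_delta_t is not None:
            grp = fh.create_group("truth")
            grp.create_dataset("delta_t", data=np.asarray(truth_delta_t),
                               compression="gzip", compression_opts=4)
            if truth_times is not None:
                grp.create_dataset("times", data=np.asarray(truth_times))
            if roi is not None:
                grp.create_dataset("roi", data=np.asarray(roi, dtype=bool))


def read_rf_series(path):
    """Read an RF container; returns (RFSeries, calibration-or-None, truth dict)."""
    with h5py.File(path, "r") as fh:
        rf = fh["rf"][()]
        frame_time = fh["frame_time"][()]
        geo_keys = {k.split("/", 1)[1]: fh.attrs[k]
                    for k in fh.attrs if k.startswith("geometry/")}
        geometry = build_geometry(
            {k: (int(v) if k == "n_elements" else float(v))
             for k, v in geo_keys.items()}) if geo_keys else None
        cal_keys = {k.split("/", 1)[1]: float(fh.attrs[k])
                    for k in fh.attrs if k.startswith("calibration/")}
        calibration = GrueneisenCalibration(**cal_keys) if cal_keys else None
        truth = {}
        if "truth" in fh:
            grp = fh["truth"]
            truth["delta_t"] = grp["delta_t"][()]
            if "times" in grp:
                truth["times"] = grp["times"][()]
            if "roi" in grp:
                truth["roi"] = grp["roi"][()].astype(bool)
    frames = [RFFrame(samples=rf[:, :, j], frame_time=float(frame_time[j]),
                      geometry=geometry) for j in range(rf.shape[2])]
    return RFSeries(frames=frames, frame_times=frame_time), calibration, truth


def write_image_tiff(path, image) -> None:
    values = np.asarray(getattr(image, "values", image), dtype=np.float32)
    tifffile.imwrite(path, values)


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
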