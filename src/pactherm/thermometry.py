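"""Gruneisen-based photoacoustic thermometry and CEM43 thermal dosimetry.

The Gruneisen parameter of soft tissue is approximately linear in
temperature, so the fractional change of the photoacoustic amplitude at a
pixel tracks its temperature change:

    dp / p0 = dT / (T0 + c/b)     =>     dT = a * dp/p0,   a = T0 + c/b

with T0 the baseline temperature and b, c the empirical slope/intercept of
the Gamma(T) calibration line.  Absolute maps are obtained by adding the
core temperature (37 C in vivo, the bath temperature for phantoms).

Thermal dose is expressed as cumulative equivalent minutes at 43 C of the
ROI median temperature (CEM43T50): each reporting interval of length t at
median temperature T50_i contributes t * R**(43 - T50_i) equivalent
minutes, with R = 0.5 at or above 43 C and R = 0.25 below.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .phantom import GrueneisenCalibration

__all__ = [
    "ThermalSeries",
    "DoseReport",
    "thermal_coefficient",
    "relative_change_series",
    "temperature_series",
    "roi_metrics",
    "cem43t50",
]


@dataclass
class ThermalSeries:
    """Time-indexed stack of 2D temperature maps with an ROI mask.

    ``times`` are minutes relative to CW-laser switch-on; ``maps`` is an
    (n_frames, n_rows, n_cols) array of temperatures in degrees C (absolute
    or delta, recorded in ``absolute``); invalid pixels are NaN.
    """

    times: np.ndarray
    maps: np.ndarray
    roi: np.ndarray | None = None
    absolute: bool = True
    calibration: GrueneisenCalibration | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.maps = np.asarray(self.maps, dtype=float)
        if self.times.ndim != 1 or self.maps.ndim != 3:
            raise ValueError("times must be 1D and maps (n_frames, rows, cols)")
        if len(self.times) != len(self.maps):
            raise ValueError("times and maps lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != self.maps.shape[1:]:
                raise ValueError("roi shape does not match maps")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DoseReport:
    """CEM43T50 thermal-dose summary over the heating period."""

    interval: float
    n_intervals: int
    t50_series: np.ndarray
    tavg_series: np.ndarray | None
    cem43t50: float
    R_above: float = 0.5
    R_below: float = 0.25

    def to_dict(self) -> dict:
        return {
            "interval_min": self.interval,
            "n_intervals": self.n_intervals,
            "t50_series": np.asarray(self.t50_series).tolist(),
            "tavg_series": (None if self.tavg_series is None
                            else np.asarray(self.tavg_series).tolist()),
            "R_above": self.R_above,
            "R_below": self.R_below,
            "cem43t50_min": self.cem43t50,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def thermal_coefficient(calib: GrueneisenCalibration) -> float:
    """Thermometry coefficient a = T0 + c/b in degrees C."""
    a = calib.T0 + calib.c_over_b
    if a <= 0:
        raise ValueError("T0 + c_over_b must be positive")
    return a


def _as_stack(frames) -> np.ndarray:
    arrs = [np.asarray(getattr(f, "values", f), dtype=float) for f in frames]
    return np.stack(arrs, axis=0)


def relative_change_series(frames, baseline_window, roi: np.ndarray | None = None,
                           floor_fraction: float = 0.05) -> np.ndarray:
    """Per-pixel relative amplitude change (frame - p0) / p0.

    ``frames`` is a sequence of registered amplitude images (arrays or
    objects with ``.values``); ``baseline_window`` is an index range (slice
    or iterable) of frames acquired before heating, averaged into the
    reference map p0.  Pixels whose baseline amplitude falls below
    ``floor_fraction`` of the ROI's median baseline amplitude (the whole
    image's when no ROI is supplied) are set to NaN — the division by p0 is
    unreliable there.
    """
    stack = _as_stack(frames)
    idx = np.arange(len(stack))[baseline_window]
    if len(idx) == 0:
        raise ValueError("baseline_window selects no frames")
    p0 = stack[idx].mean(axis=0)
    ref = p0[roi] if roi is not None else p0
    ref = ref[ref > 0]
    if ref.size == 0:
        raise ValueError("baseline amplitude is zero everywhere in the reference region")
    floor = floor_fraction * float(np.median(ref))
    invalid = p0 < floor
    if invalid.all():
        raise ValueError("all pixels fall below the baseline validity floor")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (stack - p0[None]) / p0[None]
    rel[:, invalid] = np.nan
    return rel


def temperature_series(rel: np.ndarray, times, calib: GrueneisenCalibration,
                       core_temperature: float | None = None,
                       roi: np.ndarray | None = None) -> ThermalSeries:
    """Convert a dp/p0 stack to temperature maps.

    dT = a * dp/p0 with a = T0 + c/b; when ``core_temperature`` is given
    the maps are absolute (dT + core), otherwise they remain temperature
    changes.  Invalid (NaN) pixels propagate.
    """
    a = thermal_coefficient(calib)
    maps = a * np.asarray(rel, dtype=float)
    absolute = core_temperature is not None
    if absolute:
        maps = maps + core_temperature
    return ThermalSeries(times=np.asarray(times, dtype=float), maps=maps,
                         roi=roi, absolute=absolute, calibration=calib)


def roi_metrics(series: ThermalSeries, interval: float = 1.0,
                start: float | None = None,
                duration: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval mean (T_avg) and median (T50) ROI temperature.

    Frames are binned into consecutive intervals of ``interval`` minutes
    starting at ``start`` (default: the first frame time); within each bin
    all ROI pixels of all frames are pooled, NaNs excluded.  A series
    shorter than one interval yields a single bin.  Returns
    ``(tavg_series, t50_series)``.
    """
    if series.roi is None or not series.roi.any():
        raise ValueError("series has no (nonempty) ROI mask")
    if interval <= 0:
        raise ValueError("interval must be positive")
    t = series.times
    lo = t[0] if start is None else start
    hi = t[-1] if duration is None else lo + duration
    span = hi - lo
    n_bins = max(1, int(np.floor(span / interval + 1e-9)))
    tavg = np.full(n_bins, np.nan)
    t50 = np.full(n_bins, np.nan)
    for i in range(n_bins):
        in_bin = (t >= lo + i * interval) & (t < lo + (i + 1) * interval)
        if i == n_bins - 1:  # close the last bin
            in_bin |= np.isclose(t, lo + (i + 1) * interval)
        if not in_bin.any():
            continue
        pool = series.maps[in_bin][:, series.roi].ravel()
        pool = pool[np.isfinite(pool)]
        if pool.size:
            tavg[i] = pool.mean()
            t50[i] = np.median(pool)
    return tavg, t50


def cem43t50(t50_series, interval: float = 1.0,
             tavg_series=None) -> DoseReport:
    """Cumulative equivalent minutes at 43 C of the per-interval T50.

    CEM43T50 = sum_i interval * R**(43 - T50_i), with R = 0.5 when
    T50_i >= 43 C and R = 0.25 below (the standard CEM43 convention).
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    t50 = np.asarray(t50_series, dtype=float)
    R = np.where(t50 >= 43.0, 0.5, 0.25)
    terms = interval * R ** (43.0 - t50)
    dose = float(np.nansum(terms))
    return DoseReport(interval=interval, n_intervals=len(t50),
                      t50_series=t50,
                      tavg_series=None if tavg_series is None else np.asarray(tavg_series, float),
                      cem43t50=dose)
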