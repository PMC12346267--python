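"""Digital absorption phantoms and Gruneisen calibration constants.

An :class:`AbsorptionMap` stores the specific optical absorption A_e on a
2D pixel grid; the initial photoacoustic pressure is p0 = Gamma0 * eta_th *
A_e, where the Gruneisen parameter Gamma0 is linear in baseline temperature
(Gamma0 = b*T0 + c with empirical constants b and c).  Only the ratio
c/b enters the thermometry, so the calibration carries T0 and c/b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ReconGrid, RingArrayGeometry

__all__ = ["AbsorptionMap", "GrueneisenCalibration", "make_phantom",
           "PHANTOM_CALIBRATION", "TISSUE_CALIBRATION"]


@dataclass(frozen=True)
class GrueneisenCalibration:
    """Linear Gruneisen-vs-temperature calibration.

    ``c_over_b`` is the ratio of the empirical intercept and slope of the
    Gamma0(T0) line; the thermometry coefficient is ``a = T0 + c_over_b``
    (degrees C).  ``eta_th`` is the thermal-conversion fraction.
    """

    T0: float
    c_over_b: float
    eta_th: float = 1.0

    def __post_init__(self) -> None:
        if self.T0 + self.c_over_b <= 0:
            raise ValueError("T0 + c_over_b must be positive (Gamma0 > 0 at baseline)")
        if not (0.0 < self.eta_th <= 1.0):
            raise ValueError("eta_th must lie in (0, 1]")

    @property
    def coefficient(self) -> float:
        """Thermometry coefficient a = T0 + c/b in degrees C."""
        return self.T0 + self.c_over_b

    def to_dict(self) -> dict:
        return {"T0": self.T0, "c_over_b": self.c_over_b, "eta_th": self.eta_th}


#: Calibration for agar/water phantoms (water-bath baseline 22 C).
PHANTOM_CALIBRATION = GrueneisenCalibration(T0=22.0, c_over_b=2.75)
#: Calibration for soft tissue (body-core baseline 37 C).
TISSUE_CALIBRATION = GrueneisenCalibration(T0=37.0, c_over_b=13.14)


@dataclass
class AbsorptionMap:
    """Specific optical absorption on a reconstruction grid.

    ``grid`` holds per-pixel A_e values (arbitrary energy-density units,
    nonnegative); ``masks`` records the named boolean footprint of each
    phantom primitive (e.g. ``"tumor"``).
    """

    values: np.ndarray
    grid: ReconGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("absorption values must be nonnegative")

    def check_inside_ring(self, geometry: RingArrayGeometry) -> None:
        self.grid.check_inside_ring(geometry)


def _disk_mask(grid: ReconGrid, center: tuple[float, float], radius: float,
               radius_y: float | None = None, angle_deg: float = 0.0) -> np.ndarray:
    xx, yy = grid.pixel_coords()
    dx, dy = xx - center[0], yy - center[1]
    if radius_y is None:
        return dx * dx + dy * dy <= radius * radius
    th = np.deg2rad(angle_deg)
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    return (u / radius) ** 2 + (v / radius_y) ** 2 <= 1.0


def make_phantom(primitives: list[dict], grid: ReconGrid,
                 geometry: RingArrayGeometry | None = None) -> AbsorptionMap:
    """Rasterise disk/ellipse primitives into an absorption map.

    Each primitive is a mapping with keys ``kind`` ("disk" or "ellipse"),
    ``center`` (x, y in mm), ``radius`` (mm; ellipses add ``radius_y`` and
    optional ``angle_deg``), ``amplitude`` (A_e, >= 0) and optional ``name``.
    Overlapping primitives add.  When ``geometry`` is given, every primitive
    must fit inside the detection ring.
    """
    values = np.zeros(grid.shape, dtype=float)
    masks: dict[str, np.ndarray] = {}
    for i, prim in enumerate(primitives):
        kind = prim.get("kind", "disk")
        if kind not in ("disk", "ellipse"):
            raise ValueError(f"unknown primitive kind {kind!r}")
        cx, cy = prim["center"]
        r = float(prim["radius"])
        ry = float(prim.get("radius_y", r)) if kind == "ellipse" else None
        amp = float(prim["amplitude"])
        if amp < 0:
            raise ValueError("primitive amplitude must be nonnegative")
        if r <= 0 or (ry is not None and ry <= 0):
            raise ValueError("primitive radius must be positive")
        if geometry is not None:
            reach = np.hypot(cx, cy) + max(r, ry or r)
            if reach >= geometry.ring_radius:
                raise ValueError(
                    f"primitive {prim.get('name', i)} reaches radius {reach:.2f} mm, "
                    f"outside the {geometry.ring_radius:.2f}-mm ring"
                )
        mask = _disk_mask(grid, (cx, cy), r, ry, float(prim.get("angle_deg", 0.0)))
        values[mask] += amp
        masks[str(prim.get("name", f"primitive_{i}"))] = mask
    return AbsorptionMap(values=values, grid=grid, masks=masks)
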