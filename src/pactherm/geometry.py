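"""Ring-array transducer geometry and reconstruction grids.

The imaging instrument modelled here is a full-view ring array: elements
spaced uniformly on a circle, each recording a time series of acoustic
pressure after a laser pulse.  World coordinates are in millimetres with the
ring centre at the origin; time is in microseconds; frequencies in MHz
(so sampling rates are in mega-samples per second).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RingArrayGeometry", "ReconGrid", "build_geometry", "build_grid"]


@dataclass(frozen=True)
class RingArrayGeometry:
    """Uniform circular transducer array.

    Parameters
    ----------
    ring_radius:
        Radius of the detection circle in mm.
    n_elements:
        Number of transducer elements, spaced uniformly by ``2*pi/n``.
    center_frequency:
        Element centre frequency in MHz.
    fractional_bandwidth:
        -6 dB fractional bandwidth of the element impulse response.
    sampling_rate:
        Digitiser rate in MS/s.
    speed_of_sound:
        Assumed homogeneous speed of sound in mm/us.
    """

    ring_radius: float = 40.0
    n_elements: int = 512
    center_frequency: float = 5.0
    fractional_bandwidth: float = 0.7
    sampling_rate: float = 40.0
    speed_of_sound: float = 1.50

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise ValueError(f"ring_radius must be positive, got {self.ring_radius}")
        if self.n_elements < 1:
            raise ValueError(f"n_elements must be >= 1, got {self.n_elements}")
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")
        f_max = self.center_frequency * (1.0 + self.fractional_bandwidth / 2.0)
        if self.sampling_rate <= 2.0 * f_max:
            raise ValueError(
                "Nyquist violation: sampling_rate "
                f"{self.sampling_rate} MS/s must exceed twice the maximum signal "
                f"frequency {f_max} MHz (center_frequency {self.center_frequency} MHz, "
                f"fractional_bandwidth {self.fractional_bandwidth})"
            )

    @property
    def element_angles(self) -> np.ndarray:
        """Angular element positions (radians), strictly increasing from 0."""
        return 2.0 * np.pi * np.arange(self.n_elements) / self.n_elements

    @property
    def element_positions(self) -> np.ndarray:
        """(n_elements, 2) array of element (x, y) positions in mm."""
        ang = self.element_angles
        return self.ring_radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    @property
    def dt(self) -> float:
        """Sampling interval in microseconds."""
        return 1.0 / self.sampling_rate

    def to_dict(self) -> dict:
        return {
            "ring_radius": self.ring_radius,
            "n_elements": self.n_elements,
            "center_frequency": self.center_frequency,
            "fractional_bandwidth": self.fractional_bandwidth,
            "sampling_rate": self.sampling_rate,
            "speed_of_sound": self.speed_of_sound,
        }


def build_geometry(config: dict | None = None) -> RingArrayGeometry:
    """Construct a :class:`RingArrayGeometry` from a key/value mapping.

    Missing keys fall back to the instrument defaults (512 elements on a
    40-mm ring, 5-MHz centre frequency, 40-MS/s sampling).  A sampling rate
    that violates the Nyquist bound for the element passband is rejected.
    """
    config = dict(config or {})
    known = {
        "ring_radius",
        "n_elements",
        "center_frequency",
        "fractional_bandwidth",
        "sampling_rate",
        "speed_of_sound",
    }
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
    return RingArrayGeometry(**config)


@dataclass(frozen=True)
class ReconGrid:
    """Pixel grid for image reconstruction.

    ``origin`` is the world position (mm) of the centre of pixel (0, 0);
    pixels are addressed row-major, 0-based, with row -> y and column -> x.
    """

    n_rows: int
    n_cols: int
    pixel_size: float
    origin: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one pixel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinates of every pixel centre, each (n_rows, n_cols)."""
        x0, y0 = self.origin
        cols = x0 + self.pixel_size * np.arange(self.n_cols)
        rows = y0 + self.pixel_size * np.arange(self.n_rows)
        xx, yy = np.meshgrid(cols, rows)
        return xx, yy

    @property
    def max_radius(self) -> float:
        """Largest pixel-centre distance from the world origin (mm)."""
        xx, yy = self.pixel_coords()
        return float(np.hypot(xx, yy).max())

    def check_inside_ring(self, geometry: RingArrayGeometry) -> None:
        if self.max_radius >= geometry.ring_radius:
            raise ValueError(
                f"grid extends to radius {self.max_radius:.3f} mm, outside the "
                f"{geometry.ring_radius:.3f}-mm detection ring"
            )


def build_grid(n_rows: int, n_cols: int, pixel_size: float, *, centered: bool = True,
               origin: tuple[float, float] | None = None) -> ReconGrid:
    """Build a reconstruction grid, by default centred on the ring centre."""
    if origin is None:
        if not centered:
            origin = (0.0, 0.0)
        else:
            origin = (
                -0.5 * (n_cols - 1) * pixel_size,
                -0.5 * (n_rows - 1) * pixel_size,
            )
    return ReconGrid(n_rows=n_rows, n_cols=n_cols, pixel_size=pixel_size, origin=origin)
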