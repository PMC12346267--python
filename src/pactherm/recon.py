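"""Half-time delay-and-sum reconstruction via a precomputed sparse projector.

DAS back-projects each element's RF sample at the acoustic time of flight
tau = |x - e| / c onto pixel x, summing over elements.  The delay rule and
linear interpolation between the two bracketing samples are frozen into a
sparse matrix mapping the flattened (element, sample) space to pixels, so
a reconstruction is a single sparse matrix-vector product — fast enough to
keep up with the laser repetition rate.

Half-time variant: samples later than the half-time bound are discarded
before back-projection.  Late samples are dominated by in-plane reflections
of waves that already crossed the field of view, so each pixel keeps only
its nearer elements (those with tau within the bound); the default bound is
ring_radius / c, which truncates roughly the later half of the usable
record while preserving every element for the ring centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .geometry import ReconGrid, RingArrayGeometry

__all__ = [
    "PAImage",
    "SparseProjector",
    "build_projector",
    "das_reconstruct",
    "das_naive",
    "amplitude_image",
    "roi_mean",
]


@dataclass
class PAImage:
    """Reconstructed image on a grid; amplitude images are nonnegative."""

    values: np.ndarray
    grid: ReconGrid | None = None
    bipolar: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.bipolar and np.any(self.values < 0):
            raise ValueError("amplitude (non-bipolar) images must be nonnegative")

    @property
    def shape(self):
        return self.values.shape


def _half_time_bound(geometry: RingArrayGeometry, grid: ReconGrid,
                     bound: float | None) -> float:
    if bound is not None:
        return bound
    return geometry.ring_radius / geometry.speed_of_sound


@dataclass
class SparseProjector:
    """Precomputed DAS weights: image = weights @ rf.ravel() (reshaped).

    ``weights`` is CSR with shape (n_pixels, n_elements * n_samples); each
    pixel row holds at most two nonzeros per element (linear interpolation)
    and rows are normalised by the number of contributing elements.
    """

    weights: sparse.csr_matrix
    geometry: RingArrayGeometry
    grid: ReconGrid
    n_samples: int
    t0: float
    half_time: bool
    half_time_bound: float | None = None

    @property
    def shape(self):
        return self.weights.shape


def _delay_samples(geometry: RingArrayGeometry, grid: ReconGrid,
                   t0: float) -> np.ndarray:
    """Fractional sample index of the direct arrival, (n_pixels, n_elements)."""
    xx, yy = grid.pixel_coords()
    pix = np.column_stack([xx.ravel(), yy.ravel()])
    elem = geometry.element_positions
    d = np.sqrt(((pix[:, None, :] - elem[None, :, :]) ** 2).sum(-1))
    tau = d / geometry.speed_of_sound
    return (tau - t0) * geometry.sampling_rate


def build_projector(geometry: RingArrayGeometry, grid: ReconGrid,
                    n_samples: int, *, t0: float = 0.0, half_time: bool = True,
                    half_time_bound: float | None = None,
                    interpolation: str = "linear") -> SparseProjector:
    """Precompute the sparse DAS system matrix.

    ``half_time_bound`` (us) overrides the default ring_radius / c window;
    samples whose time exceeds the bound get zero weight.  ``interpolation``
    is "linear" (two samples per element) or "nearest".
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    grid.check_inside_ring(geometry)
    s = _delay_samples(geometry, grid, t0)
    if np.any(s < 0):
        raise ValueError("t0 is later than the earliest arrival")
    if np.any(s >= n_samples - 1):
        need = int(np.ceil(s.max())) + 2
        raise ValueError(
            f"delays extend beyond the RF record: need at least {need} samples, "
            f"got {n_samples}")

    n_pix, n_elem = s.shape
    if interpolation == "nearest":
        i0 = np.round(s).astype(np.int64)
        w0 = np.ones_like(s)
        i1 = i0
        w1 = np.zeros_like(s)
    else:
        i0 = np.floor(s).astype(np.int64)
        frac = s - i0
        w0, w1 = 1.0 - frac, frac
        i1 = i0 + 1

    keep = np.ones_like(s, dtype=bool)
    if half_time:
        bound = _half_time_bound(geometry, grid, half_time_bound)
        # one-sample tolerance so centre pixels keep their interpolation pair
        s_max = (bound - t0) * geometry.sampling_rate + 1.0
        keep = s <= s_max

    n_contrib = keep.sum(axis=1)
    if np.any(n_contrib == 0):
        raise ValueError("some pixels have no contributing elements under the "
                         "half-time window; widen half_time_bound")
    norm = 1.0 / n_contrib.astype(float)

    rows = np.repeat(np.arange(n_pix), n_elem).reshape(n_pix, n_elem)
    e_idx = np.broadcast_to(np.arange(n_elem), s.shape)
    cols0 = e_idx * n_samples + i0
    cols1 = e_idx * n_samples + i1
    wn0 = w0 * norm[:, None] * keep
    wn1 = w1 * norm[:, None] * keep

    data = np.concatenate([wn0.ravel(), wn1.ravel()])
    row_idx = np.concatenate([rows.ravel(), rows.ravel()])
    col_idx = np.concatenate([cols0.ravel(), cols1.ravel()])
    nz = data != 0
    mat = sparse.csr_matrix((data[nz], (row_idx[nz], col_idx[nz])),
                            shape=(n_pix, n_elem * n_samples))
    return SparseProjector(weights=mat, geometry=geometry, grid=grid,
                           n_samples=n_samples, t0=t0, half_time=half_time,
                           half_time_bound=half_time_bound)


def das_reconstruct(rf, projector: SparseProjector) -> PAImage:
    """Apply the sparse projector to one RF frame (bipolar image)."""
    samples = np.asarray(getattr(rf, "samples", rf), dtype=float)
    expected = (projector.geometry.n_elements, projector.n_samples)
    if samples.shape != expected:
        raise ValueError(f"RF shape {samples.shape} does not match projector "
                         f"(expected {expected})")
    img = projector.weights @ samples.ravel()
    return PAImage(values=img.reshape(projector.grid.shape),
                   grid=projector.grid, bipolar=True)


def das_naive(rf, geometry: RingArrayGeometry, grid: ReconGrid, *,
              half_time: bool = True, half_time_bound: float | None = None,
              t0: float = 0.0) -> PAImage:
    """Reference loop implementation of half-time DAS (oracle only).

    Same delay, interpolation, truncation and normalisation rules as the
    sparse path, executed as an explicit per-pixel, per-element loop.
    """
    samples = np.asarray(getattr(rf, "samples", rf), dtype=float)
    grid.check_inside_ring(geometry)
    n_elem, n_t = samples.shape
    if n_elem != geometry.n_elements:
        raise ValueError("RF element count does not match geometry")
    elem = geometry.element_positions
    xx, yy = grid.pixel_coords()
    bound = _half_time_bound(geometry, grid, half_time_bound)
    s_max = (bound - t0) * geometry.sampling_rate + 1.0
    out = np.zeros(grid.shape)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            acc = 0.0
            count = 0
            for e in range(n_elem):
                d = np.hypot(xx[r, c] - elem[e, 0], yy[r, c] - elem[e, 1])
                s = (d / geometry.speed_of_sound - t0) * geometry.sampling_rate
                if s < 0 or s >= n_t - 1:
                    raise ValueError("delay outside the RF record; need at least "
                                     f"{int(np.ceil(s)) + 2} samples")
                if half_time and s > s_max:
                    continue
                i0 = int(np.floor(s))
                f = s - i0
                acc += (1.0 - f) * samples[e, i0] + f * samples[e, i0 + 1]
                count += 1
            if count == 0:
                raise ValueError("pixel has no contributing elements under the "
                                 "half-time window")
            out[r, c] = acc / count
    return PAImage(values=out, grid=grid, bipolar=True)


def amplitude_image(image: PAImage | np.ndarray) -> PAImage:
    """Absolute value of a bipolar reconstruction."""
    if isinstance(image, PAImage):
        return PAImage(values=np.abs(image.values), grid=image.grid, bipolar=False)
    return PAImage(values=np.abs(np.asarray(image, dtype=float)), bipolar=False)


def roi_mean(image: PAImage | np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of image values over a boolean ROI mask."""
    values = np.asarray(getattr(image, "values", image), dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return float(values[mask].mean())
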