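"""RF conditioning and image alignment for thermal tracking.

Thermometry divides one frame by another pixel-by-pixel, so the signal path
feeding it must (i) recover the low-frequency content the band-limited
transducer suppresses — Wiener deconvolution with the electrical impulse
response followed by a 0.5-MHz low-pass — and (ii) keep the target
stationary across frames: cross-correlation frame selection and rigid
(rotation + translation) registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.signal import butter, fftconvolve, filtfilt, gausspulse
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "ImpulseResponse",
    "RigidTransform",
    "deconvolve_eir",
    "lowpass",
    "select_frame",
    "register_rigid",
]


@dataclass(frozen=True)
class ImpulseResponse:
    """Receive-chain impulse response sampled at the DAQ rate.

    ``kernel`` is a short 1D time series; ``center`` is the sample index of
    its temporal reference (the pulse peak), so that convolution with the
    kernel followed by deconvolution is delay-free.
    """

    kernel: np.ndarray
    sampling_rate: float
    center: int = 0

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1 or k.size == 0:
            raise ValueError("kernel must be a nonempty 1D array")
        if not np.any(k != 0):
            raise ValueError("kernel has zero energy")
        object.__setattr__(self, "kernel", k)

    @classmethod
    def gaussian_pulse(cls, center_frequency: float, fractional_bandwidth: float,
                       sampling_rate: float) -> "ImpulseResponse":
        """Gaussian-modulated cosine at the element centre frequency.

        ``center_frequency`` and ``sampling_rate`` share units (MHz and
        MS/s); the -6 dB fractional bandwidth sets the envelope width.
        """
        # long enough to capture the envelope tails at any bandwidth >= 0.3
        half = max(int(np.ceil(6.0 * sampling_rate
                               / (center_frequency * fractional_bandwidth))), 4)
        t = np.arange(-half, half + 1) / sampling_rate
        k = gausspulse(t, fc=center_frequency, bw=fractional_bandwidth, bwr=-6)
        return cls(kernel=k, sampling_rate=sampling_rate, center=half)

    @classmethod
    def from_geometry(cls, geometry) -> "ImpulseResponse":
        return cls.gaussian_pulse(geometry.center_frequency,
                                  geometry.fractional_bandwidth,
                                  geometry.sampling_rate)

    def convolve(self, samples: np.ndarray) -> np.ndarray:
        """Convolve per-channel RF with the kernel, preserving delays."""
        x = np.atleast_2d(np.asarray(samples, dtype=float))
        full = fftconvolve(x, self.kernel[None, :], mode="full", axes=1)
        out = full[:, self.center:self.center + x.shape[1]]
        return out if samples.ndim > 1 else out[0]


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rotation (degrees, about the image centre) plus translation.

    ``translation`` is (dx, dy): column and row shift of the moving image,
    in pixels (multiply by the grid's pixel size for mm).
    """

    rotation: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not (-180.0 < self.rotation <= 180.0):
            raise ValueError("rotation must lie in (-180, 180] degrees")


def _rf_samples(rf) -> np.ndarray:
    return np.asarray(getattr(rf, "samples", rf), dtype=float)


def _rewrap(rf, samples):
    if hasattr(rf, "samples"):
        from dataclasses import replace
        return replace(rf, samples=samples)
    return samples


def deconvolve_eir(rf, eir: ImpulseResponse, noise_reg: float = 1e-3):
    """Wiener deconvolution of the receive impulse response, per channel.

    The estimate is X = Y H* / (|H|^2 + noise_reg * max|H|^2); ``noise_reg``
    is the relative noise floor of the regulariser.  Output length equals
    input length and the kernel's temporal reference is honoured, so
    arrival times are unchanged.
    """
    if noise_reg <= 0:
        raise ValueError("noise_reg must be positive")
    x = np.atleast_2d(_rf_samples(rf))
    n_t = x.shape[1]
    n_fft = int(2 ** np.ceil(np.log2(n_t + len(eir.kernel))))
    k = np.zeros(n_fft)
    k[:len(eir.kernel)] = eir.kernel
    k = np.roll(k, -eir.center)  # put the temporal reference at lag zero
    H = np.fft.rfft(k)
    denom = np.abs(H) ** 2 + noise_reg * np.max(np.abs(H) ** 2)
    W = np.conj(H) / denom
    Y = np.fft.rfft(x, n=n_fft, axis=1)
    out = np.fft.irfft(Y * W[None, :], n=n_fft, axis=1)[:, :n_t]
    if _rf_samples(rf).ndim == 1:
        out = out[0]
    return _rewrap(rf, out)


def lowpass(rf, cutoff: float = 0.5, sampling_rate: float | None = None,
            order: int = 4):
    """Zero-phase Butterworth low-pass, per channel; DC gain is 1.

    ``cutoff`` and ``sampling_rate`` share units (MHz and MS/s).  The
    filter runs forward and backward (``filtfilt``) so arrival times that
    feed the thermometry baseline are not skewed.
    """
    if sampling_rate is None:
        sampling_rate = getattr(rf, "sampling_rate", None)
        if sampling_rate is None:
            raise ValueError("sampling_rate required when rf carries none")
    nyq = sampling_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} must be below Nyquist {nyq}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    b, a = butter(order, cutoff / nyq)
    x = np.atleast_2d(_rf_samples(rf))
    out = filtfilt(b, a, x, axis=1)
    if _rf_samples(rf).ndim == 1:
        out = out[0]
    return _rewrap(rf, out)


def _image(arr) -> np.ndarray:
    return np.asarray(getattr(arr, "values", arr), dtype=float)


def _ncc_peak(a: np.ndarray, b: np.ndarray) -> float:
    """Peak of the normalised 2D cross-correlation over all shifts."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    corr = fftconvolve(a, b[::-1, ::-1], mode="full")
    return float(corr.max() / (na * nb))


def select_frame(candidates, reference) -> int:
    """Index of the candidate with the highest cross-correlation peak.

    Mirrors the stepwise frame selection of a whole-body scan: among the
    frames acquired at one position, keep the one best correlated with the
    chosen frame of the previous position.  Ties break to the lowest index.
    """
    cands = [_image(c) for c in candidates]
    if not cands:
        raise ValueError("candidate list is empty")
    ref = _image(reference)
    for c in cands:
        if c.shape != ref.shape:
            raise ValueError("candidate and reference shapes differ")
    scores = np.array([_ncc_peak(ref, c) for c in cands])
    return int(np.argmax(scores))  # argmax returns the first maximum


def register_rigid(moving, fixed, max_rotation: float = 10.0,
                   upsample_factor: int = 20):
    """Rigid registration of ``moving`` onto ``fixed``.

    Rotation is found by a bounded golden-section search (+- ``max_rotation``
    degrees about the image centre); at each angle the residual translation
    comes from subpixel phase correlation.  The registered image is
    resampled bilinearly.  Returns ``(RigidTransform, registered_image)``.
    """
    mov = _image(moving)
    fix = _image(fixed)
    if mov.shape != fix.shape:
        raise ValueError("images must have the same shape")
    if mov.std() == 0 or fix.std() == 0:
        raise ValueError("cannot register a flat (zero-variance) image")

    def _alignment_error(theta: float) -> float:
        rot = _sk_rotate(mov, -theta, order=1, preserve_range=True)
        _, error, _ = phase_cross_correlation(fix, rot,
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        return float(error)

    # the error surface is only locally unimodal: coarse scan, then refine
    coarse = np.linspace(-max_rotation, max_rotation, 41)
    best = coarse[int(np.argmin([_alignment_error(t) for t in coarse]))]
    step = coarse[1] - coarse[0]
    res = minimize_scalar(_alignment_error, bounds=(best - step, best + step),
                          method="bounded", options={"xatol": 1e-3})
    theta = float(res.x)
    if abs(theta) < 5e-3:
        theta = 0.0  # below the search resolution: call it unrotated
    rot = _sk_rotate(mov, -theta, order=1, preserve_range=True)
    shift, _, _ = phase_cross_correlation(fix, rot,
                                          upsample_factor=upsample_factor,
                                          normalization=None)
    registered = ndimage.shift(rot, shift, order=1, mode="constant", cval=0.0)
    transform = RigidTransform(rotation=theta,
                               translation=(float(shift[1]), float(shift[0])))
    return transform, registered
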