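"""Photothermal heating kinetics and photostability summaries.

Heating transients under continuous-wave illumination follow an
exponential-rise law

    T(t) = a * (1 - exp(-k t)) + b

with heating amplitude ``a`` (C), thermal rate constant ``k`` (1/min) and
baseline ``b`` (C).  Comparing fits of the first and last heating cycles of
a multicycle experiment quantifies photothermal stability: stable absorbers
show near-zero percent change in both a and k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "HeatingFit",
    "SpectrumTable",
    "fit_exponential_rise",
    "cycle_change",
    "photostability_summary",
    "extinction_change",
]


@dataclass(frozen=True)
class HeatingFit:
    """Fitted exponential-rise parameters for one heating cycle."""

    amp: float          # heating amplitude a, degrees C
    rate: float         # thermal rate constant k, 1/min
    baseline: float     # baseline b, degrees C
    r_squared: float
    degenerate: bool = False


@dataclass(frozen=True)
class SpectrumTable:
    """Extinction spectrum on a strictly increasing wavelength axis (nm)."""

    wavelengths: np.ndarray
    extinction: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ext = np.asarray(self.extinction, dtype=float)
        if wl.ndim != 1 or wl.shape != ext.shape:
            raise ValueError("wavelengths and extinction must be matching 1D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(ext < 0):
            raise ValueError("extinction must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "extinction", ext)


def _rise(t, a, k, b):
    return a * (1.0 - np.exp(-k * t)) + b


def fit_exponential_rise(times, temps, *, n_restarts: int = 5,
                         seed: int | None = None) -> HeatingFit:
    """Nonlinear least-squares fit of T(t) = a (1 - e^{-k t}) + b.

    Initialisation: b0 = first sample, a0 = last - first, k0 = reciprocal
    of the time to reach 63% of a0.  Up to ``n_restarts`` jittered restarts
    are attempted on non-convergence; a flat series is flagged degenerate
    (amp ~ 0, undefined R^2) rather than fitted.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(temps, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and temps must be matching 1D arrays")
    if len(t) < 4:
        raise ValueError("need at least 4 samples to fit 3 parameters")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    y_span = y.max() - y.min()
    if y_span == 0.0:
        return HeatingFit(amp=0.0, rate=np.nan, baseline=float(y[0]),
                          r_squared=np.nan, degenerate=True)

    b0 = float(y[0])
    a0 = float(y[-1] - y[0])
    # time at which the rise crosses 63% of its total excursion
    target = b0 + 0.632 * a0
    crossed = np.nonzero((y - target) * np.sign(a0 if a0 != 0 else 1.0) >= 0)[0]
    t63 = t[crossed[0]] if crossed.size and t[crossed[0]] > 0 else (t[-1] - t[0]) / 3.0
    k0 = 1.0 / t63 if t63 > 0 else 1.0
    if a0 == 0.0:
        a0 = y_span

    rng = np.random.default_rng(seed)
    best = None
    best_res = np.inf
    for trial in range(n_restarts + 1):
        if trial == 0:
            p0 = (a0, k0, b0)
        else:
            jit = rng.uniform(0.5, 1.5, size=3)
            p0 = (a0 * jit[0], k0 * jit[1], b0 + (jit[2] - 1.0) * abs(a0))
        try:
            popt, _ = curve_fit(_rise, t, y, p0=p0, maxfev=10000,
                                bounds=([-np.inf, 1e-12, -np.inf],
                                        [np.inf, np.inf, np.inf]))
        except (RuntimeError, ValueError):
            continue
        res = float(np.sum((_rise(t, *popt) - y) ** 2))
        if res < best_res:
            best_res = res
            best = popt
    if best is None:
        raise RuntimeError("exponential-rise fit failed to converge "
                           f"(best residual {best_res:.3g})")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_res / ss_tot if ss_tot > 0 else np.nan
    return HeatingFit(amp=float(best[0]), rate=float(best[1]),
                      baseline=float(best[2]), r_squared=r2)


def cycle_change(first: HeatingFit, last: HeatingFit) -> tuple[float, float]:
    """Percent change in amplitude and rate between two heating cycles.

    Both changes are relative to the first cycle; the sign convention is
    positive = decrease (so a stable absorber gives small positive or
    negative values near zero).
    """
    if first.amp == 0 or first.rate == 0:
        raise ValueError("first-cycle amplitude and rate must be nonzero")
    d_amp = 100.0 * (first.amp - last.amp) / first.amp
    d_rate = 100.0 * (first.rate - last.rate) / first.rate
    return d_amp, d_rate


def photostability_summary(amplitudes) -> np.ndarray:
    """Percent-of-initial photoacoustic amplitude per exposure point."""
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0 or a.flat[0] == 0:
        raise ValueError("initial amplitude must be nonzero")
    return 100.0 * a / a.flat[0]


def extinction_change(before: SpectrumTable, after: SpectrumTable,
                      wavelengths) -> np.ndarray:
    """Percent loss of extinction at query wavelengths (linear interpolation)."""
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    for spec in (before, after):
        if wl.min() < spec.wavelengths[0] or wl.max() > spec.wavelengths[-1]:
            raise ValueError(
                f"query wavelengths outside the measured range "
                f"[{spec.wavelengths[0]}, {spec.wavelengths[-1]}] nm of {spec.label!r}")
    e_before = np.interp(wl, before.wavelengths, before.extinction)
    e_after = np.interp(wl, after.wavelengths, after.extinction)
    if np.any(e_before == 0):
        raise ValueError("zero extinction in the reference spectrum at a query wavelength")
    return 100.0 * (e_before - e_after) / e_before
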