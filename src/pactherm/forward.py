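"""Forward acoustic model: phantom -> per-element RF time series.

Each nonzero phantom pixel acts as a 2D point source whose initial pressure
is p0 = Gamma0 * eta_th * A_e with Gamma0 proportional to (T0 + c/b).  The
wave reaches element e after |x - e| / c and is scaled by p0 / |x - e|
(cylindrical spreading); the impulse train per channel is convolved with
the element impulse response (Gaussian-modulated cosine at the centre
frequency).  Heating enters through the Gruneisen relation: a pixel at
temperature T0 + dT emits with amplitude scaled by 1 + dT / (T0 + c/b),
which the thermometry module inverts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RingArrayGeometry
from .phantom import AbsorptionMap, GrueneisenCalibration
from .signal import ImpulseResponse
from .thermometry import ThermalSeries

__all__ = [
    "RFFrame",
    "RFSeries",
    "HeatingSchedule",
    "UniformHeating",
    "ExponentialHeating",
    "MotionSpec",
    "forward_project",
    "simulate_thermometry_sequence",
]


@dataclass(frozen=True)
class RFFrame:
    """Per-element RF record for one laser shot.

    ``samples`` is (n_elements, n_time_samples) acoustic pressure in
    arbitrary units; ``t0`` the time of the first sample after the laser
    pulse (us); ``frame_time`` the acquisition timestamp in seconds.
    """

    samples: np.ndarray
    t0: float = 0.0
    frame_time: float = 0.0
    geometry: RingArrayGeometry | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2:
            raise ValueError("samples must be (n_elements, n_time_samples)")
        if not np.all(np.isfinite(s)):
            raise ValueError("RF samples must be finite")
        object.__setattr__(self, "samples", s)

    @property
    def n_elements(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def sampling_rate(self) -> float | None:
        return None if self.geometry is None else self.geometry.sampling_rate


@dataclass
class RFSeries:
    """Ordered sequence of RF frames sharing one geometry."""

    frames: list[RFFrame]
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frames) != len(self.frame_times):
            raise ValueError("frames and frame_times lengths differ")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


# ---------------------------------------------------------------------------
# heating schedules


@dataclass(frozen=True)
class UniformHeating:
    """Step heating: dT jumps to ``delta`` while the CW laser is on."""

    delta: float
    mask_name: str = "tumor"

    def delta_t(self, t_on: float) -> float:
        return self.delta


@dataclass(frozen=True)
class ExponentialHeating:
    """Exponential-rise heating dT(t) = amp * (1 - exp(-rate t)).

    ``amp`` in degrees C, ``rate`` in 1/min, ``t`` minutes since the CW
    laser switched on.
    """

    amp: float
    rate: float
    mask_name: str = "tumor"

    def delta_t(self, t_on: float) -> float:
        return self.amp * (1.0 - np.exp(-self.rate * t_on))


@dataclass(frozen=True)
class HeatingSchedule:
    """PTT session timing: baseline, CW heating, cool-down (all minutes).

    ``frame_rate`` is in frames per minute (the instrument's 10 Hz stream
    is typically decimated for simulation).  ``heating_model`` supplies the
    in-mask temperature rise as a function of time since laser-on; during
    cool-down the rise decays exponentially with ``cooldown_rate`` (1/min,
    default: the heating rate when the model has one, else instantaneous).
    """

    baseline_duration: float = 1.0
    heating_duration: float = 10.0
    cooldown_duration: float = 1.0
    frame_rate: float = 6.0
    heating_model: UniformHeating | ExponentialHeating | None = None
    cooldown_rate: float | None = None

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "heating_duration", "cooldown_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.heating_duration + self.cooldown_duration

    def frame_times(self) -> np.ndarray:
        """Frame timestamps in minutes from the start of the session."""
        n = int(np.floor(self.total_duration * self.frame_rate)) + 1
        return np.arange(n) / self.frame_rate

    def delta_t_at(self, t: float) -> float:
        """In-mask temperature rise (C) at session time ``t`` minutes."""
        if self.heating_model is None:
            return 0.0
        t_on = t - self.baseline_duration
        if t_on < 0:
            return 0.0
        if t_on <= self.heating_duration:
            return float(self.heating_model.delta_t(t_on))
        peak = float(self.heating_model.delta_t(self.heating_duration))
        rate = self.cooldown_rate
        if rate is None:
            rate = getattr(self.heating_model, "rate", None)
        if rate is None:
            return 0.0
        return peak * float(np.exp(-rate * (t_on - self.heating_duration)))


@dataclass(frozen=True)
class MotionSpec:
    """Rigid inter-frame jitter bounds: |rotation| <= max_rotation (deg),
    |dx|, |dy| <= max_translation (mm), drawn uniformly per frame."""

    max_rotation: float = 0.0
    max_translation: float = 0.0


# ---------------------------------------------------------------------------
# forward projection


def _default_n_samples(geometry: RingArrayGeometry, r_fov: float,
                       eir: ImpulseResponse) -> int:
    t_max = (geometry.ring_radius + r_fov) / geometry.speed_of_sound
    pad = len(eir.kernel)  # room for the pulse tail
    return int(np.ceil(t_max * geometry.sampling_rate)) + pad + 1


def _project_sources(positions: np.ndarray, amplitudes: np.ndarray,
                     geometry: RingArrayGeometry, eir: ImpulseResponse,
                     n_samples: int, t0: float) -> np.ndarray:
    """Accumulate delayed, 1/r-scaled impulses and convolve with the EIR."""
    elem = geometry.element_positions  # (n_e, 2)
    train = np.zeros((geometry.n_elements, n_samples))
    if len(positions):
        # distances: (n_src, n_e)
        d = np.sqrt(((positions[:, None, :] - elem[None, :, :]) ** 2).sum(-1))
        if np.any(d < 1e-9):
            raise ValueError("a source pixel coincides with a transducer element")
        tau = d / geometry.speed_of_sound
        s = (tau - t0) * geometry.sampling_rate
        if np.any(s < 0) or np.any(s >= n_samples - 1):
            raise ValueError(
                "arrival time outside the RF record; need at least "
                f"{int(np.ceil(s.max())) + 2} samples")
        i0 = np.floor(s).astype(np.int64)
        frac = s - i0
        amp = (amplitudes[:, None] / d)
        e_idx = np.broadcast_to(np.arange(geometry.n_elements)[None, :], d.shape)
        np.add.at(train, (e_idx.ravel(), i0.ravel()), (amp * (1 - frac)).ravel())
        np.add.at(train, (e_idx.ravel(), i0.ravel() + 1), (amp * frac).ravel())
    return eir.convolve(train)


def forward_project(phantom: AbsorptionMap, geometry: RingArrayGeometry,
                    calib: GrueneisenCalibration, noise_sd: float = 0.0,
                    seed: int | None = None, *, eir: ImpulseResponse | None = None,
                    n_samples: int | None = None, t0: float = 0.0,
                    delta_t_map: np.ndarray | None = None,
                    frame_time: float = 0.0) -> RFFrame:
    """Simulate one RF frame from an absorption phantom.

    ``noise_sd`` is the additive Gaussian noise standard deviation in units
    of the peak noise-free amplitude across channels.  ``delta_t_map``
    optionally supplies a per-pixel temperature rise; the source amplitude
    is then scaled by 1 + dT/(T0 + c/b) per the Gruneisen relation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    phantom.check_inside_ring(geometry)
    if eir is None:
        eir = ImpulseResponse.from_geometry(geometry)
    if n_samples is None:
        n_samples = _default_n_samples(geometry, phantom.grid.max_radius, eir)

    values = phantom.values
    if delta_t_map is not None:
        a = calib.coefficient
        factor = 1.0 + np.asarray(delta_t_map, dtype=float) / a
        if np.any(factor[values > 0] <= 0):
            raise ValueError(
                "temperature drop drives the Gruneisen parameter negative "
                f"(dT below -{a:.2f} C)")
        values = values * factor

    p0 = calib.coefficient * calib.eta_th * values
    xx, yy = phantom.grid.pixel_coords()
    src = p0 > 0
    positions = np.column_stack([xx[src], yy[src]])
    amplitudes = p0[src]
    clean = _project_sources(positions, amplitudes, geometry, eir, n_samples, t0)

    samples = clean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        peak = np.abs(clean).max()
        scale = noise_sd * (peak if peak > 0 else 1.0)
        samples = clean + rng.normal(0.0, scale, size=clean.shape)
    return RFFrame(samples=samples, t0=t0, frame_time=frame_time, geometry=geometry)


def _rotate_translate(points: np.ndarray, rotation_deg: float,
                      translation: tuple[float, float]) -> np.ndarray:
    th = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return points @ R.T + np.asarray(translation)


def simulate_thermometry_sequence(
        phantom: AbsorptionMap, geometry: RingArrayGeometry,
        schedule: HeatingSchedule, calib: GrueneisenCalibration,
        motion: MotionSpec | None = None, noise_sd: float = 0.0,
        seed: int | None = None, *, eir: ImpulseResponse | None = None,
        n_samples: int | None = None) -> tuple[RFSeries, ThermalSeries]:
    """Simulate the RF stream of a PTT session with known ground truth.

    The heating model's temperature rise is applied inside its named
    phantom mask; each frame's source amplitudes follow the Gruneisen
    scaling 1 + dT/(T0 + c/b).  Rigid jitter (if any) moves the source
    positions before projection; the returned ground-truth ThermalSeries
    is in the unmoved phantom frame, with times in minutes relative to
    CW-laser switch-on.
    """
    phantom.check_inside_ring(geometry)
    if schedule.heating_model is not None:
        mask_name = schedule.heating_model.mask_name
        if mask_name not in phantom.masks:
            raise ValueError(f"phantom has no mask named {mask_name!r}")
        mask = phantom.masks[mask_name]
    else:
        mask = np.zeros(phantom.grid.shape, dtype=bool)

    if eir is None:
        eir = ImpulseResponse.from_geometry(geometry)
    # extra headroom so jittered sources stay inside the record
    r_fov = phantom.grid.max_radius + (motion.max_translation if motion else 0.0)
    if n_samples is None:
        n_samples = _default_n_samples(geometry, r_fov, eir)

    rng = np.random.default_rng(seed)
    a = calib.coefficient
    xx, yy = phantom.grid.pixel_coords()
    base_positions = np.column_stack([xx.ravel(), yy.ravel()])

    times = schedule.frame_times()
    frames: list[RFFrame] = []
    truth_maps = np.zeros((len(times), *phantom.grid.shape))
    peak_scale: float | None = None
    for j, t in enumerate(times):
        dT = schedule.delta_t_at(t)
        dT_map = np.where(mask, dT, 0.0)
        truth_maps[j] = dT_map
        if np.any(1.0 + dT_map / a <= 0):
            raise ValueError(
                f"temperature drop at t={t:.3f} min drives the Gruneisen "
                f"parameter negative (dT below -{a:.2f} C)")
        values = phantom.values * (1.0 + dT_map / a)
        p0 = a * calib.eta_th * values
        src = p0.ravel() > 0
        positions = base_positions[src]
        if motion is not None and (motion.max_rotation or motion.max_translation):
            rot = rng.uniform(-motion.max_rotation, motion.max_rotation)
            dx, dy = rng.uniform(-motion.max_translation, motion.max_translation, 2)
            positions = _rotate_translate(positions, rot, (dx, dy))
        clean = _project_sources(positions, p0.ravel()[src], geometry, eir,
                                 n_samples, 0.0)
        samples = clean
        if noise_sd > 0:
            if peak_scale is None:  # fix the noise scale at the first frame
                peak = np.abs(clean).max()
                peak_scale = noise_sd * (peak if peak > 0 else 1.0)
            samples = clean + rng.normal(0.0, peak_scale, size=clean.shape)
        frames.append(RFFrame(samples=samples, frame_time=t * 60.0,
                              geometry=geometry))

    rel_times = times - schedule.baseline_duration
    truth = ThermalSeries(times=rel_times, maps=truth_maps, roi=mask,
                          absolute=False, calibration=calib)
    return RFSeries(frames=frames, frame_times=rel_times), truth
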