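# Methods

`pactherm` is a desk-scale re-implementation of the computational chain of
an integrated photoacoustic-computed-tomography (PACT) / photothermal-
therapy (PTT) platform: synthetic ring-array acquisition, half-time
delay-and-sum reconstruction, RF conditioning and rigid registration,
Grüneisen-based PA thermometry with CEM43T50 dosimetry, heating-kinetics
analysis, and a Monte Carlo + Pennes simulation of submerged versus
open-air PTT.  Everything runs from synthetic inputs with known ground
truth; no measured data are required.

## Forward acoustic model

The imaging array is a uniform ring (defaults: 512 elements, 40-mm radius,
5-MHz centre frequency, 40-MS/s sampling) detecting waves from a 2D
absorption phantom.  Each nonzero pixel with specific optical absorption
A_e acts as a point source with initial pressure p0 = Γ0·η_th·A_e, where
the Grüneisen parameter Γ0 is linear in baseline temperature; only the
ratio of the calibration line's intercept and slope (c/b) matters, so a
calibration is the pair (T0, c/b).  The wave reaches an element after
|x−e|/c with 1/r cylindrical spreading, and the per-channel impulse train
is convolved with the element impulse response.

Deliberate simplifications: the model is 2D (no elevational focusing —
thermometry operates on a single slice), there is no transducer
directivity, no acoustic heterogeneity, and additive channel noise is
i.i.d. Gaussian with a standard deviation quoted relative to the peak
noise-free amplitude (so "SNR 20" means sd = peak/20).  The element
impulse response is a Gaussian-modulated cosine with fractional −6 dB
bandwidth 0.7 (configurable) — the narrowed low end is what makes the EIR
deconvolution step meaningful.  The speed of sound defaults to
1.50 mm/µs and is configurable per dataset.

Heated sequences scale each in-mask source amplitude by 1 + ΔT/(T0+c/b),
the exact forward form of the thermometry inversion, so round-trip tests
have machine-precision ground truth.  Rigid inter-frame jitter is applied
to the source coordinates (exact, no resampling); the returned ground
truth stays in the unmoved frame.

## Reconstruction

Delay-and-sum back-projects each element's sample at the time of flight
τ = |x−e|/c, with linear interpolation between the two bracketing samples
and per-pixel normalisation by the number of contributing elements; the
rule is frozen into a sparse CSR matrix so a reconstruction is one
matrix-vector product.  A deliberately naive triple-loop implementation
with the identical rule serves as the oracle; sparse and naive agree to
1e−10 relative.

Half-time truncation discards samples later than ring_radius/c (with a
one-sample tolerance so centre pixels keep their interpolation pair).
Samples beyond that bound are dominated by reflections of waves that have
already crossed the field of view; geometrically the rule keeps, for each
pixel, the nearer elements and keeps every element for the ring centre.
The bound is configurable (`half_time_bound`).  Note that a bound at
(ring_radius + r_fov)/c would never exclude anything — every delay the
DAS reads is below it — which is why the tighter default was chosen.

Amplitude images are absolute values of the bipolar reconstruction; no
apodization or envelope detection is applied.

## Signal conditioning and registration

For thermal tracking the RF is Wiener-deconvolved with the electrical
impulse response, X = Y·H*/(|H|²+ε·max|H|²) with relative noise floor
ε = 1e−3 by default, then low-passed at 0.5 MHz with a zero-phase
4th-order Butterworth (forward-backward), preserving arrival times and DC
gain.  Frame selection picks the candidate maximising the normalised
cross-correlation peak with a reference (ties to the lowest index).
Rigid registration does a coarse scan plus bounded golden-section search
over rotation, with subpixel phase correlation for translation at each
angle; the registered image is resampled bilinearly.  Registration
operates on amplitude images.

## Thermometry and dose

The baseline map p0 is the pixelwise mean amplitude over the baseline
window (the pre-heating minute by default).  Pixels with p0 below 5% of
the ROI's median baseline amplitude are flagged invalid (NaN) — the
inversion divides by p0.  Temperature change is ΔT = a·Δp/p0 with
a = T0 + c/b: 24.75 °C for the water-bath phantom calibration
(T0 = 22 °C, c/b = 2.75) and 50.14 °C for soft tissue (T0 = 37 °C,
c/b = 13.14); absolute maps add the core temperature.

ROI metrics pool all ROI pixels of all frames within consecutive
reporting intervals (1 min default): T_avg is the pooled mean, T50 the
pooled median.  Thermal dose is CEM43T50 = Σ_i t·R^(43−T50_i) with
R = 0.5 at or above 43 °C and R = 0.25 below (the standard CEM43
convention; at exactly 43 °C the choice is immaterial since R⁰ = 1).

## Heating kinetics

Heating cycles are fitted with T(t) = a(1−e^(−kt)) + b by bounded
Levenberg-Marquardt least squares; initialisation uses b₀ = first sample,
a₀ = last−first, k₀ = 1/(time to 63% of the excursion), with up to five
seeded jittered restarts.  A flat series is flagged degenerate rather
than fitted.  Cycle stability is quoted as percent change relative to the
first cycle (positive = decrease).  Multi-cycle records are segmented by
the known laser-state schedule, not detected from data.

## PTT simulation

The tissue model is a 2-cm cube: 1.1 cm muscle, 0.075 cm skin, coupling
medium above, and an ellipsoidal tumor (semi-axes 3.5, 4, 2.5 mm) with
its top tangent to the skin/muscle interface.  The stated semi-axes give
a volume of ≈146.6 mm³ (the voxelised model matches this within 5%).
Tissue optical properties are µ_a = 0.1 cm⁻¹ and µ_s = 100 cm⁻¹ with
Henyey-Greenstein g = 0.9; nanoparticle loading raises the tumor's µ_a by
1.36 cm⁻¹; water absorbs 0.02 cm⁻¹.  Refractive-index mismatch and
Fresnel reflection are omitted (matched-index transport).

The Monte Carlo launches photons from a Gaussian beam (1/e² radius 16 mm)
clipped by a 4.8-mm-radius iris at 2.5 W/cm², walks them through the
voxel grid with exponential free paths in µ_a+µ_s, deposits the albedo
fraction of the weight at each interaction, and terminates by depositing
the residual weight once it falls below 1e−4 (instead of Russian
roulette), so deposited + escaped energy equals launched energy to float
precision at every run — a bookkeeping invariant the tests assert at
1e−6.  A pure-absorber configuration reproduces Beer-Lambert depth
deposition within 2% at 10⁶ photons.

The Pennes equation ρc∂T/∂t = ∇·(κ∇T) + Q + ωρ_b c_b(T_a−T) is solved on
the same grid with harmonic-mean face conductivities.  Default thermal
properties (density, heat capacity, conductivity, perfusion): skin
1109 kg/m³, 3391 J/kg/K, 0.37 W/m/K, 1.1e−3 s⁻¹; muscle 1090, 3421,
0.49, 7e−4; the tumor uses muscle's values including perfusion; blood
ρ_b = 1050 kg/m³, c_b = 3617 J/kg/K, T_a = 37 °C.  All are overridable.

Boundary treatment: exterior faces adjacent to tissue are Dirichlet
37 °C.  The coupling medium is held at its ambient temperature (20 °C
air, 35 °C water) and exchanges heat with the skin through a surface
heat-transfer coefficient: 10 W/m²K for open air (natural convection) and
5000 W/m²K for the submerged case — the bath is actively circulated to
hold its temperature, so its interface is effectively pinned near 35 °C.
Modelling the bath as stagnant conducting water instead (k = 0.6 W/m/K
over several mm) underestimates the cooling so badly that the submerged
temperature maximum stays at the tumor top; the circulated-bath coefficient
is what produces the physically observed behaviour — in open air the
maximum sits at the tumor-skin boundary with the overlying skin close
behind, while submerged the skin is the coolest probe and the maximum
moves to the tumor centre.

Time stepping is backward-Euler with a Douglas-Gunn approximate
factorisation: each step applies the full explicit operator and then three
tridiagonal sweeps (one per axis), unconditionally stable for the heat
operator and O(n) per step, with dt = 0.5 s by default.  An unsplit
backward-Euler path solved by Jacobi-preconditioned conjugate gradients
(`method="cg"`) is retained as a reference; on test cases the two agree in
the tissue region to better than 2% of the temperature rise.  The unsplit
solve is roughly two orders of magnitude slower at 0.25-mm resolution,
which is why the factorised scheme is the default.

## Problem sizes used in tests

The test suite and worked examples use reduced but structurally identical
configurations: 16-64 ring elements instead of 512, 32x32 to 128x128
reconstruction grids, a handful of frames per heating phase at a few
frames per minute instead of 10 Hz, and 2x10⁴-10⁶ Monte Carlo photons
depending on the check.  All operations are linear in these sizes and the
acceptance-grade checks (oracle equivalence, round-trip recovery, probe
orderings) are invariant to them; the full-resolution settings remain the
defaults of the library API.

## What the synthetic data do and do not show

The generator reproduces the geometry, the Grüneisen temperature
dependence, band-limited detection, channel noise and rigid motion — so
passing tests demonstrate the correctness of the reconstruction,
conditioning, registration and inversion chain.  It does not emulate
acoustic attenuation or heterogeneity, elevational effects, laser energy
drift, physiological motion beyond rigid jitter, or perfusion-driven
cooling of the imaged slice; quantitative accuracy on real tissue is
bounded by those effects, not by anything tested here.
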