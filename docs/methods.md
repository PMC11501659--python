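# Methods

`canta` models flat-field capillary-assisted nanoparticle tracking analysis
(CaNTA): a single nanoparticle diffuses inside a liquid-filled cylindrical
microchannel, is illuminated through the capillary by a wide, freely
diffracting Gaussian beam, and is imaged side-on through a diffraction-limited
microscope at kilohertz frame rates. This note records the models, the
defaults and why they were chosen, and what the synthetic tests do and do not
demonstrate.

## Flat-field illumination model

The illumination is the fundamental Gaussian beam of a low-NA delivery fiber,
propagating in a homogeneous medium of index n:

- Rayleigh range z_R = π ω₀² n / λ₀,
- beam radius ω(z) = ω₀ √(1 + (z/z_R)²),
- intensity I(r, z) = [ω₀/ω(z)]² exp(−2r²/ω(z)²), normalised to I(0,0) = 1.

With the default parameters (ω₀ = 4.2 µm, λ₀ = 0.532 µm, n ≈ 1.46) the beam
at z_a = 1 mm has expanded to ω ≈ 28 µm, so across a 4 µm channel the
centre-to-edge intensity difference is about 1 % and the on-axis decrease
over one diffusion length of a 50 nm particle is below 4 % — the design
argument for treating the illumination as a flat field.

Flat-field formation requires the liquid index to match the cladding:
`classify_regime` labels the mismatch Δn = n_liquid − n_cladding as `flat`
within a tolerance of 5·10⁻⁵ (an order of magnitude below the smallest
mismatch the design study varies), `guided` for positive Δn (total internal
reflection concentrates light in the channel) and `leaky` for negative Δn
(power dissipates through the wall).

### Scalar beam propagation

Full electromagnetic (FEM) solutions of the liquid-filled capillary are
replaced by a paraxial split-step scalar propagator in the (x, z) plane:
exact free-space diffraction in the spatial-frequency domain alternates with
thin phase screens for the index contrast, and a super-Gaussian edge absorber
emulates open boundaries. This reproduces the guided / leaky / flat
phenomenology — centre concentration for Δn = +0.004, transverse power loss
for Δn = −0.004, an unchanged profile for Δn = 0 — and agrees with the
analytic (slab) Gaussian beam to machine precision in homogeneous media.
Quantitative mode-field magnitudes (e.g. exact centre-to-wall contrast
ratios) are outside the propagator's remit: it is 2D scalar and paraxial, and
the capillary's outer surface is deliberately ignored because the tracking
region is chosen to avoid its reflections. Grid defaults are 0.05 µm
transverse spacing (≥ 10 samples per wavelength in the medium, enforced) and
0.25 µm axial steps with a configurable stability bound.

Regime demonstrations launch the analytic diverging Gaussian evaluated at
z_a (the experimental excitation); a plane-wave launch is available as an
option.

## Transport

Stokes–Einstein in both directions, D = k_B T / (3π η d), with k_B exact SI;
internal arithmetic is SI and the API uses nm / µm / s / Pa·s / K. Diffusion
length L = √(2 D τ). Capillary filling follows Washburn's law
L(t) = √(γ R cosθ t / 2η).

Confinement corrections use centerline hindered-diffusion correlations for a
sphere of relative size λ = d/D_channel in a cylindrical pore, exposed as a
correction factor R = 1/H(λ) ≥ 1 on the apparent size. Two models are
provided: `renkin` (default, R ≈ 1.053 for 50 nm in 4 µm) and
`dechadilok-deen` (R ≈ 1.088). Published analyses of this geometry quote
R_ave ≈ 1.066 from a radially averaged treatment whose full formulation is
not reproduced here; both provided models sit in the same [1.0, 1.1] band
and the package treats the model identifier as an explicit, documented
choice rather than claiming to match that figure exactly.

## Synthetic data generator

The generator is the stand-in for the experiment and its defaults are the
reference acquisition: a 50 nm gold nanosphere (d⁶ Rayleigh scattering) in a
4 µm channel of water/DMSO (η = 3.3 mPa·s, T = 293.15 K, n ≈ 1.4607),
ν = 1 kHz, τ_e = 0.2 ms exposure, N = 65,000 frames, a 16-bit camera with
≈200-count noise floor and 65,000-count saturation, 30-px transverse field
of view.

- **Brownian dynamics.** Gaussian substeps of standard deviation
  √(2D·Δt/substeps) per coordinate; 50 substeps per frame period by default,
  so 10 substeps fall inside the 0.2 ms exposure and carry motion blur.
  Transverse excursions beyond the channel radius are reflected specularly
  (radial fold-back), the simplest no-flux wall; the axial coordinate is
  unbounded. A substep rms length above R/5 is rejected as under-resolved.
  Frame-level ground-truth positions are exposure averages — what an ideal
  camera would localise.
- **Ground-truth D.** The full-pipeline runner simulates the *hindered*
  coefficient D_free/R for the configured particle, so the downstream
  hindrance correction is exercised honestly and recovers the configured
  free-solution diameter.
- **Scattered intensity.** I_s = C · (d/100 nm)⁶ · ⟨I_illum⟩ averaged over
  the exposure substeps. Under the flat field its noise-free relative spread
  is percent-level and bounded by the closed-form field envelope along the
  realised trajectory (dominated by the axial beam decay over the particle's
  ±10–15 µm axial wandering, ≈0.2 %/µm at z_a = 1 mm).
- **Camera rendering.** Airy point-spread function (first zero at
  0.61 λ/NA ≈ 1.30 µm for the 10×/0.25 objective), evaluated through a
  1 nm-sampled radial lookup table, stamped at each exposure substep;
  Poisson shot noise on the signal, Gaussian read noise (default 10 counts),
  the noise-floor offset, integer quantisation and clipping at saturation.
  Depth-of-field blur is ignored (the stated 10 µm depth of field exceeds
  the 4 µm channel). The absolute counts per particle are not published, so
  the photon scale is calibrated to place a centred particle at ~20,000 peak
  counts — mid-range of 16 bits, keeping both noise floor and saturation
  relevant. The axial rendering window re-centres on the particle when it
  approaches an edge (per-frame origins are recorded, ground truth keeps
  absolute z), which lets long runs use a reduced field of view.

What the generator does *not* emulate: multi-particle occlusion, beam
pointing/power drift, thermophoresis, liquid inhomogeneity, camera
nonlinearity and fixed-pattern noise. Passing synthetic tests therefore
demonstrates the correctness and statistical behaviour of the analysis
chain, not the performance of the physical instrument.

## Tracking

Own minimal single-particle tracker so the tests are self-contained:
median background subtraction, Gaussian smoothing (σ = 1 px), local maxima
above a count threshold with plateau merging, then subpixel refinement by
the radial-symmetry-centre method (least-squares intersection of
intensity-gradient lines — exact for symmetric spots and near the
information bound under shot noise; noise-free error is well below 0.05 px,
shot-noise-limited RMSE below 0.2 px). Saturated spots are flagged, never
dropped. Linking is greedy nearest-neighbour within a search radius
(default 5 px ≫ the ≈0.2 px per-frame rms step at 1 kHz) with gap bridging
(default 1 frame); ambiguities resolve by distance, ties by mass. The
experimental tracker's exact parameters are not published; these defaults
are documented, not claimed to match.

## Flat-field statistics

The channel cross-section is divided into a central bin and two side bins —
by default the central and outer thirds of the channel width (the published
bin extents appear only in a figure), half-open intervals [lo, hi) for
deterministic boundary assignment, configurable in µm. Intensities are
normalised to their mean, histogrammed per bin as occurrence probabilities
(Freedman–Diaconis binning — the original binning rule is unstated) and
fitted with Gaussians by bounded nonlinear least squares initialised from
the sample moments; the peak location is constrained to the sample range so
edge-peaked distributions (leaky illumination) peg at the boundary instead
of diverging. Reported metrics, after renormalising by the CB peak:

- δI_max = 100·(μ_CB − μ_SB)/μ_CB — positive when the centre is brighter
  (guided-like), negative when the sides are brighter (leaky-like), near
  zero for a flat field. The sign convention is fixed by the published
  example where μ_SB > μ_CB gives −0.23 %.
- δI = 100·σ_I/Ī of the full series, and its skewness as a symmetry
  diagnostic.

The experimental values of δI (5.7 %), the Table-style FWHMs and bin counts
depend on unavailable raw video and are treated as plausibility references
only; the synthetic flat-field run is required to stay below |δI_max| = 1 %
while a 2.5:1 centre-peaked profile exceeds the flat value more than
tenfold.

The dynamic-range calculator δd = (I_max/I_min)^(1/6) converts the camera's
usable count range into the ratio of simultaneously detectable diameters
(≈2.6 for 200 → 65,000 counts).

## MSD analysis and sizing

The MSD uses the axial coordinate only (1D, D = slope/2): transverse motion
is wall-confined and would bias a multi-dimensional MSD. All overlapping
pairs enter each lag (N − k pairs at lag k). The default fit uses the first
two lag times with a free intercept: with negligible localisation error the
shortest lags carry the greatest statistical weight, and the intercept
diagnoses localisation error (motion blur contributes −2Dτ_e/3, of order
10⁻⁴ µm² here — the clean-data tests assert an intercept near zero). Fitting
beyond four lags triggers a warning. The hydrodynamic diameter is
d_h = k_B T / (3π η (D_meas·R)) with R the hindrance factor (R = 1 reduces
to bare Stokes–Einstein).

Uncertainty is a block standard error: D is re-estimated on 20 contiguous
non-overlapping segments and the standard error of the full estimate is
std/√20, propagated to d_h via σ_d/d = σ_D/D. The estimator spread follows
the information-bound scaling σ_D ∝ 1/√N, verified by Monte-Carlo replicates
at N = 4,000 vs 16,000.

## Problem sizes and numerical choices

The experiment-scale synthetic acceptance run uses the full N = 65,000 frames at
1 kHz with a 30 × 128 px rendering window (the re-centring window makes the
long 600 px sensor unnecessary) and completes in a few minutes on one core;
video is rendered and tracked in 2,000-frame chunks so memory stays flat.
The uniformity test of the confined walk uses faster-mixing parameters
(D = 10 µm²/s at 50 Hz sampling) so that widely spaced samples are
effectively independent for the χ² test. Statistical assertions use fixed
seeds; tolerance bands are three standard errors unless a printed precision
applies. Degenerate inputs (zero diffusion, constant intensity series,
empty channels, saturated spots, non-positive MSD slopes) raise explicit
errors rather than propagating silently.

## Known limitations

- The scalar propagator is qualitative for mode-field magnitudes; no
  polarisation, no 3D geometry, no outer-wall reflections.
- Hindrance models are centerline correlations; no radial averaging or
  exposure-blur coupling.
- The tracker is single-particle by design; linking is not multi-hypothesis.
- Axial-only MSD assumes drift-free motion along the channel; no
  confined-MSD plateau correction (the first lags are required to be linear
  instead).
- Viscosity and refractive index of the water/DMSO mixture are inputs, not
  computed from the mixing ratio or temperature.
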