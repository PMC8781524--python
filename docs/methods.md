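# Methods

## Scope and model

`psoct` simulates and analyzes polarization-sensitive OCT (PS-OCT) B-scans
of layered, scattering, birefringent samples: elastomer phantoms that mimic
the bladder wall, and single-layer PDMS slabs stretched in a clamp rig.
Two channels are modelled per scan:

**Retardation.** Cumulative phase retardation through a birefringent medium
grows linearly with the one-way physical path z at constant birefringence
Δn:

    δ = 2π Δn z / λ

with λ the center wavelength (1300 nm by default). Per layer i the
simulator accumulates 2π Δn_i z_i / λ (z_i = path inside layer i), converts
to degrees, and folds the result into [0°, 90°] by triangle-wave reflection
(period 180°, reflections at 0° and 90°) — the standard display convention
for PS-OCT retardation maps. No round-trip factor is inserted: the forward
model and the inverse fit use the same one-way convention, so Δn recovered
from simulated data is directly comparable to the configured value. The
inverse is the same relation read off a straight-line fit: the slope of
retardation vs depth in deg/μm, converted to rad/m, gives
Δn = slope · λ / 2π.

**Intensity.** One-way Beer–Lambert decay, I(z) = I₀ exp(−Σ μ_i z_i), with
per-layer attenuation coefficients μ in mm⁻¹ applied to the linear-scale
intensity. No confocal gating or sensitivity roll-off is modelled; the
attenuation coefficient is a single per-layer scalar. Fully developed
speckle is modelled as multiplicative unit-mean exponential noise on the
linear intensity; retardation noise is additive Gaussian (in degrees)
applied before folding. Pixels outside the sample carry a constant
background level plus retardation noise only.

**Depth sampling.** The axial pixel grid measures optical path in air: a
physical depth z in a medium of group index n lands on pixel
round(n·z / Δ_px). The default Δ_px = 2.75 μm is half the 5.5-μm axial
resolution of the emulated 1300-nm system; the lateral spacing defaults to
7.8 μm. Analysis converts pixel counts back to physical thickness by
dividing by an assumed index of 1.4 (PDMS and soft tissue alike), matching
the simulator's default so forward–inverse round trips are exact up to
pixel quantization.

## Extraction procedure

Analysis of a B-scan pair proceeds in four steps:

1. **Surface segmentation.** The intensity image is median-filtered (3×3),
   log-scaled to dB, linearly rescaled into a 256-bin histogram, and
   thresholded with Otsu's method (maximum between-class variance; ties
   broken toward the smallest bin index). Log scaling is used because the
   exponential depth decay otherwise concentrates nearly all sample pixels
   in the lowest bins and the threshold lands far above the deep signal;
   dB is also the scale on which OCT images are displayed and thresholded
   in practice. Per column, runs of ≥ 3 consecutive suprathreshold pixels
   define the sample: the first run's first pixel is the top surface, the
   deepest run pixel bounds the detectable depth. If that bound touches
   the bottom of the frame the bottom surface is "not visible" and only a
   maximum detection depth is recorded. Columns with no qualifying run are
   flagged invalid and excluded downstream.
2. **Flattening.** Each valid column is shifted up by its top index so the
   surface lies at row 0. Shifts are integer pixels (no subpixel
   resampling, which would interpolate and therefore alter retardation
   values); vacated pixels become NaN and are excluded from every average.
   The shifts are recorded, so the sample region inverts exactly; the
   above-surface background discarded by the shift is not recoverable and
   returns as NaN.
3. **Lateral averaging.** The flattened retardation is averaged across
   valid columns over a 2-mm region (256 columns at 7.8 μm) by default,
   ignoring NaNs; depths supported by fewer than half the selected columns
   are dropped. The depth axis is converted to physical μm below the
   surface.
4. **Slope fitting.** Ordinary least squares of mean retardation vs depth
   inside a window, truncated at the maximum detection depth and at the
   first depth where the profile exceeds 80° (so only the monotone
   pre-fold region is fitted). Windows that start at the surface skip the
   first 10 μm (specular surface pixels). Negative slopes yield negative
   Δn, reported rather than clipped — thin, near-zero layers routinely fit
   slightly negative.

For bladder samples the windows follow the tissue convention: urothelium
0–50 μm below the surface, lamina propria (LP) the next 200 μm; phantom
analysis adds a muscularis propria (MP) window below the 450-μm LP bottom,
and the diseased (carcinoma-in-situ) case replaces urothelium+LP with one
450-μm "fused" window. The MP window is usually truncated by the detection
depth, mirroring the strong signal attenuation that prevents MP analysis
in real scans.

## Fold-bias-corrected fitting

The displayed retardation is folded at 0° and 90°, so additive noise
biases the *mean* upward wherever the true retardation sits within ~2σ of
the 0° fold: for Z standard normal,

    g(μ) = E[fold(μ + σZ)] = μ + 2[σ·φ(μ/σ) − μ·Φ(−μ/σ)].

With the 2° noise level used throughout and the shallow tissue windows
(δ spans 0–7° across the LP window), a naive OLS fit of the folded means
underestimates the LP slope by ≈ 19% — far outside the intended accuracy.
The fitter therefore inverts g pointwise on the laterally averaged profile
before regression, using the noise σ estimated from above-surface pixels
(pure folded noise with mean σ·√(2/π)). g is strictly increasing with
g(0) = σ√(2/π); observed means at or below g(0) map to 0, and values above
45° use the mirrored relation at the 90° fold. With σ = 0 the correction
vanishes and the fit is plain OLS, so noise-free round trips are exact to
quantization.

Two consequences are worth knowing. First, g′(0) = 0, so the inversion
amplifies sampling noise where the true retardation is near zero: the
standard error of the fitted Δn shrinks as 1/√n_columns in the linear
regime away from the fold but more slowly across near-zero windows. A
near-zero layer observed through the fold with 2° noise has an irreducible
single-scan Δn scatter of order 1–2×10⁻⁵ regardless of estimator — the
same reason real urothelium fits scatter widely and sometimes go negative.
Second, every fit reports a standard error propagated from its residual
scatter (which already carries the amplification), and the design-criteria
validator uses it: a layer passes its birefringence-class target either
when the point estimate lies in the class range or when the ±2 s.e.
interval is consistent with it. Point values supplied without a standard
error are checked against the range alone. The demo workflow additionally
averages five replicate scans per condition, the replicate count used for
characterization curves, before validating.

## Stretch mechanics and calibration

Uniaxial clamp stretch is parameterized by the length ratio (elongated /
original clamp separation, original 6 mm by default, advanced in 2.5-mm
increments in the reference protocol). The clamps fix the width, and the
elastomer is treated as incompressible, so all thinning goes into the
thickness: every layer's thickness divides by the length ratio, exactly.
Engineering stress is σ = P / (L1·L2,0) with the *relaxed* cross-section.

Stretch-induced birefringence is supplied by a per-curing-ratio anchor
table, interpolated piecewise-linearly in length ratio and never
extrapolated (the reachable stretch before clamp slipping differs per
recipe, and no functional form is established). Two anchor facts are
measured: every curve passes through (1, 0), and the 20:1 recipe reaches
Δn = 2.1×10⁻⁴ at roughly five-fold stretch. **All other shipped anchors
are synthetic placeholders** that reproduce the qualitative trends (lower
curing ratios stiffen, gain birefringence faster, slip sooner) and should
be replaced by user measurements for quantitative work. Non-photoelastic
materials (Dragon-Skin-like) keep Δn = 0 at every stretch. Scatterer
(TiO₂) weight fraction is decoupled from the calibration, reflecting the
observed independence of the birefringence–stretch rate from scatterer
load. Campaign force values come from a synthetic linear stress–stretch
law (configurable effective modulus, 50 kPa default); they exist only to
populate the stress axis of characterization curves.

## Bladder design models

The normal model is urothelium 50 μm (AC 0.8 mm⁻¹, Δn 0, Dragon-Skin-like),
LP 400 μm (AC 3.5, Δn 1.18×10⁻⁴, 15:1 PDMS), MP 1600 μm (AC 1.5, 25:1
PDMS). The diseased model fuses urothelium+LP into a 450-μm near-zero-Δn
layer with graded attenuation (2.2 mm⁻¹ at the top to 1.8 near the MP,
represented as two sublayers) over an unchanged MP. Default Δn values are
the measured ex-vivo tissue means (normal LP 1.18×10⁻⁴; CIS fused layer
3.21×10⁻⁵); the MP default, 4.50×10⁻⁵, is the level achieved in the
fabricated reference phantom, since tissue MP lies beyond reliable
imaging depth and carcinoma in situ does not invade the muscle. A separate
table (`ACHIEVED_PHANTOM_DELTA_N`) carries the per-layer values measured
in the fabricated reference phantoms; the demo uses it so that simulated
"as-built" phantoms validate against the design criteria the way built
ones do. Birefringence classes used by the validator — none [0, 1×10⁻⁵),
low [1×10⁻⁵, 7×10⁻⁵), moderate [7×10⁻⁵, ∞) — are package-defined ranges
chosen so the reference measurements fall where expected; they are not
measured boundaries. The normal-vs-diseased call thresholds the LP/fused
window Δn at the geometric mean of the two tissue means (≈ 6.2×10⁻⁵),
boundary assigned to diseased.

## What the simulator does and does not capture

The generator reproduces the features the extraction pipeline is sensitive
to: per-layer exponential decay with realistic attenuation coefficients
(0.8–3.5 mm⁻¹), linear retardation growth with Δn in [0, 2.5×10⁻⁴],
multiplicative speckle, additive folded retardation noise (2° default),
surface tilt/roughness via a per-column surface profile, and
volume-conserving layer thinning under stretch. It does not model full
Jones/Mueller propagation, the optic-axis channel, diattenuation,
polarization mode scrambling by multiple scattering, confocal/roll-off
depth sensitivity, or motion. Passing round-trip tests therefore
demonstrates that the *analysis* is correct and unbiased under the stated
noise model, not that the noise model captures every artifact of a
physical instrument; imported instrument data can be analyzed through the
same pipeline but may need its own noise estimate and window choices.

## Numerical choices and problem sizes

- Default frame: 1200 × 320 pixels (3.3 mm optical depth × 2.5 mm width),
  enough to hold the 2.05-mm bladder stack at n = 1.4 under a tilted
  surface with background above and below.
- Otsu ties break toward the smallest qualifying bin; the histogram uses
  256 bins after min–max rescaling.
- Surface detection requires 3 consecutive suprathreshold pixels
  (rejecting isolated speckle hits) after a 3×3 median filter. The filter
  blurs abrupt column-to-column surface jumps by design; exact whole-pixel
  surface recovery holds with smoothing disabled.
- Fits require ≥ 3 points and nonzero depth spread; layer windows whose
  start lies beyond the detection depth are reported absent, not fitted.
- Replicate spread uses the sample (n−1) standard deviation; single
  replicates report zero spread.
- All stochastic paths are driven by explicit integer seeds
  (`numpy.random.default_rng`); campaign and multi-seed workflows derive
  child seeds from a `SeedSequence`, so identical seeds give bit-identical
  outputs.
- Test and demo problem sizes (20 seeds × one frame for noisy recovery,
  five replicates per condition, 96–320 columns) were chosen so the full
  suite runs in well under a minute while leaving across-seed standard
  errors an order of magnitude below the tolerances being checked.

## Known limitations

- The anchor calibration is honest only at (1, 0) and the 20:1 maximum;
  everything between is a labelled placeholder.
- Near-zero Δn windows have wide single-scan confidence intervals (see
  fold bias above); averaging replicates or widening windows is the only
  remedy, and the validator is deliberately tolerant there.
- Layer interfaces are not segmented; per-layer thickness is available
  only as total top-to-bottom thickness plus the fixed window convention.
- Attenuation coefficients are treated as one-way exponential rates; if an
  instrument's values follow a round-trip convention they must be halved
  before simulation.
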