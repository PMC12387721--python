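# Methods

This note records the model, the numerical choices and their rationale, and
what the synthetic validation does and does not demonstrate.

## Measurement model

**Body stage.** The phantom is assumed to be a single, roughly circular,
water-equivalent object surrounded by air.  Thresholding at −200 HU
separates body from air by a wide margin on both sides; the largest
8-connected component rejects couch/cable debris, and hole filling keeps
air-filled inserts inside the body.  The diameter is the equivalent-circle
diameter 2·√(area/π) of the filled mask, which is robust to boundary
pixelation (measured error < 0.05 px on analytic disks of 100–250 mm).
Masking the exterior to exactly 0 HU reproduces the element-wise
multiplication convention and gives pin windows that exclude 0 a clean
background.

**Pin stage.** Each material's HU window is thresholded on the masked
image, restricted to radii < 0.8× the body radius so the phantom shell and
edge cannot enter high-density windows.  Components must have an area
within [25%, 400%] of the template's nominal pin area (nominal radius
12.5 mm by default), which removes noise speckle and merged fragments.
Centroids are binary-mask centroids — intensity weighting is deliberately
not used, matching the convention that centroids come from the thresholded
binary images.  Where windows overlap (AAPM acrylic 80–165, polycarbonate
100–114, nylon 80–115 HU), HU alone cannot identify the pins; candidate
components pooled across the overlapping group are assigned to materials by
minimizing total angular distance to the template's expected polar angles
(Hungarian assignment).  This is the only place layout knowledge is used.

**ROIs and CNR.** The inner ROI is a disk of diameter *D*/10 at the
centroid (nearest-pixel membership at pixel centres).  The background
region is a concentric annulus outside the pin edge, 1.5 pin radii in outer
extent, clipped to the body and away from all other pins (1.6× their
radii).  Its inner boundary is offset from the pin edge by a 2 mm **edge
guard**: the blurred edge transition decays over several σ of the
reconstruction blur, and without the guard the transition tail inflates the
background standard deviation by an order of magnitude, destroying the CNR.
2 mm is 4σ of a typical 0.5 mm blur; pins smaller than ~4 mm radius would
need a proportionally reduced guard.  CNR = |μ_inner − μ_annulus| /
σ_annulus.  A noiseless background makes this ratio diverge; it is reported
as `inf` with a `zero-noise` flag rather than an error so that ideal
synthetic images remain measurable.

**ESF sampling.** Every pixel within pin radius + `added_size` of the
centroid contributes one sample at signed radial distance (negative inside
the pin).  `added_size` defaults to one pin radius — enough background
plateau for a stable baseline without reaching neighbouring structures.
The edge radius used as the distance origin is refined from the radial
profile's crossing of the midpoint between robust plateau medians, so the
segmentation-derived radius only seeds the estimate.

**Phase alignment.** Samples are grouped into 32 angular sectors (≈11°;
enough samples per sector at typical pixel sizes, fine enough to track
sub-pixel centre error and mild ellipticity).  Each sector's
distance-sorted profile is smoothed with a 15-sample moving average and the
radius where it crosses the global mid-level becomes the sector's phase
shift.  Sectors without a crossing are dropped; more than half dropping
aborts with an alignment error (typically meaning near-zero contrast).
This is a statistical mid-level-crossing estimator — fast and closed-form;
it is our own variant, not a reproduction of any published estimator's
exact form.

**Logistic fit.** ESF(x) = a/(1+exp(−b(x−c)))+d fitted with SciPy's
`least_squares(method="dogbox")`, a dogleg-type trust-region scheme.
Initialization: d from the inner plateau median, a from the plateau
difference, c from the mid-level crossing, b from the 25–75% transition
width (b = 2·ln 3/Δx₂₅₋₇₅).  Restarts at 0.3× and 3× the initial rate guard
against a poor width estimate.  The amplitude sign is free, so dark pins
(air) fit with a < 0 and |a| is the contrast.  Fits with |a| below 3× the
background noise carry a `low-contrast` flag; |a| ≈ 0 is rejected as
degenerate.

**LSF and TTF.** The LSF is the analytic derivative of the fitted logistic
— |a|·b/4·sech²(b(x−c)/2) — evaluated on a uniform 0.02 mm grid over
±20/b mm.  Analytic differentiation is exact and noise-free; differencing a
fitted curve would only add discretization error.  The grid extent puts the
tails below 4×10⁻⁹ of the peak (the "zeroing"); the samples are normalized
to sum 1 (unit area), so the DFT is exactly 1 at zero frequency.  The TTF
is the modulus of the FFT after zero-padding to ≥ 4096 points, giving a
frequency spacing of ~0.012 mm⁻¹ at the default grid; f50 and f10 are
linearly interpolated at the first downward crossings of 0.5 and 0.1, with
a flag if the spectrum re-rises above the threshold afterwards.  Against
the closed form s/sinh(s) these defaults are accurate to ~10⁻⁸ in TTF
amplitude and < 0.1% in f50/f10.

With curve fitting disabled, the TTF comes from the binned empirical ESF
(0.1 mm bins) differentiated numerically, baseline-zeroed from the tail
medians and Hann-windowed — noisier, but within ~10% in f50 at high CNR,
which is its purpose as a cross-check on the fit.

## Synthetic phantom generator

The generator emulates an axial slice of a multi-pin phantom: a 200 mm
water-equivalent disk (0 HU) in air (−1000 HU) with disk inserts at
material-typical CT numbers, on a 512-pixel, 200 mm field of view
(0.39 mm pixels) by default.  Degradation is an isotropic blur kernel with
a closed-form TTF — Gaussian (σ in mm, applied spatially) or a
logistic-OTF kernel (applied in the frequency domain, whose edge response
is exactly a logistic of rate b) — plus i.i.d. Gaussian noise per pixel
from a seeded generator.  Default conditions are σ = 0.5 mm and 5 HU
noise, which put the four ACR-style pins at CNR ≈ 19–200.  A per-material
kernel map blurs each insert with its own kernel (by linearity of the
blur), emulating the contrast-dependent resolution of iterative and
deep-learning reconstructions.

Geometry is rasterized at 8× supersampling, the kernel is applied at that
resolution, and the final image samples the blurred field at pixel centres
(mean of the central 2×2 subsamples, an effective aperture of ¼ subpixel,
MTF ≥ 0.999 over the band of interest).  Point sampling, rather than
averaging each pixel's full area, is deliberate: pixel-area averaging would
convolve an additional aperture-box MTF of sinc(πwf) (≈ −6% at 0.375 mm⁻¹
for w = 0.5 mm), and the generator's contract is that the *kernel's*
closed-form TTF is exactly the image's TTF below Nyquist.  Aliasing from
point sampling is negligible once the kernel attenuates the spectrum at
Nyquist (at σ = 0.5 mm and 0.39 mm pixels the Gaussian MTF at Nyquist is
< 0.01).

What the generator does **not** emulate: correlated CT noise texture
(reconstruction-filtered noise), beam hardening and other artifacts,
phantom tilt, the exact insert layouts of the physical phantoms (presets
use a plausible ring layout and are labelled synthetic), and the
non-linear behaviour of real iterative reconstruction beyond the per-pin
kernel abstraction.  Passing the validation therefore demonstrates the
correctness of the measurement chain under known blur and white noise, not
performance on any particular scanner's images.

## Validation results and known biases

The end-to-end study (50 seeds, default conditions) recovers the kernel
f50 within ~1% at CNR ≥ 100 and ~3% at CNR ≈ 20, with centroids within
0.15 px.  Two small, understood biases contribute: a least-squares
logistic fitted to an erf-shaped (Gaussian-blurred) edge understates f50
by 1.36% regardless of σ (model mismatch — the logistic's tails are
heavier), and the circular-edge curvature adds a smaller, radius-dependent
term.  Both are far inside the stated tolerances and are left uncorrected;
correcting them would presume the blur is Gaussian, which the TTF method
must not assume.

The f50/f10 ratio of any logistic fit is 2.17732/4.49995 ≈ 0.48384 by
construction; measured ratios deviate by < 10⁻⁴, so a larger deviation in
a report indicates the empirical (non-fitted) path or a flagged fit.

## Numerical and degenerate-input conventions

- Non-square pixel spacing is accepted with a warning; all distances are
  computed in mm with per-axis spacing.
- HU are floating point internally; DICOM output quantizes to signed
  16-bit with slope 1/intercept −1024 (round trip ≤ 0.5 HU).
- Uniform images (no edge) fail the fit with a degenerate-contrast error;
  ROIs with < 200 samples raise a sampling error suggesting a larger
  `added_size`; < 50 background pixels after clipping raise an
  insufficient-background error.
- Ties in the first TTF threshold crossing take the first crossing and set
  a flag.
- Batch reports process slices independently in filename order; CSV output
  uses fixed column order and `%.6g` formatting so identical inputs give
  byte-identical files.  Timestamps are confined to places that do not
  break this.

## Problem sizes

Default images are 512² (0.39 mm pixels); the recovery study uses 50 seeds
of the 4-pin preset; the oracle checks use b ∈ {1, 2, 3, 5} mm⁻¹ and
σ ∈ {0.3, 0.5, 0.8} mm; the CNR check averages 5 seeds.  These sizes give
Monte-Carlo noise comfortably below the tolerances they are tested
against.
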