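# Methods

`mammofractal` measures the local roughness of mammographic texture with the
2D wavelet transform modulus maxima (WTMM) formalism, classifies overlapping
image windows into tissue classes from their Hurst exponent, and scores
bilateral breast asymmetry per patient. This note records the model, the
numerical choices and their rationale, what the synthetic generator does and
does not emulate, and the known limitations.

## The roughness model

A mammographic subregion is modeled as a realization of an isotropic,
monofractal rough surface: intensity increments obey
`E[(f(r+e) − f(r))²] ~ |e|^(2H)` with a single Hurst exponent `H ∈ (0, 1)`.
`H < 0.5` means anti-correlated fluctuations (radiographically fatty
texture), `H ≈ 0.5` uncorrelated fluctuations (interpreted as disrupted
tissue, the signature of interest), `H > 0.5` long-range correlated
fluctuations (dense tissue).

## The WTMM estimator

1. **Transform.** `T_θ[f](b, a)` smooths the image with the L¹-normalized
   Gaussian `a⁻² exp(−|r|²/2a²)` (FFT convolution; transfer function
   `2π·exp(−a²|k|²/2)`). The analyzing vector field is the scale-adapted
   gradient `T_ψ = a·∇T_θ`, whose modulus scales like a local increment:
   `M ~ a^h` at a point of Hölder exponent `h`. The scale factor `a` in
   front of the gradient is essential — a bare gradient would scale as
   `a^(h−1)` and shift every exponent by one unit of q.
2. **Maxima chains.** At each scale, pixels where the modulus strictly
   exceeds the bilinear-interpolated value 1 px ahead along the gradient
   (and is ≥ the value 1 px behind; the asymmetry resolves flat-ridge ties
   toward the first pixel in raster order) form 8-connected chains. The
   modulus at a retained maximum is refined to the vertex of the parabola
   through the three samples along the gradient; the raw pixel value
   under-reads the crest by an amount that shrinks like `1/a²` and would
   otherwise masquerade as spurious modulus growth at fine scales.
3. **Skeleton.** Local maxima of the modulus along each chain are linked
   across consecutive scales (nearest unclaimed endpoint, greedily by
   distance) into maxima lines. The linking radius is `max(2 px, 2a)`:
   maxima positions drift by `O(a)` between log-spaced scales, and a
   tighter radius kills lines spuriously, which imprints a survivorship
   bias on both the line-count decay and the modulus growth (measured:
   `τ(0) ≈ −2.9` instead of −2 with a radius tied to the scale step).
4. **Partition functions.** `Z(q, a)` sums, over the lines alive at scale
   `a`, the q-th power of a per-line statistic. Only lines that extend down
   to the smallest analyzed scale enter `L(a)` — a maxima line carries
   meaning because it points to a singularity as `a → 0`; admitting lines
   born at coarse scales flattens the count decay to `τ(0) ≈ −1.5` and
   biases H low by ≈ 0.2. The per-line statistic is the modulus of the
   line's maximum at the current scale. The classical running-supremum
   regularization (`sup` of the modulus over the line up to scale `a`) is
   implemented and selectable, but over the ~2.5 octaves a 256-px patch
   supports the running maximum of a fluctuating line keeps creeping upward
   even when the modulus itself barely grows, inflating low-H slopes by up
   to +0.25; the per-scale modulus is asymptotically equivalent and
   measurably unbiased at this patch size, hence the default.
5. **Boundary handling.** The transform mirror-pads the patch, which pins
   the normal gradient to zero at the patch edge and depresses moduli
   within roughly one scale of the boundary. Maxima within a band of width
   `max(2 px, a)` of the true field boundary are therefore excluded, and
   `Z(q, a)` is normalized per unit analyzable area so the shrinking
   coverage does not read as extra line-count decay. When a window is
   analyzed with surrounding context (the sliding-window protocol), only
   the outer window boundary is treated this way — the core's own edge is
   clean.
6. **Scaling range and τ(q).** The automated range selector returns the
   widest contiguous scale window in which `log₂ Z(q, a)` is linear in
   `log₂ a` (R² ≥ 0.98 simultaneously for q ∈ {−1, 0, 1, 2}), spanning at
   least 1.5 octaves and at least 4 scales, and only over scales where at
   least 20 lines survive — a power sum over a handful of lines is smooth
   by accident, not evidence of scaling. No qualifying window is a
   rejection ("no-scaling"), mirroring the gray windows of the sliding-
   window protocol. τ(q) is the weighted least-squares slope per q
   (weights = line counts), with standard errors from the weighted
   residuals.
7. **Monofractality and H.** τ(q) is fit with a quadratic over
   q ∈ [−2, 3] (step 0.25), weighted by the inverse per-q standard errors
   so the noisy negative-moment branch cannot drag the fit. The patch is
   monofractal when the quadratic coefficient's magnitude is ≤ 0.05
   (τ units); then H is the linear coefficient. Stronger curvature rejects
   the patch as multifractal. `D(h) = min_q(q h − τ(q))` is available as a
   discrete Legendre transform (central differences) for diagnostics.

**Defaults.** Scales: 40 log-spaced values from 2 px to `3·side/32`
(24 px for a 256-px patch). Chains shorter than 2 px are dropped. All
floating point is 64-bit; every stochastic path takes an explicit seed.

**Measured accuracy.** On synthetic fractional Brownian surfaces at
256², across H ∈ {0.2 … 0.8} with 10 independent surfaces per value, the
per-patch mean absolute error is ≈ 0.045 with |mean signed bias| < 0.03;
per-patch standard deviation is ≈ 0.04–0.06, growing mildly with H.
Rejections concentrate at H ≥ 0.7 (smoother surfaces sustain fewer maxima
lines) and stay below 20% overall. These numbers are what the test suite
asserts; nothing beyond them is claimed.

## Sliding-window protocol

Windows of 360 × 360 px advance in 32-px steps, top-left to bottom-right;
the wavelet transform sees the full window and the maxima statistics come
from the central 256 × 256 core, so core estimates carry no patch-boundary
artifacts. A window is analyzed when the breast mask covers at least half
of its core (the mask-coverage rule is this package's choice; boundary
windows have no published convention). Classes: fatty `H ≤ 0.45`,
disrupted `0.45 < H < 0.55`, dense `H ≥ 0.55`, boundaries closed on the
outer classes exactly as printed in the protocol this package follows;
rejected windows are shown gray and excluded from metric denominators (a
config switch can include them, in which case %B+%Y+%R < 100).

Because the disrupted band is only one window-level standard deviation
wide on each side, the fraction of truly-H=0.5 windows labelled disrupted
is ≈ 0.7 in expectation and fluctuates strongly with the texture
realization; the stable observables are the mean window H and the modal
class, and the tests assert those forms. Fatty vs dense classification
(classes a full band apart) is ≥ 95% accurate per window.

## Metrics and the YB Factor

Per mammogram: %B, %Y, %R over accepted windows and the ratio %Y/%B. Per
patient: `YB Factor = (%Y/%B)_tumor / (%Y/%B)_opposite`; exactly 1 for
identical class compositions, reciprocal under breast swap. A breast with
no blue windows has an undefined ratio; such patients are excluded from
YB-Factor statistics with a logged reason rather than propagating an
infinity.

## Synthetic data

* **fBm surfaces** are synthesized spectrally (white noise shaped to
  `|k|^−(2H+2)`) on a grid 8× the requested side and center-cropped. The
  generous margin matters: with a 2× margin the missing infrared (box-size)
  spectral power measurably flattens the modulus growth of smooth surfaces
  and biases recovered H by up to −0.16 at H = 0.8. Integer bit depths
  rescale the surface to full range (default 8-bit, the dynamic range of
  digitally acquired mammograms).
* **Phantoms** fill polygonal/elliptical regions with fBm textures of
  chosen target H (defaults: fatty 0.30, disrupted 0.50, dense 0.65 —
  configuration values, not claims about real tissue), blended with a
  16-px cosine taper so region borders do not inject step singularities,
  over a full-frame or MLO-like half-elliptical breast mask.
* **Cohorts** follow the study design this package models: groups
  ILC 43 / IDC grade 1–3 (1, 27, 10) / fibroadenoma 12 / fibrocystic
  mastopathy 11 (104 patients; 81 cancer, 23 benign). Per-patient class
  fractions are drawn from a Dirichlet around baseline (fatty 0.55,
  disrupted 0.10, dense 0.35; concentration 60), per-breast fractions from
  a Dirichlet around the patient mean (concentration 150), and window
  counts from a multinomial over 2500 windows per mammogram ("several
  thousands" in the protocol). Cancer patients receive an additive shift
  of 0.15 of window share from fatty to disrupted on the tumor side only;
  benign patients are exchangeable by construction. The image-level
  generator renders each breast as horizontal tissue bands with these
  fractions; the metrics-level generator samples the same statistical
  structure directly and is what powers the statistical calibration
  studies, where rendering and wavelet-transforming hundreds of thousands
  of windows would add runtime but no information.

What the generator does **not** emulate: X-ray physics, anatomical
structure (ducts, vasculature, pectoral muscle), microcalcifications,
compression artifacts, scanner noise, or spatial correlation between the
two breasts beyond shared class fractions. Passing tests therefore
demonstrate that the pipeline recovers known roughness structure and that
the statistical machinery is calibrated — not that the effect sizes of the
synthetic cohort match clinical reality.

## Statistics

Wilcoxon rank-sum (Mann–Whitney) throughout, two-sided, exact null
distribution when the pooled sample is ≤ 20 without ties and a normal
approximation with tie/continuity corrections otherwise; p-values are
reported unadjusted (a Benjamini–Hochberg column is emitted for reference
only). Shapiro–Wilk is available for normality screening. Box-plot
summaries use linear-interpolation (type-7) quartiles and 1.5·IQR fences.
Breast-level contrasts use the tumorous breast by default (switchable);
YB-Factor contrasts are patient-level. Calibration, measured by the test
suite on the metrics-level cohort: type-I error at α = 0.05 within
[0.01, 0.10] over 200 null replicates; power ≥ 80% for the cancer-vs-benign
YB-Factor contrast over 50 replicates at the default effect.

## Degenerate inputs and determinism

Constant or feature-free patches are rejected with reason "too-few-lines";
scales whose skeleton is empty are dropped with a warning; a flat image
segments to an empty mask with a warning rather than an error. Every CSV/
JSON output embeds a SHA-256 hash of the canonical configuration JSON, and
identical inputs + configuration reproduce outputs byte-identically (floats
are serialized with fixed rounding, no timestamps).

## Problem sizes used in the test suite

Test phantoms run at 448–704 px with reduced window geometries (256- or
320-px windows, 192- or 256-px cores, 64-px stride), sizes at which a whole
phantom maps in seconds while each core still matches or approaches the
256-px analysis core of the full protocol. The Hurst-recovery study uses
70 independent 256² surfaces; the statistical calibration uses 250
metrics-level cohort replicates.

## Known limitations

* Per-window H carries an irreducible ±0.04–0.06 scatter at 256² cores;
  maxima lines are sparse (spacing ≈ 3a along chains), so the formalism
  uses far fewer numbers than the patch contains pixels. Class maps of
  borderline (H ≈ 0.45 or 0.55) tissue are correspondingly speckled.
* The automated scaling-range selector is a documented substitute for an
  unpublished selection procedure; its thresholds (R² ≥ 0.98, ≥ 1.5
  octaves, ≥ 20 lines) are this package's choices, exposed in the
  configuration.
* The monofractality screen tests only quadratic curvature of τ(q); a
  genuinely multifractal patch with small curvature over q ∈ [−2, 3] would
  pass.
* Cohort phantom images texture tissue as horizontal bands, which is
  convenient for ground truth but anatomically arbitrary; image-level
  cohort analyses should be read as pipeline integration checks only.
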