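# Methods

## The measure

The Retinal Pigment Score (RPS) summarises the colour of the retinal
*background* — the tissue left after excluding everything that is not
background: the dark surround outside the camera's field of view, the
retinal vasculature, and the optic disc. The model underlying the score is
deliberately minimal:

- **Background isolation.** Pixels at or below the 0.5th percentile of the
  grayscale distribution (Rec.601 luma, 0.299R + 0.587G + 0.114B) are
  declared border/surround. The border, vessel and disc masks are united
  and then binary-dilated with the 8-connected 3×3 structuring element for
  `round(4 · width / 600)` iterations, so the exclusion zone scales with
  image resolution and swallows partial-volume pixels at structure edges.
  The complement of the dilated union is the retinal background.
- **Representative colour.** The per-channel (marginal) median RGB over the
  background is converted to CIELAB. The median makes the estimate robust
  to residual bright or dark pixels; taking it per channel keeps the
  representative colour an actually occurring quantised value (for even
  counts the lower central element is used, for the same reason).
- **Chromaticity only.** Only (a\*, b\*) enter the score. CIELAB separates
  lightness from opponent chromatic axes, so discarding L\* removes, by
  construction, any illumination effect that acts on luminance alone. This
  is the core design claim, and it is tested end to end: two renders whose
  backgrounds share (a\*, b\*) but differ by 40 L\*-units receive identical
  scores (to 1e-6 on continuous-valued renders; 8-bit quantisation alone
  perturbs recovered chromaticity by up to ~0.5 Lab units, which is why
  the exact-invariance check runs on the unquantised path).
- **One axis.** A two-component PCA is fitted to the cohort's (a\*, b\*)
  cloud (mean-centred covariance with divisor n−1; fitted to *all* images,
  not per-participant means, with per-eye deduplication available as an
  option). The RPS is the signed projection onto the first eigenvector.
  On synthetic cohorts the first component carries ~95% of the variance,
  so little information is lost by the 1-D summary.

### Conventions that the method's description leaves open

These were genuinely open design choices; each is fixed, documented, and
configurable where it matters:

- **Grayscale rule** for border detection: Rec.601 luma.
- **Percentile definition**: linear-interpolation percentile of the full
  pixel population, threshold applied inclusively; ties all flagged. On a
  constant image every pixel is flagged and the gradability gate rejects
  the frame.
- **Rounding** of the dilation-iteration formula: half-to-even (4.5 → 4),
  as "nearest integer" leaves .5 open.
- **Structuring element**: connectivity-2 is read as the full 8-connected
  3×3 element, standard morphology terminology. The sensitivity analysis's
  3×3 perturbation kernel is fixed independently of the pipeline's element.
- **Colour conversion**: sRGB with D65/2° observer. The chain (IEC
  61966-2-1 piecewise linearisation → XYZ → CIELAB with the 6/29
  threshold) is implemented in-package with the full-precision published
  forward matrix, because library implementations round the matrix to six
  decimals, which is coarser than the 1e-3 agreement we verify against an
  independently derived reference. The white point is taken as the XYZ
  that the matrix maps RGB (1,1,1) to, so white is exactly achromatic.
- **PC sign**: PCA fixes an axis only up to sign. The score is oriented so
  that it correlates positively with a\* (falling back to b\* in the
  degenerate uncorrelated case): redder/browner backgrounds — more melanin
  — score higher. The flag is stored in the model file.
- **Transfer**: applying a fitted scale to a new cohort reuses the stored
  mean, eigenvector and orientation unchanged. Projection is affine, so
  cohort shifts along the first eigenvector move scores one-for-one and
  orthogonal shifts leave them untouched; this is tested exactly.

## Gradability

A rule-based gate replaces learned quality classifiers: an image fails if
the background covers less than 10% of the image area, more than 20% of
background pixels are saturated (≥250 in any channel), or the grayscale
interquartile range is below 5. The floors are deliberately conservative;
externally supplied quality labels can simply be applied upstream by
filtering the manifest. On bright, low-pigment synthetic images a strong
positive illumination draw occasionally trips the saturation rule — the
correct behaviour for an overexposed frame — so cohort-level analyses
always operate on the gradable subset.

## Reliability

Repeatability and inter-eye agreement use the one-way single-rater
intraclass correlation ICC(1,1) — the only one-way form in the
Shrout–Fleiss taxonomy: ICC = (MSB − MSW)/(MSB + (k−1)·MSW) from one-way
random-effects ANOVA, with exact F-distribution confidence bounds and the
conventional upper-tail F-test p-value. Subjects with missing measurements
are dropped listwise. The implementation is validated against a longhand
sums-of-squares oracle, a closed-form two-column identity, pingouin's
ICC1, a null simulation, and a coverage simulation (93–97% at the 95%
level).

The (a,b)-vs-(L,a,b) comparison harness scores the same cohort twice —
once with the standard 2-D chromaticity scale and once with a 3-component
PCA on (L\*, a\*, b\*) projected on its first eigenvector — and reports both
inter-eye ICCs and paired-difference summaries. Under per-image
illumination jitter the L-bearing variant's reliability collapses while
the chromaticity-only scale is untouched; with no illumination variation
the two agree.

## Synthetic data: what it emulates, and what it does not

The generator renders a circular field of view on a black surround
(guaranteeing the percentile border rule finds the surround), a background
colour driven by a pigment parameter p ∈ [0,1] through a linear Lab ramp —
L\*: 75→35, a\*: 10→30, b\*: 25→45 — anchored at plausible fundus tones
(light yellow-orange to dark red-brown; the anchors are synthetic
conventions chosen for unambiguous ordering, not empirical claims), a
random-walk vessel tree rendered darker than background, a brighter disc,
and two nuisance processes:

- **Illumination** — a random affine L\*-plane (offset plus tilt, each
  scaled by `illumination_sd`) applied before conversion to RGB. The
  offset component is what moves a masked median L\* between images; a
  zero-mean tilt through the field centre would barely shift it, and real
  acquisitions vary in overall exposure, so illumination includes both.
- **Noise** — `noise_sd` scales a per-image per-channel offset
  (acquisition-level exposure/white-balance jitter between captures) plus
  i.i.d. per-pixel Gaussian noise. The global component is included
  because a per-channel median over thousands of background pixels
  suppresses purely pixel-level noise as σ/√n, whereas repeat captures of
  the same eye in practice differ mainly by global exposure and colour
  balance; without it, repeat-image reliability would be essentially
  independent of the noise level.

Two eyes of one participant share a pigment value up to N(0, 0.02) jitter,
modelling strong but imperfect left–right symmetry; repeats of one eye
share pigment exactly and differ only in illumination/noise draws.
Default raster size is 128×128 (192–160 in segmenter tests): large enough
that every masking stage behaves as at native resolution (the dilation
formula yields ≥1 iteration), small enough that cohort-scale simulations
run in seconds.

Passing tests on these images demonstrates the pipeline's internal
correctness and its claimed invariances — they do not certify behaviour on
real fundus photographs, which add camera-specific colour response,
pathology, media opacity and spatially structured illumination that the
generator does not model. Cross-camera absolute standardisation is
explicitly out of scope.

The continuous-valued rendering mode (`quantize=False`) exists for
numerical experiments: it skips the 8-bit rounding step so that exact
identities (chromaticity recovery, luminance invariance) can be asserted
at float precision. File-backed cohorts are always 8-bit PNG.

## Baseline segmenter

The classical fallback segmenter (used when no masks are supplied) is a
self-contained substitute for learned segmentation: Frangi vesselness on
the smoothed intensity with hysteresis thresholding (weak ridges kept only
when connected to Otsu-strong ones) inside an eroded field of view for
vessels, and the largest connected component above the 98th in-field
percentile of the smoothed intensity for the disc. On synthetic trees it
reaches Dice ≈ 0.8–0.9; it is a test harness and a convenience, not a
competitor to modern segmentation networks.

## Numerical and degenerate-case choices

- Collinear chromaticity clouds are legal (second eigenvalue 0); only a
  zero-variance cloud aborts fitting. Fewer than 3 points is an error.
- Model JSON stores floats at full repr precision; save → load → project
  is bit-identical.
- z-scoring uses the sample SD (n−1) and refuses zero spread.
- ICC on a table with zero between- and within-variance raises rather than
  returning 0/0; identical non-constant columns return exactly 1.
- Masks must match image shape exactly; no implicit resizing.
- All randomness (generator, perturbation choice, cohort seeds) flows from
  explicit integer seeds; every CLI run is deterministic given its inputs
  and writes its resolved configuration next to its outputs.

## Known limitations

- The pigment→Lab ramp is linear and one-dimensional; real fundus colour
  varies with haemoglobin as well as melanin and is not constrained to a
  line in (a\*, b\*).
- The quality gate is heuristic; it approximates, but does not reproduce,
  learned gradability classifiers.
- The per-channel median convention differs in principle from a pixelwise
  Lab median (provided behind `median_space="lab"` for sensitivity
  checks); on constant backgrounds they coincide exactly.
- ICC confidence intervals assume the one-way normal random-effects model;
  heavy-tailed score distributions would need bootstrap intervals, which
  are deliberately not implemented to keep results deterministic.
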