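# rpscore

Continuous, illumination-robust quantification of background retinal
pigmentation from colour fundus photographs.

Most large retinal-imaging datasets skew heavily toward lightly pigmented
eyes, and algorithms trained on them can degrade on darker fundi. Auditing
and correcting that bias needs a *measurement* of retinal pigmentation that
is objective, continuous, and insensitive to how brightly an image happens
to be lit. `rpscore` implements such a measure — the **Retinal Pigment
Score (RPS)** — for researchers working on ophthalmic imaging, algorithmic
fairness and pigmentation genetics/epidemiology.

## Method

For each image:

1. **Exclusion masking.** The image border/surround is detected as all
   pixels at or below the 0.5th percentile of the grayscale intensity
   distribution. The border, vessel and optic-disc masks are united and
   dilated with an 8-connected 3×3 structuring element for
   `round(4·width/600)` iterations; the complement is the *retinal
   background*. Vessel/disc masks are ingested from any segmentation tool
   via the manifest, or produced by a built-in classical vesselness
   baseline.
2. **Chromaticity.** The background's per-channel median RGB is converted
   to CIELAB (sRGB, D65/2°). Only the chromatic axes (a\*, b\*) are kept —
   lightness L\* is discarded, which removes illumination from the measure.
3. **Scoring.** A two-component PCA is fitted to the cohort's (a\*, b\*)
   points; each eye's RPS is the projection onto the eigenvector with the
   largest eigenvalue,

   RPS = s · ⟨(a, b) − μ, v₁⟩,

   with the sign s chosen so that higher RPS means a redder/browner — more
   pigmented — background. A fitted scale (μ, v₁, s) is saved as JSON and
   can be applied unchanged to other cohorts, putting them on one scale.

Reliability is quantified with the one-way intraclass correlation ICC(1,1)
from one-way random-effects ANOVA (repeat captures of one eye, or right vs
left eye), and robustness with a mask-perturbation sensitivity analysis
(random one-iteration 3×3 erosion/dilation of the vessel+disc mask).

A synthetic fundus generator with pixel-exact ground truth (pigment-driven
background colour, vessel trees, disc, illumination planes, sensor noise)
makes the whole pipeline testable without any real imagery.

## Worked example

```sh
rpscore simulate --out cohort --n 20 --seed 7 --eyes 2 --repeats 2
rpscore score    --manifest cohort/manifest.csv --out scores.csv
rpscore fit      --scores scores.csv --out model.json --scores-out scores_rps.csv
rpscore reliability --scores scores_rps.csv --pairing repeat --out repeat_icc.json
rpscore reliability --scores scores_rps.csv --pairing eye    --out eye_icc.json
```

prints

```
wrote cohort of 20 participants to cohort
scored 80 images (0 ungradable) -> scores.csv
fitted on 80 images; proportional eigenvalues 0.958/0.042 -> model.json
ICC(1,1) = 0.980 (95% CI 0.962, 0.989)
ICC(1,1) = 0.993 (95% CI 0.984, 0.997)
```

Reading the output: the first PCA component carries 95.8% of the
chromaticity variance, so a single axis summarises background colour well;
the repeat-capture ICC of 0.980 says two photographs of the same eye get
nearly identical scores despite fresh noise and illumination draws; the
inter-eye ICC of 0.993 reflects the strong left–right symmetry of ocular
pigmentation built into the simulated cohort. Each row of `scores_rps.csv`
carries the audit trail per image — median RGB, the full L/a/b triple, the
background pixel count, gradability and the RPS.

A fitted model can be transferred to a second cohort with
`rpscore apply --model model.json --scores other_scores.csv --out other_rps.csv`,
and `rpscore sensitivity` reports how much the score moves when the
vessel+disc mask is randomly eroded or dilated.

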