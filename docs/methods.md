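# Methods

This note documents the models, conventions and design choices behind
`stripscreen`: what the pipeline computes, what the synthetic cohort does
and does not emulate, and where genuinely open choices were resolved.

## Colorimetry

A strip region of interest is an H×W grid of 8-bit RGB pixels (the
photograph-to-ROI step — localization, quality approval, white-balance
against a printed reference scale — is out of scope; the ROI is taken as
given). Twelve per-pixel channels are derived:

| model  | channels | convention |
|--------|----------|------------|
| RGB    | R, G, B  | raw 0–255 |
| HSV    | H, S, V  | hexcone on [0,1]-scaled channels; H in degrees [0,360); achromatic pixels carry H = 0 and a degenerate flag |
| YCbCr  | Y, Cb, Cr | full-range ITU-R BT.601 (JPEG/JFIF), +128 chroma offset, floating precision, clipped to [0,255] |
| CIELAB | L\*, a\*, b\* | sRGB inverse companding → published IEC 61966-2-1 sRGB→XYZ matrix → D65/2° Lab |

The BT.601 *full-range* dialect and the sRGB/D65/2° Lab path were fixed
because they are the consumer-imaging defaults for smartphone PNG/JPEG
content. The YCbCr and Lab conversions are implemented directly from the
published constants (the widely used studio-swing YCbCr variant and
higher-precision primaries-derived Lab matrices differ measurably); the
HSV conversion delegates to scikit-image, which matches the textbook
hexcone formula to machine precision.

Each channel is summarised by min, max, mean, sample standard deviation
(n−1 denominator; defined as 0 for a single pixel), range (= max − min)
and median (midpoint convention), yielding the fixed 72-name schema
`<channel>_<summary>` in channel-major order. Hue is summarised linearly
like every other channel — no circular statistics — with degenerate-hue
pixels contributing 0; this mirrors naive per-channel summarisation and is
a known caveat for strips whose hue wraps near 0°/360° (the white→purple
chemistry here stays near 280°, far from the wrap).

The longitudinal scalar is the **combined minimum RGB value**: per pixel
the unweighted mean (R+G+B)/3, minimised over the strip. "Lowest RGB
value" is inherently ambiguous (per-channel minimum, luminance minimum,
mean); the unweighted mean is the simplest scalar on the 0–255 intensity
scale and is the documented choice. Summaries use all ROI pixels; no
calibration against a photographed color reference is attempted (flagged
as future work).

## Longitudinal assembly

* **Compliance** = submitted weeks / total weeks from enrollment to
  delivery (inclusive), as a percentage.
* **Landmark datasets** (default week 25): a woman is included iff her
  earliest in-grouping event is absent or after the landmark *and* she
  submitted a test in the landmark week; both exclusion reasons are
  logged per participant so the filtering is auditable. Cases are included
  women with a later in-grouping event. Requiring the week-25 test is the
  natural reading of a week-25 analysis and is logged explicitly because
  the alternative (nearest available test) is also defensible.
* **Weekly changes**: adjacent-week differences value(w+1) − value(w) for
  the five pairs in weeks 20–25, computed only when both weeks were
  submitted, regardless of other missing weeks. Together with the week-25
  level this gives the six screen time points. Change-analysis labels
  mirror the landmark logic at the later week of the pair: events at or
  before it exclude the woman, later events make her a case.
* **Trajectory table**: combined-minimum-RGB series restricted to women
  with a test in every week from enrollment to delivery, stratified
  (IUGR > PE > PIH > normotensive), with seeded random subsampling of the
  non-IUGR strata for legible plots; IUGR women are always kept.

One test per participant-week is assumed; duplicate rows for a week keep
the last entry.

## Discrimination screen

AUC is the Mann–Whitney concordance probability with ties counted ½,
reported on the 0–100 scale. The 95% CI uses DeLong's structural-component
estimator (midrank implementation; Hanley–McNeil available as an option).
Orientation is never flipped: an AUC below 50 is reported as-is, matching
a heat map anchored at 50.

*Significance* defaults to the CI lower bound exceeding 50. A
point-estimate rule ("AUC > 50") would flag about half of all null cells
and is inconsistent with a screen that flags a small minority; it remains
available as a configurable alternative. The flag is deliberately
uncorrected for multiple testing; BH-adjusted p-values accompany the
output as a supplementary column. Cells with a single case keep a result
(the case-side DeLong variance component is then undefined and set to 0)
flagged `low_n`; cells with no cases or no controls are logged as skipped
rather than silently dropped, keeping the screen dimensions stable. A
pooled sample with no variation yields AUC 50 with a zero-width CI and a
`degenerate` flag, never a significant call.

The full screen is 72 variables × 3 groupings × 6 time points = 1296
cells. Under label permutation the significant fraction sits near the
one-sided nominal 2.5% (verified by a 200-replicate permutation test at
n = 495).

## Synthetic cohort

The generator reproduces the *statistical structure* the analysis assumes,
not the chemistry. Defaults (all overridable):

| parameter | default | meaning |
|-----------|---------|---------|
| n_participants | 495 | eligible cohort size |
| prevalence_pe / pih / iugr | 0.069 / 0.034 / 0.020 | marginal outcome frequencies |
| p_iugr_given_pe | 0.147 | IUGR frequency inside the PE stratum |
| compliance_rate | 0.67 | mean weekly submission probability |
| compliance_concentration | 1.2 | Beta concentration of per-woman rates |
| enrollment_week | 20 | gestational week at first test |
| sua_baseline_mean / between_sd / within_sd | 1.0 / 0.7 / 0.8 | latent signal (logistic units) |
| iugr_effect / pe_effect | 5.0 / 0.25 | additive latent shifts |
| strip_rows × strip_cols | 16 × 16 | ROI pixels |
| pixel_noise_sd | 8.0 | 8-bit Gaussian channel noise |

Key mechanisms:

* **Outcome exclusivity.** PE and PIH are mutually exclusive (PIH =
  hypertension without progression); the PE draw takes precedence over the
  PIH draw rather than using a joint multinomial. IUGR is drawn with
  probability `p_iugr_given_pe` inside the PE stratum and with the solved
  complement `(prev_iugr − prev_pe·p_iugr_given_pe)/(1 − prev_pe)` outside
  it, so the marginal IUGR frequency converges to the configured
  prevalence while preserving the PE–IUGR association.
* **Delivery weeks** come from a categorical distribution over
  gestational-age bands (<32, 32–34, 34–37, 37–40, >40 weeks) with
  outcome-specific weights (IUGR and hypertensive pregnancies deliver
  earlier).
* **Event weeks.** Hypertensive onset is uniform over (32, delivery] —
  most hypertensive events cluster at term — and the latent shift begins
  four weeks before onset. IUGR diagnosis is uniform over [28, delivery],
  but its latent darkness effect is present from enrollment (placental
  origin); the diagnosis week only matters for landmark eligibility.
* **Latent signal and rendering.** z_it = baseline_i + shifts + weekly
  noise drives an affine-logistic ramp from white (255,255,255) to a deep
  purple anchor (80,20,110): channel = white − σ(z)·(white − purple), the
  simplest strictly monotone map consistent with a white→purple reaction
  where darker means more analyte. A column-wise saturation gradient
  (factor 0.6→1.0) makes one strip end darkest so the per-test minimum is
  informative; Gaussian pixel noise is added per channel, clipped, and
  rounded to 8 bits.
* **Compliance** is Beta-Bernoulli: each woman draws a personal weekly
  submission probability from Beta with mean `compliance_rate`. i.i.d.
  Bernoulli weeks would leave essentially no fully compliant women,
  emptying the all-weeks trajectory view; observed self-testing cohorts
  are strongly overdispersed (rates spanning 0–100% with a large
  fully-compliant group), which the low concentration reproduces while
  keeping the mean at 67%.
* **Reproducibility.** Every participant (and every image) draws from its
  own PRNG stream spawned from the master seed, so enlarging the cohort
  never perturbs existing participants, and identical config + seed gives
  byte-identical outputs end to end.

**Effect-size choice.** `iugr_effect = 5.0` within-person-sd units places
IUGR strips deep on the ramp so that, across seeds, *every* IUGR test
keeps its combined minimum RGB below 110 while most unaffected women
exceed 110 at least once — the qualitative separation the pipeline must
detect (tail arithmetic puts the violation probability near 0.4% per
cohort). `pe_effect = 0.25` (≈0.3 within-person sd) keeps hypertensive
discrimination weak and inconsistent: the simulator is built to reproduce
a *negative* screening finding, not an idealized positive one.

**What the simulator does not emulate.** Real strip photographs vary in
illumination, exposure and perspective; the simulator renders ideal ROIs
with stationary Gaussian noise. The single logistic ramp also compresses
the extremes of the real value distribution: simulated IUGR minima span
roughly 55–95 (observed cohorts report wider ranges reaching both lower
and higher), and simulated light strips can approach white. No absolute
sUA concentration scale is modelled — latent units are logistic-ramp
units, since no quantitative sUA-to-color calibration is available.
Passing tests therefore demonstrate that the *pipeline* recovers structure
it was designed to detect under its stated assumptions, not that the
physical test has clinical validity.

## Numerical and testing notes

* Conversion exactness is tested against independently coded textbook
  formulas (1e-6 on 1,000 random pixels) and cross-checked against
  scikit-image's Lab (agreement ~1e-2, reflecting its higher-precision
  matrix); AUC is tested against brute-force pair enumeration (exact) and
  frozen DeLong CIs computed with R's pROC.
* Problem sizes in the test suite: the cohort-level checks run one default
  n = 495 cohort with 16×16 strips (~6,600 tests), a 200-replicate
  permutation null, and 50 replicate cohorts for the IUGR landmark AUC,
  rendering only week-25 strips in the replicates. These sizes give
  binomial/permutation noise well inside the asserted bands.
* The zero-effect null check aggregates per-cell mean AUCs over the 18
  grouping × time-point cells (variables within a cell are strongly
  correlated, so the cell is the right independence unit for a standard
  error).
* Degenerate inputs: empty images, empty case/control groups and unknown
  groupings raise errors; constant images produce sd = range = 0 and
  degenerate-CI AUCs; missing weeks silently produce no change rows (by
  design, logged at the dataset level).

## Known limitations

* Linear summaries of hue would misbehave for chemistries whose hue
  crosses 0°; acceptable here, documented for reuse.
* DeLong CIs are asymptotic; with very few cases (flagged `low_n`)
  coverage is approximate and the permutation machinery in the test suite
  is the better reference.
* The landmark uses the week-25 test only; no imputation or
  nearest-test fallback is provided, and no survival modelling is
  attempted.
* Combinations of color variables (multivariable classifiers) are out of
  scope; the screen is deliberately univariable.
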