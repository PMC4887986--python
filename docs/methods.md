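# Methods

## The ratio-image model

A biomarker ratio image is the pixel-wise quotient of two fluorescence
channels of the same field: a numerator biomarker whose expression
correlates with tumor aggressiveness (CD44, N-cadherin, CD74) and a
denominator biomarker that anti-correlates (CD24, E-cadherin, CD59).  The
method assumes the recorded intensity is linear in biomarker abundance
(immunofluorescence, not enzyme-amplified stains) and that nuisance
factors — section thickness, cell shape, illumination, detector gain —
act *multiplicatively and identically* on both channels, so they cancel
in the quotient.  Additive detector noise does not cancel; frame
averaging (`average_frames`, kept in floating precision) is the intended
countermeasure at acquisition time.

The continuous ratio `r = N/D` is quantized through an explicit linear
scale:

    gray = round((levels − 1) · clamp((r − r_min)/(r_max − r_min), 0, 1))

with half-away-from-zero rounding applied exactly once.  Defaults:
`r_min = 0`, `r_max = 5`, `levels = 256`, so the conventional gray-130
threshold corresponds to a ratio of 130/255 · 5 ≈ 2.55.  Because the
ratio→gray calibration of the original acquisition software is not
standardized, absolute gray thresholds are only meaningful *within* one
scale; the package records the scale in every output and refuses to pool
counts computed under different scales.

Division by zero is handled by masking, not by an epsilon: pixels whose
denominator is at or below `denominator_floor` (default 0, i.e. only
exact zeros) are marked invalid and carry gray 0.  An epsilon would
silently compress exactly the high ratios the method exists to detect.
No background subtraction or pre-smoothing is applied.

## Quantification

Segmentation is *global* only; local/adaptive thresholds are excluded
because bright fat droplets in mammary tissue mislead them.  Three
thresholds are provided:

- **fixed** (default): mask = valid ∧ gray **strictly >** t, t = 130;
- **isodata**: intermeans iteration from the overall histogram mean,
  `T ← (mean(gray ≤ T) + mean(gray > T))/2`, run until the class
  partition stops changing.  This is the exact fixed point of the
  piecewise-constant intermeans map (one further update leaves T
  unchanged); a looser "stop when ΔT < 0.5" rule can halt up to a gray
  level away from the fixed point.  The converged value is rounded
  half-away-from-zero; the iteration count is reported.
- **otsu**: exhaustive search over all 256 cuts maximizing between-class
  variance, evaluated in exact rational arithmetic (`fractions.Fraction`)
  so plateau ties are detected reliably; a plateau returns its midpoint
  rounded down.  For two spikes of equal mass at 50 and 200 the plateau
  is 50..199 and the result 124.

For bimodal histograms with a near-empty valley the two automatic methods
select essentially the same mask (Jaccard ≥ 0.95 in the test suite), but
their thresholds need not coincide: on an equal-mass mixture of
N(60, 10) and N(190, 12) the intermeans fixed point sits at 125 while the
between-class-variance maximum sits at ≈ 119–121 (scikit-image's Otsu
shows the same offset).  Both land where almost no pixels lie, so the
segmentations agree even though the thresholds differ by a few levels.

Particles are connected components of the mask — 8-connectivity by
default (the ImageJ particle-analysis convention), 4-connectivity
available — retained when their area is **≥ 5 px** (inclusive, versus the
strict `>` of the gray threshold).  Holes are not filled and image-edge
particles are not excluded.  `count_single_marker` gives the
conventional-fluorescence comparator: one channel binned to 256 levels
over its observed range (making the count invariant under intensity
rescaling), ISODATA-thresholded, labeled and size-filtered identically; a
constant image counts 0 with a warning.

## Patient scores and cohort stratification

A patient's score for a biomarker pair is the **maximum** particle count
over that patient's micrographs: fields vary in cellularity (fatty
regions), so the maximum captures the lesion's expression potential where
the mean would dilute it.  Scores sorted ascending against rank form the
Pareto series.

The low/high split replaces the visual "inflection point" with an
exhaustive search over all cut points of the sorted scores (each side
≥ 2 members; cohorts smaller than 4 are reported unsplittable, never
forced) minimizing the pooled within-group sum of squared deviations —
one-dimensional 2-means.  The cut is selected on a **log(1 + score)**
scale: particle counts are over-dispersed across orders of magnitude, and
on the raw scale the high group's large variance makes it cheaper (in
sum-of-squares terms) to absorb intermediate scores into the low group,
biasing both recovered means upward.  In Monte-Carlo runs of the packaged
DCIS preset (components 4 ± 6 and 190 ± 100, 400 cohorts of 23) the raw-
scale cut recovers group means averaging ≈ 15.6 and ≈ 229; the log-scale
cut recovers ≈ 5.0 and ≈ 197.  All reported statistics (group means,
sample SDs with n−1, Welch's t and p) are on the original count scale;
`transform="linear"` remains available.

Separation is summarized by Ashman's statistic

    D = √2 · |µ₁ − µ₂| / √(σ₁² + σ₂²)

with the conventional D > 2 cutoff flagged as `bimodal` (both SDs zero
gives D = 0 for equal means and +∞ otherwise).  **Caveat:** D > 2
supports separation but cannot by itself refute unimodality.  A forced
two-group split of even a single Gaussian sample manufactures conditional
means about 2.7 pooled-SD apart (median D ≈ 2.9 over 500 simulated
unimodal cohorts of 23 in the test suite), so the flag should be read
together with the Pareto plot, not instead of it.

Welch's t (Welch–Satterthwaite degrees of freedom) is the reported
between-group test; Student's pooled t is provided alongside.  With one
tight and one wide group the two differ materially: Welch's effective df
collapses to roughly the high group's n − 1, so at these cohort sizes
Welch p-values near 1e-4 correspond to Student p-values near 1e-6.  The
"indistinguishable results" equivalence between the two tests is verified
in the regime where such claims live — equal-variance groups of 12 and 11
at the study's weakest significant contrast (ages 50 vs 64 years, SD 8,
≈ 1.75 SD), where |Δp| < 0.01 holds in > 99% of simulations.  Under a
null effect with groups this small, the agreement rate is ≈ 94%.

Multi-pair classification: a patient is `low_BRIM` iff every pair's score
is at or below its inclusive bound — defaults CD74/CD59 ≤ 2,
CD44/CD24 ≤ 2, N-cad/E-cad ≤ 49 (the higher N-cad/E-cad bound absorbs
stromal N-cad-high/E-cad-low cells).  The rule is monotone (raising a
score never demotes a patient to low) and fully configurable; published
descriptions of which pair carries the < 50 bound are internally
inconsistent, so the default follows the textual rule and the
configuration is the escape hatch.  `compare_single_vs_ratio` reduces the
single-marker and ratio counts to per-patient maxima and reports
Pearson's r across patients.

## The synthetic-data generator

`generate_scene` renders a pair of 16-bit channels (default 256 × 256 px)
containing cells as Gaussian-profile disks, amplitude · exp(−d²/2r²)
truncated at 3r, on a baseline of 100 counts with cell amplitude 2000.
A cell's phenotype sets its numerator:denominator amplitude ratio — high
cells 4:1 (peak noiseless ratio ≈ 3.5, gray ≈ 178, comfortably above the
130 line), low/background cells 1:1 (gray ≈ 51, comfortably below).  Both
channels are multiplied by one shared smooth positive field
(Gaussian-filtered white noise, correlation length 40 px, amplitude
within [1 − a, 1 + a], default a = 0.2) and optionally by a shared
horizontal sinusoidal ripple emulating knife chatter; these cancel in the
ratio by construction.  Per-channel noise is signal-dependent
(Poisson draws at variance = gain · signal, gain 2) plus additive
Gaussian read noise (SD 5), drawn independently per channel.

Cells sit on a jittered grid (spacing 13 px, jitter ± 1 px, radii
N(1.8, 0.2) clipped to [1.3, 2.1] px).  The spacing/radius budget is
chosen so that neighbouring supra-threshold regions can neither touch nor
be bridged: at the closest possible centers (11 px) the midpoint's
noiseless ratio stays ≈ 40 gray levels below threshold, beyond the reach
of shot noise.  Every high cell's supra-threshold area (≥ 16 px for the
smallest radius) passes the 5-px filter, so with noise off the pipeline
count equals the number of rendered high cells exactly — the scene's
ground truth — and requesting more cells than grid slots raises a packing
error rather than degrading silently.  An optional duct annulus adds
equal-intensity wall structure to both channels and labels cells
intraductal vs stromal by position; placement is a geometric convenience,
not a model of real tissue architecture.

Cohorts: each patient draws a mixture component governing the
per-micrograph number of high cells, then per-micrograph counts as
`round(max(0, Normal(µ, σ)))` — a *censored* normal, piling probability
mass at zero as clinically quiet samples do.  (Parameterizing the published
group statistics as conditionally-truncated normals is not an option even
in principle: a left-truncated-at-0 normal has coefficient of variation
< 1, while the quiet components published for these cohorts have CV
1.5–2.4.)  Note the censored mean exceeds µ when µ/σ is small — e.g. a
(5, 12) component yields scores with expectation ≈ 7.7 — which is the
price of keeping the published values as the generating parameters.
Components and diagnosis classes are apportioned across patients by
largest-remainder rounding of their weights with seed-shuffled
assignment, so subpopulation sizes are determinate (12/11 for equal
weights over 23 patients).  Per-micrograph targets are capped at the
scene's packing capacity (331 cells with the default background), which
trims the extreme upper tail of the high component by ≈ 2 counts in
expectation.

Packaged presets take their component parameters from the published
cohort statistics: `paper_dcis` (23 patients, components 4 ± 6 and
190 ± 100, equal weights — the subpopulation sizes were not published and
the weights are configurable), `fibroadenoma` (16 patients, 5 ± 12),
`idc` (26 patients, 76 ± 94).  The presets use **one micrograph per
patient**: the published statistics describe the plotted per-patient
scores (the max over micrographs), and drawing several i.i.d. counts per
patient and taking their max would inflate the high component by roughly
σ · E[max of m standard normals] (≈ +100 for m = 4).  The general
`CohortConfig` supports any `micrographs_per_patient` for pipelines whose
components describe per-micrograph counts directly.

All randomness flows from explicit seeds (master seed → per-patient
seeds → per-scene seeds); no global state is touched, and the artifact
field consumes the random stream identically at every amplitude so that
amplitude-0 and amplitude-0.4 runs of the same seed are cell-for-cell
comparable.

### What the generator does and does not emulate

It reproduces the physics the method's claims rest on: shared
multiplicative artifacts (they must cancel), independent channel noise
(it must not create spurious particles), phenotype contrast spanning the
threshold, count mixtures across patients.  It does not attempt
histology: no real stromal/intraductal spatial statistics, no H&E
texture, no antibody cross-reactivity or spectral bleed-through, no
section-to-section registration error.  Passing tests therefore certify
the *pipeline arithmetic* under controlled conditions, not performance on
real slides.

## Problem sizes and runtime

Scenes are 256 × 256 px and cohorts 16–26 patients with one rendered
micrograph pair each, so a full cohort run (simulate → ratio → quantify →
stratify) takes a few seconds on one CPU; the complete test suite,
including a 20-replicate separation study and a 1000-mask labeling oracle
comparison, runs in about a minute.

## Known limitations

- The recovered high-group mean is an upwards-biased estimator of the
  generating mean (the split conditions on scores above the cut) and the
  low group inherits any low-tail draws of the high component; at the
  packaged parameters these biases are within two standard errors of the
  generating means, but they are not zero.
- With components as overlapping as 4 ± 6 vs 190 ± 100 at n = 23,
  Welch's p between the recovered groups straddles 1e-4 across seeds
  (Student's pooled p is consistently far smaller); see the test suite's
  separation-significance check.
- Ashman's D after a forced split cannot certify bimodality (above).
- The fixed gray-130 threshold is meaningful only under the default
  ratio scale; changing `r_min`/`r_max` without re-deriving the threshold
  silently changes what is counted — hence the scale-pooling guard.
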