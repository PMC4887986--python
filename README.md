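# brim — biomarker ratio imaging microscopy

`brim` implements biomarker ratio imaging microscopy (BRIM), a
digital-pathology technique for stratifying breast lesions — in particular
ductal carcinoma in situ (DCIS), which conventional histopathology cannot
separate into aggressive and non-aggressive forms.  A fluorescence
micrograph of a biomarker whose expression **rises** with tumor
aggressiveness (CD44, N-cadherin, CD74) is divided, pixel by pixel, by a
micrograph of a paired biomarker whose expression **falls** with
aggressiveness (CD24, E-cadherin, CD59).  Optical path-length artifacts
(section thickness, cell shape, illumination) multiply both channels
equally and cancel in the quotient, leaving a high-contrast map of the
aggressiveness-linked expression ratio.

The package is for image-analysis and translational-research groups who
want the complete pipeline behind that idea:

1. **Ratio images** — `gray = round(255 · clamp((N/D − r_min)/(r_max − r_min), 0, 1))`
   with an explicit scale (default ratio 0–5 over 256 gray levels), a
   validity mask instead of division-by-zero epsilons, and frame averaging.
2. **Particle quantification** — a global gray threshold (fixed `> 130` by
   default; ISODATA intermeans and exhaustive-search Otsu as automatic
   alternatives), 8-connected component labeling, and a ≥ 5 px size filter.
3. **Patient scoring and cohort stratification** — per-patient score =
   max particle count over micrographs; ascending Pareto ordering; an
   exhaustive two-group split minimizing within-group sum of squares (cut
   selected on a log(1+score) scale); Ashman's bimodality statistic
   `D = √2·|µ₁−µ₂| / √(σ₁²+σ₂²)` with D > 2 read as clean separation;
   Welch and Student two-sample tests; multi-pair low/high-BRIM
   classification; single-marker vs ratio-count correlation.
4. **Synthetic cohorts** — a generator that renders two-channel micrographs
   of cells with known phenotypes under a shared multiplicative artifact
   field plus per-channel detector noise, and whole cohorts whose
   per-patient counts follow configurable mixture components, so every
   stage is testable against ground truth.

## Worked example

Simulate a 23-patient DCIS cohort whose per-patient high-ratio cell counts
come from a two-component mixture (means ± SD of 4 ± 6 and 190 ± 100,
equal weights), run the full pipeline on the rendered image pairs, and
split the cohort:

```python
import brim

run = brim.run_synthetic_cohort(brim.preset_cohort("paper_dcis", seed=1))
split = run.result.split
print("scores:", [int(s) for s in run.result.series.scores()])
print(f"low:  mean {split.low_mean:.1f} sd {split.low_sd:.1f} (n={len(split.low_members)})")
print(f"high: mean {split.high_mean:.1f} sd {split.high_sd:.1f} (n={len(split.high_members)})")
print(f"Ashman D = {split.ashman_D:.2f}  bimodal = {split.bimodal}")
print(f"Welch t = {split.t_statistic:.2f}, p = {split.p_value:.2e}")
```

prints

```
scores: [0, 0, 0, 0, 0, 0, 0, 0, 1, 4, 4, 7, 10, 81, 108, 123, 140, 144, 177, 191, 308, 324, 326]
low:  mean 2.0 sd 3.3 (n=13)
high: mean 192.2 sd 93.2 (n=10)
Ashman D = 2.88  bimodal = True
Welch t = -6.45, p = 1.17e-04
```

The ascending score list is the Pareto series; its inflection separates a
quiet subpopulation (mean 2.0, resembling benign fibroadenoma) from a
high-scoring one (mean 192, resembling invasive carcinoma) — recovering
the generating component means 4 and 190 from the rendered images alone.
Ashman's D > 2 supports clean separation of the two groups.

The same pipeline is available as a command-line tool:

```sh
brim run-all --preset paper_dcis --seed 1 -o out/
# out/simulate/   TIFF tree + manifest + ground truth
# out/ratio/      8-bit ratio TIFFs + JSON sidecars + validity masks
# out/counts_manifest.csv
# out/stratify/   scores.csv, pareto.csv, split.json, classification.csv
```

plus `brim ratio`, `brim quantify`, `brim stratify` and `brim simulate`
for the individual stages (see `--help`; exit codes: 0 success, 2 bad
input, 3 degenerate statistics).

## Limitations

The synthetic generator reproduces the imaging physics that the method
relies on (shared multiplicative artifacts, channel noise, thresholdable
phenotype contrast) but not histological texture; see `docs/methods.md`
for the model, its parameters, and known caveats — including why a forced
two-group split inflates Ashman's D and why Welch's test is slightly
weaker than Student's on these group sizes.
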