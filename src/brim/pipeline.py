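"""End-to-end orchestration: ratio → threshold → count → score → stratify.

This module glues the stage modules together with one shared settings
object so the same defaults drive the library API, the command line and
the synthetic-cohort recovery runs.  The default quantification path is
the fixed gray cut (strictly above 130) followed by 8-connected labeling
and the ≥5-pixel size filter; automatic thresholds (ISODATA / Otsu) are
selectable.  Counts computed under different ratio scales are never
pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cohort import (
    BrimScore,
    ParetoSeries,
    PatientSample,
    PopulationSplit,
    pareto_order,
    patient_score,
    split_bimodal,
)
from .imaging_io import Micrograph
from .ratio import RatioImage, RatioScale, compute_ratio
from .segmentation import (
    DEFAULT_CONNECTIVITY,
    DEFAULT_GRAY_THRESHOLD,
    DEFAULT_MIN_PARTICLE_SIZE,
    ParticleSet,
    ThresholdResult,
    filter_particles,
    label_particles,
    threshold_auto,
    threshold_fixed,
)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

__all__ = [
    "PipelineSettings",
    "FieldMeasurement",
    "StratificationResult",
    "CohortRun",
    "measure_field",
    "measure_cohort",
    "stratify_samples",
    "run_synthetic_cohort",
]


@dataclass(frozen=True)
class PipelineSettings:
    """Every tunable of the default quantification path, in one place."""

    scale: RatioScale = field(default_factory=RatioScale)
    denominator_floor: float = 0.0
    threshold_method: str = "fixed"  # "fixed" | "isodata" | "otsu"
    threshold_value: int = DEFAULT_GRAY_THRESHOLD
    connectivity: int = DEFAULT_CONNECTIVITY
    min_particle_size: int = DEFAULT_MIN_PARTICLE_SIZE


@dataclass
class FieldMeasurement:
    """Quantification of one micrograph pair."""

    ratio: RatioImage
    threshold: ThresholdResult
    particles: ParticleSet  # size-filtered
    count: int


def measure_field(
    numerator: Micrograph,
    denominator: Micrograph,
    settings: PipelineSettings | None = None,
) -> FieldMeasurement:
    """Ratio a micrograph pair and count its supra-threshold particles."""
    settings = settings or PipelineSettings()
    ratio = compute_ratio(numerator, denominator, settings.scale,
                          settings.denominator_floor)
    if settings.threshold_method == "fixed":
        mask = threshold_fixed(ratio, settings.threshold_value)
        threshold = ThresholdResult("fixed", settings.threshold_value)
    else:
        mask, threshold = threshold_auto(ratio, settings.threshold_method)
    particles = filter_particles(
        label_particles(mask, settings.connectivity),
        settings.min_particle_size,
    )
    return FieldMeasurement(ratio, threshold, particles, len(particles))


def measure_cohort(
    cohort: SyntheticCohort,
    settings: PipelineSettings | None = None,
) -> list[PatientSample]:
    """Run the image pipeline over every simulated patient's micrographs.

    Returns new patient samples whose counts are the *measured* particle
    counts (the simulation's target counts stay in the cohort's ground
    truth).
    """
    settings = settings or PipelineSettings()
    pair = cohort.config.pair
    measured = []
    for patient in cohort.patients:
        counts = [
            measure_field(num, den, settings).count
            for num, den, _ in patient.scenes
        ]
        s = patient.sample
        measured.append(PatientSample(s.patient_id, s.diagnosis, s.age,
                                      {pair: counts}))
    return measured


@dataclass
class StratificationResult:
    scores: list[BrimScore]
    series: ParetoSeries
    split: PopulationSplit | None  # None when the cohort is unsplittable

    @property
    def splittable(self) -> bool:
        return self.split is not None


def stratify_samples(
    samples: Sequence[PatientSample],
    pair: str,
    min_group: int = 2,
) -> StratificationResult:
    """Score each patient (max over micrographs), order, and split.

    Cohorts smaller than ``2 * min_group`` are reported unsplittable
    (``split is None``) rather than forced.
    """
    scores = [patient_score(s, pair) for s in samples]
    series = pareto_order(scores)
    split = (split_bimodal(series, min_group)
             if len(scores) >= 2 * min_group else None)
    return StratificationResult(scores, series, split)


@dataclass
class CohortRun:
    cohort: SyntheticCohort
    measured: list[PatientSample]
    result: StratificationResult


def run_synthetic_cohort(
    config: CohortConfig,
    settings: PipelineSettings | None = None,
) -> CohortRun:
    """simulate → ratio → quantify → stratify, end to end, in memory."""
    cohort = generate_cohort(config)
    measured = measure_cohort(cohort, settings)
    result = stratify_samples(measured, config.pair)
    return CohortRun(cohort, measured, result)
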