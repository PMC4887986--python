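"""Synthetic two-channel micrographs and cohorts with known ground truth.

The generator emulates the imaging physics the ratio method exploits.  A
scene is a pair of 16-bit fluorescence channels of one field containing
cells rendered as Gaussian-profile disks (amplitude × exp(-d²/2r²),
truncated at 3r).  A cell's *phenotype* sets its numerator:denominator
amplitude ratio: "high" cells (default 4:1) land well above the gray-130
line of the default ratio scale, "low" cells (1:1) well below.  Both
channels are multiplied by ONE shared smooth positive artifact field
(optical path length / section thickness) and, optionally, a shared
horizontal intensity ripple emulating knife chatter during sectioning —
structure that contaminates each channel but cancels in their quotient.
Channel noise (signal-dependent Poisson-like noise with a gain factor,
plus additive Gaussian read noise) is drawn independently per channel and
does not cancel.

Cells are placed on a jittered grid whose spacing guarantees that
supra-threshold regions of neighbouring cells can neither merge nor
bridge, so with noise off the pipeline's particle count equals the number
of rendered high cells exactly — the scene's ground truth.

A cohort draws, for each patient, a mixture component governing the
per-micrograph number of high cells, as ``round(max(0, Normal(µ, σ)))``:
counts are non-negative and the low component piles probability mass at
zero, as clinically quiet samples do.  Packaged presets parameterize the
components from the published population statistics of DCIS
(4 ± 6 / 190 ± 100, equal weights), fibroadenoma (5 ± 12) and invasive
carcinoma (76 ± 94) cohorts.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cohort import DIAGNOSES, PatientSample, write_counts_manifest
from .imaging_io import Micrograph, write_micrograph
from .ratio import RatioScale
from .segmentation import DEFAULT_GRAY_THRESHOLD, DEFAULT_MIN_PARTICLE_SIZE

__all__ = [
    "SceneConfig",
    "CellTruth",
    "GroundTruth",
    "CountComponent",
    "CohortConfig",
    "SimulatedPatient",
    "SyntheticCohort",
    "generate_scene",
    "generate_patient",
    "generate_cohort",
    "preset_cohort",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise of one simulated two-channel field."""

    image_size: tuple[int, int] = (256, 256)
    duct: tuple[float, float, float, float] | None = None  # (row, col, r_in, r_out)
    n_background_cells: int = 30
    cell_radius: tuple[float, float] = (1.8, 0.2)  # mean, sd in pixels
    radius_bounds: tuple[float, float] = (1.3, 2.1)
    ratio_low: float = 1.0
    ratio_high: float = 4.0
    baseline: float = 100.0
    cell_amplitude: float = 2000.0
    artifact_amplitude: float = 0.2  # field spans [1-a, 1+a]
    artifact_corr_length: float = 40.0  # pixels
    poisson_gain: float = 2.0  # variance = gain * signal; 0 disables
    gaussian_sd: float = 5.0  # additive read noise; 0 disables
    chatter_amplitude: float = 0.0
    chatter_period: float = 16.0
    grid_spacing: int = 13
    jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ratio_high > self.ratio_low > 0:
            raise ValueError("need ratio_high > ratio_low > 0")
        if min(self.image_size) <= 0 or self.cell_amplitude <= 0 or self.baseline <= 0:
            raise ValueError("sizes and amplitudes must be positive")
        if not 0 <= self.artifact_amplitude < 1:
            raise ValueError("artifact amplitude must lie in [0, 1)")

    @property
    def capacity(self) -> int:
        """Number of grid slots, i.e. the packing limit on total cells."""
        rows, cols = self.image_size
        return (rows // self.grid_spacing) * (cols // self.grid_spacing)


@dataclass(frozen=True)
class CellTruth:
    center: tuple[float, float]
    radius: float
    phenotype: str  # "high" | "low"
    placement: str  # "intraductal" | "stromal"


@dataclass
class GroundTruth:
    """Per-cell truth and the expected default-pipeline particle count."""

    cells: list[CellTruth]
    expected_count: int

    def to_dict(self) -> dict:
        return {
            "expected_count": self.expected_count,
            "cells": [
                {"center": list(c.center), "radius": c.radius,
                 "phenotype": c.phenotype, "placement": c.placement}
                for c in self.cells
            ],
        }


def _supra_area(radius: float, config: SceneConfig,
                scale: RatioScale, threshold: int) -> int:
    """Noise-free supra-threshold pixel area of one high cell."""
    half = int(math.ceil(3 * radius))
    rr, cc = np.mgrid[-half:half + 1, -half:half + 1]
    d2 = rr**2 + cc**2
    g = np.exp(-d2 / (2 * radius**2))
    g[d2 > (3 * radius) ** 2] = 0.0
    num = config.baseline + config.cell_amplitude * g
    den = config.baseline + (config.cell_amplitude / config.ratio_high) * g
    return int(np.count_nonzero(scale.to_gray(num / den) > threshold))


def _render_cell(channel: np.ndarray, center: tuple[float, float],
                 radius: float, amplitude: float) -> None:
    rows, cols = channel.shape
    half = int(math.ceil(3 * radius))
    r0 = max(0, int(math.floor(center[0])) - half)
    r1 = min(rows, int(math.floor(center[0])) + half + 1)
    c0 = max(0, int(math.floor(center[1])) - half)
    c1 = min(cols, int(math.floor(center[1])) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    g = np.exp(-d2 / (2 * radius**2))
    g[d2 > (3 * radius) ** 2] = 0.0
    channel[r0:r1, c0:c1] += amplitude * g


def generate_scene(
    config: SceneConfig,
    n_high_cells: int,
    seed: int | None = None,
) -> tuple[Micrograph, Micrograph, GroundTruth]:
    """Render one two-channel field with ``n_high_cells`` high-ratio cells.

    Deterministic given the seed (``config.seed`` unless overridden).
    Raises ``ValueError`` when the requested cells exceed the grid packing
    limit.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.image_size
    spacing = config.grid_spacing

    # --- placement on a jittered grid ------------------------------------
    slot_rows = rows // spacing
    slot_cols = cols // spacing
    slots = [
        (spacing / 2 + i * spacing, spacing / 2 + j * spacing)
        for i in range(slot_rows) for j in range(slot_cols)
    ]
    if config.duct is not None:
        dr, dc, r_in, r_out = config.duct
        margin = 3 * config.radius_bounds[1]
        slots = [
            s for s in slots
            if not (r_in - margin <= math.hypot(s[0] - dr, s[1] - dc) <= r_out + margin)
        ]
    n_total = n_high_cells + config.n_background_cells
    if n_total > len(slots):
        raise ValueError(
            f"impossible packing: {n_total} cells but only {len(slots)} slots"
        )
    order = rng.permutation(len(slots))[:n_total]
    jitter = rng.uniform(-config.jitter, config.jitter, size=(n_total, 2))
    centers = [
        (slots[int(k)][0] + jitter[i, 0], slots[int(k)][1] + jitter[i, 1])
        for i, k in enumerate(order)
    ]
    radii = np.clip(
        rng.normal(config.cell_radius[0], config.cell_radius[1], size=n_total),
        *config.radius_bounds,
    )
    phenotypes = ["high"] * n_high_cells + ["low"] * config.n_background_cells

    # --- noiseless channels ----------------------------------------------
    num = np.full((rows, cols), config.baseline, dtype=float)
    den = np.full((rows, cols), config.baseline, dtype=float)
    for center, radius, phen in zip(centers, radii, phenotypes):
        ratio = config.ratio_high if phen == "high" else config.ratio_low
        _render_cell(num, center, radius, config.cell_amplitude)
        _render_cell(den, center, radius, config.cell_amplitude / ratio)
    if config.duct is not None:
        dr, dc, r_in, r_out = config.duct
        rr, cc = np.mgrid[0:rows, 0:cols]
        dist = np.hypot(rr - dr, cc - dc)
        mid, width = (r_in + r_out) / 2, max((r_out - r_in) / 2, 1.0)
        wall = 0.5 * config.cell_amplitude * np.exp(-((dist - mid) / width) ** 2)
        num += wall  # identical in both channels: neutral in the ratio
        den += wall

    # --- shared multiplicative structure ---------------------------------
    # The field is always drawn so the random stream is independent of the
    # amplitude setting; amplitude only scales it.
    white = rng.standard_normal((rows, cols))
    smooth = gaussian_filter(white, config.artifact_corr_length, mode="reflect")
    peak = np.max(np.abs(smooth))
    shared = 1.0 + (config.artifact_amplitude * smooth / peak if peak > 0 else 0.0)
    if config.chatter_amplitude > 0:
        ripple = 1.0 + config.chatter_amplitude * np.sin(
            2 * np.pi * np.arange(rows) / config.chatter_period
        )
        shared = shared * ripple[:, None]
    num *= shared
    den *= shared

    # --- independent per-channel detector noise --------------------------
    if config.poisson_gain > 0:
        num = rng.poisson(num / config.poisson_gain) * config.poisson_gain
        den = rng.poisson(den / config.poisson_gain) * config.poisson_gain
    if config.gaussian_sd > 0:
        num = num + rng.normal(0.0, config.gaussian_sd, size=num.shape)
        den = den + rng.normal(0.0, config.gaussian_sd, size=den.shape)
    num = np.clip(np.rint(num), 0, 65535).astype(np.uint16)
    den = np.clip(np.rint(den), 0, 65535).astype(np.uint16)

    # --- ground truth -----------------------------------------------------
    scale = RatioScale()
    cells = []
    expected = 0
    for center, radius, phen in zip(centers, radii, phenotypes):
        if config.duct is not None:
            dr, dc, _, _ = config.duct
            placement = ("intraductal"
                         if math.hypot(center[0] - dr, center[1] - dc)
                         < config.duct[2] else "stromal")
        else:
            placement = "stromal"
        cells.append(CellTruth(center, float(radius), phen, placement))
        if phen == "high" and _supra_area(
            float(radius), config, scale, DEFAULT_GRAY_THRESHOLD
        ) >= DEFAULT_MIN_PARTICLE_SIZE:
            expected += 1
    return (
        Micrograph(num, 16, biomarker="NUM"),
        Micrograph(den, 16, biomarker="DEN"),
        GroundTruth(cells, expected),
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CountComponent:
    """One mixture component of per-micrograph high-cell counts."""

    weight: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.weight < 0 or self.sd < 0:
            raise ValueError("weight and sd must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int
    micrographs_per_patient: int = 1
    diagnosis_mix: tuple[tuple[str, float], ...] = (("DCIS", 1.0),)
    count_model: tuple[tuple[str, tuple[CountComponent, ...]], ...] = (
        ("DCIS", (CountComponent(1.0, 10.0, 3.0),)),
    )
    age_model: tuple[tuple[str, tuple[tuple[float, float], ...]], ...] = ()
    pair: str = "CD74/CD59"
    scene: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.micrographs_per_patient < 1:
            raise ValueError("bad cohort size parameters")
        mix = dict(self.diagnosis_mix)
        if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("diagnosis fractions must sum to 1")
        for cls, comps in self.count_model:
            if cls not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis class {cls!r}")
            if abs(sum(c.weight for c in comps) - 1.0) > 1e-9:
                raise ValueError(f"{cls}: component weights must sum to 1")

    def components_for(self, diagnosis: str) -> tuple[CountComponent, ...]:
        model = dict(self.count_model)
        if diagnosis not in model:
            raise KeyError(f"no count model for diagnosis {diagnosis!r}")
        return model[diagnosis]

    def ages_for(self, diagnosis: str) -> tuple[tuple[float, float], ...]:
        return dict(self.age_model).get(diagnosis, ((55.0, 10.0),))


@dataclass
class SimulatedPatient:
    sample: PatientSample
    scenes: list[tuple[Micrograph, Micrograph, GroundTruth]]
    component: int


@dataclass
class SyntheticCohort:
    patients: list[SimulatedPatient]
    config: CohortConfig

    @property
    def samples(self) -> list[PatientSample]:
        return [p.sample for p in self.patients]

    def write(self, out_dir: str | Path) -> Path:
        """Write the TIFF tree, file manifest, truth counts and truth JSON.

        Returns the path of the file manifest CSV.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        num_marker, den_marker = (self.config.pair.split("/") + ["DEN"])[:2]
        rows = []
        truth: dict = {}
        for patient in self.patients:
            s = patient.sample
            pdir = out_dir / s.patient_id
            pdir.mkdir(exist_ok=True)
            truth[s.patient_id] = {"component": patient.component, "fields": {}}
            for j, (num, den, gt) in enumerate(patient.scenes):
                field_id = f"F{j:02d}"
                num_path = pdir / f"{field_id}_{num_marker}.tif"
                den_path = pdir / f"{field_id}_{den_marker}.tif"
                write_micrograph(num, num_path)
                write_micrograph(den, den_path)
                rows.append({
                    "patient_id": s.patient_id, "diagnosis": s.diagnosis,
                    "age": s.age, "pair": self.config.pair, "field_id": field_id,
                    "numerator": str(num_path.relative_to(out_dir)),
                    "denominator": str(den_path.relative_to(out_dir)),
                })
                truth[s.patient_id]["fields"][field_id] = gt.to_dict()
        manifest = out_dir / "manifest.csv"
        pd.DataFrame(
            rows,
            columns=["patient_id", "diagnosis", "age", "pair", "field_id",
                     "numerator", "denominator"],
        ).to_csv(manifest, index=False)
        write_counts_manifest(self.samples, out_dir / "truth_counts.csv")
        (out_dir / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n")
        return manifest

    def manifest_hash(self) -> str:
        """Stable digest of the cohort's ground-truth counts."""
        payload = json.dumps(
            [(p.sample.patient_id, p.sample.diagnosis, p.component,
              p.sample.counts) for p in self.patients],
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def _largest_remainder(n: int, weights: Sequence[float]) -> list[int]:
    """Apportion n items to weights; deterministic largest-remainder rounding."""
    quotas = [w * n for w in weights]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: (quotas[i] - counts[i], -i),
                   reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _draw_count(rng: np.random.Generator, comp: CountComponent, cap: int) -> int:
    value = rng.normal(comp.mean, comp.sd) if comp.sd > 0 else comp.mean
    return min(int(math.floor(max(0.0, value) + 0.5)), cap)


def generate_patient(
    config: CohortConfig,
    diagnosis: str,
    patient_seed: int,
    patient_id: str = "P000",
    component: int | None = None,
) -> SimulatedPatient:
    """Simulate one patient: component, per-micrograph counts, rendered scenes."""
    rng = np.random.default_rng(patient_seed)
    comps = config.components_for(diagnosis)
    if component is None:
        component = int(rng.choice(len(comps), p=[c.weight for c in comps]))
    comp = comps[component]
    ages = config.ages_for(diagnosis)
    age_mean, age_sd = ages[min(component, len(ages) - 1)]
    age = round(float(rng.normal(age_mean, age_sd)), 1)
    cap = config.scene.capacity - config.scene.n_background_cells
    scenes = []
    counts = []
    for _ in range(config.micrographs_per_patient):
        target = _draw_count(rng, comp, cap)
        scene_seed = int(rng.integers(0, 2**31))
        scenes.append(generate_scene(config.scene, target, seed=scene_seed))
        counts.append(target)
    sample = PatientSample(patient_id, diagnosis, age, {config.pair: counts})
    return SimulatedPatient(sample, scenes, component)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a whole cohort, reproducibly, from the master seed.

    Diagnosis classes and mixture components are apportioned across
    patients by largest-remainder rounding of their weights (so the
    subpopulation sizes are determinate), with the assignment order
    shuffled by the master seed.
    """
    master = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_seeds = master.integers(0, 2**31, size=n) if n else []
    mix = dict(config.diagnosis_mix)
    classes = list(mix)
    class_counts = _largest_remainder(n, [mix[c] for c in classes])
    diagnoses = [c for c, k in zip(classes, class_counts) for _ in range(k)]
    diagnoses = [diagnoses[i] for i in master.permutation(n)] if n else []
    # stratified component assignment within each class
    component_of = {}
    for cls in classes:
        idx = [i for i, d in enumerate(diagnoses) if d == cls]
        comps = config.components_for(cls)
        per_comp = _largest_remainder(len(idx), [c.weight for c in comps])
        assigned = [j for j, k in enumerate(per_comp) for _ in range(k)]
        assigned = [assigned[int(t)] for t in master.permutation(len(idx))]
        component_of.update(dict(zip(idx, assigned)))
    patients = [
        generate_patient(config, diagnoses[i], int(patient_seeds[i]),
                         patient_id=f"P{i:03d}", component=component_of[i])
        for i in range(n)
    ]
    return SyntheticCohort(patients, config)


_PRESETS = {
    # Components parameterized from the published cohort statistics:
    # DCIS scores split into 4 ± 6 and 190 ± 100 subpopulations (n=23,
    # subpopulation weights not published; equal weights by default),
    # fibroadenoma 5 ± 12 (n=16), IDC 76 ± 94 (n=26).  One micrograph per
    # patient so the rendered count is the patient's plotted score.
    "paper_dcis": dict(
        n_patients=23,
        diagnosis_mix=(("DCIS", 1.0),),
        count_model=(("DCIS", (CountComponent(0.5, 4.0, 6.0),
                               CountComponent(0.5, 190.0, 100.0))),),
        age_model=(("DCIS", ((50.0, 8.0), (64.0, 8.0))),),
    ),
    "fibroadenoma": dict(
        n_patients=16,
        diagnosis_mix=(("fibroadenoma", 1.0),),
        count_model=(("fibroadenoma", (CountComponent(1.0, 5.0, 12.0),)),),
        age_model=(("fibroadenoma", ((45.0, 10.0),)),),
    ),
    "idc": dict(
        n_patients=26,
        diagnosis_mix=(("IDC", 1.0),),
        count_model=(("IDC", (CountComponent(1.0, 76.0, 94.0),)),),
        age_model=(("IDC", ((60.0, 10.0),)),),
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset_cohort(name: str, seed: int = 0, **overrides) -> CohortConfig:
    """Packaged cohort presets: ``paper_dcis``, ``fibroadenoma``, ``idc``."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return CohortConfig(seed=seed, **params)
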