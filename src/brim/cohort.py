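"""Patient scoring, cohort stratification, and the associated statistics.

Each patient contributes several micrographs per biomarker pair; the
patient's score for a pair is the *maximum* supra-threshold particle count
over those micrographs (micrographs vary in cellularity — e.g. fields
dominated by fatty tissue — so the maximum, not the mean, captures the
lesion's expression potential).  Scores sorted ascending against rank form
an ascending Pareto series whose inflection reveals two subpopulations.

The split is made algorithmic rather than visual: an exhaustive search over
all cut points of the sorted scores (each side keeping at least two
members) minimizes the pooled within-group sum of squared deviations —
one-dimensional 2-means — with the cut selected on a log(1+score) scale
because counts spanning orders of magnitude are heavily over-dispersed.
Separation is then asserted with Ashman's D,

    D = sqrt(2) |mu1 - mu2| / sqrt(sd1^2 + sd2^2),

with D > 2 read as clean bimodal separation, and tested with Welch's
two-sample t (Student's pooled t is provided as the cross-check; under
near-normal, equal-variance data the two are practically indistinguishable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DIAGNOSES",
    "PatientSample",
    "BrimScore",
    "ParetoSeries",
    "PopulationSplit",
    "ClassificationRule",
    "CorrelationResult",
    "patient_score",
    "pareto_order",
    "split_bimodal",
    "ashman_D",
    "welch_t",
    "student_t",
    "pearson_r",
    "classify_patient",
    "compare_single_vs_ratio",
    "default_classification_rule",
    "read_counts_manifest",
    "write_counts_manifest",
    "scores_wide_table",
]

DIAGNOSES = ("fibroadenoma", "DCIS", "IDC", "control")


@dataclass
class PatientSample:
    """One patient's per-micrograph particle counts, keyed by measure label.

    ``counts`` maps a biomarker-pair label (``"CD74/CD59"``) — or a
    single-marker label for the conventional-fluorescence comparator — to
    the list of counts of that patient's micrographs.
    """

    patient_id: str
    diagnosis: str
    age: float | None = None
    counts: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"unknown diagnosis {self.diagnosis!r}; expected one of {DIAGNOSES}"
            )
        for pair, values in self.counts.items():
            if len(values) == 0:
                raise ValueError(f"{self.patient_id}/{pair}: no micrograph counts")
            if any(c < 0 for c in values):
                raise ValueError(f"{self.patient_id}/{pair}: negative count")


@dataclass(frozen=True)
class BrimScore:
    patient_id: str
    pair: str
    score: int


@dataclass
class ParetoSeries:
    """Scores sorted ascending with 1-based rank; ties keep input order."""

    pair: str
    entries: list[tuple[int, str, int]]  # (rank, patient_id, score)

    def scores(self) -> np.ndarray:
        return np.array([s for _, _, s in self.entries], dtype=float)

    def patient_ids(self) -> list[str]:
        return [p for _, p, _ in self.entries]


@dataclass
class PopulationSplit:
    pair: str
    low_members: list[str]
    high_members: list[str]
    low_mean: float
    low_sd: float
    high_mean: float
    high_sd: float
    ashman_D: float
    t_statistic: float
    p_value: float
    bimodal: bool

    def to_dict(self) -> dict:
        return {
            "pair": self.pair,
            "low_members": list(self.low_members),
            "high_members": list(self.high_members),
            "low_mean": self.low_mean,
            "low_sd": self.low_sd,
            "high_mean": self.high_mean,
            "high_sd": self.high_sd,
            "ashman_D": self.ashman_D,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "bimodal": self.bimodal,
        }


@dataclass
class ClassificationRule:
    """Per-pair inclusive upper bounds defining the low-scoring class.

    A patient is ``low_BRIM`` only if *every* pair's score is at or below
    its bound.  The default encodes scores of 0–2 for CD74/CD59 and
    CD44/CD24 and below 50 for N-cadherin/E-cadherin (the higher bound
    absorbs stromal N-cad-high/E-cad-low cells).
    """

    bounds: dict[str, int]

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("classification rule needs at least one pair")
        if any(b < 0 for b in self.bounds.values()):
            raise ValueError("bounds must be non-negative")


def default_classification_rule() -> ClassificationRule:
    return ClassificationRule(
        {"CD74/CD59": 2, "CD44/CD24": 2, "NCAD/ECAD": 49}
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


def patient_score(sample: PatientSample, pair: str) -> BrimScore:
    """Patient score: maximum particle count over the pair's micrographs."""
    if pair not in sample.counts or not sample.counts[pair]:
        raise KeyError(f"{sample.patient_id}: no counts for pair {pair!r}")
    return BrimScore(sample.patient_id, pair, int(max(sample.counts[pair])))


def pareto_order(scores: Sequence[BrimScore]) -> ParetoSeries:
    """Stable ascending sort of scores with 1-based rank indices."""
    if not scores:
        raise ValueError("need at least one score")
    pairs = {s.pair for s in scores}
    if len(pairs) > 1:
        raise ValueError(f"scores mix biomarker pairs: {sorted(pairs)}")
    ordered = sorted(scores, key=lambda s: s.score)  # sorted() is stable
    return ParetoSeries(
        pair=next(iter(pairs)),
        entries=[(i + 1, s.patient_id, s.score) for i, s in enumerate(ordered)],
    )


def ashman_D(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Ashman's bimodality statistic sqrt(2)|mu1-mu2|/sqrt(sd1^2+sd2^2).

    D > 2 indicates cleanly separated components.  Symmetric in the two
    components and invariant under a common shift of both means.  With both
    SDs zero: 0 for equal means, +inf otherwise.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    diff = abs(mu1 - mu2)
    denom = math.hypot(sd1, sd2)
    if denom == 0:
        return 0.0 if diff == 0 else math.inf
    return math.sqrt(2.0) * diff / denom


def _two_sample_t(a, b, equal_var: bool) -> tuple[float, float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1 / na + 1 / nb)
    else:
        se2 = va / na + vb / nb
        if se2 > 0:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = float(na + nb - 2)
    if se2 == 0:
        # both samples constant: identical means are a perfect null fit
        t = 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
        return t, float(df), 1.0 if ma == mb else 0.0
    t = (ma - mb) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    return _two_sample_t(sample_a, sample_b, equal_var=False)


def student_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Student's pooled-variance t-test: (t, n_a + n_b - 2, two-sided p)."""
    return _two_sample_t(sample_a, sample_b, equal_var=True)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length sequences (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


_SPLIT_TRANSFORMS = {"log1p": np.log1p, "linear": lambda x: x}


def split_bimodal(series: ParetoSeries, min_group: int = 2,
                  transform: str = "log1p") -> PopulationSplit:
    """Partition an ascending score series into low/high subpopulations.

    Exhaustive search over all cut points of the sorted scores (each side
    at least ``min_group`` members) minimizing the pooled within-group sum
    of squared deviations; ties take the smallest low group.  Because
    particle counts are over-dispersed across orders of magnitude, the cut
    is selected on a variance-stabilized ``log(1 + score)`` scale by
    default (``transform="linear"`` selects it on raw counts, where the
    high group's large variance systematically pulls intermediate scores
    into the low group).  All reported statistics — group means and sample
    SDs (n-1), Ashman's D, and Welch's t/p between the groups — are on the
    original count scale; ``bimodal`` is ``D > 2``.

    Note that D > 2 supports separation but cannot by itself rule out
    unimodality: any forced two-group split of even a single Gaussian
    sample manufactures conditional means roughly 2.7 pooled-SD apart.

    Raises
    ------
    ValueError
        With fewer than ``2 * min_group`` scores the cohort is unsplittable.
    """
    scores = series.scores()
    ids = series.patient_ids()
    n = scores.size
    if n < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} scores to split, got {n}")
    if transform not in _SPLIT_TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")

    if scores.max() == scores.min():
        # degenerate: a single spike is unimodal by definition
        k = min_group
        low, high = scores[:k], scores[k:]
        t, _, p = welch_t(low, high)
        return PopulationSplit(series.pair, ids[:k], ids[k:],
                               float(low.mean()), float(low.std(ddof=1)),
                               float(high.mean()), float(high.std(ddof=1)),
                               0.0, t, p, False)

    z = _SPLIT_TRANSFORMS[transform](scores)
    best_k, best_sse = None, math.inf
    for k in range(min_group, n - min_group + 1):
        low, high = z[:k], z[k:]
        sse = ((low - low.mean()) ** 2).sum() + ((high - high.mean()) ** 2).sum()
        if sse < best_sse - 1e-12:
            best_k, best_sse = k, sse
    assert best_k is not None
    low, high = scores[:best_k], scores[best_k:]
    low_mean, high_mean = float(low.mean()), float(high.mean())
    low_sd, high_sd = float(low.std(ddof=1)), float(high.std(ddof=1))
    D = ashman_D(low_mean, low_sd, high_mean, high_sd)
    t, _, p = welch_t(low, high)
    return PopulationSplit(series.pair, ids[:best_k], ids[best_k:],
                           low_mean, low_sd, high_mean, high_sd,
                           D, t, p, D > 2)


def classify_patient(scores: Mapping[str, "BrimScore | int"],
                     rule: ClassificationRule | None = None) -> str:
    """Classify a patient as ``low_BRIM`` or ``high_BRIM`` across pairs.

    ``low_BRIM`` iff every pair named in the rule has a score at or below
    its inclusive bound.  Raising any score never moves a patient from
    high to low.
    """
    if rule is None:
        rule = default_classification_rule()
    for pair, bound in rule.bounds.items():
        if pair not in scores:
            raise KeyError(f"no score for pair {pair!r}")
        value = scores[pair]
        score = value.score if isinstance(value, BrimScore) else int(value)
        if score > bound:
            return "high_BRIM"
    return "low_BRIM"


def compare_single_vs_ratio(
    samples: Iterable[PatientSample],
    ratio_pair: str,
    single_marker: str,
) -> CorrelationResult:
    """Correlate per-patient single-marker scores against ratio scores.

    Both measures are reduced to the per-patient maximum over micrographs;
    Pearson's r across patients quantifies how much of the ratio signal the
    conventional single-channel count already carries.
    """
    single_scores, ratio_scores = [], []
    for sample in samples:
        if ratio_pair not in sample.counts or single_marker not in sample.counts:
            raise KeyError(
                f"{sample.patient_id}: needs counts for both "
                f"{ratio_pair!r} and {single_marker!r}"
            )
        if len(sample.counts[ratio_pair]) != len(sample.counts[single_marker]):
            raise ValueError(
                f"{sample.patient_id}: mismatched micrograph sets for "
                f"{ratio_pair!r} vs {single_marker!r}"
            )
        ratio_scores.append(max(sample.counts[ratio_pair]))
        single_scores.append(max(sample.counts[single_marker]))
    return CorrelationResult(pearson_r(single_scores, ratio_scores),
                             len(ratio_scores))


# ---------------------------------------------------------------------------
# Cohort manifest I/O (one row per patient x pair x micrograph)

_MANIFEST_COLUMNS = ["patient_id", "diagnosis", "age", "pair", "micrograph_count"]


def read_counts_manifest(path: str | Path) -> list[PatientSample]:
    """Read a cohort counts manifest CSV into patient samples.

    Expected columns: patient_id, diagnosis, age, pair, micrograph_count.
    Malformed rows raise ``ValueError`` naming the offending row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    samples: dict[str, PatientSample] = {}
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based with header line
        pid = str(row["patient_id"])
        diagnosis = str(row["diagnosis"])
        if diagnosis not in DIAGNOSES:
            raise ValueError(f"{path}: row {rowno}: unknown diagnosis {diagnosis!r}")
        try:
            count = int(row["micrograph_count"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {rowno}: bad micrograph_count "
                f"{row['micrograph_count']!r}"
            ) from None
        if count < 0:
            raise ValueError(f"{path}: row {rowno}: negative micrograph_count")
        age = None if pd.isna(row["age"]) else float(row["age"])
        sample = samples.get(pid)
        if sample is None:
            sample = PatientSample(pid, diagnosis, age, {})
            samples[pid] = sample
        elif sample.diagnosis != diagnosis:
            raise ValueError(f"{path}: row {rowno}: diagnosis conflicts for {pid}")
        sample.counts.setdefault(str(row["pair"]), []).append(count)
    return list(samples.values())


def write_counts_manifest(samples: Iterable[PatientSample], path: str | Path) -> Path:
    rows = []
    for s in samples:
        for pair, counts in s.counts.items():
            for c in counts:
                rows.append({"patient_id": s.patient_id, "diagnosis": s.diagnosis,
                             "age": s.age, "pair": pair, "micrograph_count": c})
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)
    return Path(path)


def scores_wide_table(samples: Iterable[PatientSample],
                      pairs: Sequence[str]) -> pd.DataFrame:
    """Patient-by-pair score table (for external 3-axis plotting)."""
    rows = []
    for s in samples:
        row: dict = {"patient_id": s.patient_id, "diagnosis": s.diagnosis}
        for pair in pairs:
            row[pair] = (patient_score(s, pair).score
                         if pair in s.counts and s.counts[pair] else None)
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "diagnosis", *pairs])
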