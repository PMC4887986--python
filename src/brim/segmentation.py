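"""Thresholding and supra-threshold particle quantification.

Quantification of a ratio image proceeds in three steps: (1) a global
threshold on the 8-bit gray histogram — either the fixed clinical cut
(strictly greater than gray 130 by default) or an automatic histogram
method (iterative intermeans "ISODATA", or Otsu's between-class-variance
criterion as a non-interactive comparator); (2) connected-component
labeling of the supra-threshold mask (8-connectivity by default, the
ImageJ particle-analysis convention); (3) a minimum-size filter keeping
particles of five or more pixels.  Only global thresholds are offered:
local/adaptive schemes can misread bright fat droplets in mammary tissue.

ISODATA here is the classic intermeans fixed point: starting from the
overall histogram mean, the threshold is repeatedly replaced by the
midpoint of the two class means until the class partition stops changing
(an exact, stable fixed point).  Otsu is an exhaustive search over all candidate cuts ``t`` (class 0
= gray <= t) maximizing between-class variance, carried out in exact
rational arithmetic so plateau ties are detected reliably; a plateau
returns its midpoint rounded down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from skimage import measure

from .imaging_io import Micrograph
from .ratio import RatioImage

__all__ = [
    "ThresholdResult",
    "BinaryMask",
    "Particle",
    "ParticleSet",
    "DegenerateHistogramError",
    "threshold_fixed",
    "threshold_isodata",
    "threshold_otsu",
    "threshold_auto",
    "label_particles",
    "filter_particles",
    "count_particles",
    "count_single_marker",
    "mask_jaccard",
    "particles_to_dataframe",
]

DEFAULT_GRAY_THRESHOLD = 130
DEFAULT_MIN_PARTICLE_SIZE = 5
DEFAULT_CONNECTIVITY = 8


class DegenerateHistogramError(ValueError):
    """Histogram carries all its mass at a single value; no cut exists."""


@dataclass(frozen=True)
class ThresholdResult:
    """A chosen gray threshold and how it was obtained."""

    method: str  # "fixed" | "isodata" | "otsu"
    threshold: int
    iterations: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold outside [0, 255]")


@dataclass
class BinaryMask:
    """Boolean segmentation mask plus provenance of the threshold applied."""

    pixels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass(frozen=True)
class Particle:
    label: int
    pixel_count: int
    centroid: tuple[float, float]
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1) half-open


@dataclass
class ParticleSet:
    particles: list[Particle]
    min_size_applied: int = 1
    connectivity: int = DEFAULT_CONNECTIVITY

    def __len__(self) -> int:
        return len(self.particles)


def threshold_fixed(ratio: RatioImage, t: int = DEFAULT_GRAY_THRESHOLD) -> BinaryMask:
    """Select valid pixels with gray strictly greater than ``t``."""
    if not 0 <= t <= 255:
        raise ValueError("fixed threshold outside [0, 255]")
    return BinaryMask(ratio.valid & (ratio.gray > t), source=f"fixed>{t}")


def _check_histogram(histogram: np.ndarray) -> np.ndarray:
    hist = np.asarray(histogram)
    if hist.ndim != 1 or np.any(hist < 0):
        raise ValueError("histogram must be a 1-D vector of counts")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("unimodal degenerate histogram")
    return hist


def threshold_isodata(histogram: np.ndarray) -> ThresholdResult:
    """Iterative intermeans threshold of a gray-level histogram.

    Starting at the overall mean, iterate
    ``T <- (mean of values <= T + mean of values > T) / 2`` until the
    class partition stops changing — the exact fixed point of the
    (piecewise-constant) intermeans map, so one further update leaves the
    threshold unchanged — then round to an integer.
    """
    hist = _check_histogram(histogram).astype(float)
    values = np.arange(hist.size, dtype=float)
    total = hist.sum()
    t = float((values * hist).sum() / total)
    iterations = 0
    for _ in range(hist.size):
        lo = values <= t
        w_lo, w_hi = hist[lo].sum(), hist[~lo].sum()
        if w_lo == 0 or w_hi == 0:  # cannot happen while min < t < max
            break
        mean_lo = (values[lo] * hist[lo]).sum() / w_lo
        mean_hi = (values[~lo] * hist[~lo]).sum() / w_hi
        t_new = 0.5 * (mean_lo + mean_hi)
        iterations += 1
        stable = bool(np.array_equal(values <= t_new, lo))
        t = t_new
        if stable:
            break
    return ThresholdResult("isodata", int(np.floor(t + 0.5)), iterations)


def threshold_otsu(histogram: np.ndarray) -> ThresholdResult:
    """Exhaustive between-class-variance maximization over all cuts.

    Class 0 is ``gray <= t``.  The objective is evaluated in exact rational
    arithmetic; when the maximum is attained on a plateau of cuts, the
    plateau midpoint (rounded down) is returned.
    """
    hist = _check_histogram(histogram)
    counts = [int(c) for c in hist]
    total = sum(counts)
    total_sum = sum(v * c for v, c in enumerate(counts))
    best: Fraction | None = None
    arg: list[int] = []
    w0 = 0
    s0 = 0
    for t in range(len(counts) - 1):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        # between-class variance up to the constant 1/total^2
        score = Fraction((s0 * total - total_sum * w0) ** 2, w0 * w1)
        if best is None or score > best:
            best, arg = score, [t]
        elif score == best:
            arg.append(t)
    assert best is not None and arg
    return ThresholdResult("otsu", (arg[0] + arg[-1]) // 2, None)


def threshold_auto(ratio: RatioImage, method: str = "isodata") -> tuple[BinaryMask, ThresholdResult]:
    """Histogram-threshold a ratio image with ISODATA or Otsu."""
    from .ratio import ratio_histogram

    if method == "isodata":
        result = threshold_isodata(ratio_histogram(ratio))
    elif method == "otsu":
        result = threshold_otsu(ratio_histogram(ratio))
    else:
        raise ValueError(f"unknown threshold method: {method}")
    mask = BinaryMask(ratio.valid & (ratio.gray > result.threshold),
                      source=f"{method}>{result.threshold}")
    return mask, result


def label_particles(mask: BinaryMask, connectivity: int = DEFAULT_CONNECTIVITY) -> ParticleSet:
    """Connected components of a binary mask (unfiltered, min size 1)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask.pixels, connectivity=2 if connectivity == 8 else 1)
    particles = [
        Particle(
            label=int(region.label),
            pixel_count=int(region.area),
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            bounding_box=tuple(int(b) for b in region.bbox),
        )
        for region in measure.regionprops(labels)
    ]
    return ParticleSet(particles, min_size_applied=1, connectivity=connectivity)


def filter_particles(particles: ParticleSet, min_size: int = DEFAULT_MIN_PARTICLE_SIZE) -> ParticleSet:
    """Keep particles of at least ``min_size`` pixels (inclusive)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [p for p in particles.particles if p.pixel_count >= min_size]
    return ParticleSet(kept, min_size_applied=max(min_size, particles.min_size_applied),
                       connectivity=particles.connectivity)


def count_particles(particles: ParticleSet, min_size: int = DEFAULT_MIN_PARTICLE_SIZE) -> int:
    """Number of particles of ``min_size`` or more pixels."""
    return len(filter_particles(particles, min_size))


def count_single_marker(
    image: Micrograph,
    min_size: int = DEFAULT_MIN_PARTICLE_SIZE,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> int:
    """Particle count of a single fluorescence channel — the conventional
    (non-ratio) comparator.

    The channel's intensities are binned into 256 equal-width bins over
    their observed range, thresholded with ISODATA, labeled and counted
    with the same size filter as the ratio path.  Because the binning spans
    the observed range, the count is invariant under rescaling the channel
    intensity.  A degenerate (constant) image counts 0 with a warning.
    """
    vals = np.asarray(image.pixels, dtype=float)
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax <= vmin:
        warnings.warn("degenerate single-marker histogram; count set to 0")
        return 0
    idx = np.clip(((vals - vmin) / (vmax - vmin) * 256).astype(int), 0, 255)
    try:
        result = threshold_isodata(np.bincount(idx.ravel(), minlength=256))
    except DegenerateHistogramError:
        warnings.warn("degenerate single-marker histogram; count set to 0")
        return 0
    mask = BinaryMask(idx > result.threshold,
                      source=f"single-marker isodata>{result.threshold}")
    return count_particles(label_particles(mask, connectivity), min_size)


def mask_jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard overlap of two masks; 1.0 when both are empty."""
    pa, pb = a.pixels, b.pixels
    union = np.count_nonzero(pa | pb)
    if union == 0:
        return 1.0
    return np.count_nonzero(pa & pb) / union


def particles_to_dataframe(particles: ParticleSet) -> pd.DataFrame:
    """Particle table (label, area, centroid, bbox) for CSV export."""
    return pd.DataFrame(
        [
            {
                "label": p.label,
                "area_px": p.pixel_count,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
                "bbox_row0": p.bounding_box[0],
                "bbox_col0": p.bounding_box[1],
                "bbox_row1": p.bounding_box[2],
                "bbox_col1": p.bounding_box[3],
            }
            for p in particles.particles
        ],
        columns=[
            "label", "area_px", "centroid_row", "centroid_col",
            "bbox_row0", "bbox_col0", "bbox_row1", "bbox_col1",
        ],
    )
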