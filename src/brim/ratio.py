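"""The core ratio-image computation.

A biomarker ratio image divides, pixel by pixel, a micrograph of a
biomarker whose expression rises with tumor aggressiveness (the numerator,
e.g. CD44, N-cadherin, CD74) by a micrograph of a biomarker whose
expression falls with aggressiveness (the denominator, e.g. CD24,
E-cadherin, CD59).  Because cell shape, section thickness and illumination
multiply both channels by the same optical path-length factor, these
artifacts cancel in the quotient, leaving a high-contrast map of the
aggressiveness-linked expression ratio.

The continuous ratio ``r = N/D`` is mapped to an 8-bit gray value through
an explicit, auditable :class:`RatioScale`::

    gray = round((levels - 1) * clamp((r - r_min) / (r_max - r_min), 0, 1))

with half-away-from-zero rounding applied exactly once.  Pixels whose
denominator does not exceed the ``denominator_floor`` are marked invalid
(gray 0) rather than perturbed with an epsilon: an epsilon would silently
compress exactly the high ratios the method exists to detect.

Absolute gray thresholds (such as the conventional ``> 130`` cut) are only
comparable across images computed under one fixed scale; pooling counts
produced under different scales is refused downstream
(:func:`scales_compatible`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import tifffile

from .imaging_io import Micrograph, read_mask_png, write_mask_png

__all__ = [
    "RatioScale",
    "RatioImage",
    "compute_ratio",
    "ratio_histogram",
    "save_ratio_image",
    "load_ratio_image",
    "scales_compatible",
]


@dataclass(frozen=True)
class RatioScale:
    """Linear calibration from ratio units to gray levels.

    ``r_min`` maps to gray 0 and ``r_max`` to the top gray level, with
    clamping outside the interval.  Defaults (0–5 over 256 levels) put the
    conventional gray-130 cut at a ratio of 130/255*5 ≈ 2.55.
    """

    r_min: float = 0.0
    r_max: float = 5.0
    levels: int = 256

    def __post_init__(self) -> None:
        if not self.r_min >= 0:
            raise ValueError("r_min must be >= 0")
        if not self.r_max > self.r_min:
            raise ValueError("r_max must exceed r_min")
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")

    def to_gray(self, r: np.ndarray) -> np.ndarray:
        """Quantize ratio values to integer gray levels (rounded once)."""
        frac = np.clip((np.asarray(r, dtype=float) - self.r_min)
                       / (self.r_max - self.r_min), 0.0, 1.0)
        # half-away-from-zero; frac is non-negative so floor(x+0.5) suffices
        return np.floor(frac * (self.levels - 1) + 0.5).astype(np.int64)

    def to_dict(self) -> dict:
        return {"r_min": self.r_min, "r_max": self.r_max, "levels": self.levels}


@dataclass
class RatioImage:
    """Quantized pixel-wise biomarker ratio with validity mask and provenance."""

    gray: np.ndarray
    valid: np.ndarray
    scale: RatioScale = field(default_factory=RatioScale)
    numerator_biomarker: str = ""
    denominator_biomarker: str = ""
    patient_id: str = ""
    field_id: str = ""
    denominator_floor: float = 0.0

    def __post_init__(self) -> None:
        gray = np.asarray(self.gray)
        valid = np.asarray(self.valid, dtype=bool)
        if gray.ndim != 2 or gray.shape != valid.shape:
            raise ValueError("gray and valid must be equal-shape 2-D grids")
        if gray.min() < 0 or gray.max() > self.scale.levels - 1:
            raise ValueError("gray values outside [0, levels-1]")
        if np.any(gray[~valid] != 0):
            raise ValueError("invalid pixels must carry gray 0")
        self.gray = gray
        self.valid = valid

    @property
    def shape(self) -> tuple[int, int]:
        return self.gray.shape  # type: ignore[return-value]

    @property
    def pair(self) -> str:
        return f"{self.numerator_biomarker}/{self.denominator_biomarker}"


def compute_ratio(
    numerator: Micrograph,
    denominator: Micrograph,
    scale: RatioScale | None = None,
    denominator_floor: float = 0.0,
) -> RatioImage:
    """Divide the numerator channel by the denominator channel pixel-wise.

    Pixels whose denominator intensity is strictly above
    ``denominator_floor`` get ``gray = scale.to_gray(N/D)`` and are valid;
    all others are invalid with gray 0.  No background subtraction or
    smoothing is applied before division.

    Raises
    ------
    ValueError
        On shape mismatch, identical biomarker labels, a negative floor, or
        an ill-ordered scale.
    """
    if scale is None:
        scale = RatioScale()
    if numerator.shape != denominator.shape:
        raise ValueError(
            f"shape mismatch: {numerator.shape} vs {denominator.shape}"
        )
    if numerator.biomarker and numerator.biomarker == denominator.biomarker:
        raise ValueError("numerator and denominator biomarkers must differ")
    if denominator_floor < 0:
        raise ValueError("denominator_floor must be >= 0")

    num = np.asarray(numerator.pixels, dtype=float)
    den = np.asarray(denominator.pixels, dtype=float)
    valid = den > denominator_floor
    r = np.zeros_like(num)
    np.divide(num, den, out=r, where=valid)
    gray = scale.to_gray(r)
    gray[~valid] = 0
    return RatioImage(
        gray=gray,
        valid=valid,
        scale=scale,
        numerator_biomarker=numerator.biomarker,
        denominator_biomarker=denominator.biomarker,
        patient_id=numerator.patient_id or denominator.patient_id,
        field_id=numerator.field_id or denominator.field_id,
        denominator_floor=denominator_floor,
    )


def ratio_histogram(ratio: RatioImage) -> np.ndarray:
    """Count valid pixels per gray level; bins sum to the valid-pixel count."""
    return np.bincount(ratio.gray[ratio.valid].ravel(),
                       minlength=ratio.scale.levels)


def scales_compatible(ratios: Iterable[RatioImage]) -> bool:
    """True iff every ratio image was computed under one identical scale."""
    scales = {r.scale for r in ratios}
    return len(scales) <= 1


def save_ratio_image(ratio: RatioImage, path: str | Path) -> Path:
    """Persist as 8-bit TIFF + JSON sidecar + 1-bit validity-mask PNG."""
    path = Path(path)
    if ratio.scale.levels > 256:
        raise ValueError("only scales with <= 256 levels can be saved as 8-bit")
    tifffile.imwrite(path, ratio.gray.astype(np.uint8))
    sidecar = {
        "scale": ratio.scale.to_dict(),
        "denominator_floor": ratio.denominator_floor,
        "numerator_biomarker": ratio.numerator_biomarker,
        "denominator_biomarker": ratio.denominator_biomarker,
        "patient_id": ratio.patient_id,
        "field_id": ratio.field_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    sort_keys=True) + "\n")
    write_mask_png(ratio.valid, path.with_suffix(".mask.png"))
    return path


def load_ratio_image(path: str | Path) -> RatioImage:
    path = Path(path)
    gray = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    valid = read_mask_png(path.with_suffix(".mask.png"))
    return RatioImage(
        gray=gray.astype(np.int64),
        valid=valid,
        scale=RatioScale(**meta["scale"]),
        numerator_biomarker=meta["numerator_biomarker"],
        denominator_biomarker=meta["denominator_biomarker"],
        patient_id=meta["patient_id"],
        field_id=meta["field_id"],
        denominator_floor=meta["denominator_floor"],
    )
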