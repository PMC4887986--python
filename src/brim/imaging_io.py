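"""Micrograph I/O, frame averaging, line profiles, and pseudocolor rendering.

A *micrograph* here is one fluorescence channel of one microscope field: a
rectangular grid of non-negative intensities together with the biomarker
label (e.g. ``"CD44"``), patient and field identifiers, and an optional
physical pixel size.  Acquisition commonly records a burst of short
exposures of the same field which are then averaged to suppress shot noise;
:func:`average_frames` implements that step in floating precision so no
intermediate re-quantization occurs.

Files are plain grayscale TIFF: a single page is one micrograph, a
multi-page file is a frame stack.  RGB or otherwise multi-sample TIFFs are
rejected — channels must be acquired (and ratioed) separately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from matplotlib import colormaps
from PIL import Image

__all__ = [
    "Micrograph",
    "FrameStack",
    "read_micrograph",
    "write_micrograph",
    "read_frame_stack",
    "write_frame_stack",
    "average_frames",
    "line_profile",
    "write_line_profile",
    "render_pseudocolor",
    "write_png",
    "write_mask_png",
    "read_mask_png",
]


@dataclass
class Micrograph:
    """Single-channel grayscale micrograph with acquisition metadata.

    Parameters
    ----------
    pixels
        2-D array of intensities in arbitrary fluorescence units.  Stored
        as given (integer or float); values must lie in
        ``[0, 2**bit_depth - 1]``.
    bit_depth
        Digitization depth of the source camera file, 8 or 16.
    biomarker
        Antigen label of the channel, e.g. ``"CD74"``.
    patient_id, field_id
        Sample provenance labels.
    pixel_size
        Physical size of one pixel in micrometres, if known.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    biomarker: str = ""
    patient_id: str = ""
    field_id: str = ""
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("micrograph pixels must form a non-empty 2-D grid")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth: {self.bit_depth}")
        if px.min() < 0:
            raise ValueError("micrograph intensities must be non-negative")
        if px.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities exceed the {self.bit_depth}-bit range"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FrameStack:
    """Ordered burst of frames of one field/channel, all the same shape."""

    frames: list[Micrograph]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a frame stack needs at least one frame")
        first = self.frames[0]
        for i, frame in enumerate(self.frames):
            if frame.shape != first.shape:
                raise ValueError(
                    f"frame {i} shape {frame.shape} differs from {first.shape}"
                )
            if frame.biomarker != first.biomarker:
                raise ValueError("all frames must share one biomarker label")

    def __len__(self) -> int:
        return len(self.frames)


def _bit_depth_for(dtype: np.dtype, path: Path) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise OSError(f"{path}: unsupported bit depth (dtype {dtype})")


def read_micrograph(
    path: str | Path,
    biomarker: str = "",
    patient_id: str = "",
    field_id: str = "",
) -> Micrograph:
    """Load a single-page grayscale TIFF without rescaling.

    Raises
    ------
    OSError
        If the file is unreadable, multi-page, not single-channel, or of an
        unsupported bit depth.  The message names the offending path.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise OSError(
                    f"{path}: multi-page stack; use read_frame_stack"
                )
            page = tif.pages[0]
            if page.samplesperpixel != 1:
                raise OSError(f"{path}: not single-channel")
            arr = page.asarray()
    except OSError:
        raise
    except Exception as exc:  # tifffile raises various parse errors
        raise OSError(f"{path}: cannot read TIFF ({exc})") from exc
    if arr.ndim != 2:
        raise OSError(f"{path}: not single-channel")
    return Micrograph(arr, _bit_depth_for(arr.dtype, path), biomarker,
                      patient_id, field_id)


def _quantize(m: Micrograph) -> np.ndarray:
    """Round-and-clip pixels to the integer dtype of the micrograph's depth."""
    dtype = np.uint8 if m.bit_depth == 8 else np.uint16
    arr = np.asarray(m.pixels)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.rint(arr)
    return np.clip(arr, 0, 2**m.bit_depth - 1).astype(dtype)


def write_micrograph(m: Micrograph, path: str | Path) -> Path:
    """Write one micrograph as a single-page grayscale TIFF."""
    path = Path(path)
    tifffile.imwrite(path, _quantize(m))
    return path


def read_frame_stack(
    path: str | Path,
    biomarker: str = "",
    patient_id: str = "",
    field_id: str = "",
) -> FrameStack:
    """Load a grayscale TIFF (one or more pages) as a frame stack."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if tif.pages[0].samplesperpixel != 1:
                raise OSError(f"{path}: not single-channel")
            frames = [page.asarray() for page in tif.pages]
    except OSError:
        raise
    except Exception as exc:
        raise OSError(f"{path}: cannot read TIFF ({exc})") from exc
    depth = _bit_depth_for(frames[0].dtype, path)
    return FrameStack([
        Micrograph(arr, depth, biomarker, patient_id, field_id)
        for arr in frames
    ])


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.stack([_quantize(f) for f in stack.frames]))
    return path


def average_frames(stack: FrameStack) -> Micrograph:
    """Pixel-wise arithmetic mean of a frame stack, kept in float precision.

    The result is not re-quantized; rounding happens only when the image is
    written to file or converted to a ratio image.  Metadata is copied from
    the first frame.
    """
    mean = np.mean([np.asarray(f.pixels, dtype=float) for f in stack.frames],
                   axis=0)
    return replace(stack.frames[0], pixels=mean)


def line_profile(image, row: int) -> np.ndarray:
    """Horizontal intensity profile at ``row``, left to right.

    Accepts a :class:`Micrograph` or a ratio image (anything with a ``gray``
    attribute).  Returns an ``(width, 2)`` array of ``(column, value)``
    pairs of raw pixel values.
    """
    values = image.gray if hasattr(image, "gray") else image.pixels
    values = np.asarray(values)
    n_rows, n_cols = values.shape
    if not 0 <= int(row) < n_rows:
        raise IndexError(f"row {row} outside image with {n_rows} rows")
    return np.column_stack(
        [np.arange(n_cols, dtype=float), values[int(row)].astype(float)]
    )


def write_line_profile(profile: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["column", "value"])
        for col, value in profile:
            writer.writerow([int(col), float(value)])
    return path


def render_pseudocolor(
    ratio,
    colormap: str = "viridis",
    highlight_above: int | None = None,
) -> np.ndarray:
    """Map a ratio image's gray values through a colormap to 8-bit RGB.

    Pixels strictly above ``highlight_above`` (if given) are painted solid
    red, the conventional display for supra-threshold "high ratio" signal;
    invalid pixels (masked denominator) are black.  The colormap is display
    only and never enters quantification.
    """
    try:
        cmap = colormaps[colormap]
    except KeyError:
        raise ValueError(f"unknown colormap: {colormap}") from None
    gray = np.asarray(ratio.gray)
    levels = ratio.scale.levels
    rgba = cmap(gray.astype(float) / (levels - 1))
    rgb = np.clip(np.rint(np.asarray(rgba)[..., :3] * 255), 0, 255).astype(np.uint8)
    if highlight_above is not None:
        rgb[(gray > int(highlight_above)) & ratio.valid] = (255, 0, 0)
    rgb[~ratio.valid] = 0
    return rgb


def write_png(rgb: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(rgb).save(path)
    return path


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Persist a boolean mask as a 1-bit PNG."""
    path = Path(path)
    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("1"), dtype=bool)
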