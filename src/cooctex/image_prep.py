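"""Image loading, ROI extraction, averaging-filter denoising and grey-level
quantization.

Images are plain 2-D ``numpy`` arrays of dtype ``uint8`` (row-major,
``pixels[y, x]``, top-left origin, values in [0, 255]).  ROI coordinates are
0-based with ``x`` as the column and ``y`` as the row, matching the rest of
the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import ValidationError

__all__ = [
    "ROISpec",
    "QuantizedMap",
    "load_image",
    "extract_roi",
    "mean_filter",
    "quantize",
    "read_manifest",
]

#: ITU-R BT.601 luminance weights used to collapse RGB to grey.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = ["image_path", "x0", "y0", "width", "height", "class_label"]


@dataclasses.dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest.

    ``x0``/``y0`` are the 0-based top-left corner; the default 50x50 size is
    the region size used throughout for tissue patches.
    """

    x0: int
    y0: int
    width: int = 50
    height: int = 50
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"ROI must have positive size, got {self.width}x{self.height}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ValidationError(f"ROI corner must be non-negative, got ({self.x0}, {self.y0})")


@dataclasses.dataclass
class QuantizedMap:
    """Integer label grid with a validity mask, ready for cooccurrence counting.

    For grey-level maps the mask is all-true; edge-orientation maps restrict
    counting to edge pixels.
    """

    labels: np.ndarray
    levels: int
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.labels.shape != self.valid_mask.shape:
            raise ValidationError("labels and valid_mask shapes differ")
        if not 2 <= self.levels <= 360:
            raise ValidationError(f"level count {self.levels} out of range")
        if self.valid_mask.any():
            observed = self.labels[self.valid_mask]
            if observed.min() < 0 or observed.max() >= self.levels:
                raise ValidationError("labels outside [0, levels) under the valid mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _as_image(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit greyscale image; RGB input is collapsed to luminance.

    Raises an :class:`IOError` naming the path for unreadable files and a
    :class:`ValidationError` for zero-area images.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            if img.mode in ("RGB", "RGBA"):
                rgb = np.asarray(img)[..., :3].astype(np.float64)
                arr = np.rint(rgb @ _LUMA_WEIGHTS)
            elif img.mode == "L":
                arr = np.asarray(img, dtype=np.float64)
            else:
                arr = np.asarray(img.convert("L"), dtype=np.float64)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"image {path} decodes to zero area")
    return np.clip(arr, 0, 255).astype(np.uint8)


def extract_roi(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Copy a rectangular region out of ``image``.

    The ROI must lie fully inside the image; violations raise a
    :class:`ValidationError` naming the offending coordinates.
    """
    image = _as_image(image)
    h, w = image.shape
    if roi.x0 + roi.width > w or roi.y0 + roi.height > h:
        raise ValidationError(
            f"ROI (x0={roi.x0}, y0={roi.y0}, w={roi.width}, h={roi.height}) "
            f"exceeds image bounds {w}x{h}"
        )
    return image[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width].copy()


def mean_filter(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Averaging-filter denoising: each pixel becomes the rounded mean of its
    ``kernel`` x ``kernel`` neighbourhood (edge replication at borders).

    ``kernel`` must be odd and positive; ``kernel=1`` is the identity.
    Rounding is half-up on the exact integer neighbourhood sum.
    """
    image = _as_image(image)
    if kernel < 1 or kernel % 2 == 0:
        raise ValidationError(f"kernel must be an odd positive integer, got {kernel}")
    if kernel == 1:
        return image.copy()
    k2 = kernel * kernel
    sums = ndimage.correlate(
        image.astype(np.int64), np.ones((kernel, kernel), dtype=np.int64), mode="nearest"
    )
    return ((sums + k2 // 2) // k2).astype(np.uint8)


def quantize(image: np.ndarray, levels: int = 256) -> QuantizedMap:
    """Uniformly bin 8-bit grey values into ``levels`` labels.

    ``label = floor(value * levels / 256)``; monotone in the grey value.
    """
    image = _as_image(image)
    if not 2 <= levels <= 256:
        raise ValidationError(f"levels must be in [2, 256], got {levels}")
    labels = (image.astype(np.int64) * levels) // 256
    return QuantizedMap(labels=labels, levels=levels, valid_mask=np.ones(image.shape, bool))


def read_manifest(path: str | Path) -> list[tuple[str, ROISpec]]:
    """Read a ROI manifest CSV (``image_path,x0,y0,width,height,class_label``)."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} lacks columns {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            (
                str(rec.image_path),
                ROISpec(
                    x0=int(rec.x0),
                    y0=int(rec.y0),
                    width=int(rec.width),
                    height=int(rec.height),
                    class_label=str(rec.class_label),
                ),
            )
        )
    return rows
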