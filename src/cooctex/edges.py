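"""Sobel gradients, edge-orientation maps and edge/gradient statistics.

Edge orientations are undirected (a boundary and its reverse are the same
physical structure), so angles are folded into [0, 180) at integer-degree
resolution.  Dispersion of such axial data is measured on doubled angles.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_prep import QuantizedMap, _as_image

__all__ = [
    "OrientationMap",
    "sobel_gradients",
    "orientation_map",
    "edge_orientation_variability",
    "gradient_statistics",
]

#: Largest possible angular deviation (uniform circular distribution), degrees.
MAX_ANGULAR_DEVIATION_DEG = math.degrees(math.sqrt(2.0))


@dataclasses.dataclass
class OrientationMap:
    """Per-pixel edge orientation in integer degrees [0, 180) with edge mask.

    ``orientation`` is only meaningful where ``edge_mask`` is true; the signed
    Sobel gradients are kept for downstream statistics.
    """

    orientation: np.ndarray
    edge_mask: np.ndarray
    gx: np.ndarray
    gy: np.ndarray

    def to_quantized(self) -> QuantizedMap:
        """View as a label map for cooccurrence counting (labels = degrees)."""
        labels = np.where(self.edge_mask, self.orientation, 0)
        return QuantizedMap(labels=labels, levels=180, valid_mask=self.edge_mask)


def sobel_gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed horizontal and vertical Sobel gradients (edge replication).

    ``gx`` is the derivative along x (columns), ``gy`` along y (rows, positive
    downward).  The image must be at least 3x3.
    """
    image = _as_image(image)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValidationError(f"image {image.shape} smaller than the 3x3 Sobel kernel")
    f = image.astype(np.float64)
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    return gx, gy


def orientation_map(
    gx: np.ndarray,
    gy: np.ndarray,
    magnitude_threshold: float = 0.0,
    bin_width: int = 1,
) -> OrientationMap:
    """Edge orientation = atan2(gy, gx) folded into [0, 180), integer degrees.

    A pixel is an edge where the gradient magnitude is strictly above
    ``magnitude_threshold`` (so gx = gy = 0 is never an edge).  ``bin_width``
    optionally coarsens the orientation to multiples of that many degrees.
    """
    gx = np.asarray(gx, dtype=np.float64)
    gy = np.asarray(gy, dtype=np.float64)
    if gx.shape != gy.shape:
        raise ValidationError(f"gradient shapes differ: {gx.shape} vs {gy.shape}")
    if bin_width < 1 or 180 % bin_width != 0:
        raise ValidationError(f"bin_width must divide 180, got {bin_width}")
    magnitude = np.hypot(gx, gy)
    edge_mask = magnitude > magnitude_threshold
    deg = np.rint(np.degrees(np.arctan2(gy, gx))).astype(np.int64) % 180
    if bin_width > 1:
        deg = (np.rint(deg / bin_width).astype(np.int64) * bin_width) % 180
    return OrientationMap(orientation=deg, edge_mask=edge_mask, gx=gx, gy=gy)


def edge_orientation_variability(omap: OrientationMap) -> float:
    """Angular deviation of the doubled-angle orientation distribution, degrees.

    Orientations are axial (period 180 degrees), so each angle is doubled
    before computing the circular resultant R; the reported value is
    sqrt(2(1-R)) converted to degrees.  It is 0 iff all edge orientations are
    equal and approaches ~81.03 degrees for a uniform spread.  With fewer than
    two edge pixels the feature is undefined and NaN is returned.
    """
    angles = omap.orientation[omap.edge_mask]
    if angles.size < 2:
        return float("nan")
    doubled = np.radians(2.0 * angles.astype(np.float64))
    resultant = np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean())
    return math.degrees(math.sqrt(max(0.0, 2.0 * (1.0 - resultant))))


def gradient_statistics(image: np.ndarray, magnitude_threshold: float = 0.0) -> dict[str, float]:
    """Classical edge/gradient statistics of a ROI.

    Returns ``gradient_mean`` and ``gradient_std`` of the Sobel magnitude over
    all pixels, and ``edge_density`` = fraction of pixels whose magnitude
    exceeds the threshold.
    """
    gx, gy = sobel_gradients(image)
    magnitude = np.hypot(gx, gy)
    return {
        "gradient_mean": float(magnitude.mean()),
        "gradient_std": float(magnitude.std()),
        "edge_density": float((magnitude > magnitude_threshold).mean()),
    }
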