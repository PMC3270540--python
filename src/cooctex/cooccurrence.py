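"""Sparse order-n cooccurrence counting.

A cooccurrence matrix of order ``n`` counts n-tuples of pixels whose positions
satisfy a displacement relation and records the n-tuple of labels they carry
(grey levels for GLCM, edge orientations in degrees for EOCM).  The anchor
pixel is the first tuple element and sits in the central position of the
geometric pattern; the remaining ``n-1`` positions are given by displacement
vectors ``(dx_i, dy_i)`` matched in absolute value:

    |x_{i+1} - x_1| = |dx_i|,  |y_{i+1} - y_1| = |dy_i|,
    sgn((x_{i+1} - x_1)(y_{i+1} - y_1)) = sgn(dx_i * dy_i)

so an axis-aligned vector contributes both +/- placements of the neighbour and
a diagonal vector contributes the two placements whose coordinate-difference
product has the matching sign.  At order 2 this reduces to classical symmetric
Haralick counting.

Storage is a sparse mapping keyed by label tuples: a dense order-5 array over
256 levels would need 256^5 cells, while the number of distinct observed
tuples is bounded by the pixel count.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .image_prep import QuantizedMap

__all__ = [
    "DisplacementSet",
    "CoocTensor",
    "standard_direction_sets",
    "count_cooccurrence",
    "to_probability",
]


@dataclasses.dataclass(frozen=True)
class DisplacementSet:
    """Ordered displacement vectors relating an anchor to its n-1 partners.

    ``vectors`` holds ``(dx, dy)`` pairs with x increasing rightwards and y
    increasing downwards; ``name`` is a stable tag such as ``"0_270"`` built
    from the direction angles in degrees.
    """

    order: int
    vectors: tuple[tuple[int, int], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValidationError(f"order must be >= 2, got {self.order}")
        if len(self.vectors) != self.order - 1:
            raise ValidationError(
                f"order {self.order} needs {self.order - 1} vectors, got {len(self.vectors)}"
            )
        for dx, dy in self.vectors:
            if dx == 0 and dy == 0:
                raise ValidationError("displacement vector must have a nonzero component")


@dataclasses.dataclass
class CoocTensor:
    """Sparse cooccurrence counts or probabilities over label n-tuples."""

    order: int
    levels: int
    entries: dict[tuple[int, ...], float]
    normalized: bool = False
    total: float = 0.0

    def __len__(self) -> int:
        return len(self.entries)

    def max_probability(self) -> float:
        if not self.normalized:
            raise ValidationError("max_probability requires a normalized tensor")
        return max(self.entries.values())


def _angle_to_vector(angle_deg: float, magnitude: int) -> tuple[int, int]:
    # image convention: y grows downward, so a positive angle points up;
    # magnitude scales each nonzero component, so diagonals at magnitude m
    # are (+/-m, +/-m) — components stay in {0, +/-m}
    rad = math.radians(angle_deg)
    return (
        magnitude * int(round(math.cos(rad))),
        magnitude * int(round(-math.sin(rad))),
    )


# direction-angle layouts printed in degrees; orders 3 and 5 use magnitude 2
_ORDER3_COLLINEAR = [(0, 180), (90, 270), (45, 225), (135, 315)]
_ORDER3_RIGHT_ANGLE = [
    (0, 90),
    (90, 180),
    (180, 270),
    (0, 270),
    (45, 135),
    (135, 225),
    (225, 315),
    (45, 315),
]
_ORDER5_GROUPS = [(0, 180, 90, 270), (45, 225, 135, 315)]


def standard_direction_sets(
    order: int, family: str = "glcm", magnitude: int | None = None
) -> list[DisplacementSet]:
    """The standard displacement-vector geometries for orders 2, 3 and 5.

    Order 2 uses the four classical directions 0/45/90/135 degrees at
    magnitude ``d`` (default 1).  Order 3 uses twelve two-vector sets — four
    collinear direction pairs and eight right-angle pairs — and order 5 two
    four-vector groups, both at magnitude 2 by default (components from
    {0, +/-2}).  The EOCM family shares the order-2 and order-3 geometries;
    order 5 is a GLCM-only configuration.
    """
    if family not in ("glcm", "eocm"):
        raise ValidationError(f"unknown family {family!r}")
    if order == 2:
        m = 1 if magnitude is None else magnitude
        return [
            DisplacementSet(2, (_angle_to_vector(a, m),), name=str(a))
            for a in (0, 45, 90, 135)
        ]
    if order == 3:
        m = 2 if magnitude is None else magnitude
        sets = []
        for pair in _ORDER3_COLLINEAR + _ORDER3_RIGHT_ANGLE:
            vecs = tuple(_angle_to_vector(a, m) for a in pair)
            sets.append(DisplacementSet(3, vecs, name="_".join(map(str, pair))))
        return sets
    if order == 5 and family == "glcm":
        m = 2 if magnitude is None else magnitude
        return [
            DisplacementSet(5, tuple(_angle_to_vector(a, m) for a in grp),
                            name="_".join(map(str, grp)))
            for grp in _ORDER5_GROUPS
        ]
    raise ValidationError(f"unsupported order {order} for family {family!r}")


def _candidate_offsets(vec: tuple[int, int]) -> list[tuple[int, int]]:
    """The placements compatible with absolute-value matching of one vector."""
    dx, dy = vec
    if dx != 0 and dy != 0:
        # sign of the coordinate-difference product must match sgn(dx*dy)
        return [(dx, dy), (-dx, -dy)]
    if dx != 0:
        return [(dx, 0), (-dx, 0)]
    return [(0, dy), (0, -dy)]


def _shift(labels: np.ndarray, valid: np.ndarray, dx: int, dy: int):
    """Neighbour view: out[y, x] = labels[y + dy, x + dx] where in bounds."""
    h, w = labels.shape
    out = np.full((h, w), -1, dtype=np.int64)
    ok = np.zeros((h, w), dtype=bool)
    y0, y1 = max(0, -dy), min(h, h - dy)
    x0, x1 = max(0, -dx), min(w, w - dx)
    if y1 > y0 and x1 > x0:
        out[y0:y1, x0:x1] = labels[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        ok[y0:y1, x0:x1] = valid[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    return out, ok


def count_cooccurrence(qmap: QuantizedMap, dset: DisplacementSet) -> CoocTensor:
    """Count label n-tuples over all anchor pixels and compatible placements.

    A tuple is counted only when the anchor and every neighbour are in bounds
    and valid under ``qmap.valid_mask`` (no partial counting).  Displacements
    larger than the map yield an empty tensor with ``total`` 0.
    """
    labels = qmap.labels.astype(np.int64)
    valid = qmap.valid_mask
    n = dset.order
    L = qmap.levels

    code_chunks: list[np.ndarray] = []
    candidate_lists = [_candidate_offsets(v) for v in dset.vectors]
    for combo in itertools.product(*candidate_lists):
        ok = valid.copy()
        stack = [labels]
        for dx, dy in combo:
            shifted, sok = _shift(labels, valid, dx, dy)
            ok &= sok
            stack.append(shifted)
        if not ok.any():
            continue
        code = stack[0][ok].copy()
        for s in stack[1:]:
            code = code * L + s[ok]
        code_chunks.append(code)

    if not code_chunks:
        return CoocTensor(order=n, levels=L, entries={}, normalized=False, total=0.0)

    codes, counts = np.unique(np.concatenate(code_chunks), return_counts=True)
    digits = []
    rest = codes.copy()
    for _ in range(n):
        digits.append(rest % L)
        rest //= L
    tuples = zip(*(d.tolist() for d in reversed(digits)))
    entries = dict(zip(tuples, counts.astype(np.float64).tolist()))
    return CoocTensor(
        order=n, levels=L, entries=entries, normalized=False, total=float(counts.sum())
    )


def to_probability(tensor: CoocTensor) -> CoocTensor:
    """Normalize counts to a probability tensor (entries sum to 1).

    An empty tensor carries no texture information and raises
    :class:`DegenerateInputError`; callers skip that direction set.
    """
    if tensor.total <= 0:
        raise DegenerateInputError("cannot normalize a tensor with zero total count")
    entries = {t: v / tensor.total for t, v in tensor.entries.items()}
    return CoocTensor(
        order=tensor.order,
        levels=tensor.levels,
        entries=entries,
        normalized=True,
        total=tensor.total,
    )
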