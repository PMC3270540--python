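"""Independent oracles used by the test suite.

These deliberately avoid the package's counting engine: the cooccurrence
oracle re-evaluates the displacement predicate over every pixel position for
every tuple slot, and the order-2 Haralick oracle is scikit-image.
"""

from __future__ import annotations

import itertools

import numpy as np

from cooctex.cooccurrence import CoocTensor, DisplacementSet
from cooctex.image_prep import QuantizedMap


def _sign(v: int) -> int:
    return (v > 0) - (v < 0)


def brute_force_cooccurrence(qmap: QuantizedMap, dset: DisplacementSet) -> dict:
    """Enumerate every pixel n-tuple satisfying the displacement predicate.

    For each anchor and each tuple slot, all pixel positions are tested
    against |dx|/|dy| absolute-value matching and the sign rule on the
    coordinate-difference product; counts are accumulated per label tuple.
    """
    labels = qmap.labels
    valid = qmap.valid_mask
    h, w = labels.shape
    positions = [(y, x) for y in range(h) for x in range(w)]
    counts: dict[tuple[int, ...], int] = {}
    for (y1, x1) in positions:
        if not valid[y1, x1]:
            continue
        slot_candidates = []
        for dx, dy in dset.vectors:
            cands = []
            for (y, x) in positions:
                if not valid[y, x]:
                    continue
                if abs(x - x1) != abs(dx) or abs(y - y1) != abs(dy):
                    continue
                if _sign((x - x1) * (y - y1)) != _sign(dx * dy):
                    continue
                cands.append((y, x))
            slot_candidates.append(cands)
        for assignment in itertools.product(*slot_candidates):
            tup = (int(labels[y1, x1]),) + tuple(int(labels[y, x]) for y, x in assignment)
            counts[tup] = counts.get(tup, 0) + 1
    return counts


def skimage_reference_glcm(image: np.ndarray, distance: int = 1):
    """Classical symmetric normalized GLCMs for the four standard directions.

    Returns a list of (levels x levels) probability matrices, one per
    scikit-image angle 0, 45, 90, 135 degrees.
    """
    from skimage.feature import graycomatrix

    levels = int(image.max()) + 1
    mats = graycomatrix(
        image,
        distances=[distance],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    return [mats[:, :, 0, a] for a in range(4)]


def classical_haralick(P: np.ndarray) -> dict:
    """Haralick statistics of one normalized order-2 matrix, by direct sums."""
    levels = P.shape[0]
    i, j = np.mgrid[0:levels, 0:levels]
    p = P
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    sd_i = np.sqrt((((i - mu_i) ** 2) * p).sum())
    sd_j = np.sqrt((((j - mu_j) ** 2) * p).sum())
    nz = p > 0
    corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j)) if sd_i * sd_j > 0 else 0.0
    return {
        "energy": float((p**2).sum()),
        "entropy": float(-(p[nz] * np.log(p[nz])).sum()),
        "contrast": float((((i - j) ** 2) * p).sum()),
        "homogeneity": float((p / (1.0 + (i - j) ** 2)).sum()),
        "correlation": corr,
        "max_probability": float(p.max()),
    }


def exhaustive_cfs_optimum(table, evaluator=None):
    """Best CFS merit over all nonempty feature subsets (oracle for the GA)."""
    from cooctex.selection import CfsEvaluator

    evaluator = evaluator or CfsEvaluator(table)
    names = evaluator.feature_names
    best_merit, best_subset = -np.inf, None
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            m = evaluator.merit(combo)
            if m > best_merit:
                best_merit, best_subset = m, combo
    return list(best_subset), float(best_merit)
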