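"""Relevant-feature selection.

Two complementary selectors are implemented on MDL-discretized columns:

* correlation-based feature selection (CFS), scoring a subset S of k features

      Merit_S = k * r_cf / sqrt(k + k(k-1) * r_ff)

  where r_cf is the mean feature-class correlation and r_ff the mean pairwise
  feature-feature correlation, both measured by symmetrical uncertainty; the
  subset space is explored by a seeded genetic search;

* information-gain attribute evaluation, ranking single features by
  IG = H(C) - H(C|A).

The final relevant set is the union of the CFS subset and the top-ranked
information-gain features.  Entropies in this module are in bits (log2).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GAParams
from .errors import ValidationError

__all__ = [
    "CLASS_COLUMN",
    "SelectionResult",
    "mdl_discretize",
    "discretize_column",
    "symmetrical_uncertainty",
    "info_gain",
    "merit_from_correlations",
    "cfs_merit",
    "CfsEvaluator",
    "genetic_search",
    "select_union",
    "split_features",
    "impute_missing",
]

CLASS_COLUMN = "class"


def split_features(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split a feature table into (features, class labels)."""
    if CLASS_COLUMN not in table.columns:
        raise ValidationError(f"feature table lacks a {CLASS_COLUMN!r} column")
    return table.drop(columns=[CLASS_COLUMN]), table[CLASS_COLUMN]


def impute_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing feature values by the column mean (class column kept).

    Columns that are entirely missing are set to 0.
    """
    X, y = split_features(table)
    X = X.apply(lambda c: c.fillna(c.mean()))
    X = X.fillna(0.0)
    X[CLASS_COLUMN] = y.values
    return X


# --- entropies on discrete codes -----------------------------------------


def _entropy_bits(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, a_codes = np.unique(a, return_inverse=True)
    _, b_codes = np.unique(b, return_inverse=True)
    return a_codes.astype(np.int64) * (b_codes.max() + 1) + b_codes


def _encode(column) -> np.ndarray:
    _, codes = np.unique(np.asarray(column), return_inverse=True)
    return codes


# --- MDL discretization ---------------------------------------------------


def _class_entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _mdl_split(values: np.ndarray, onehot: np.ndarray, cuts: list[float]) -> None:
    """Recursive entropy-based binary splitting with the MDL stopping rule."""
    n = len(values)
    if n < 2:
        return
    totals = onehot.sum(axis=0)
    ent_s = _class_entropy_from_counts(totals)
    k_s = int((totals > 0).sum())
    if ent_s == 0.0:
        return

    # candidate boundaries between adjacent distinct values
    boundary = np.nonzero(values[:-1] < values[1:])[0]
    if boundary.size == 0:
        return
    cum = np.cumsum(onehot, axis=0)  # (n, K)
    left = cum[boundary].astype(np.float64)  # counts left of each candidate
    right = totals[None, :] - left
    n_left = left.sum(axis=1)
    n_right = right.sum(axis=1)

    def _ent_rows(c: np.ndarray) -> np.ndarray:
        tot = c.sum(axis=1, keepdims=True)
        p = np.divide(c, tot, out=np.zeros_like(c), where=tot > 0)
        return -(p * np.log2(p, out=np.zeros_like(p), where=p > 0)).sum(axis=1)

    ent_left = _ent_rows(left)
    ent_right = _ent_rows(right)
    weighted = (n_left * ent_left + n_right * ent_right) / n
    best = int(np.argmin(weighted))
    gain = ent_s - weighted[best]

    k1 = int((left[best] > 0).sum())
    k2 = int((right[best] > 0).sum())
    delta = np.log2(3.0**k_s - 2.0) - (
        k_s * ent_s - k1 * ent_left[best] - k2 * ent_right[best]
    )
    if gain <= (np.log2(n - 1) + delta) / n:
        return

    idx = boundary[best]
    cuts.append(float((values[idx] + values[idx + 1]) / 2.0))
    _mdl_split(values[: idx + 1], onehot[: idx + 1], cuts)
    _mdl_split(values[idx + 1 :], onehot[idx + 1 :], cuts)


def mdl_discretize(values, classes) -> np.ndarray:
    """Fayyad-Irani MDL-stopped entropy discretization; returns sorted cuts.

    A column for which no cut passes the MDL criterion is single-bin (zero
    information).  Requires at least 4 rows.
    """
    values = np.asarray(values, dtype=np.float64)
    classes = np.asarray(classes)
    if values.shape != classes.shape:
        raise ValidationError("values and classes differ in length")
    if len(values) < 4:
        raise ValidationError(f"need >= 4 rows to discretize, got {len(values)}")
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    codes = _encode(classes[order])
    onehot = np.zeros((len(v), codes.max() + 1), dtype=np.int64)
    onehot[np.arange(len(v)), codes] = 1
    cuts: list[float] = []
    _mdl_split(v, onehot, cuts)
    return np.array(sorted(cuts))


def discretize_column(values, classes) -> np.ndarray:
    """Discretized integer codes of a real column (NaN goes to its own bin)."""
    values = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(values)
    codes = np.zeros(len(values), dtype=np.int64)
    if finite.sum() >= 4:
        cuts = mdl_discretize(values[finite], np.asarray(classes)[finite])
        codes[finite] = np.searchsorted(cuts, values[finite])
    codes[~finite] = codes.max() + 1 if (~finite).any() else 0
    return codes


# --- correlation measures -------------------------------------------------


def symmetrical_uncertainty(a, b) -> float:
    """SU(a, b) = 2 (H(a) + H(b) - H(a, b)) / (H(a) + H(b)) in [0, 1].

    Defined as 0 when both columns carry zero entropy.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("columns differ in length")
    ha = _entropy_bits(a)
    hb = _entropy_bits(b)
    if ha + hb == 0.0:
        return 0.0
    hab = _entropy_bits(_joint_codes(a, b))
    su = 2.0 * (ha + hb - hab) / (ha + hb)
    return float(min(1.0, max(0.0, su)))


def info_gain(attr, cls) -> float:
    """Information gain IG = H(C) - H(C|A) in bits, always in [0, H(C)]."""
    attr = np.asarray(attr)
    cls = np.asarray(cls)
    if attr.shape != cls.shape:
        raise ValidationError("columns differ in length")
    hc = _entropy_bits(cls)
    ha = _entropy_bits(attr)
    hac = _entropy_bits(_joint_codes(attr, cls))
    return float(max(0.0, hc + ha - hac))


def merit_from_correlations(k: int, r_cf: float, r_ff: float) -> float:
    """CFS subset merit k*r_cf / sqrt(k + k(k-1)*r_ff); 0 on a zero denominator."""
    if k < 1:
        raise ValidationError("subset must contain at least one feature")
    denom = k + k * (k - 1) * r_ff
    if denom <= 0:
        return 0.0
    return k * r_cf / float(np.sqrt(denom))


class CfsEvaluator:
    """Caches discretized columns and symmetrical-uncertainty values so the
    genetic search can score thousands of subsets cheaply."""

    def __init__(self, table: pd.DataFrame):
        X, y = split_features(table)
        self.feature_names: list[str] = list(X.columns)
        y_codes = _encode(y)
        self._cols = {
            name: discretize_column(X[name].to_numpy(), y_codes) for name in self.feature_names
        }
        self.su_class = {
            name: symmetrical_uncertainty(self._cols[name], y_codes)
            for name in self.feature_names
        }
        self._pair_cache: dict[frozenset, float] = {}
        self._y = y_codes

    def su_pair(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self._pair_cache:
            self._pair_cache[key] = symmetrical_uncertainty(self._cols[a], self._cols[b])
        return self._pair_cache[key]

    def merit(self, names) -> float:
        names = list(names)
        if not names:
            return 0.0
        k = len(names)
        r_cf = float(np.mean([self.su_class[n] for n in names]))
        if k == 1:
            return merit_from_correlations(1, r_cf, 0.0)
        pairs = [self.su_pair(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        r_ff = float(np.mean(pairs))
        return merit_from_correlations(k, r_cf, r_ff)

    def info_gains(self) -> list[tuple[str, float]]:
        """Ranked (feature, IG) list, ties broken by column order."""
        gains = [(name, info_gain(self._cols[name], self._y)) for name in self.feature_names]
        order = {name: i for i, name in enumerate(self.feature_names)}
        return sorted(gains, key=lambda t: (-t[1], order[t[0]]))


def cfs_merit(subset, table: pd.DataFrame) -> float:
    """Merit of a named feature subset on a feature table."""
    subset = list(subset)
    if not subset:
        raise ValidationError("subset must be nonempty")
    evaluator = CfsEvaluator(table)
    missing = [s for s in subset if s not in evaluator.su_class]
    if missing:
        raise ValidationError(f"features not in table: {missing}")
    return evaluator.merit(subset)


# --- genetic search -------------------------------------------------------


def genetic_search(
    table: pd.DataFrame,
    ga: GAParams | None = None,
    evaluator: CfsEvaluator | None = None,
) -> tuple[list[str], float]:
    """Maximize CFS merit over bitstring chromosomes.

    Roulette-wheel selection on merit, single-point crossover, independent
    per-bit mutation, one elite chromosome carried over, and the best-ever
    subset returned.  Fully reproducible under a fixed seed.
    """
    ga = ga or GAParams()
    ga.validate()
    evaluator = evaluator or CfsEvaluator(table)
    names = evaluator.feature_names
    m = len(names)
    if m < 1:
        raise ValidationError("table has no features")
    rng = np.random.default_rng(ga.seed)

    def fitness(chrom: np.ndarray) -> float:
        if not chrom.any():
            return 0.0
        return evaluator.merit([names[i] for i in np.nonzero(chrom)[0]])

    pop = rng.integers(0, 2, size=(ga.population_size, m)).astype(bool)
    merits = np.array([fitness(c) for c in pop])
    best_idx = int(np.argmax(merits))
    best_chrom, best_merit = pop[best_idx].copy(), float(merits[best_idx])

    for _ in range(ga.generations):
        # windowed roulette wheel: selection probability proportional to the
        # merit above the worst chromosome, which keeps selection pressure
        # meaningful when merits cluster
        weights = merits - merits.min()
        probs = weights / weights.sum() if weights.sum() > 0 else np.full(len(pop), 1 / len(pop))
        next_pop = [pop[int(np.argmax(merits))].copy() for _ in range(ga.elitism)]
        while len(next_pop) < ga.population_size:
            i, j = rng.choice(len(pop), size=2, p=probs)
            a, b = pop[i].copy(), pop[j].copy()
            if m > 1 and rng.random() < ga.crossover_prob:
                cut = int(rng.integers(1, m))
                a[:cut], b[:cut] = pop[j][:cut], pop[i][:cut]
            for child in (a, b):
                flip = rng.random(m) < ga.mutation_prob
                child[flip] = ~child[flip]
                next_pop.append(child)
        pop = np.array(next_pop[: ga.population_size])
        merits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmax(merits))
        if merits[gen_best] > best_merit:
            best_merit = float(merits[gen_best])
            best_chrom = pop[gen_best].copy()

    # the search can always represent singletons; never return worse than the
    # best single feature
    for i, name in enumerate(names):
        single = evaluator.merit([name])
        if single > best_merit:
            best_merit = single
            best_chrom = np.zeros(m, dtype=bool)
            best_chrom[i] = True

    subset = [names[i] for i in np.nonzero(best_chrom)[0]]
    return subset, best_merit


# --- union rule -----------------------------------------------------------


@dataclasses.dataclass
class SelectionResult:
    """CFS subset, information-gain ranking and their union."""

    cfs_subset: list[str]
    cfs_merit: float
    ig_ranking: list[tuple[str, float]]
    ig_top_k: int
    final_set: list[str]

    @property
    def ig_selected(self) -> list[str]:
        return [name for name, _ in self.ig_ranking[: self.ig_top_k]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cfs_subset": self.cfs_subset,
                    "cfs_merit": self.cfs_merit,
                    "ig_ranking": [[n, g] for n, g in self.ig_ranking],
                    "ig_top_k": self.ig_top_k,
                    "final_set": self.final_set,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            cfs_subset=list(d["cfs_subset"]),
            cfs_merit=float(d["cfs_merit"]),
            ig_ranking=[(n, float(g)) for n, g in d["ig_ranking"]],
            ig_top_k=int(d["ig_top_k"]),
            final_set=list(d["final_set"]),
        )


def select_union(
    table: pd.DataFrame,
    ig_top_k: int = 10,
    ga: GAParams | None = None,
    ig_positive_only: bool = False,
) -> SelectionResult:
    """Final relevant set = (genetic CFS subset) union (top-IG features).

    ``ig_top_k`` is capped at the feature count; with ``ig_positive_only``
    zero-gain features never enter through the ranking.  The result is never
    empty: if both selectors come back empty the single best-IG feature is
    retained.
    """
    evaluator = CfsEvaluator(table)
    ig_top_k = min(ig_top_k, len(evaluator.feature_names))
    cfs_subset, merit = genetic_search(table, ga=ga, evaluator=evaluator)
    ranking = evaluator.info_gains()
    top = ranking[:ig_top_k]
    if ig_positive_only:
        top = [(n, g) for n, g in top if g > 0]
    chosen = set(cfs_subset) | {n for n, _ in top}
    if not chosen and ranking:
        chosen = {ranking[0][0]}
    final = [n for n in evaluator.feature_names if n in chosen]
    return SelectionResult(
        cfs_subset=cfs_subset,
        cfs_merit=merit,
        ig_ranking=ranking,
        ig_top_k=ig_top_k,
        final_set=final,
    )
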