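"""Fuzzy-rough nearest neighbour (FRNN) classification.

Similarity between objects is a fuzzy tolerance relation: the minimum over
attributes of ``1 - |a(x) - a(y)| / (a_max - a_min)``, with the per-attribute
ranges taken from the training pool's statistics. Class membership of a test
object is scored through its fuzzy lower and upper approximations over the k
nearest (most similar) neighbours:

* lower(C) = min over neighbours x of I(R(x, y), C(x)) — high when *all*
  neighbours belong to C;
* upper(C) = max over neighbours x of T(R(x, y), C(x)) — high when *at least
  one* neighbour belongs to C;

with the Kleene-Dienes implicator I(a, b) = max(1 - a, b), the minimum t-norm
T(a, b) = min(a, b), and crisp memberships C(x) in {0, 1}. The predicted
class maximises (lower + upper) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pool import AttributeStats, TrainingPool

__all__ = [
    "NeighbourList",
    "ClassScores",
    "attr_similarity",
    "tolerance",
    "pool_similarities",
    "nearest_neighbours",
    "scores_from_neighbours",
    "frnn_predict",
]


@dataclass(frozen=True)
class NeighbourList:
    """Nearest neighbours of a test object, ordered by descending similarity.

    ``entries`` pairs each neighbour's insertion index with its tolerance
    similarity; ``positions`` carries the corresponding physical rows in the
    pool for fast counter updates.
    """

    entries: tuple[tuple[int, float], ...]
    k_requested: int
    positions: tuple[int, ...] = field(default=(), compare=False)

    @property
    def similarities(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ClassScores:
    """Per-class fuzzy-rough approximation memberships and the prediction."""

    lower: dict[str, float]
    upper: dict[str, float]
    predicted: str

    def score(self, label: str) -> float:
        return 0.5 * (self.lower[label] + self.upper[label])

    @property
    def scores(self) -> dict[str, float]:
        return {c: self.score(c) for c in self.lower}


def attr_similarity(a_x: float, a_y: float, a_min: float, a_max: float) -> float:
    """Per-attribute similarity ``1 - |a_x - a_y| / (a_max - a_min)`` in [0, 1].

    Inputs are clamped into [a_min, a_max] first, so values outside the
    recorded range (possible on a stream) cannot push the similarity below
    zero. A zero-width range means the attribute is constant and carries no
    discriminating information: similarity 1.
    """
    if not (math.isfinite(a_x) and math.isfinite(a_y)):
        raise ValueError("non-finite attribute value")
    if a_min > a_max:
        raise ValueError("a_min must not exceed a_max")
    if a_max == a_min:
        return 1.0
    a_x = min(max(a_x, a_min), a_max)
    a_y = min(max(a_y, a_min), a_max)
    return 1.0 - abs(a_x - a_y) / (a_max - a_min)


def tolerance(x: np.ndarray, y: np.ndarray, stats: AttributeStats) -> float:
    """Fuzzy tolerance relation R(x, y): min over attributes of attr_similarity."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    return min(
        attr_similarity(x[j], y[j], stats.a_min[j], stats.a_max[j])
        for j in range(x.size)
    )


def pool_similarities(pool: TrainingPool, y: np.ndarray) -> np.ndarray:
    """Tolerance similarity of ``y`` to every pool object (vectorised)."""
    y = np.asarray(y, dtype=float)
    if y.size != pool.n_attributes:
        raise ValueError("test vector length does not match pool attributes")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite test vector")
    lo, hi = pool.stats.a_min, pool.stats.a_max
    rng = hi - lo
    yc = np.clip(y, lo, hi)
    # stored values always lie within the (widen-only) stats, so only the
    # test vector needs clamping
    with np.errstate(divide="ignore", invalid="ignore"):
        per_attr = 1.0 - np.abs(pool.features - yc[None, :]) / rng[None, :]
    per_attr[:, rng == 0] = 1.0  # constant attribute: similarity 1
    return per_attr.min(axis=1)


def nearest_neighbours(pool: TrainingPool, y: np.ndarray, k: int) -> NeighbourList:
    """Top ``min(k, len(pool))`` objects by tolerance similarity, descending.

    Ties in similarity go to the object with the smaller insertion index,
    so the ranking is deterministic and independent of physical storage
    order.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if k < 1:
        raise ValueError("k must be >= 1")
    sims = pool_similarities(pool, y)
    idx = pool.insertion_indices
    m = min(k, len(pool))
    # lexicographic: primary descending similarity, secondary ascending index
    order = np.lexsort((idx, -sims))[:m]
    entries = tuple((int(idx[p]), float(sims[p])) for p in order)
    return NeighbourList(entries=entries, k_requested=k,
                         positions=tuple(int(p) for p in order))


def scores_from_neighbours(
    pool: TrainingPool, neighbours: NeighbourList
) -> ClassScores:
    """Lower/upper approximations and prediction from an explicit
    neighbour list (the core of :func:`frnn_predict`)."""
    classes = sorted(pool.class_set)
    sims = neighbours.similarities
    nb_labels = [pool.labels[p] for p in neighbours.positions]
    lower: dict[str, float] = {}
    upper: dict[str, float] = {}
    for c in classes:
        member = np.array([lab == c for lab in nb_labels])
        # I(a, b) = max(1 - a, b) with crisp b: 1 on members, 1 - sim otherwise
        lower[c] = float(np.min(np.where(member, 1.0, 1.0 - sims)))
        # T(a, b) = min(a, b): sim on members, 0 otherwise
        upper[c] = float(np.max(np.where(member, sims, 0.0)))
    # argmax of mean(lower, upper); ties -> larger upper, then label order
    predicted = min(
        classes,
        key=lambda c: (-0.5 * (lower[c] + upper[c]), -upper[c], c),
    )
    return ClassScores(lower=lower, upper=upper, predicted=predicted)


def frnn_predict(
    pool: TrainingPool, y: np.ndarray, k: int = 5
) -> ClassScores:
    """Classify ``y`` from its k most similar pool objects.

    Returns per-class lower/upper approximation values and the predicted
    class (argmax of their mean; ties resolved by larger upper approximation
    then lexicographically smaller label).
    """
    neighbours = nearest_neighbours(pool, y, k)
    return scores_from_neighbours(pool, neighbours)
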