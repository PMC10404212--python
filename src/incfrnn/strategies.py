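"""Incremental update strategies for the FRNN training pool.

Two strategies refine the knowledge granule as test objects stream in:

* **actual-class** — the ground-truth strategy: a test object is inserted
  whenever it was misclassified. Usable only when the true label is
  available, which authentication at run time does not grant.
* **probability-based** — the label-free strategy: the insertion decision
  combines (a) the relative difference D between the top two neighbour
  similarities against a threshold derived from the whole neighbour list,
  and (b) agreement between the predicted class and the class with the
  highest usage-weighted probability. Inserted objects carry the predicted
  label.

Both strategies increment the usage counters of the k nearest neighbours on
every step, and when a window size threshold W > 0 is set they evict the
least-used object (FIFO among ties) until the pool fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .frnn import ClassScores, NeighbourList, nearest_neighbours
from .pool import TrainingPool, pool_delete_least_used, pool_insert

__all__ = [
    "Strategy",
    "UpdateConfig",
    "InsertionContext",
    "relative_difference",
    "insertion_threshold",
    "class_probabilities",
    "decide_insertion",
    "apply_probability_update",
    "apply_actual_class_update",
]


class Strategy(str, Enum):
    ACTUAL_CLASS = "actual_class"
    PROBABILITY = "probability"
    NONE = "none"


@dataclass(frozen=True)
class UpdateConfig:
    """Parameters of an incremental run.

    ``window_size`` caps the pool (0 = unlimited); ``k`` is the neighbour
    count used both for classification and for counter updates.
    """

    k: int = 5
    window_size: int = 0
    strategy: Strategy = Strategy.PROBABILITY

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.window_size < 0:
            raise ValueError("window_size must be >= 0")


@dataclass
class InsertionContext:
    """Audit record of one probability-based update step."""

    sims: tuple[float, ...]
    top_two_diff: float
    threshold: float
    probs: dict[str, float]
    best_prob_class: str
    predicted: str
    inserted: bool
    deleted_ids: list[int] = field(default_factory=list)
    neighbour_ids: tuple[int, ...] = ()  # the k objects whose counters rose
    cold_start: bool = False


def relative_difference(sim_a: float, sim_b: float) -> float:
    """Difference of two similarities relative to their mean:
    ``(sim_a - sim_b) / ((sim_a + sim_b) / 2)``; 0 when both are 0."""
    if sim_a < sim_b:
        raise ValueError("similarities must be in descending order")
    if sim_a == 0.0:
        return 0.0
    return (sim_a - sim_b) / ((sim_a + sim_b) / 2.0)


def insertion_threshold(sims) -> float:
    """Half the summed relative differences of consecutive similarity pairs.

    The list is the descending similarities of the retrieved neighbours
    (k+1 of them when the pool allows, so that k consecutive pairs enter
    the sum)."""
    sims = [float(s) for s in sims]
    if len(sims) < 2:
        raise ValueError("need at least two similarities")
    return 0.5 * sum(
        relative_difference(sims[i], sims[i + 1]) for i in range(len(sims) - 1)
    )


def class_probabilities(
    pool: TrainingPool, neighbours: NeighbourList
) -> dict[str, float]:
    """Usage-weighted class probabilities over the neighbour list.

    For each class C present in the pool::

        P(C) = [ sum of counters of neighbours in C / sum of all neighbour
                 counters ] / sum of counters of pool objects in C

    Classes absent from the neighbour list score 0. The values are not a
    normalised distribution; only their argmax is used downstream.
    """
    if len(neighbours) == 0:
        raise ValueError("empty neighbour list")
    counters = pool.counters
    labels = pool.labels
    nb_pos = list(neighbours.positions)
    total_nb = float(sum(int(counters[p]) for p in nb_pos))
    probs: dict[str, float] = {}
    for c in sorted(pool.class_set):
        nb_mass = float(sum(int(counters[p]) for p in nb_pos if labels[p] == c))
        class_mass = float(pool.class_counter_mass(c))
        probs[c] = (nb_mass / total_nb) / class_mass if nb_mass > 0 else 0.0
    return probs


def _best_prob_class(probs: dict[str, float], predicted: str) -> str:
    """Argmax of the class probabilities; if the predicted class ties for the
    maximum it wins, otherwise ties resolve lexicographically."""
    best = max(probs.values())
    tied = sorted(c for c, p in probs.items() if p == best)
    if predicted in tied:
        return predicted
    return tied[0]


def decide_insertion(
    D: float, threshold: float, predicted: str, best_prob_class: str
) -> bool:
    """The two insertion conditions, strict on both inequalities:

    1. D > threshold and predicted differs from the highest-probability class
       (a clear-cut neighbourhood voting against the established classes:
       likely a new characteristic worth storing);
    2. D < threshold and predicted equals the highest-probability class
       (an ambiguous neighbourhood where the prediction is nevertheless
       corroborated).

    ``D == threshold`` inserts nothing.
    """
    if D < 0 or threshold < 0:
        raise ValueError("D and threshold must be non-negative")
    if D > threshold:
        return predicted != best_prob_class
    if D < threshold:
        return predicted == best_prob_class
    return False


def _increment_positions(pool: TrainingPool, positions) -> None:
    """Counter increment by physical position (valid only immediately after
    neighbour retrieval, before any insertion or deletion); equivalent to
    :func:`incfrnn.pool.increment_usage` on the same objects."""
    for pos in positions:
        pool._counters[pos] += 1
        pool._class_mass[pool._labels[pos]] += 1


def _window_evict(pool: TrainingPool, window_size: int) -> list[int]:
    deleted: list[int] = []
    while window_size > 0 and len(pool) > window_size:
        victim = None
        counters = pool.counters
        low = np.nonzero(counters == counters.min())[0]
        pos = low[np.argmin(pool.insertion_indices[low])]
        victim = int(pool.insertion_indices[pos])
        pool_delete_least_used(pool)
        deleted.append(victim)
    return deleted


def apply_probability_update(
    pool: TrainingPool,
    y: np.ndarray,
    scores: ClassScores,
    config: UpdateConfig,
    retrieved: NeighbourList | None = None,
) -> tuple[TrainingPool, InsertionContext]:
    """One probability-based update step; never reads a true label.

    Order of operations: retrieve min(k+1, pool size) neighbours; D from the
    top two similarities, threshold over the whole retrieved list; class
    probabilities on the pre-increment counters of the top k; increment the
    top k counters; insert ``y`` under its predicted label if the insertion
    conditions say so; evict least-used objects down to the window size.

    A pool with fewer than two objects cannot produce the two similarities
    the threshold needs: the object is inserted unconditionally (cold start).

    ``retrieved`` may carry a pre-fetched ``nearest_neighbours(pool, y,
    k + 1)`` result to avoid a second similarity sweep; it must come from
    this pool and ``y`` with no intervening pool mutation.
    """
    predicted = scores.predicted
    if len(pool) < 2:
        pool_insert(pool, y, predicted)
        deleted = _window_evict(pool, config.window_size)
        return pool, InsertionContext(
            sims=(), top_two_diff=0.0, threshold=0.0, probs={},
            best_prob_class=predicted, predicted=predicted,
            inserted=True, deleted_ids=deleted, cold_start=True,
        )

    if retrieved is None or retrieved.k_requested != config.k + 1:
        retrieved = nearest_neighbours(pool, y, config.k + 1)
    sims = retrieved.similarities
    D = relative_difference(float(sims[0]), float(sims[1]))
    threshold = insertion_threshold(sims)

    top_k = NeighbourList(
        entries=retrieved.entries[: config.k],
        k_requested=config.k,
        positions=retrieved.positions[: config.k],
    )
    probs = class_probabilities(pool, top_k)
    best = _best_prob_class(probs, predicted)
    _increment_positions(pool, top_k.positions)

    inserted = decide_insertion(D, threshold, predicted, best)
    if inserted:
        pool_insert(pool, y, predicted)
    deleted = _window_evict(pool, config.window_size)
    return pool, InsertionContext(
        sims=tuple(float(s) for s in sims),
        top_two_diff=D, threshold=threshold, probs=probs,
        best_prob_class=best, predicted=predicted,
        inserted=inserted, deleted_ids=deleted,
        neighbour_ids=top_k.ids,
    )


def apply_actual_class_update(
    pool: TrainingPool,
    y: np.ndarray,
    predicted: str,
    actual: str,
    config: UpdateConfig,
    neighbours: NeighbourList | None = None,
) -> TrainingPool:
    """One ground-truth update step: insert ``y`` under its actual label when
    it was misclassified; always increment the k nearest neighbours' counters;
    then apply the window eviction loop.

    ``neighbours`` may carry the prediction's neighbour list to avoid a
    second similarity sweep (same caveats as in
    :func:`apply_probability_update`)."""
    if len(pool) > 0:
        if neighbours is None:
            neighbours = nearest_neighbours(pool, y, config.k)
        _increment_positions(pool, neighbours.positions[: config.k])
    if predicted != actual:
        pool_insert(pool, y, actual)
    _window_evict(pool, config.window_size)
    return pool
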