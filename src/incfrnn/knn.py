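"""KNN benchmark with a FIFO window (an IBk-style incremental learner).

Plain Euclidean k-nearest-neighbour majority voting, updated by the
first-in-first-out strategy: every test object is inserted and, once the
window is full, the oldest object is evicted regardless of label or usage.
On an imbalanced stream this label-blind eviction can wash every minority
(client) object out of the pool — the failure mode the probability-based
strategy exists to avoid.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .pool import TrainingPool, pool_insert

__all__ = ["InsertLabelMode", "KNNConfig", "knn_predict", "apply_fifo_update"]


class InsertLabelMode(str, Enum):
    PREDICTED = "predicted"
    ACTUAL = "actual"


@dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    window_size: int = 0
    insert_label_mode: InsertLabelMode = InsertLabelMode.PREDICTED

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.window_size < 0:
            raise ValueError("window_size must be >= 0")


def knn_predict(
    pool: TrainingPool, y: np.ndarray, k: int = 5, positive_label: str = "client"
) -> tuple[str, float]:
    """Majority vote over the k nearest objects by Euclidean distance.

    Vote ties go to the class of the single nearest neighbour; distance ties
    in neighbour selection go to the older object. The returned score is the
    fraction of votes for ``positive_label``, for ROC ranking.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if k < 1:
        raise ValueError("k must be >= 1")
    y = np.asarray(y, dtype=float)
    diffs = pool.features - y[None, :]
    dists = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    idx = pool.insertion_indices
    m = min(k, len(pool))
    order = np.lexsort((idx, dists))[:m]
    votes = Counter(pool.labels[p] for p in order)
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    if len(tied) == 1:
        predicted = tied[0]
    else:
        predicted = pool.labels[order[0]]
    score = votes.get(positive_label, 0) / m
    return predicted, score


def apply_fifo_update(
    pool: TrainingPool, y: np.ndarray, label: str, config: KNNConfig
) -> TrainingPool:
    """Insert ``y`` unconditionally, then evict oldest objects past the window."""
    pool_insert(pool, y, label)
    while config.window_size > 0 and len(pool) > config.window_size:
        pos = int(np.argmin(pool.insertion_indices))
        pool._remove_at(pos)
    return pool
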