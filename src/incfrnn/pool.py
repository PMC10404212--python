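"""Training pool: the mutable knowledge granule of instance-based learning.

A :class:`TrainingPool` holds labelled feature vectors together with the
bookkeeping the incremental update strategies need: a per-object usage
(frequency) counter, a per-object insertion index recording arrival order,
and running per-attribute min/max statistics that normalise the fuzzy
similarity measure.

Storage is numpy-backed with amortised growth so that similarity queries
against the whole pool vectorise; logical identity of an object is its
insertion index, never its physical row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledObject",
    "AttributeStats",
    "TrainingPool",
    "pool_insert",
    "pool_delete_least_used",
    "increment_usage",
]


@dataclass(frozen=True)
class LabeledObject:
    """One training object: feature vector, class label, usage counter, arrival order."""

    features: np.ndarray
    class_label: str
    frequency_counter: int
    insertion_index: int


@dataclass
class AttributeStats:
    """Per-attribute observed minima and maxima (the a_min / a_max of the
    similarity normalisation)."""

    a_min: np.ndarray
    a_max: np.ndarray

    def __post_init__(self) -> None:
        self.a_min = np.asarray(self.a_min, dtype=float)
        self.a_max = np.asarray(self.a_max, dtype=float)
        if self.a_min.shape != self.a_max.shape:
            raise ValueError("a_min and a_max must have the same shape")
        if np.any(self.a_min > self.a_max):
            raise ValueError("a_min must not exceed a_max")

    @property
    def n_attributes(self) -> int:
        return self.a_min.size

    def widen(self, values: np.ndarray) -> None:
        np.minimum(self.a_min, values, out=self.a_min)
        np.maximum(self.a_max, values, out=self.a_max)

    def range(self) -> np.ndarray:
        return self.a_max - self.a_min


class TrainingPool:
    """Ordered collection of labelled objects with usage counters.

    Attribute statistics only widen on insertion; they are not shrunk on
    deletion (pass ``exact_stats=True`` to :func:`pool_delete_least_used`
    to recompute exactly). Widened ranges keep all similarities in [0, 1]
    and change them only by a bounded monotone rescaling.
    """

    _GROW = 256

    def __init__(self, n_attributes: int):
        if n_attributes < 1:
            raise ValueError("pool needs at least one attribute")
        self._d = int(n_attributes)
        cap = self._GROW
        self._X = np.empty((cap, self._d), dtype=float)
        self._labels: list[str] = []
        self._counters = np.empty(cap, dtype=np.int64)
        self._indices = np.empty(cap, dtype=np.int64)
        self._n = 0
        self.next_index = 0
        self.stats = AttributeStats(np.zeros(self._d), np.zeros(self._d))
        # stats of an empty pool are a placeholder; the first insertion
        # collapses them onto the inserted vector
        self._sentinel = True
        self._class_mass: dict[str, int] = {}  # summed counters per class

    # -- introspection -------------------------------------------------

    def __len__(self) -> int:
        return self._n

    @property
    def n_attributes(self) -> int:
        return self._d

    @property
    def features(self) -> np.ndarray:
        """View of the stored feature matrix, shape (n, d). Do not mutate."""
        return self._X[: self._n]

    @property
    def labels(self) -> list[str]:
        return self._labels

    @property
    def counters(self) -> np.ndarray:
        return self._counters[: self._n]

    @property
    def insertion_indices(self) -> np.ndarray:
        return self._indices[: self._n]

    @property
    def class_set(self) -> set[str]:
        return set(self._labels)

    def class_counter_mass(self, label: str) -> int:
        """Summed frequency counters of all objects with the given label."""
        return self._class_mass.get(label, 0)

    def objects(self) -> list[LabeledObject]:
        """Objects in arrival order."""
        order = np.argsort(self._indices[: self._n])
        return [
            LabeledObject(
                features=self._X[i].copy(),
                class_label=self._labels[i],
                frequency_counter=int(self._counters[i]),
                insertion_index=int(self._indices[i]),
            )
            for i in order
        ]

    def position_of(self, insertion_index: int) -> int:
        pos = np.nonzero(self._indices[: self._n] == insertion_index)[0]
        if pos.size == 0:
            raise KeyError(f"no object with insertion index {insertion_index}")
        return int(pos[0])

    # -- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Snapshot as a DataFrame (one row per object, arrival order)."""
        objs = self.objects()
        data = {f"f{j}": [o.features[j] for o in objs] for j in range(self._d)}
        data["class"] = [o.class_label for o in objs]
        data["frequency_counter"] = [o.frequency_counter for o in objs]
        data["insertion_index"] = [o.insertion_index for o in objs]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrainingPool":
        meta = {"class", "frequency_counter", "insertion_index"}
        feat_cols = [c for c in frame.columns if c not in meta]
        pool = cls(len(feat_cols))
        for _, row in frame.iterrows():
            pool._append(
                np.asarray([row[c] for c in feat_cols], dtype=float),
                str(row["class"]),
                int(row["frequency_counter"]),
                int(row["insertion_index"]),
            )
        pool.next_index = int(frame["insertion_index"].max()) + 1 if len(frame) else 0
        return pool

    # -- internal ------------------------------------------------------

    def _ensure_capacity(self) -> None:
        if self._n == self._X.shape[0]:
            cap = self._X.shape[0] * 2
            self._X = np.resize(self._X, (cap, self._d))
            self._counters = np.resize(self._counters, cap)
            self._indices = np.resize(self._indices, cap)

    def _append(self, x: np.ndarray, label: str, counter: int, index: int) -> None:
        self._ensure_capacity()
        self._X[self._n] = x
        self._labels.append(label)
        self._counters[self._n] = counter
        self._indices[self._n] = index
        self._n += 1
        self._class_mass[label] = self._class_mass.get(label, 0) + counter
        if self._sentinel:
            self.stats.a_min[:] = x
            self.stats.a_max[:] = x
            self._sentinel = False
        else:
            self.stats.widen(x)

    def _remove_at(self, pos: int) -> LabeledObject:
        removed = LabeledObject(
            self._X[pos].copy(), self._labels[pos],
            int(self._counters[pos]), int(self._indices[pos]),
        )
        self._class_mass[removed.class_label] -= removed.frequency_counter
        if self._class_mass[removed.class_label] == 0:
            del self._class_mass[removed.class_label]
        last = self._n - 1
        if pos != last:  # swap-remove; identity lives in insertion_index
            self._X[pos] = self._X[last]
            self._labels[pos] = self._labels[last]
            self._counters[pos] = self._counters[last]
            self._indices[pos] = self._indices[last]
        self._labels.pop()
        self._n = last
        return removed


def pool_insert(pool: TrainingPool, features: Sequence[float], label: str) -> TrainingPool:
    """Append a new object with frequency counter 1 and the next insertion index.

    The counter starts at 1, not 0, so the per-class counter mass in the
    class-probability denominator can never be zero for a class that is
    present in the pool. Attribute stats widen to cover the new values.
    Mutates and returns ``pool``.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 1 or x.size != pool.n_attributes:
        raise ValueError(
            f"feature vector of length {x.size} does not match pool "
            f"attribute count {pool.n_attributes}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature value rejected")
    pool._append(x, str(label), 1, pool.next_index)
    pool.next_index += 1
    return pool


def pool_delete_least_used(pool: TrainingPool, exact_stats: bool = False) -> TrainingPool:
    """Remove the object with the lowest frequency counter.

    Ties break first-in-first-out: among equal counters the smallest
    insertion index goes. With all-equal counters the rule therefore
    degenerates to plain FIFO eviction. Attribute stats are left widened
    unless ``exact_stats`` requests an exact recompute.
    """
    if len(pool) == 0:
        raise ValueError("cannot delete from an empty pool")
    counters = pool.counters
    low = np.nonzero(counters == counters.min())[0]
    pos = low[np.argmin(pool.insertion_indices[low])]
    pool._remove_at(int(pos))
    if exact_stats and len(pool):
        pool.stats.a_min[:] = pool.features.min(axis=0)
        pool.stats.a_max[:] = pool.features.max(axis=0)
    return pool


def increment_usage(pool: TrainingPool, neighbour_indices: Iterable[int]) -> TrainingPool:
    """Add 1 to the frequency counter of each listed object (by insertion index)."""
    for idx in neighbour_indices:
        pos = pool.position_of(int(idx))
        pool._counters[pos] += 1
        pool._class_mass[pool._labels[pos]] += 1
    return pool
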