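"""Correlation-based feature selection (CFS).

A feature subset S of size k is scored by the heuristic merit

    Merit_S = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where r_cf is the mean absolute feature-class correlation of the subset and
r_ff its mean absolute feature-feature inter-correlation. The merit rewards
relevance and penalises redundancy: a duplicate of a feature already in the
subset raises r_ff without raising r_cf and can never improve the score.

Correlations are absolute Pearson (point-biserial against the 0/1-coded
class), appropriate for the continuous spectral descriptors this package
produces. The search is greedy forward best-first with a patience of five
non-improving expansions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["feature_class_correlation", "merit", "cfs_select"]


def feature_class_correlation(values: np.ndarray, labels: np.ndarray) -> float:
    """Absolute Pearson correlation between a feature and the 0/1-coded class.

    A constant feature has no linear association with anything: 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    y = (labels == classes[-1]).astype(float)
    if np.std(values) == 0.0 or np.std(y) == 0.0:
        return 0.0
    return float(abs(np.corrcoef(values, y)[0, 1]))


def merit(k: int, r_cf_mean: float, r_ff_mean: float) -> float:
    """CFS heuristic merit of a k-feature subset."""
    if k < 1:
        raise ValueError("subset size must be >= 1")
    if r_ff_mean < 0:
        raise ValueError("mean inter-correlation must be non-negative")
    denom = math.sqrt(k + k * (k - 1) * r_ff_mean)
    if denom == 0.0:
        raise ValueError("degenerate merit denominator")
    return k * r_cf_mean / denom


def cfs_select(
    table: pd.DataFrame,
    class_column: str = "class",
    patience: int = 5,
) -> list[str]:
    """Greedy forward CFS over a descriptor table with a binary class column.

    Starting empty, the feature whose addition maximises the merit is
    appended at each step (ties broken by lexicographic feature name); the
    search stops after ``patience`` consecutive additions that fail to beat
    the best merit seen, and returns the best subset found.
    """
    if class_column not in table.columns:
        raise ValueError(f"missing class column {class_column!r}")
    features = [c for c in table.columns if c != class_column]
    if len(features) < 2:
        raise ValueError("need at least two candidate features")
    labels = table[class_column].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError("class column must contain at least two classes")

    X = table[features].to_numpy(dtype=float)
    n_feat = X.shape[1]
    r_cf = np.array(
        [feature_class_correlation(X[:, j], labels) for j in range(n_feat)]
    )
    # absolute feature-feature correlations; constant features correlate 0
    stds = X.std(axis=0)
    ok = stds > 0
    r_ff = np.zeros((n_feat, n_feat))
    if ok.sum() >= 2:
        sub = np.abs(np.corrcoef(X[:, ok], rowvar=False))
        r_ff[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r_ff, 1.0)

    def subset_merit(idx: list[int]) -> float:
        k = len(idx)
        mean_cf = float(r_cf[idx].mean())
        if k == 1:
            return merit(1, mean_cf, 0.0)
        pair_sum = float(r_ff[np.ix_(idx, idx)].sum() - k)  # off-diagonal
        mean_ff = pair_sum / (k * (k - 1))
        return merit(k, mean_cf, mean_ff)

    current: list[int] = []
    best_subset: list[int] = []
    best_merit = -math.inf
    stale = 0
    remaining = sorted(range(n_feat), key=lambda j: features[j])
    while remaining and stale < patience:
        scored = [(subset_merit(current + [j]), features[j], j) for j in remaining]
        m, _, j = min(scored, key=lambda t: (-t[0], t[1]))
        current = current + [j]
        remaining.remove(j)
        if m > best_merit:
            best_merit = m
            best_subset = list(current)
            stale = 0
        else:
            stale += 1
    if not best_subset:  # all-noise table: keep the single best feature
        best_subset = [current[0]]
    return sorted(features[j] for j in best_subset)
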