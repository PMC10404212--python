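"""Streaming evaluation protocol: inverse 10-fold splits, per-object
prequential classification, metrics, and significance testing.

Each fold of the inverse 10-fold cross-validation uses one stratified tenth
of the table as the initial training pool and streams the remaining nine
tenths as test objects in a seeded arrival order that is identical across
compared strategies (so paired tests over folds are valid). The client
class is the positive class throughout; on 1:44-imbalanced streams accuracy
is dominated by the impostor majority, which is why recall, precision,
F-measure and AUC carry the comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.diagnostic import normal_ad

from .frnn import NeighbourList, frnn_predict, nearest_neighbours, scores_from_neighbours
from .knn import KNNConfig, InsertLabelMode, apply_fifo_update, knn_predict
from .pool import TrainingPool, pool_insert
from .strategies import Strategy, UpdateConfig, apply_actual_class_update, apply_probability_update

__all__ = [
    "StreamReport",
    "PairedTest",
    "inverse_tenfold_split",
    "pool_from_table",
    "stream_run",
    "compute_metrics",
    "anderson_darling",
    "paired_t",
    "compare_strategies",
]

POSITIVE_LABEL = "client"
METRICS = ("auc", "accuracy", "recall", "precision", "f_measure")


@dataclass
class StreamReport:
    """Per-object predictions and aggregate metrics of one streamed run."""

    true_labels: list[str]
    predicted_labels: list[str]
    scores: list[float]
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, float]
    final_pool_size: int
    n_inserted: int
    fold_id: int = -1
    strategy_id: str = ""
    audit: pd.DataFrame | None = field(default=None, repr=False)


@dataclass(frozen=True)
class PairedTest:
    """Paired-sample t statistic t = mean(D) / (sd(D)/sqrt(N)), two-sided."""

    mean_diff: float
    sd_diff: float
    n: int
    t: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def inverse_tenfold_split(
    table: pd.DataFrame,
    seed: int,
    n_folds: int = 10,
    class_column: str = "class",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds where each fold is the *training* tenth.

    Returns ``n_folds`` pairs (train ids, stream ids): fold f trains on its
    own ~10% and streams the other ~90% in the seeded arrival order.
    """
    labels = table[class_column].to_numpy()
    rng = np.random.default_rng(seed)
    arrival = rng.permutation(len(table))  # arrival order shared by all folds
    fold_of = np.empty(len(table), dtype=int)
    for c in np.unique(labels):
        members = arrival[labels[arrival] == c]
        if members.size < n_folds:
            raise ValueError(
                f"class {c!r} has {members.size} objects; need >= {n_folds}"
            )
        fold_of[members] = np.arange(members.size) % n_folds
    splits = []
    for f in range(n_folds):
        train = arrival[fold_of[arrival] == f]
        stream = arrival[fold_of[arrival] != f]
        splits.append((train, stream))
    return splits


def pool_from_table(
    table: pd.DataFrame, ids: np.ndarray, class_column: str = "class"
) -> TrainingPool:
    """Initial training pool from the given rows of a descriptor table."""
    feats = [c for c in table.columns if c != class_column]
    pool = TrainingPool(len(feats))
    X = table[feats].to_numpy(dtype=float)
    y = table[class_column].to_numpy()
    for i in ids:
        pool_insert(pool, X[i], str(y[i]))
    return pool


def stream_run(
    table: pd.DataFrame,
    train_ids: np.ndarray,
    stream_ids: np.ndarray,
    classifier: str = "frnn",
    config: UpdateConfig | KNNConfig | None = None,
    class_column: str = "class",
    positive_label: str = POSITIVE_LABEL,
    fold_id: int = -1,
    collect_audit: bool = False,
) -> StreamReport:
    """Classify then update on every streamed object, prequentially.

    ``classifier`` is ``"frnn"`` (with an :class:`UpdateConfig` strategy) or
    ``"knn"`` (with a :class:`KNNConfig`). True labels feed only the metric
    computation — and the update itself for the actual-class strategy and
    KNN's actual insert-label mode.
    """
    if classifier == "frnn":
        cfg = config if config is not None else UpdateConfig()
        if not isinstance(cfg, UpdateConfig):
            raise TypeError("frnn requires an UpdateConfig")
    elif classifier == "knn":
        cfg = config if config is not None else KNNConfig()
        if not isinstance(cfg, KNNConfig):
            raise TypeError("knn requires a KNNConfig")
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    feats = [c for c in table.columns if c != class_column]
    X = table[feats].to_numpy(dtype=float)
    y = table[class_column].to_numpy()
    pool = pool_from_table(table, train_ids, class_column)

    true_labels: list[str] = []
    predicted: list[str] = []
    scores: list[float] = []
    n_inserted = 0
    audit_rows: list[dict] = []

    for i in stream_ids:
        x = X[i]
        actual = str(y[i])
        if classifier == "frnn":
            # one similarity sweep serves both prediction and update
            retrieved = None
            if cfg.strategy == Strategy.PROBABILITY and len(pool) >= 2:
                retrieved = nearest_neighbours(pool, x, cfg.k + 1)
                top_k = NeighbourList(
                    retrieved.entries[: cfg.k], cfg.k,
                    retrieved.positions[: cfg.k],
                )
                cs = scores_from_neighbours(pool, top_k)
            elif cfg.strategy == Strategy.ACTUAL_CLASS and len(pool) > 0:
                retrieved = nearest_neighbours(pool, x, cfg.k)
                cs = scores_from_neighbours(pool, retrieved)
            else:
                cs = frnn_predict(pool, x, cfg.k)
            pred = cs.predicted
            score = cs.score(positive_label) if positive_label in cs.lower else 0.0
            size_before = len(pool)
            if cfg.strategy == Strategy.PROBABILITY:
                _, ctx = apply_probability_update(pool, x, cs, cfg, retrieved)
                if ctx.inserted:
                    n_inserted += 1
                if collect_audit:
                    audit_rows.append(
                        {
                            "object": int(i),
                            "D": ctx.top_two_diff,
                            "threshold": ctx.threshold,
                            "predicted": ctx.predicted,
                            "best_prob_class": ctx.best_prob_class,
                            "inserted": ctx.inserted,
                            "n_deleted": len(ctx.deleted_ids),
                            **{f"P_{c}": p for c, p in ctx.probs.items()},
                        }
                    )
            elif cfg.strategy == Strategy.ACTUAL_CLASS:
                apply_actual_class_update(pool, x, pred, actual, cfg, retrieved)
                n_inserted += int(len(pool) > size_before)
        else:
            pred, score = knn_predict(pool, x, cfg.k, positive_label)
            label = actual if cfg.insert_label_mode == InsertLabelMode.ACTUAL else pred
            apply_fifo_update(pool, x, label, cfg)
            n_inserted += 1
        true_labels.append(actual)
        predicted.append(pred)
        scores.append(float(score))

    tp, fp, tn, fn, metrics = compute_metrics(
        true_labels, predicted, scores, positive_label
    )
    return StreamReport(
        true_labels=true_labels,
        predicted_labels=predicted,
        scores=scores,
        tp=tp, fp=fp, tn=tn, fn=fn,
        metrics=metrics,
        final_pool_size=len(pool),
        n_inserted=n_inserted,
        fold_id=fold_id,
        strategy_id=f"{classifier}",
        audit=pd.DataFrame(audit_rows) if collect_audit else None,
    )


def roc_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal sweep over score thresholds.

    Tied scores contribute half credit, making the area equal to the
    Mann-Whitney pair-counting statistic.
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both a positive and a negative example")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = positives[order]
    tps = np.cumsum(p)
    fps = np.cumsum(~p)
    # keep only the last index of each tied-score run (threshold points)
    last = np.nonzero(np.diff(s, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[last] / n_pos])
    fpr = np.concatenate([[0.0], fps[last] / n_neg])
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(
    true_labels,
    predicted_labels,
    scores,
    positive_label: str = POSITIVE_LABEL,
) -> tuple[int, int, int, int, dict[str, float]]:
    """Confusion counts and the five evaluation metrics (client = positive)."""
    t = np.asarray([lab == positive_label for lab in true_labels])
    p = np.asarray([lab == positive_label for lab in predicted_labels])
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    total = t.size
    accuracy = (tp + tn) / total if total else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f_measure = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    auc = roc_auc(np.asarray(scores, dtype=float), t)
    return tp, fp, tn, fn, {
        "auc": auc,
        "accuracy": accuracy,
        "recall": recall,
        "precision": precision,
        "f_measure": f_measure,
    }


def anderson_darling(values: np.ndarray) -> tuple[float, float]:
    """Anderson-Darling normality test (mean and variance estimated).

    Returns the small-sample-corrected A^2 statistic and its p-value.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError("need at least 8 observations")
    if np.std(values) == 0.0:
        raise ValueError("constant sample")
    a2, p = normal_ad(values)
    return float(a2), float(p)


def paired_t(pairs) -> PairedTest:
    """Paired-sample t-test with hypothesised mean difference 0.

    All-zero differences give t = 0, p = 1. Identical nonzero differences
    (zero standard deviation, nonzero mean) are the limit of the statistic:
    t = +-inf, p = 0.
    """
    diffs = np.asarray([float(a) - float(b) for a, b in pairs])
    n = diffs.size
    if n < 2:
        raise ValueError("need at least two pairs")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTest(0.0, 0.0, n, 0.0, 1.0)
        t = float(np.sign(mean)) * float("inf")
        return PairedTest(mean, 0.0, n, t, 0.0)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return PairedTest(mean, sd, n, float(t), float(p))


def compare_strategies(
    table: pd.DataFrame,
    configs: dict[str, tuple[str, UpdateConfig | KNNConfig]],
    seeds,
    n_folds: int = 10,
    class_column: str = "class",
    positive_label: str = POSITIVE_LABEL,
) -> dict:
    """Run every configuration over the same splits and compare them.

    ``configs`` maps a condition name to ``(classifier, config)``. Per-fold
    metrics are aggregated per configuration; every configuration pair gets
    an Anderson-Darling normality check and a paired t-test per metric
    (pairing over fold x seed runs, which share splits and stream order).
    Returns a dict with ``per_run`` (DataFrame), ``summary`` (DataFrame of
    means) and ``tests`` (DataFrame of pairwise tests).
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    rows = []
    for seed in seeds:
        splits = inverse_tenfold_split(table, seed, n_folds, class_column)
        for fold_id, (train, stream) in enumerate(splits):
            for name, (classifier, cfg) in configs.items():
                report = stream_run(
                    table, train, stream, classifier, cfg,
                    class_column, positive_label, fold_id,
                )
                row = {"config": name, "seed": seed, "fold": fold_id}
                row.update(report.metrics)
                rows.append(row)
    per_run = pd.DataFrame(rows)
    summary = per_run.groupby("config")[list(METRICS)].mean()

    test_rows = []
    names = list(configs)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra = per_run[per_run["config"] == a].sort_values(["seed", "fold"])
            rb = per_run[per_run["config"] == b].sort_values(["seed", "fold"])
            for metric in METRICS:
                da = ra[metric].to_numpy()
                db = rb[metric].to_numpy()
                diffs = da - db
                try:
                    _, ad_p = anderson_darling(diffs)
                except ValueError:
                    ad_p = float("nan")
                test = paired_t(list(zip(da, db)))
                test_rows.append(
                    {
                        "config_a": a, "config_b": b, "metric": metric,
                        "mean_a": da.mean(), "mean_b": db.mean(),
                        "mean_diff": test.mean_diff, "t": test.t,
                        "p_value": test.p_value,
                        "significant": test.significant,
                        "normality_p": ad_p,
                    }
                )
    return {"per_run": per_run, "summary": summary, "tests": pd.DataFrame(test_rows)}
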