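"""Cross-validation and performance metrics for the binary classifier.

Implements stratified five-fold cross-validation (each class shuffled by
seed and dealt round-robin into folds, so every record is tested exactly
once), the four standard metrics (ACC, SN, SP as percentages; Matthews
correlation coefficient in [-1, 1]), threshold-sweep tables, and
per-sequence prediction-score summaries including the false positive rate.

The Matthews coefficient is computed with the square root over the
denominator product, MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
defined as 0 when any denominator factor vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureVector
from .model import SVMConfig, ScoreRecord, predict, train


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """ACC/SN/SP in percent, MCC in [-1, 1]."""

    acc: float
    sn: float
    sp: float
    mcc: float


@dataclass
class CVResult:
    fold_metrics: list[MetricsReport]
    mean_metrics: MetricsReport
    pooled_metrics: MetricsReport  # secondary: metrics on pooled counts
    fold_assignments: dict[str, int]  # record id (or index as str) -> fold


def count_confusion(records: Sequence[ScoreRecord]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from scored records carrying true labels."""
    tp = tn = fp = fn = 0
    for r in records:
        if r.true_label is None:
            raise ValueError(f"record {r.source_id!r} has no true label")
        if r.true_label == 1:
            if r.predicted_label == 1:
                tp += 1
            else:
                fn += 1
        else:
            if r.predicted_label == -1:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp, tn, fp, fn)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC = 100(TP+TN)/N, SN = 100 TP/(TP+FN), SP = 100 TN/(TN+FP), MCC as above."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    if n == 0:
        raise ValueError("all confusion counts are zero")
    acc = 100.0 * (tp + tn) / n
    pos = tp + fn
    neg = tn + fp
    sn = 100.0 * tp / pos if pos else 0.0
    sp = 100.0 * tn / neg if neg else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(acc=acc, sn=sn, sp=sp, mcc=mcc)


def kfold_split(
    n_pos: int,
    n_neg: int,
    k: int = 5,
    seed: int = 0,
    pos_ids: Sequence[str] | None = None,
    neg_ids: Sequence[str] | None = None,
) -> dict[str, int]:
    """Stratified fold assignment: shuffle each class, deal round-robin.

    Returns a mapping from record id to fold index 0..k-1. When explicit ids
    are not given, ids default to ``pos<i>`` / ``neg<i>``. Ids are shuffled
    in sorted order keyed only on the seed, so the assignment is invariant
    to the caller's example ordering. Per-class fold sizes differ by at
    most one.
    """
    if n_pos < k or n_neg < k:
        raise ValueError(f"each class needs >= k={k} examples (got {n_pos}, {n_neg})")
    if pos_ids is None:
        pos_ids = [f"pos{i}" for i in range(n_pos)]
    if neg_ids is None:
        neg_ids = [f"neg{i}" for i in range(n_neg)]
    if len(pos_ids) != n_pos or len(neg_ids) != n_neg:
        raise ValueError("id list lengths must match n_pos / n_neg")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for ids in (pos_ids, neg_ids):
        order = sorted(ids)
        rng.shuffle(order)
        for i, rid in enumerate(order):
            assignment[rid] = i % k
    return assignment


def cross_validate(
    vectors: Sequence[FeatureVector],
    labels: Sequence[int],
    config: SVMConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the SVM on encoded vectors.

    For each fold the model is trained on the remaining k-1 folds and the
    held-out fold is scored at the config's decision threshold. The primary
    summary is the unweighted mean of per-fold metrics; metrics on pooled
    confusion counts are kept as a secondary output.
    """
    labels = [int(l) for l in labels]
    if len(vectors) != len(labels):
        raise ValueError("vectors/labels length mismatch")
    ids = [v.source_id or f"idx{i}" for i, v in enumerate(vectors)]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate source ids in vectors")
    pos_ids = [i for i, l in zip(ids, labels) if l == 1]
    neg_ids = [i for i, l in zip(ids, labels) if l == -1]
    assignment = kfold_split(
        len(pos_ids), len(neg_ids), k=k, seed=seed,
        pos_ids=pos_ids, neg_ids=neg_ids,
    )
    threshold = config.threshold if config is not None else 0.0
    fold_metrics: list[MetricsReport] = []
    pooled = np.zeros(4, dtype=int)  # tp, tn, fp, fn
    for fold in range(k):
        train_idx = [i for i, rid in enumerate(ids) if assignment[rid] != fold]
        test_idx = [i for i, rid in enumerate(ids) if assignment[rid] == fold]
        model = train(
            [vectors[i] for i in train_idx],
            [labels[i] for i in train_idx],
            config,
        )
        scored = predict(
            model,
            [vectors[i] for i in test_idx],
            threshold=threshold,
            true_labels=[labels[i] for i in test_idx],
        )
        counts = count_confusion(scored)
        pooled += np.array([counts.tp, counts.tn, counts.fp, counts.fn])
        fold_metrics.append(compute_metrics(counts))
    mean = MetricsReport(
        acc=float(np.mean([m.acc for m in fold_metrics])),
        sn=float(np.mean([m.sn for m in fold_metrics])),
        sp=float(np.mean([m.sp for m in fold_metrics])),
        mcc=float(np.mean([m.mcc for m in fold_metrics])),
    )
    pooled_metrics = compute_metrics(ConfusionCounts(*pooled.tolist()))
    return CVResult(fold_metrics, mean, pooled_metrics, assignment)


def threshold_sweep(
    records: Sequence[ScoreRecord],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Metrics at each decision threshold, as a table ordered by threshold.

    Defaults to 101 evenly spaced thresholds between the minimum and
    maximum observed decision value. SN is non-increasing and SP
    non-decreasing along the grid.
    """
    if any(r.true_label is None for r in records):
        raise ValueError("threshold_sweep needs true labels on every record")
    scores = np.array([r.decision_value for r in records])
    if thresholds is None:
        thresholds = np.linspace(scores.min(), scores.max(), 101)
    rows = []
    for t in sorted(thresholds):
        relabelled = [
            ScoreRecord(r.source_id, r.decision_value,
                        1 if r.decision_value >= t else -1, r.true_label)
            for r in records
        ]
        m = compute_metrics(count_confusion(relabelled))
        rows.append({"threshold": t, "acc": m.acc, "sn": m.sn, "sp": m.sp, "mcc": m.mcc})
    return pd.DataFrame(rows)


@dataclass
class ScoreGraph:
    """Per-sequence score series split by class, with misclassification counts."""

    positive_series: pd.DataFrame  # columns: index, decision_value
    negative_series: pd.DataFrame
    false_negatives: int
    false_positives: int
    fpr: float


def score_graph(records: Sequence[ScoreRecord]) -> ScoreGraph:
    """Summarise per-sequence prediction scores and the false positive rate.

    FPR = FP / (FP + TN) over the negative class at the labels already
    attached to the records.
    """
    pos_rows, neg_rows = [], []
    fn = fp = tn = 0
    for i, r in enumerate(records):
        if r.true_label is None:
            raise ValueError(f"record {r.source_id!r} has no true label")
        row = {"index": i, "source_id": r.source_id, "decision_value": r.decision_value}
        if r.true_label == 1:
            pos_rows.append(row)
            if r.predicted_label == -1:
                fn += 1
        else:
            neg_rows.append(row)
            if r.predicted_label == 1:
                fp += 1
            else:
                tn += 1
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    return ScoreGraph(
        positive_series=pd.DataFrame(pos_rows, columns=["index", "source_id", "decision_value"]),
        negative_series=pd.DataFrame(neg_rows, columns=["index", "source_id", "decision_value"]),
        false_negatives=fn,
        false_positives=fp,
        fpr=fpr,
    )


def plot_threshold_sweep(table: pd.DataFrame, path: str | Path) -> Path:
    """Render the four metric-vs-threshold curves to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, (col, label) in zip(axes.ravel(), [
        ("acc", "Accuracy (%)"), ("sn", "Sensitivity (%)"),
        ("sp", "Specificity (%)"), ("mcc", "MCC"),
    ]):
        ax.plot(table["threshold"], table[col])
        ax.set_ylabel(label)
        ax.set_xlabel("decision threshold")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_score_graph(graph: ScoreGraph, path: str | Path, threshold: float = 0.0) -> Path:
    """Render per-sequence decision values split by class, with the cutoff line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    ax.scatter(graph.positive_series["index"], graph.positive_series["decision_value"],
               s=12, label="positives")
    ax.scatter(graph.negative_series["index"], graph.negative_series["decision_value"],
               s=12, marker="x", label="negatives")
    ax.axhline(threshold, color="grey", linewidth=1)
    ax.set_xlabel("sequence index")
    ax.set_ylabel("decision value")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def cv_table(result: CVResult) -> pd.DataFrame:
    """Per-fold rows plus a mean row, for report writing."""
    rows = [
        {"fold": i, "acc": m.acc, "sn": m.sn, "sp": m.sp, "mcc": m.mcc}
        for i, m in enumerate(result.fold_metrics)
    ]
    m = result.mean_metrics
    rows.append({"fold": "mean", "acc": m.acc, "sn": m.sn, "sp": m.sp, "mcc": m.mcc})
    return pd.DataFrame(rows)
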