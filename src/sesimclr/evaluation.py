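"""Metrics and analysis artifacts.

Class 1 (non-math) is the positive class throughout.  Scalar metrics derive
from confusion counts:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    Precision = TP / (TP + FP)
    Recall = TP / (TP + FN)
    F1 = 2 * Precision * Recall / (Precision + Recall)

Undefined ratios (zero denominators) are reported as NaN with a warning,
never silently as 0.  Student-level ROC scores are vote fractions
(votes-for-class-1 / 20), the single monotone score consistent with the
">10 of 20" voting rule.  AUC is the rank-based probability
P(score_pos > score_neg) + 0.5 P(equal), i.e. the area under the empirical
ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "scalar_metrics",
    "student_score",
    "roc_auc",
    "per_slice_accuracy",
    "probability_histogram",
    "paired_ttest",
    "visualize_embeddings",
    "metric_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Scalar classification metrics at one level (image slices or students)."""

    acc: float
    precision: float
    recall: float
    f1: float
    auc: float = float("nan")
    level: str = "image"


def _check_binary(arr, name):
    arr = np.asarray(arr)
    if arr.size and not np.all(np.isin(arr, (0, 1))):
        raise ValueError(f"{name} must be binary 0/1")
    return arr.astype(int)


def confusion(true_labels, pred_labels, positive_class: int = 1) -> ConfusionCounts:
    """Confusion counts with class `positive_class` as positive."""
    y = _check_binary(true_labels, "true_labels")
    p = _check_binary(pred_labels, "pred_labels")
    if y.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    pos = y == positive_class
    hit = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & hit)),
        fp=int(np.sum(~pos & hit)),
        fn=int(np.sum(pos & ~hit)),
        tn=int(np.sum(~pos & ~hit)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def scalar_metrics(counts: ConfusionCounts, level: str = "image") -> MetricReport:
    """ACC / Precision / Recall / F1 from confusion counts."""
    if counts.total == 0:
        raise ValueError("no evaluated units")
    acc = (counts.tp + counts.tn) / counts.total
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        if precision + recall == 0 and not (np.isnan(precision) or np.isnan(recall)):
            warnings.warn("F1 undefined (precision + recall = 0); reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricReport(acc=acc, precision=precision, recall=recall, f1=f1, level=level)


def student_score(slice_preds) -> float:
    """Class-1 vote fraction of a student's 20 slice labels; the ROC score.

    Equals N_correct/20 for a true class-1 student and 1 - N_correct/20 for a
    true class-0 student, and exceeds 0.5 exactly when the voting rule emits
    label 1.
    """
    preds = _check_binary(slice_preds, "slice_preds")
    if preds.size != 20:
        raise ValueError("student_score expects exactly 20 slice predictions")
    return float(preds.sum() / 20.0)


def roc_auc(scores, true_labels) -> float:
    """Rank-based AUC; requires both classes present."""
    y = _check_binary(true_labels, "true_labels")
    scores = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(y, scores))


def per_slice_accuracy(slice_pred_table: pd.DataFrame) -> pd.Series:
    """Accuracy over subjects for each slice ID (index 1..n_slices).

    Expects columns subject_id, slice_id, label, pred with exactly one row
    per (subject, slice_id) cell.
    """
    t = slice_pred_table
    required = {"subject_id", "slice_id", "label", "pred"}
    if not required.issubset(t.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = t.groupby("slice_id")["subject_id"].count()
    if counts.nunique() != 1 or t.duplicated(["subject_id", "slice_id"]).any():
        raise ValueError("need exactly one prediction per (subject, slice_id)")
    correct = (t["label"] == t["pred"]).groupby(t["slice_id"]).mean()
    return correct.sort_index()


def probability_histogram(scores, true_labels, bin_width: float = 0.1) -> pd.DataFrame:
    """Per-class counts over half-open bins [b, b+w) covering [0, 1]; the last
    bin is closed so a score of exactly 1 is counted."""
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(true_labels, "true_labels")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    rows = []
    for cls in (0, 1):
        counts, _ = np.histogram(scores[y == cls], bins=edges)
        for b in range(n_bins):
            rows.append({"class": cls, "bin_left": edges[b], "bin_right": edges[b + 1],
                         "count": int(counts[b])})
    return pd.DataFrame(rows)


def paired_ttest(metric_by_fold_a, metric_by_fold_b) -> float:
    """Two-tailed paired t-test p-value on fold-wise metric differences.

    Returns NaN (with a warning) when the differences have zero variance,
    where the t statistic is undefined.
    """
    a = np.asarray(metric_by_fold_a, dtype=float)
    b = np.asarray(metric_by_fold_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length fold-metric vectors, length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences: paired t-test degenerate; reporting NaN",
                      stacklevel=2)
        return float("nan")
    return float(stats.ttest_rel(a, b).pvalue)


def visualize_embeddings(encoder_features, labels, seed: int = 0,
                         pca_dim: int = 50, perplexity: float = 30.0):
    """PCA (to <=50 components) then 2D t-SNE at perplexity 30, plus a
    single-layer linear probe trained on the 2D coordinates.

    Returns (coords, probe_accuracy): one 2D row per input row, and the
    probe's training accuracy on the embedded points — a separability score
    for the learned representation.
    """
    from sklearn.decomposition import PCA
    from sklearn.linear_model import LogisticRegression
    from sklearn.manifold import TSNE

    x = np.asarray(encoder_features, dtype=float)
    y = _check_binary(labels, "labels")
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be 2D with one row per label")
    n, d = x.shape
    k = min(pca_dim, d, n)
    if n <= k:
        raise ValueError(f"need more than {k} feature rows for a {k}-component PCA")
    reduced = PCA(n_components=k, random_state=seed).fit_transform(x)
    perp = min(perplexity, max(1.0, (n - 1) / 3.0))
    coords = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca").fit_transform(reduced)
    probe = LogisticRegression(max_iter=2000).fit(coords, y)
    acc = float(probe.score(coords, y))
    return coords, acc


def metric_table(runs: dict) -> pd.DataFrame:
    """Assemble the headline comparison table: one column per (run, level).

    `runs` maps run name (e.g. "SimCLR", "SeSimCLR") to a dict with keys
    "image" and "student", each a MetricReport.  Rows are ACC, Precision,
    Recall, F1, AUC; image-level AUC is left NaN when not computed.
    """
    cols = {}
    for run_name, levels in runs.items():
        for level in ("image", "student"):
            r = levels[level]
            cols[(level, run_name)] = [r.acc, r.precision, r.recall, r.f1, r.auc]
    table = pd.DataFrame(cols, index=["ACC", "Precision", "Recall", "F1", "AUC"])
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["level", "model"])
    return table
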