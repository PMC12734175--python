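"""Confusion-matrix metrics, McNemar paired testing, gate analytics.

Conventions: confusion-matrix rows are true classes and columns are
predictions, so for class ``i`` the true positives are ``C[i, i]``,
false positives the off-diagonal column sum, and false negatives the
off-diagonal row sum. Zero-denominator precision/recall/F1 return 0
(with a logged note), which keeps macro averages defined for classes
that are absent or never predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("leafgate.evaluation")

__all__ = [
    "confusion_matrix", "per_class_metrics", "overall_accuracy", "macro_f1",
    "row_normalize", "PairedPredictions", "mcnemar_test", "gate_summary",
]


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """K x K count matrix; ``cm[i, j]`` = samples with true i predicted j."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted labels differ in length")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def per_class_metrics(cm: np.ndarray) -> dict[str, np.ndarray]:
    """Per-class precision, recall, and F1 from a confusion matrix."""
    cm = np.asarray(cm)
    tp = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall
                      / np.where(denom > 0, denom, 1), 0.0)
    if np.any(col == 0) or np.any(row == 0):
        logger.info("zero-denominator class(es); metrics reported as 0")
    return {"precision": precision, "recall": recall, "f1": f1}


def overall_accuracy(cm: np.ndarray) -> float:
    """trace(C) / sum(C): fraction of correctly classified samples."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def macro_f1(cm: np.ndarray) -> float:
    """Unweighted mean of per-class F1 (robust to class imbalance)."""
    return float(per_class_metrics(cm)["f1"].mean())


def row_normalize(cm: np.ndarray) -> np.ndarray:
    """Row-stochastic version of the matrix; zero rows stay zero."""
    cm = np.asarray(cm, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, sums, out=np.zeros_like(cm), where=sums > 0)


# ---------------------------------------------------------------------------
# McNemar paired test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedPredictions:
    """Discordant-pair counts for two classifiers on identical samples.

    ``b`` counts samples model A got right and model B wrong; ``c`` the
    reverse.
    """

    b: int
    c: int

    def __post_init__(self):
        if self.b < 0 or self.c < 0:
            raise ValueError("discordant counts must be nonnegative")

    @classmethod
    def from_predictions(cls, true, pred_a, pred_b) -> "PairedPredictions":
        true, pa, pb = (np.asarray(x) for x in (true, pred_a, pred_b))
        if not (true.shape == pa.shape == pb.shape):
            raise ValueError("prediction arrays must align with true labels")
        ca, cb = pa == true, pb == true
        return cls(b=int(np.sum(ca & ~cb)), c=int(np.sum(~ca & cb)))


def mcnemar_test(pairs: PairedPredictions) -> float:
    """Two-sided McNemar p-value on discordant counts.

    Exact binomial test for ``b + c < 25``; chi-square with continuity
    correction otherwise. Returns 1.0 when there are no discordant
    pairs (with a logged note).
    """
    b, c = pairs.b, pairs.c
    n = b + c
    if n == 0:
        logger.info("no discordant pairs; McNemar p = 1.0 by convention")
        return 1.0
    if n < 25:
        return float(stats.binomtest(min(b, c), n, 0.5,
                                     alternative="two-sided").pvalue)
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# gate analytics
# ---------------------------------------------------------------------------

_BRANCHES = ("detail", "global", "trans")


def gate_summary(gate_rows: list[dict]) -> dict:
    """Per-class gate-weight distributions plus per-image breakdowns.

    ``gate_rows`` are dicts with keys ``id``, ``true_label``,
    ``predicted_label``, ``g_detail``, ``g_global``, ``g_trans`` (the
    export format of gate reports). Returns per-class mean/median/
    quartiles of each gate component, each class's dominant branch, and
    a formatted percentage breakdown per image.
    """
    if not gate_rows:
        raise ValueError("empty gate report")
    labels = np.array([r["true_label"] for r in gate_rows])
    g = np.array([[r["g_detail"], r["g_global"], r["g_trans"]]
                  for r in gate_rows])
    per_class = {}
    for cls in np.unique(labels):
        sub = g[labels == cls]
        stats_ = {}
        for j, name in enumerate(_BRANCHES):
            q25, q50, q75 = np.percentile(sub[:, j], [25, 50, 75])
            stats_[name] = {"mean": float(sub[:, j].mean()),
                            "median": float(q50),
                            "q25": float(q25), "q75": float(q75)}
        means = sub.mean(axis=0)
        stats_["dominant_branch"] = _BRANCHES[int(means.argmax())]
        per_class[int(cls)] = stats_
    per_image = [
        {"id": r["id"],
         "breakdown": "Transformer {:.0f}%, Global {:.0f}%, Detail {:.0f}%"
                      .format(100 * r["g_trans"], 100 * r["g_global"],
                              100 * r["g_detail"])}
        for r in gate_rows
    ]
    return {"per_class": per_class, "per_image": per_image}
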