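"""Binary classification metrics and the repeated stratified CV harness.

Conventions: degenerate 0/0 ratios (precision with no positive calls, recall
with no positives, F1 with zero precision+recall) are reported as 0 rather
than NaN.  ROC-AUC equals the probability a random positive outscores a
random negative with ties counted one half; AUPR is the step-wise
precision-recall integral.  The CV harness runs seeded stratified k-fold,
reshuffled per repeat, and aggregates fold-level metrics as mean +- sd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Per-fold metric table plus mean +- sd summary."""

    folds: pd.DataFrame  # columns: repeat, fold, precision, recall, ...
    summary: pd.DataFrame  # index: metric, columns: mean, sd

    def to_json(self) -> str:
        return pd.Series(
            {
                f"{m}_{stat}": self.summary.loc[m, stat]
                for m in self.summary.index
                for stat in ("mean", "sd")
            }
        ).to_json()


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if not set(np.unique(np.concatenate([y_true, y_pred]))) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    precision = _safe_div(c.TP, c.TP + c.FP)
    recall = _safe_div(c.TP, c.TP + c.FN)
    accuracy = _safe_div(c.TP + c.TN, c.n)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "accuracy": accuracy,
        "f1": f1,
    }


def roc_auc(y_true, scores) -> float:
    y_true = np.asarray(y_true).astype(int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC-AUC needs both classes present")
    return float(roc_auc_score(y_true, scores))


def pr_auc(y_true, scores) -> float:
    y_true = np.asarray(y_true).astype(int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUPR needs both classes present")
    return float(average_precision_score(y_true, scores))


def jaccard(A, B) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    A, B = set(A), set(B)
    union = A | B
    return len(A & B) / len(union) if union else 0.0


def repeated_cv(
    X,
    y,
    trainer,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> MetricsReport:
    """Repeated seeded stratified k-fold cross-validation.

    ``trainer(X_train, y_train, seed)`` must return an object with a
    ``predict_proba_1(X) -> P(y=1)`` method or a plain callable mapping X to
    P(y=1).  Labels are thresholded at 0.5 (strict) for the count metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] < k:
        raise ValueError(f"n={X.shape[0]} smaller than k={k}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"minority class ({counts.min()}) too small for {k}-fold stratification"
        )
    rows = []
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(splitter.split(X, y)):
            fitted = trainer(X[tr], y[tr], seed + rep)
            score_fn = getattr(fitted, "predict_proba_1", fitted)
            scores = np.asarray(score_fn(X[te]), dtype=float)
            preds = (scores > 0.5).astype(int)
            row = {"repeat": rep, "fold": fold}
            row.update(binary_metrics(confusion(y[te], preds)))
            row["auc"] = roc_auc(y[te], scores)
            row["aupr"] = pr_auc(y[te], scores)
            rows.append(row)
    folds = pd.DataFrame(rows)
    metric_cols = ["precision", "recall", "accuracy", "f1", "auc", "aupr"]
    summary = pd.DataFrame(
        {
            "mean": folds[metric_cols].mean(),
            "sd": folds[metric_cols].std(ddof=1),
        }
    )
    return MetricsReport(folds=folds, summary=summary)
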