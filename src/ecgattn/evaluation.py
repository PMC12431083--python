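"""Evaluation: confusion matrices, one-vs-rest metrics, chi-square, ROC/AUC.

Per class c the K×K confusion matrix (rows = true, columns = predicted)
collapses to a 2×2 one-vs-rest table (TP, FN, FP, TN) from which

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F1          = 2·sensitivity·precision / (sensitivity + precision)

all reported as percentages.  0/0 ratios are defined as 0 (so a class never
predicted and never present scores 0, with specificity 100).  The micro
(TOTAL) row pools the one-vs-rest counts across classes; for single-label
data micro sensitivity = precision = F1 = overall accuracy = trace/total.

The per-class association test is the Pearson chi-square on the 2×2
one-vs-rest table, without continuity correction, 1 degree of freedom; it is
flagged inapplicable when any marginal total is zero.  ROC curves are
one-vs-rest from each class's probability column (trapezoidal AUC).

Two reference confusion matrices from the published MIT-BIH / INCART
evaluations ship with the package, loadable by name, as golden inputs for the
metric pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .records import AAMI_CLASSES


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """K × K non-negative integer matrix; rows = true class, cols = predicted."""

    table: np.ndarray
    class_names: tuple[str, ...] = AAMI_CLASSES

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        K = len(self.class_names)
        if self.table.shape != (K, K):
            raise EvaluationError(
                f"confusion matrix shape {self.table.shape} does not match "
                f"{K} classes"
            )
        if (self.table < 0).any():
            raise EvaluationError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def ovr_counts(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for class index c, one-vs-rest."""
        tp = int(self.table[c, c])
        fn = int(self.table[c].sum() - tp)
        fp = int(self.table[:, c].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


def confusion(y_true, y_pred, K: int = 5,
              class_names: tuple[str, ...] = AAMI_CLASSES) -> ConfusionMatrix:
    """Count matrix: entry [i, j] = number of true-i segments predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise EvaluationError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    if y_true.size and not (
        (0 <= y_true).all() and (y_true < K).all()
        and (0 <= y_pred).all() and (y_pred < K).all()
    ):
        raise EvaluationError(f"labels outside 0..{K - 1}")
    table = np.zeros((K, K), dtype=np.int64)
    np.add.at(table, (y_true, y_pred), 1)
    return ConfusionMatrix(table, class_names[:K])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def _one_vs_rest_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    sen = _safe_div(tp, tp + fn)
    pre = _safe_div(tp, tp + fp)
    return {
        "accuracy": 100.0 * _safe_div(tp + tn, tp + tn + fp + fn),
        "sensitivity": 100.0 * sen,
        "specificity": 100.0 * _safe_div(tn, tn + fp),
        "precision": 100.0 * pre,
        "f1": 100.0 * _safe_div(2.0 * sen * pre, sen + pre),
    }


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


def class_metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-class one-vs-rest metrics (percent, full precision).

    Keys are class names; values map metric name → percentage.  Use
    :func:`display_round` for 2-decimal presentation.
    """
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    return {
        name: _one_vs_rest_metrics(*cm.ovr_counts(c))
        for c, name in enumerate(cm.class_names)
    }


def micro_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Micro-averaged TOTAL row: pool TP/FN/FP/TN across the K one-vs-rest
    tables.  For single-label data micro sensitivity = precision = F1 =
    overall accuracy = trace/total; the accuracy entry reports that overall
    accuracy (not the pooled 2×2 accuracy, which double-counts negatives)."""
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    counts = np.array([cm.ovr_counts(c) for c in range(len(cm.class_names))])
    tp, fn, fp, tn = counts.sum(axis=0)
    m = _one_vs_rest_metrics(tp, fn, fp, tn)
    m["accuracy"] = 100.0 * np.trace(cm.table) / cm.total
    return m


def display_round(value: float, decimals: int = 2) -> float:
    """Half-away-from-zero rounding used for printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float | None
    p_value: float | None
    applicable: bool


def chi_square_class(cm: ConfusionMatrix, c: int) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction, df = 1) on the 2×2
    one-vs-rest table of class ``c``; inapplicable when any marginal is 0."""
    tp, fn, fp, tn = cm.ovr_counts(c)
    a, b, cc, d = tp, fn, fp, tn
    margins = (a + b, cc + d, a + cc, b + d)
    if any(m == 0 for m in margins):
        return ChiSquareResult(None, None, False)
    n = a + b + cc + d
    stat = n * (a * d - b * cc) ** 2 / (
        float(a + b) * (cc + d) * (a + cc) * (b + d)
    )
    return ChiSquareResult(float(stat), float(stats.chi2.sf(stat, df=1)), True)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    fpr: np.ndarray | None
    tpr: np.ndarray | None
    auc: float | None
    defined: bool


def roc_auc(y_true, probabilities: np.ndarray) -> dict[str, ROCResult]:
    """One-vs-rest ROC per class from that class's probability column.

    Ties in scores are grouped (one curve vertex per distinct score); AUC is
    the trapezoidal integral.  A class absent from ``y_true`` yields an
    undefined result rather than an error.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    P = np.asarray(probabilities, dtype=np.float64)
    if P.ndim != 2 or len(P) != len(y_true):
        raise EvaluationError("probabilities must be N × K aligned with y_true")
    results: dict[str, ROCResult] = {}
    K = P.shape[1]
    for c in range(K):
        name = AAMI_CLASSES[c] if K == len(AAMI_CLASSES) else str(c)
        pos = y_true == c
        if pos.all() or not pos.any():
            results[name] = ROCResult(None, None, None, False)
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), P[:, c])
        results[name] = ROCResult(fpr, tpr, float(_sk_auc(fpr, tpr)), True)
    return results


# ---------------------------------------------------------------------------
# Bundled reference confusion matrices (published MIT-BIH / INCART test-set
# results; rows/cols ordered N, S, V, F, Q)
# ---------------------------------------------------------------------------

REFERENCE_CONFUSIONS: dict[str, ConfusionMatrix] = {
    "mitbih": ConfusionMatrix(np.array([
        [18021, 12, 4, 3, 5],
        [83, 483, 3, 1, 0],
        [21, 0, 1438, 7, 2],
        [9, 0, 18, 144, 0],
        [10, 0, 1, 0, 1610],
    ])),
    "incart": ConfusionMatrix(np.array([
        [30687, 10, 11, 2, 0],
        [87, 324, 0, 0, 0],
        [33, 2, 3930, 7, 0],
        [12, 0, 18, 14, 0],
        [0, 0, 2, 0, 0],
    ])),
}


def load_reference_confusion(name: str) -> ConfusionMatrix:
    """Fetch a bundled reference confusion matrix ('mitbih' or 'incart')."""
    try:
        ref = REFERENCE_CONFUSIONS[name]
    except KeyError:
        raise EvaluationError(
            f"unknown reference matrix {name!r}; available: "
            f"{sorted(REFERENCE_CONFUSIONS)}"
        ) from None
    return ConfusionMatrix(ref.table.copy(), ref.class_names)
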