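"""Classification metrics from a confusion matrix and class probabilities.

Class order is fixed as (Early, Variable, Late).  Per-class statistics use
the one-vs-rest 2×2 reduction of the multiclass confusion matrix:

* TP rate = recall = sensitivity = TP / (TP + FN)
* FP rate = FP / (FP + TN);  specificity = TN / (TN + FP)
* precision = TP / (TP + FP);  F = 2PR / (P + R)
* MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Aggregates: accuracy in percent, Cohen's kappa, macro MCC (unweighted mean
of the per-class binary MCCs) and support-weighted averages of the
per-class statistics.  A statistic with a zero denominator is reported as 0
and flagged rather than dropped, so degenerate classes (e.g. a class the
classifier never predicts) still produce a complete report.

AUC is the non-parametric (Mann–Whitney) estimate; RMSE is the root mean
square of (one-hot truth − predicted probability) over all instances and
classes, the convention of classical data-mining toolkits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "CLASS_ORDER",
    "ConfusionMatrix",
    "EvaluationReport",
    "report_from_confusion",
    "auc_nonparametric",
    "classifier_rmse",
]

CLASS_ORDER = ("Early", "Variable", "Late")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("labels must match matrix dimension")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("confusion matrix must contain observations")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=CLASS_ORDER) -> "ConfusionMatrix":
        index = {lbl: i for i, lbl in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, labels=tuple(labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Per-class and aggregate classification metrics."""

    labels: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    accuracy_pct: float
    kappa: float
    macro_mcc: float
    rmse: float | None = None
    #: support-weighted averages over classes (tp_rate, fp_rate, ...)
    averages: dict[str, float] = field(default_factory=dict)
    #: names of per-class statistics zeroed due to an empty denominator
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "per_class": self.per_class,
            "accuracy_pct": self.accuracy_pct,
            "kappa": self.kappa,
            "macro_mcc": self.macro_mcc,
            "rmse": self.rmse,
            "averages": self.averages,
            "undefined": self.undefined,
        }


def _safe_div(num: float, den: float, flag: list, name: str) -> float:
    if den == 0:
        flag.append(name)
        return 0.0
    return num / den


def report_from_confusion(
    cm: ConfusionMatrix,
    probabilities: np.ndarray | None = None,
    true_indices: np.ndarray | None = None,
) -> EvaluationReport:
    """Compute the full evaluation report from a confusion matrix.

    ``probabilities`` (n × k class probabilities, column order matching
    ``cm.labels``) together with ``true_indices`` enables AUC and RMSE;
    without them those entries are omitted/None.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    k = len(cm.labels)
    undefined: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for i, lbl in enumerate(cm.labels):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        stats = {
            "tp_rate": _safe_div(tp, tp + fn, undefined, f"{lbl}.tp_rate"),
            "fp_rate": _safe_div(fp, fp + tn, undefined, f"{lbl}.fp_rate"),
            "precision": _safe_div(tp, tp + fp, undefined, f"{lbl}.precision"),
            "specificity": _safe_div(tn, tn + fp, undefined, f"{lbl}.specificity"),
        }
        stats["recall"] = stats["tp_rate"]
        stats["sensitivity"] = stats["tp_rate"]
        pr = stats["precision"] + stats["recall"]
        stats["f_score"] = (
            2.0 * stats["precision"] * stats["recall"] / pr if pr > 0 else 0.0
        )
        if pr == 0:
            undefined.append(f"{lbl}.f_score")
        mcc_den = math_sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        stats["mcc"] = _safe_div(tp * tn - fp * fn, mcc_den, undefined, f"{lbl}.mcc")
        per_class[lbl] = stats
    accuracy_pct = 100.0 * np.trace(counts) / total
    p_o = np.trace(counts) / total
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0)) / total**2)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    macro_mcc = float(np.mean([per_class[lbl]["mcc"] for lbl in cm.labels]))

    support = counts.sum(axis=1)
    averages = {}
    for key in ("tp_rate", "fp_rate", "precision", "recall", "f_score"):
        averages[key] = float(
            np.sum([per_class[lbl][key] * support[i] for i, lbl in enumerate(cm.labels)])
            / total
        )

    rmse = None
    if probabilities is not None and true_indices is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        true_indices = np.asarray(true_indices, dtype=int)
        rmse = classifier_rmse(probabilities, true_indices)
        for i, lbl in enumerate(cm.labels):
            y_bin = (true_indices == i).astype(int)
            if 0 < y_bin.sum() < len(y_bin):
                per_class[lbl]["auc"] = auc_nonparametric(probabilities[:, i], y_bin)
            else:
                per_class[lbl]["auc"] = 0.0
                undefined.append(f"{lbl}.auc")
        averages["auc"] = float(
            np.sum(
                [per_class[lbl]["auc"] * support[i] for i, lbl in enumerate(cm.labels)]
            )
            / total
        )
    return EvaluationReport(
        labels=cm.labels,
        per_class=per_class,
        accuracy_pct=float(accuracy_pct),
        kappa=float(kappa),
        macro_mcc=macro_mcc,
        rmse=rmse,
        averages=averages,
        undefined=undefined,
    )


def math_sqrt(x: float) -> float:
    return float(np.sqrt(x)) if x > 0 else 0.0


def auc_nonparametric(scores, labels) -> float:
    """Non-parametric AUC: Mann–Whitney U / (n1·n0), ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as half
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classifier_rmse(probabilities: np.ndarray, true_indices: np.ndarray) -> float:
    """Root mean square of (one-hot truth − probability) over all cells."""
    probabilities = np.asarray(probabilities, dtype=float)
    n, k = probabilities.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), np.asarray(true_indices, dtype=int)] = 1.0
    return float(np.sqrt(np.mean((onehot - probabilities) ** 2)))
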