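"""Binary diagnostic metric panel and ROC/AUC.

AD is the positive class throughout. The seven-metric panel (sensitivity,
specificity, accuracy, PPV, NPV, F1, AUC) follows the standard confusion
identities; a metric whose denominator is zero is reported as undefined
(NaN), never coerced to 0 or 1. The ROC curve is swept over the unique
scores and AUC computed by the trapezoidal rule, which (with ties counted
half) equals the Mann-Whitney U statistic normalized by the number of
positive-negative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "confusion_and_metrics", "roc_auc"]

PANEL_FIELDS = ("sensitivity", "specificity", "accuracy", "ppv", "npv", "f1", "auc")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class MetricsReport:
    """Confusion counts plus the seven-metric panel and optional ROC curve."""

    tp: int
    fn: int
    fp: int
    tn: int
    auc: float = float("nan")
    roc: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.total)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.ppv, self.sensitivity
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            return float("nan")
        return 2.0 * p * r / (p + r)

    def panel(self) -> dict[str, float]:
        """The seven-metric panel plus counts, as a flat dict."""
        out = {k: getattr(self, k) for k in ("tp", "fn", "fp", "tn")}
        out.update({k: getattr(self, k) for k in PANEL_FIELDS})
        return out


def confusion_and_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Threshold scores at ``threshold`` and build the metric panel.

    ``labels`` are 0/1 with 1 = AD. AUC is attached when both classes are
    present in ``labels``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    report = MetricsReport(
        tp=int(np.sum(pred & pos)),
        fn=int(np.sum(~pred & pos)),
        fp=int(np.sum(pred & neg)),
        tn=int(np.sum(~pred & neg)),
    )
    if pos.any() and neg.any():
        report.auc, report.roc = roc_auc(scores, labels)
    return report


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    """ROC curve and trapezoidal AUC.

    Thresholds sweep the unique scores in descending order (predict
    positive when score >= threshold); the curve runs from (0, 0) to
    (1, 1). Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # group tied scores so curve vertices sit on threshold boundaries
    distinct = np.where(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, len(sorted_scores) - 1]
    tps = np.cumsum(sorted_labels == 1)[idx]
    fps = np.cumsum(sorted_labels == 0)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))
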