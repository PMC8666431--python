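"""ROC analysis of read depth (DP) and allele fraction (MAF) as
discriminators of review-passed versus review-failed calls.

The positive class is the review true-positive; the decision rule is
"score >= threshold predicts positive" throughout, so a discriminator
that runs the wrong way (as DP does when false positives concentrate
at extreme depth) yields AUC < 0.5 rather than being silently flipped.
AUC confidence intervals use the Hanley-McNeil standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["ROCCurve", "roc_curve", "optimal_threshold", "rates_at_threshold"]


@dataclass(frozen=True)
class ROCCurve:
    """Swept ROC curve: thresholds descending, (fpr, tpr) non-decreasing."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D and equal length")
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present; AUC is undefined")
    return labels, scores


def _hanley_mcneil_ci(auc: float, n1: int, n0: int, alpha: float = 0.05):
    """Hanley-McNeil SE for the area under the curve; Wald interval."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(norm.ppf(1 - alpha / 2))
    return (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))


def roc_curve(labels, scores) -> ROCCurve:
    """Sweep thresholds over the distinct scores (ties collapse to one
    step); AUC by the trapezoidal rule, 95% CI by Hanley-McNeil."""
    labels, scores = _validate(labels, scores)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n1, n0 = int(y.sum()), int((~y).sum())
    # step only at the last index of each tied-score block
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(~y)[idx]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        auc_ci=_hanley_mcneil_ci(auc, n1, n0),
    )


def optimal_threshold(roc: ROCCurve) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = TPR - FPR; ties go to the
    smaller threshold."""
    j = roc.tpr - roc.fpr
    best = max(
        range(len(j)),
        key=lambda i: (j[i], -roc.thresholds[i] if np.isfinite(roc.thresholds[i]) else -np.inf),
    )
    return float(roc.thresholds[best]), float(roc.tpr[best]), float(roc.fpr[best])


def rates_at_threshold(labels, scores, thr: float) -> tuple[float, float]:
    """(FPR, FNR) of the rule "score >= thr predicts positive"."""
    labels, scores = _validate(labels, scores)
    pred = scores >= thr
    fpr = float((pred & ~labels).sum() / (~labels).sum())
    fnr = float((~pred & labels).sum() / labels.sum())
    return fpr, fnr
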