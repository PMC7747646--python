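"""Classification and support-recovery metrics.

Classification metrics use label 1 as the positive class.  Support
recovery compares the nonzero pattern of an estimated coefficient vector
against the simulation truth:

    TP = #{j: beta_j != 0 and betahat_j != 0}    FN = #{beta_j != 0, betahat_j == 0}
    FP = #{j: beta_j == 0 and betahat_j != 0}    TN = #{both zero}

    beta-sensitivity = TP / (TP + FN)    beta-specificity = TN / (TN + FP)

Undefined ratios (0/0) are reported as NaN, never silently 0.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricsReport", "classification_metrics", "auc", "support_metrics"]


@dataclasses.dataclass
class MetricsReport:
    accuracy: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    auc: float = math.nan
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    beta_sensitivity: float = math.nan
    beta_specificity: float = math.nan
    beta_tp: int = 0
    beta_fp: int = 0
    beta_tn: int = 0
    beta_fn: int = 0


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def auc(scores, y_true) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction.

    Equals the probability that a positive outscores a negative, counting
    ties as 1/2 -- i.e. the trapezoidal ROC area.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=int)
    if scores.size != y.size:
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classification_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Confusion counts, accuracy, sensitivity, specificity and (when
    scores are given and both classes occur) AUC."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred differ in length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    rep = MetricsReport(
        accuracy=_ratio(tp + tn, y_true.size),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )
    if scores is not None and tp + fn > 0 and tn + fp > 0:
        rep.auc = auc(scores, y_true)
    return rep


def support_metrics(beta_true, beta_hat, tol: float = 0.0) -> MetricsReport:
    """Support-recovery confusion of an estimated coefficient vector."""
    beta_true = np.asarray(beta_true, dtype=float)
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_true.size != beta_hat.size:
        raise ValueError("coefficient vectors differ in length")
    true_nz = np.abs(beta_true) > 0
    hat_nz = np.abs(beta_hat) > tol
    tp = int(np.sum(true_nz & hat_nz))
    fn = int(np.sum(true_nz & ~hat_nz))
    fp = int(np.sum(~true_nz & hat_nz))
    tn = int(np.sum(~true_nz & ~hat_nz))
    return MetricsReport(
        beta_sensitivity=_ratio(tp, tp + fn),
        beta_specificity=_ratio(tn, tn + fp),
        beta_tp=tp, beta_fp=fp, beta_tn=tn, beta_fn=fn,
    )
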