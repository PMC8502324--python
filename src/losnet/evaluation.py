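"""Diagnostic-test evaluation of the binary prediction models.

Eight indexes summarise a fitted classifier on a validation set: incorrect
classification, sensitivity, specificity, false positive rate (Type I
error), false negative rate (Type II error), positive and negative
likelihood ratios, and the area under the ROC curve.  Sensitivity and
specificity additionally carry a normal-approximation (Wald) standard error
and 95% confidence interval.

Two conventions matter for matching published tables of this kind:

* The AUC of a single hard classifier is the trapezoidal area of the
  degenerate three-point ROC {(0,0), (FPR, sens), (1,1)}, which reduces to
  (sens + spec)/2.  A score-based ROC AUC is available separately via
  :func:`roc_auc` when continuous scores exist.
* The confidence bounds are built from the standard error rounded to three
  decimals, the precision such tables print, so the printed interval is
  exactly reproducible from the printed SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

Z_95 = 1.96


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (school rounding, not banker's)."""
    q = 10.0 ** ndigits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


@dataclass
class EvaluationReport:
    """Confusion counts plus the eight evaluation indexes with SE/CI."""

    tp: int
    fp: int
    tn: int
    fn: int
    n: int
    occurrence: int          # actual positives
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float
    incorrect_classification: float
    lr_pos: float            # +inf when specificity == 1
    lr_neg: float            # nan when specificity == 0
    auc_binary: float
    sens_se: float
    spec_se: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    auc_roc: float | None = None

    def summary_dict(self) -> dict:
        return {
            "n": self.n,
            "occurrence": self.occurrence,
            "incorrect_classification": self.incorrect_classification,
            "sensitivity": self.sensitivity,
            "sensitivity_std_err": self.sens_se,
            "sensitivity_ci95": list(self.sens_ci),
            "specificity": self.specificity,
            "specificity_std_err": self.spec_se,
            "specificity_ci95": list(self.spec_ci),
            "false_positive_rate": self.fpr,
            "false_negative_rate": self.fnr,
            "positive_likelihood_ratio": self.lr_pos,
            "negative_likelihood_ratio": self.lr_neg,
            "area_under_the_curve": self.auc_binary,
        }


def confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) counts; inputs must be equal-length binary vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


def likelihood_ratios(sens: float, spec: float) -> tuple[float, float]:
    """LR+ = sens/(1−spec), LR− = (1−sens)/spec.

    ``spec == 1`` gives LR+ = +inf (perfectly specific test); ``spec == 0``
    leaves LR− undefined (returned as nan).
    """
    for v in (sens, spec):
        if not 0.0 <= v <= 1.0:
            raise ValueError("sensitivity and specificity must lie in [0, 1]")
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = math.nan if spec == 0.0 else (1.0 - sens) / spec
    return lr_pos, lr_neg


def incorrect_classification(sens: float, spec: float, occurrence: int, n: int) -> float:
    """Proportion of all patients misclassified, from the two rates.

    ((1−sens)·occurrence + (1−spec)·(n−occurrence)) / n — the weighted
    complement of sensitivity and specificity by class size.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= occurrence <= n:
        raise ValueError("occurrence must lie in [0, n]")
    return ((1.0 - sens) * occurrence + (1.0 - spec) * (n - occurrence)) / n


def auc_binary(sens: float, spec: float) -> float:
    """(sens + spec)/2 — ROC area of the single-threshold classifier."""
    for v in (sens, spec):
        if not 0.0 <= v <= 1.0:
            raise ValueError("inputs must lie in [0, 1]")
    return (sens + spec) / 2.0


def wald_interval(p: float, m: int) -> tuple[float, float, float]:
    """(se, lo, hi): Wald SE and 95% CI built from the 3-dp-rounded SE.

    ``m`` is the denominator count of the proportion (positives for
    sensitivity, negatives for specificity).
    """
    if m < 1:
        raise ValueError("denominator count must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    se = math.sqrt(p * (1.0 - p) / m)
    se_r = round_half_away(se, 3)
    return se, p - Z_95 * se_r, p + Z_95 * se_r


def roc_auc(y_true, scores) -> float:
    """Score-based trapezoidal ROC AUC (Mann–Whitney form)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for a ROC AUC")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


def evaluate(y_true, y_pred, scores=None) -> EvaluationReport:
    """Full evaluation report from true labels and hard predictions.

    The sensitivity SE uses the positive count as denominator, the
    specificity SE the negative count.  When continuous ``scores`` are given
    the proper score-based ROC AUC is reported alongside the binary one.
    """
    tp, fp, tn, fn = confusion(y_true, y_pred)
    n = tp + fp + tn + fn
    occurrence = tp + fn
    n_neg = tn + fp
    if occurrence == 0 or n_neg == 0:
        raise ValueError("both classes must be present in y_true")
    sens = tp / occurrence
    spec = tn / n_neg
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    sens_se, sens_lo, sens_hi = wald_interval(sens, occurrence)
    spec_se, spec_lo, spec_hi = wald_interval(spec, n_neg)
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn, n=n, occurrence=occurrence,
        sensitivity=sens,
        specificity=spec,
        fpr=1.0 - spec,
        fnr=1.0 - sens,
        incorrect_classification=incorrect_classification(sens, spec, occurrence, n),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        auc_binary=auc_binary(sens, spec),
        sens_se=sens_se,
        spec_se=spec_se,
        sens_ci=(sens_lo, sens_hi),
        spec_ci=(spec_lo, spec_hi),
        auc_roc=None if scores is None else roc_auc(y_true, scores),
    )
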