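"""Confusion-matrix accumulation and derived performance statistics.

Trials simulated as truly bioequivalent form the positive class; a
method's bioequivalence verdict is the predicted label.  From the
(TP, FN, FP, TN) counts eight statistics are derived: sensitivity
(power, 1-beta), specificity (1 - type I error), precision, negative
predictive value, accuracy, F1, the Matthews correlation coefficient
and Cohen's kappa (standard two-class form).  Statistics with a zero
denominator are reported as NaN and flagged in ``undefined`` rather
than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ConfusionSummary", "accumulate", "statistics"]


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    f1: float
    mcc: float
    kappa: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_percent(self) -> dict[str, float]:
        """The eight statistics on the 0-100 scale (kappa/MCC included)."""
        return {
            name: getattr(self, name) * 100.0
            for name in (
                "sensitivity", "specificity", "precision", "npv",
                "accuracy", "f1", "mcc", "kappa",
            )
        }


def accumulate(
    truth_labels: Sequence[bool], decisions: Sequence[bool]
) -> tuple[int, int, int, int]:
    """Count (tp, fn, fp, tn); truth True = truly bioequivalent."""
    t = np.asarray(truth_labels, dtype=bool)
    p = np.asarray(decisions, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("truth and decision vectors must have equal length")
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    return tp, fn, fp, tn


def _ratio(num: float, den: float, name: str, undef: set[str]) -> float:
    if den == 0:
        undef.add(name)
        return float("nan")
    return num / den


def statistics(tp: int, fn: int, fp: int, tn: int) -> ConfusionSummary:
    """All eight confusion-matrix statistics as fractions."""
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fn + fp + tn
    if total == 0:
        raise ValueError("empty confusion matrix")
    undef: set[str] = set()
    sens = _ratio(tp, tp + fn, "sensitivity", undef)
    spec = _ratio(tn, tn + fp, "specificity", undef)
    prec = _ratio(tp, tp + fp, "precision", undef)
    npv = _ratio(tn, tn + fn, "npv", undef)
    acc = (tp + tn) / total
    if np.isnan(sens) or np.isnan(prec) or (sens + prec) == 0:
        undef.add("f1")
        f1 = float("nan")
    else:
        f1 = 2.0 * sens * prec / (sens + prec)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", undef)
    kappa_den = float(tp + fp) * float(fp + tn) + float(tp + fn) * float(fn + tn)
    kappa = _ratio(2.0 * (tp * tn - fp * fn), kappa_den, "kappa", undef)
    return ConfusionSummary(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=sens, specificity=spec, precision=prec, npv=npv,
        accuracy=acc, f1=f1, mcc=mcc, kappa=kappa,
        undefined=frozenset(undef),
    )
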