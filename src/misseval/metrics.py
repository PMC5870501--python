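"""Confusion matrices, performance statistics and clinical-impact counts.

Sensitivity, specificity, accuracy and the Matthews correlation
coefficient (MCC) over binary pathogenic/benign calls:

    SENS = TP/(TP+FN)          SPEC = TN/(FP+TN)
    ACC  = (TP+TN)/total       MCC  = (TP*TN - FP*FN)/sqrt(prod of marginals)

MCC is the preferred single-number summary on the strongly
benign-skewed variant sets typical of diagnostic practice.  Because raw
proportions understate clinical impact — one founder mutation may be
carried by hundreds of families — :func:`impact_counts` additionally
weights each misclassified variant by the number of index families
carrying it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .curation import VariantRecord, truth_call
from .harmonize import BENIGN, PATHOGENIC

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "confusion",
    "performance",
    "impact_counts",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, matching how results tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError(f"negative confusion-matrix entry: {self}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    """SENS/SPEC/ACC/MCC with a display-rounding policy.

    A statistic whose denominator is empty (no pathogenic truth for SENS,
    no neutral truth for SPEC) is ``None``.  When any MCC marginal is zero
    the coefficient is reported as 0.0 with ``mcc_degenerate`` set.
    """

    sens: float | None
    spec: float | None
    acc: float
    mcc: float
    mcc_degenerate: bool = False

    def rounded(self, precision: int = 2) -> dict[str, float | None]:
        return {
            name: None if value is None else round_half_up(value, precision)
            for name, value in (
                ("sens", self.sens),
                ("spec", self.spec),
                ("acc", self.acc),
                ("mcc", self.mcc),
            )
        }


def confusion(truth: list[str], calls: list[str]) -> ConfusionMatrix:
    """Tally the four outcome cells of paired truth/call labels ('P'/'B')."""
    if len(truth) != len(calls):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(calls)} calls")
    tp = fp = tn = fn = 0
    for t, c in zip(truth, calls):
        if t not in (PATHOGENIC, BENIGN) or c not in (PATHOGENIC, BENIGN):
            raise ValueError(f"non-binary pair ({t!r}, {c!r}); drop missing calls upstream")
        if t == PATHOGENIC:
            if c == PATHOGENIC:
                tp += 1
            else:
                fn += 1
        else:
            if c == PATHOGENIC:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def performance(cm: ConfusionMatrix) -> PerformanceReport:
    """Compute SENS, SPEC, ACC and MCC from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    spec = cm.tn / (cm.fp + cm.tn) if cm.fp + cm.tn else None
    acc = (cm.tp + cm.tn) / cm.total
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return PerformanceReport(sens, spec, acc, mcc=0.0, mcc_degenerate=True)
    mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return PerformanceReport(sens, spec, acc, mcc=mcc)


def impact_counts(
    records: list[VariantRecord], calls: dict[str, str]
) -> tuple[int, int]:
    """Family-weighted error counts.

    Returns ``(families_false_negative, families_false_positive)``: the
    number of index families that would receive an erroneous negative
    (pathogenic variant called benign) or positive (neutral variant called
    pathogenic) result were diagnosis based on ``calls`` alone.
    """
    fn_families = fp_families = 0
    for rec in records:
        if rec.variant_id not in calls:
            raise ValueError(f"no call for variant {rec.variant_id}")
        call = calls[rec.variant_id]
        t = truth_call(rec)
        if t == PATHOGENIC and call == BENIGN:
            fn_families += rec.family_count
        elif t == BENIGN and call == PATHOGENIC:
            fp_families += rec.family_count
    return fn_families, fp_families
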