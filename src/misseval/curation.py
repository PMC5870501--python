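"""Curation of classified and circularity-free evaluation variant sets.

Starting from an annotated table of BRCA1/2 missense variants, the
*classified set* keeps variants with a definite five-tier class (1, 2, 4
or 5), a maximum population allele frequency below 0.01 (common variants
are benign by frequency alone under the ENIGMA rules) and no known effect
on splicing.  The *evaluation set* further restricts to variants whose
classification does not depend on the in silico prior: either their
product of likelihood ratios clears a prior-independence threshold
(:func:`misseval.multifactorial.prior_independence`) or an expert panel
classified them on functional / published evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .multifactorial import (
    INDEPENDENT_NEUTRAL,
    INDEPENDENT_PATHOGENIC,
    PRIOR_DEPENDENT,
    PlonThresholds,
    PriorConfig,
    prior_independence,
)

__all__ = [
    "POPULATIONS",
    "GENES",
    "VariantRecord",
    "CurationResult",
    "CompositionCounts",
    "IntegrityError",
    "max_af",
    "truth_call",
    "build_classified_set",
    "build_evaluation_set",
    "set_composition",
]

#: ExAC ancestry cohorts whose allele frequencies feed the rarity filter.
POPULATIONS = ("afr", "eas", "sas", "fin", "nfe", "amr")

GENES = ("BRCA1", "BRCA2")

PATHOGENIC_CLASSES = frozenset({4, 5})
NEUTRAL_CLASSES = frozenset({1, 2})


class IntegrityError(ValueError):
    """A variant's LR-based direction contradicts its truth class."""


@dataclass
class VariantRecord:
    """One annotated missense variant.

    ``truth_class`` is the expert five-tier classification (None when
    unknown), ``product_of_lrs`` the combined likelihood ratio from
    prior-independent evidence, ``population_afs`` a cohort-label -> allele
    frequency map (absent cohorts mean "not observed"), ``raw_calls`` the
    untouched per-tool outputs keyed by raw column name.
    """

    variant_id: str
    gene: str
    truth_class: int | None = None
    product_of_lrs: float | None = None
    population_afs: dict[str, float] = field(default_factory=dict)
    spliceogenic: bool = False
    expert_override: bool = False
    family_count: int = 0
    raw_calls: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.truth_class is not None and self.truth_class not in range(1, 6):
            raise ValueError(
                f"{self.variant_id}: truth_class must be 1..5, got {self.truth_class}"
            )
        for pop, af in self.population_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"{self.variant_id}: AF[{pop}]={af} outside [0, 1]")
        if self.family_count < 0:
            raise ValueError(f"{self.variant_id}: negative family_count")


@dataclass
class CurationResult:
    """Outcome of a curation stage: kept records plus an exclusion log."""

    classified_set: list[VariantRecord] = field(default_factory=list)
    evaluation_set: list[VariantRecord] = field(default_factory=list)
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)


def max_af(record: VariantRecord) -> float:
    """Maximum allele frequency over the population cohorts.

    Variants absent from the reference panel carry an empty map and are
    treated as frequency zero.
    """
    if not record.population_afs:
        return 0.0
    return max(record.population_afs.values())


def truth_call(record: VariantRecord) -> str:
    """Binarized truth: 'P' for classes 4/5, 'B' for classes 1/2."""
    if record.truth_class in PATHOGENIC_CLASSES:
        return "P"
    if record.truth_class in NEUTRAL_CLASSES:
        return "B"
    raise ValueError(
        f"{record.variant_id}: truth_class {record.truth_class} has no binary truth"
    )


def build_classified_set(records: list[VariantRecord]) -> CurationResult:
    """Apply the classified-set filter cascade.

    Keeps records with a definite class (1/2/4/5), maximum AF < 0.01 and no
    known spliceogenic effect.  Each rejected record is logged once with the
    first failing rule, in the order: class filter, AF filter, splice filter.
    """
    result = CurationResult()
    for rec in records:
        if rec.truth_class is None:
            result.exclusion_log.append((rec.variant_id, "unclassified"))
        elif rec.truth_class == 3:
            result.exclusion_log.append((rec.variant_id, "uncertain class"))
        elif max_af(rec) >= 0.01:
            result.exclusion_log.append((rec.variant_id, "AF >= 0.01"))
        elif rec.spliceogenic:
            result.exclusion_log.append((rec.variant_id, "spliceogenic"))
        else:
            result.classified_set.append(rec)
    return result


def build_evaluation_set(
    classified: list[VariantRecord],
    priors: PriorConfig = PriorConfig(),
    thresholds: PlonThresholds = PlonThresholds(),
) -> CurationResult:
    """Restrict a classified set to prior-independent variants.

    A variant is admitted when an expert panel classified it directly
    (``expert_override``) or when its product of LRs is extreme enough that
    the five-tier class is the same under both extreme priors.  An admitted
    LR direction must agree with the truth class (an "independent
    pathogenic" LR on a benign variant indicates corrupted input) —
    disagreement raises :class:`IntegrityError` naming the variant.
    """
    result = CurationResult(classified_set=list(classified))
    for rec in classified:
        if rec.expert_override:
            result.evaluation_set.append(rec)
            continue
        if rec.product_of_lrs is None:
            result.exclusion_log.append((rec.variant_id, "missing product_of_lrs"))
            continue
        status = prior_independence(rec.product_of_lrs, priors, thresholds)
        if status == PRIOR_DEPENDENT:
            result.exclusion_log.append((rec.variant_id, "prior-dependent"))
            continue
        if status == INDEPENDENT_PATHOGENIC and rec.truth_class not in PATHOGENIC_CLASSES:
            raise IntegrityError(
                f"{rec.variant_id}: product_of_lrs {rec.product_of_lrs} supports "
                f"pathogenicity but truth_class is {rec.truth_class}"
            )
        if status == INDEPENDENT_NEUTRAL and rec.truth_class not in NEUTRAL_CLASSES:
            raise IntegrityError(
                f"{rec.variant_id}: product_of_lrs {rec.product_of_lrs} supports "
                f"benignity but truth_class is {rec.truth_class}"
            )
        result.evaluation_set.append(rec)
    return result


@dataclass(frozen=True)
class CompositionCounts:
    """Per-gene pathogenic/neutral counts of a curated set."""

    per_gene: dict[str, tuple[int, int]]  # gene -> (n_pathogenic, n_neutral)

    @property
    def total(self) -> int:
        return sum(p + n for p, n in self.per_gene.values())

    @property
    def pathogenic(self) -> int:
        return sum(p for p, _ in self.per_gene.values())

    @property
    def neutral(self) -> int:
        return sum(n for _, n in self.per_gene.values())


def set_composition(records: list[VariantRecord]) -> CompositionCounts:
    """Count pathogenic (class 4/5) and neutral (class 1/2) variants per gene."""
    per_gene: dict[str, list[int]] = {}
    for rec in records:
        direction = truth_call(rec)  # raises on class 3 / unclassified
        counts = per_gene.setdefault(rec.gene, [0, 0])
        counts[0 if direction == "P" else 1] += 1
    return CompositionCounts({g: (p, n) for g, (p, n) in per_gene.items()})
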