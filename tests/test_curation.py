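"""Classified-set filters, prior-independence admission and composition counts."""

import numpy as np
import pytest

from misseval import (
    IntegrityError,
    build_classified_set,
    build_evaluation_set,
    max_af,
    set_composition,
)
from misseval.synthetic import SyntheticConfig, admission_probability, generate
from misseval.harmonize import PATHOGENIC


class TestMaxAf:
    def test_unobserved_variant_is_frequency_zero(self, make_record):
        assert max_af(make_record(population_afs={})) == 0.0

    def test_maximum_over_cohorts(self, make_record):
        rec = make_record(population_afs={"afr": 0.002, "amr": 0.008})
        assert max_af(rec) == 0.008

    def test_single_cohort(self, make_record):
        assert max_af(make_record(population_afs={"nfe": 0.012})) == 0.012


class TestClassifiedSet:
    def test_filter_cascade_reasons(self, make_record):
        records = [
            make_record(variant_id="v_ok", truth_class=2, product_of_lrs=0.001),
            make_record(variant_id="v_vus", truth_class=3),
            make_record(variant_id="v_none", truth_class=None),
            make_record(variant_id="v_common", truth_class=5,
                        population_afs={"nfe": 0.02}),
            make_record(variant_id="v_splice", truth_class=5, spliceogenic=True),
        ]
        result = build_classified_set(records)
        assert [r.variant_id for r in result.classified_set] == ["v_ok"]
        assert dict(result.exclusion_log) == {
            "v_vus": "uncertain class",
            "v_none": "unclassified",
            "v_common": "AF >= 0.01",
            "v_splice": "spliceogenic",
        }

    def test_first_failing_rule_wins(self, make_record):
        # class filter is logged before AF and splice filters
        rec = make_record(truth_class=3, population_afs={"nfe": 0.5},
                          spliceogenic=True)
        result = build_classified_set([rec])
        assert result.exclusion_log[0][1] == "uncertain class"

    def test_partition_covers_input_once(self, make_record):
        records = [make_record(truth_class=c) for c in (1, 2, 3, 4, 5, None)]
        result = build_classified_set(records)
        assert len(result.classified_set) + len(result.exclusion_log) == len(records)

    def test_af_boundary_is_exclusive(self, make_record):
        kept = build_classified_set(
            [make_record(population_afs={"eas": 0.00999})]
        ).classified_set
        assert len(kept) == 1
        dropped = build_classified_set(
            [make_record(population_afs={"eas": 0.01})]
        ).exclusion_log
        assert dropped[0][1] == "AF >= 0.01"


class TestEvaluationSet:
    def test_expert_override_included_without_lr(self, make_record):
        rec = make_record(truth_class=4, product_of_lrs=None, expert_override=True)
        result = build_evaluation_set([rec])
        assert result.evaluation_set == [rec]

    def test_extreme_lr_admitted(self, make_record):
        rec = make_record(truth_class=5, product_of_lrs=1000.0)
        assert build_evaluation_set([rec]).evaluation_set == [rec]

    def test_prior_dependent_excluded(self, make_record):
        rec = make_record(variant_id="v_mid", truth_class=1, product_of_lrs=0.5)
        result = build_evaluation_set([rec])
        assert result.evaluation_set == []
        assert ("v_mid", "prior-dependent") in result.exclusion_log

    def test_missing_lr_excluded(self, make_record):
        rec = make_record(variant_id="v_nolr", truth_class=1, product_of_lrs=None)
        result = build_evaluation_set([rec])
        assert ("v_nolr", "missing product_of_lrs") in result.exclusion_log

    def test_direction_contradiction_raises(self, make_record):
        rec = make_record(variant_id="v_bad", truth_class=1, product_of_lrs=1000.0)
        with pytest.raises(IntegrityError, match="v_bad"):
            build_evaluation_set([rec])

    def test_subset_of_classified(self, make_record):
        records = [
            make_record(truth_class=5, product_of_lrs=1e5),
            make_record(truth_class=1, product_of_lrs=1.0),
            make_record(truth_class=2, product_of_lrs=1e-5),
        ]
        result = build_evaluation_set(records)
        assert set(r.variant_id for r in result.evaluation_set) <= set(
            r.variant_id for r in result.classified_set
        )

    def test_admission_fraction_matches_analytic_probability(self):
        """Monte-Carlo admission rate agrees with the log-normal closed form."""
        config = SyntheticConfig(
            n_pathogenic=4000, n_neutral=0, correlation=0.0,
            expert_fraction=0.0, seed=7,
        )
        records = generate(config)
        result = build_evaluation_set(records)
        observed = len(result.evaluation_set) / len(records)
        expected = admission_probability(config, PATHOGENIC)
        se = np.sqrt(expected * (1 - expected) / len(records))
        assert abs(observed - expected) < 3 * se


class TestComposition:
    def test_published_composition_sums(self, paper_composition):
        comp = set_composition(paper_composition)
        assert comp.per_gene == {"BRCA1": (16, 73), "BRCA2": (5, 67)}
        assert comp.total == 161
        assert comp.pathogenic == 21
        assert comp.neutral == 140

    def test_empty_list(self):
        comp = set_composition([])
        assert comp.per_gene == {} and comp.total == 0

    def test_small_mixed_set(self, make_record):
        records = [
            make_record(gene="BRCA1", truth_class=5),
            make_record(gene="BRCA1", truth_class=5),
            make_record(gene="BRCA2", truth_class=2, product_of_lrs=0.001),
        ]
        assert set_composition(records).per_gene == {
            "BRCA1": (2, 0),
            "BRCA2": (0, 1),
        }

    def test_unclassified_record_rejected(self, make_record):
        with pytest.raises(ValueError):
            set_composition([make_record(truth_class=3)])
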