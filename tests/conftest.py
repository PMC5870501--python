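import pytest

from misseval import VariantRecord


@pytest.fixture
def make_record():
    """Factory for minimal variant records with sensible defaults."""

    counter = {"n": 0}

    def _make(**kwargs):
        counter["n"] += 1
        defaults = dict(
            variant_id=f"BRCA1:test{counter['n']:03d}",
            gene="BRCA1",
            truth_class=5,
            product_of_lrs=1000.0,
            population_afs={},
            spliceogenic=False,
            expert_override=False,
            family_count=1,
            raw_calls={},
        )
        defaults.update(kwargs)
        return VariantRecord(**defaults)

    return _make


@pytest.fixture
def paper_composition(make_record):
    """An evaluation set with the published per-gene composition:
    89 BRCA1 (16 pathogenic, 73 neutral) + 72 BRCA2 (5 pathogenic, 67 neutral).
    """
    records = []
    for gene, n_path, n_neut in (("BRCA1", 16, 73), ("BRCA2", 5, 67)):
        for _ in range(n_path):
            records.append(make_record(gene=gene, truth_class=5))
        for _ in range(n_neut):
            records.append(make_record(gene=gene, truth_class=1, product_of_lrs=0.001))
    return records
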