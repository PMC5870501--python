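"""m-of-n voting, the Poisson-binomial independence model and consensus."""

import itertools
import math

import numpy as np
import pytest

from misseval import (
    EnsembleScheme,
    admissible_schemes,
    benignity_screen,
    consensus_partition,
    ensemble_call,
    evaluate_schemes,
    expected_combined,
    vote_count_pmf,
)
from misseval.harmonize import TOOLS


def enumerate_vote_tail(probs, m):
    """Oracle: P(at least m successes) by summing over all 2^n outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=len(probs)):
        if sum(outcome) >= m:
            total += math.prod(
                p if o else 1 - p for p, o in zip(probs, outcome)
            )
    return total


class TestAdmissibleSchemes:
    def test_no_two_tool_schemes(self):
        assert all(s.n >= 3 for s in admissible_schemes())

    def test_vote_thresholds_per_size(self):
        schemes = admissible_schemes()
        assert {s.m for s in schemes if s.n == 3} == {2, 3}
        assert {s.m for s in schemes if s.n == 4} == {2, 3, 4}

    def test_total_count(self):
        # 4 three-tool subsets x 2 thresholds + 1 four-tool subset x 3
        assert len(admissible_schemes()) == 11

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            EnsembleScheme(tools=("sift", "polyphen2"), m=2)  # excluded pair
        with pytest.raises(ValueError):
            EnsembleScheme(tools=TOOLS[:3], m=1)  # below majority


class TestEnsembleCall:
    @pytest.mark.parametrize(
        "calls,m,expected",
        [
            (["P", "P", "B", "B"], 2, "P"),
            (["P", "P", "B", "B"], 3, "B"),
            (["P", "P", "P", "P"], 4, "P"),
            (["B", "B", "B"], 2, "B"),
        ],
    )
    def test_vote_threshold(self, calls, m, expected):
        assert ensemble_call(calls, m) == expected

    def test_missing_call_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ensemble_call(["P", None, "B"], 2)


class TestExpectedCombined:
    @pytest.mark.parametrize(
        "probs,m,mode,expected",
        [
            ([1.0, 1.0, 0.90, 0.67], 4, "sensitivity", 0.603),
            ([1.0, 1.0, 0.90, 0.67], 3, "sensitivity", 0.967),
            ([0.1, 0.2, 0.3], 2, "specificity", 0.902),
        ],
    )
    def test_enumerated_examples(self, probs, m, mode, expected):
        assert expected_combined(probs, m, mode) == pytest.approx(expected, abs=5e-4)

    def test_matches_enumeration_oracle(self):
        """Convolution equals brute-force 2^n enumeration on random draws."""
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = rng.integers(2, 5)
            probs = rng.random(n).tolist()
            for m in range(1, n + 1):
                assert expected_combined(probs, m, "sensitivity") == pytest.approx(
                    enumerate_vote_tail(probs, m), abs=1e-12
                )
                assert expected_combined(probs, m, "specificity") == pytest.approx(
                    1.0 - enumerate_vote_tail(probs, m), abs=1e-12
                )

    def test_identical_tools_reduce_to_binomial(self):
        from scipy.stats import binom

        p, n = 0.73, 4
        for m in range(1, n + 1):
            assert expected_combined([p] * n, m, "sensitivity") == pytest.approx(
                binom.sf(m - 1, n, p)
            )

    def test_agrees_with_scipy_poisson_binom(self):
        """Independent cross-check of the hand convolution."""
        from scipy.stats import poisson_binom

        probs = [0.9, 0.5, 0.31, 0.77]
        np.testing.assert_allclose(
            vote_count_pmf(probs), poisson_binom.pmf(range(5), probs), atol=1e-12
        )

    def test_monotone_in_m(self):
        sens = [0.9, 1.0, 0.67, 0.9]
        fpr = [0.08, 0.28, 0.21, 0.33]
        sens_vals = [expected_combined(sens, m, "sensitivity") for m in (2, 3, 4)]
        spec_vals = [expected_combined(fpr, m, "specificity") for m in (2, 3, 4)]
        assert sens_vals == sorted(sens_vals, reverse=True)
        assert spec_vals == sorted(spec_vals)

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            expected_combined([0.5, 0.5], 3, "sensitivity")


class TestConsensus:
    def test_partition_and_exclusive_counts(self):
        calls = {
            "v1": dict.fromkeys(TOOLS, "B"),
            "v2": dict.fromkeys(TOOLS, "P"),
            "v3": {**dict.fromkeys(TOOLS, "B"), "polyphen2": "P"},
            "v4": {**dict.fromkeys(TOOLS, "P"), "align_gvgd": "B"},
            "v5": {"align_gvgd": "P", "sift": "P", "mutation_taster2": "B",
                   "polyphen2": "B"},
        }
        part = consensus_partition(calls)
        assert part.sizes == (1, 1, 3)
        assert sum(part.sizes) == len(calls)
        assert part.exclusive_pathogenic["polyphen2"] == 1
        assert part.exclusive_benign["align_gvgd"] == 1
        assert part.exclusive_pathogenic["sift"] == 0

    def test_missing_call_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            consensus_partition({"v": {"align_gvgd": "P"}})


class TestBenignityScreen:
    def test_unanimous_benign(self):
        assert benignity_screen({"sift": "B", "mutation_taster2": "B"})

    def test_any_pathogenic_blocks(self):
        assert not benignity_screen({"sift": "B", "mutation_taster2": "P"})

    def test_single_tool_degenerates(self):
        assert benignity_screen({"sift": "B"}, screen_tools=("sift",))
        assert not benignity_screen({"sift": "P"}, screen_tools=("sift",))


class TestEvaluateSchemes:
    def test_complete_case_handling_and_columns(self):
        truth = {"v1": "P", "v2": "B", "v3": "B"}
        calls = {
            "v1": dict.fromkeys(TOOLS, "P"),
            "v2": dict.fromkeys(TOOLS, "B"),
            "v3": {**dict.fromkeys(TOOLS, "B"), "sift": None},
        }
        rows = evaluate_schemes(truth, calls)
        assert len(rows) == 11
        with_sift = [r for r in rows if "sift" in r["tools"]]
        assert all(r["n_dropped"] == 1 for r in with_sift)
        no_sift = [r for r in rows if "sift" not in r["tools"]]
        assert all(r["n_dropped"] == 0 for r in no_sift)
        assert all(0 <= r["expected_sens"] <= 1 for r in rows)
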