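"""m-of-n voting over predictor calls and its independence expectation.

A combined approach over a subset of n tools calls a variant pathogenic
when at least m tools do.  Admissible schemes require a majority
(m >= n/2) and exclude the unanimous pair (m=2, n=2); since m=2 is the
only majority option for n=2, no two-tool scheme exists and schemes span
n in {3, 4}.

The expected performance of a combined approach under the best-case
assumption that tools err *independently* follows from the exact
distribution of the number of pathogenic votes: a Poisson-binomial count
over per-tool success probabilities (sensitivities on pathogenic variants,
false-positive rates on neutral ones).  Comparing observed ensemble
specificity against this expectation quantifies how much the tools' shared
reliance on conservation features erodes the benefit of combining them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .harmonize import BENIGN, PATHOGENIC, TOOLS
from .metrics import ConfusionMatrix, PerformanceReport, confusion, performance

__all__ = [
    "EnsembleScheme",
    "IndependenceExpectation",
    "ConsensusPartition",
    "admissible_schemes",
    "ensemble_call",
    "vote_count_pmf",
    "expected_combined",
    "expected_performance",
    "consensus_partition",
    "benignity_screen",
    "evaluate_schemes",
]


@dataclass(frozen=True)
class EnsembleScheme:
    """An (m, n) voting rule over an ordered tool subset."""

    tools: tuple[str, ...]
    m: int

    def __post_init__(self) -> None:
        n = len(self.tools)
        if len(set(self.tools)) != n:
            raise ValueError(f"duplicate tools in {self.tools}")
        if not 2 <= n <= 4:
            raise ValueError(f"scheme size must be 2..4, got {n}")
        if not (n / 2 <= self.m <= n):
            raise ValueError(f"m={self.m} violates n/2 <= m <= n for n={n}")
        if self.m == 2 and n == 2:
            raise ValueError("the unanimous two-tool scheme (m=2, n=2) is excluded")

    @property
    def n(self) -> int:
        return len(self.tools)

    @property
    def label(self) -> str:
        return f"{self.m}-of-{self.n}[" + ",".join(self.tools) + "]"


@dataclass(frozen=True)
class IndependenceExpectation:
    expected_sens: float
    expected_spec: float


def admissible_schemes(tools: tuple[str, ...] = TOOLS) -> list[EnsembleScheme]:
    """Every admissible (m, n) scheme over subsets of the given tools.

    Majority rule m >= n/2 with the (2, 2) case excluded leaves no
    admissible two-tool scheme, so subsets of size 3 and 4 remain:
    n=3 admits m in {2, 3} and n=4 admits m in {2, 3, 4}.
    """
    if len(set(tools)) != len(tools):
        raise ValueError("tools must be distinct")
    schemes = []
    for n in range(3, len(tools) + 1):
        for subset in itertools.combinations(tools, n):
            for m in range(math.ceil(n / 2), n + 1):
                schemes.append(EnsembleScheme(tools=subset, m=m))
    return schemes


def ensemble_call(calls: list[str], m: int) -> str:
    """Pathogenic iff at least m of the calls are pathogenic."""
    if not 1 <= m <= len(calls):
        raise ValueError(f"m={m} out of range for {len(calls)} calls")
    votes = 0
    for c in calls:
        if c not in (PATHOGENIC, BENIGN):
            raise ValueError(
                f"missing or non-binary call {c!r}; variants with incomplete "
                "calls must be dropped upstream"
            )
        votes += c == PATHOGENIC
    return PATHOGENIC if votes >= m else BENIGN


def vote_count_pmf(probs: list[float]) -> np.ndarray:
    """Exact pmf of the number of successes among independent Bernoulli trials.

    Poisson-binomial distribution by iterative convolution: pmf[k] is the
    probability of exactly k pathogenic votes.  Exact (up to float
    arithmetic) for any n; the ensembles here use n <= 4.
    """
    pmf = np.array([1.0])
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def expected_combined(probs: list[float], m: int, mode: str) -> float:
    """Expected combined sensitivity or specificity under independence.

    ``mode="sensitivity"``: ``probs`` are per-tool sensitivities and the
    result is P(votes >= m) on a pathogenic variant.  ``mode="specificity"``:
    ``probs`` are per-tool false-positive rates (1 - specificity) and the
    result is P(votes < m) on a neutral variant.
    """
    n = len(probs)
    if n < 2:
        raise ValueError("need at least two tools")
    if not 1 <= m <= n:
        raise ValueError(f"m={m} out of range for n={n}")
    pmf = vote_count_pmf(probs)
    if mode == "sensitivity":
        return float(pmf[m:].sum())
    if mode == "specificity":
        return float(pmf[:m].sum())
    raise ValueError(f"mode must be 'sensitivity' or 'specificity', got {mode!r}")


def expected_performance(
    scheme: EnsembleScheme,
    tool_sens: dict[str, float],
    tool_spec: dict[str, float],
    prevalence: float | None = None,
) -> tuple[IndependenceExpectation, PerformanceReport | None]:
    """Independence expectation for a scheme, from stand-alone marginals.

    Returns the expected sensitivity/specificity pair and, when a
    prevalence (fraction of pathogenic variants) is supplied, a full
    expected performance report built from the expected confusion-cell
    fractions — a derived construction layered on the vote-count model,
    not part of it.
    """
    sens = [tool_sens[t] for t in scheme.tools]
    fpr = [1.0 - tool_spec[t] for t in scheme.tools]
    exp = IndependenceExpectation(
        expected_sens=expected_combined(sens, scheme.m, "sensitivity"),
        expected_spec=expected_combined(fpr, scheme.m, "specificity"),
    )
    if prevalence is None:
        return exp, None
    # expected cell fractions; MCC/ACC evaluated on them directly
    tp = prevalence * exp.expected_sens
    fn = prevalence * (1.0 - exp.expected_sens)
    tn = (1.0 - prevalence) * exp.expected_spec
    fp = (1.0 - prevalence) * (1.0 - exp.expected_spec)
    acc = tp + tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    report = PerformanceReport(
        sens=exp.expected_sens,
        spec=exp.expected_spec,
        acc=acc,
        mcc=mcc,
        mcc_degenerate=denom == 0,
    )
    return exp, report


@dataclass
class ConsensusPartition:
    """Agreement structure of all four tools over a variant set."""

    concordant_benign: list[str] = field(default_factory=list)
    concordant_pathogenic: list[str] = field(default_factory=list)
    discordant: list[str] = field(default_factory=list)
    exclusive_pathogenic: dict[str, int] = field(default_factory=dict)
    exclusive_benign: dict[str, int] = field(default_factory=dict)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (
            len(self.concordant_benign),
            len(self.concordant_pathogenic),
            len(self.discordant),
        )


def consensus_partition(
    calls_by_variant: dict[str, dict[str, str]],
    tools: tuple[str, ...] = TOOLS,
) -> ConsensusPartition:
    """Partition variants by four-tool agreement.

    Every variant lands in exactly one of concordant-benign,
    concordant-pathogenic or discordant; for discordant variants the tool
    that alone called pathogenic (or alone benign) gets its exclusive-call
    counter incremented.
    """
    part = ConsensusPartition(
        exclusive_pathogenic={t: 0 for t in tools},
        exclusive_benign={t: 0 for t in tools},
    )
    for variant_id, calls in calls_by_variant.items():
        values = []
        for t in tools:
            c = calls.get(t)
            if c not in (PATHOGENIC, BENIGN):
                raise ValueError(f"{variant_id}: missing call for {t}")
            values.append(c)
        n_path = values.count(PATHOGENIC)
        if n_path == 0:
            part.concordant_benign.append(variant_id)
        elif n_path == len(tools):
            part.concordant_pathogenic.append(variant_id)
        else:
            part.discordant.append(variant_id)
            if n_path == 1:
                part.exclusive_pathogenic[tools[values.index(PATHOGENIC)]] += 1
            elif n_path == len(tools) - 1:
                part.exclusive_benign[tools[values.index(BENIGN)]] += 1
    return part


def benignity_screen(
    calls: dict[str, str],
    screen_tools: tuple[str, ...] = ("sift", "mutation_taster2"),
) -> bool:
    """True iff every screening tool calls the variant benign.

    High-sensitivity tools that produce no false negatives can be used to
    *exclude* pathogenicity: a variant they unanimously call benign may be
    deprioritized even when pathogenicity cannot be predicted reliably.
    """
    for t in screen_tools:
        if calls.get(t) not in (PATHOGENIC, BENIGN):
            raise ValueError(f"missing call for screen tool {t}")
    return all(calls[t] == BENIGN for t in screen_tools)


def evaluate_schemes(
    truth: dict[str, str],
    calls_by_variant: dict[str, dict[str, str | None]],
    schemes: list[EnsembleScheme] | None = None,
) -> list[dict]:
    """Observed and independence-expected performance for each scheme.

    For every scheme, variants with a missing call from any member tool
    are dropped (and counted); the observed confusion matrix, the
    stand-alone marginals on the same complete-case subset, and the
    independence expectations are computed on what remains.  Returns one
    plain dict per scheme, ready for tabulation.
    """
    if schemes is None:
        schemes = admissible_schemes()
    rows = []
    for scheme in schemes:
        ids = [
            v
            for v, calls in calls_by_variant.items()
            if all(calls.get(t) in (PATHOGENIC, BENIGN) for t in scheme.tools)
        ]
        dropped = len(calls_by_variant) - len(ids)
        truths = [truth[v] for v in ids]
        combined = [
            ensemble_call([calls_by_variant[v][t] for t in scheme.tools], scheme.m)
            for v in ids
        ]
        cm = confusion(truths, combined)
        obs = performance(cm)
        tool_sens, tool_spec = {}, {}
        for t in scheme.tools:
            tool_cm = confusion(truths, [calls_by_variant[v][t] for v in ids])
            tool_perf = performance(tool_cm)
            tool_sens[t] = tool_perf.sens if tool_perf.sens is not None else 0.0
            tool_spec[t] = tool_perf.spec if tool_perf.spec is not None else 0.0
        prevalence = sum(t == PATHOGENIC for t in truths) / len(truths) if ids else 0.0
        exp, exp_report = expected_performance(
            scheme, tool_sens, tool_spec, prevalence=prevalence
        )
        rows.append(
            {
                "scheme": scheme.label,
                "tools": ",".join(scheme.tools),
                "m": scheme.m,
                "n": scheme.n,
                "n_variants": len(ids),
                "n_dropped": dropped,
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "sens": obs.sens,
                "spec": obs.spec,
                "acc": obs.acc,
                "mcc": obs.mcc,
                "expected_sens": exp.expected_sens,
                "expected_spec": exp.expected_spec,
                "expected_acc": exp_report.acc if exp_report else None,
                "expected_mcc": exp_report.mcc if exp_report else None,
            }
        )
    return rows
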