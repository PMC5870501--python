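"""Synthetic classified-variant sets with correlated predictor errors.

Generates variant tables with the statistical structure the evaluation
pipeline assumes — truth classes, products of likelihood ratios, allele
frequencies, family counts, and four predictors' raw outputs — so every
stage runs and is testable without external data.

Tool calls follow a Gaussian copula with a single exchangeable latent
factor: per variant a latent z ~ N(0,1) is drawn, and tool i calls
pathogenic when sqrt(rho)*z + sqrt(1-rho)*e_i exceeds a threshold chosen
so the *marginal* call probability equals the tool's configured
sensitivity (on pathogenic variants) or false-positive rate (on neutral
ones).  The marginals are therefore exact for any correlation rho, while
rho > 0 makes the tools err on the *same* variants — the signature of
predictors that share conservation features.  Raw outputs are rendered in
each tool's native vocabulary so that harmonization recovers the intended
binary call exactly.

Products of LRs are log-normal within each truth direction, which keeps
the analytic prior-independence admission probability in closed form for
test assertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .curation import GENES, VariantRecord
from .harmonize import BENIGN, PATHOGENIC, TOOLS
from .multifactorial import PlonThresholds, PriorConfig, solve_lr_threshold

__all__ = [
    "SyntheticConfig",
    "generate",
    "generate_lr_products",
    "admission_probability",
    "DEFAULT_TOOL_PROFILES",
]

#: Stand-alone (sensitivity, specificity) marginals of the four predictors
#: on a curated BRCA1/2 evaluation set; used as generator defaults.
DEFAULT_TOOL_PROFILES: dict[str, tuple[float, float]] = {
    "align_gvgd": (0.90, 0.92),
    "sift": (1.00, 0.72),
    "mutation_taster2": (1.00, 0.79),
    "polyphen2": (0.67, 0.67),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    Defaults emulate a curated hereditary breast/ovarian-cancer missense
    set: 21 pathogenic vs 140 neutral variants, tool marginals as observed
    for Align-GVGD / SIFT / MutationTaster2 / PolyPhen-2, a mid-range
    inter-tool correlation, log-normal LR products placing ~85% of each
    truth direction beyond the prior-independence thresholds, mostly-absent
    population allele frequencies, and power-law family counts with one
    founder-like pathogenic variant carried by 368 families.
    """

    n_pathogenic: int = 21
    n_neutral: int = 140
    tool_profiles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TOOL_PROFILES)
    )
    correlation: float = 0.5
    # per truth direction: (mu, sigma) of log(Product of LRs)
    lr_pathogenic: tuple[float, float] = (math.log(1e4), 2.5)
    lr_neutral: tuple[float, float] = (math.log(1e-3), 2.5)
    af_unobserved_fraction: float = 0.64
    af_beta: tuple[float, float] = (0.5, 300.0)
    family_zipf_a: float = 2.0
    family_max: int = 368
    founder_count: int = 368
    spliceogenic_fraction: float = 0.02
    expert_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathogenic + self.n_neutral <= 0:
            raise ValueError("need at least one variant")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError(f"correlation must be in [0, 1), got {self.correlation}")
        for tool, (sens, spec) in self.tool_profiles.items():
            if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
                raise ValueError(f"invalid profile for {tool}: ({sens}, {spec})")
        for mu, sigma in (self.lr_pathogenic, self.lr_neutral):
            if sigma <= 0:
                raise ValueError(f"log-LR sigma must be > 0, got {sigma}")


def _call_threshold(p_call: float) -> float:
    # marginal P(call) = p  <=>  latent threshold = Phi^{-1}(1 - p);
    # degenerate marginals clamp to +/-inf so rho cannot perturb them
    if p_call <= 0.0:
        return math.inf
    if p_call >= 1.0:
        return -math.inf
    return norm.ppf(1.0 - p_call)


def generate_lr_products(
    config: SyntheticConfig,
    truth_directions: list[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Log-normal products of LRs consistent with each truth direction."""
    out = np.empty(len(truth_directions))
    for i, direction in enumerate(truth_directions):
        mu, sigma = (
            config.lr_pathogenic if direction == PATHOGENIC else config.lr_neutral
        )
        out[i] = math.exp(rng.normal(mu, sigma))
    return out


def admission_probability(
    config: SyntheticConfig,
    direction: str,
    priors: PriorConfig = PriorConfig(),
    thresholds: PlonThresholds = PlonThresholds(),
) -> float:
    """Closed-form probability that a generated LR is prior-independent.

    For a pathogenic variant this is P(LR > LR_path*) under the configured
    log-normal; for a neutral one P(LR < LR_neut*); the thresholds are
    derived from the posterior model, never hard-coded.
    """
    if direction == PATHOGENIC:
        mu, sigma = config.lr_pathogenic
        bound = solve_lr_threshold(priors.prior_low, thresholds.c4_lower)
        return float(norm.sf((math.log(bound) - mu) / sigma))
    mu, sigma = config.lr_neutral
    bound = solve_lr_threshold(priors.prior_high, thresholds.c2_upper)
    return float(norm.cdf((math.log(bound) - mu) / sigma))


def _render_raw(tool: str, call: str, rng: np.random.Generator) -> dict[str, object]:
    """Raw output in the tool's vocabulary that harmonizes back to ``call``."""
    if tool == "align_gvgd":
        return {"agvgd_class": "C65" if call == PATHOGENIC else "C0"}
    if tool == "sift":
        # scores straddle the 0.05 cut-off to exercise its exact boundary
        if call == PATHOGENIC:
            return {"sift_score": float(rng.uniform(0.0, 0.049))}
        return {"sift_score": float(rng.uniform(0.05, 1.0))}
    if tool == "mutation_taster2":
        return {"mt2_label": "disease causing" if call == PATHOGENIC else "polymorphism"}
    if tool == "polyphen2":
        if call == PATHOGENIC:
            return {
                "pph2_label": str(
                    rng.choice(["possibly damaging", "probably damaging"])
                )
            }
        return {"pph2_label": "benign"}
    raise ValueError(f"unknown tool {tool!r}")


def generate(config: SyntheticConfig) -> list[VariantRecord]:
    """Generate a synthetic classified variant set.

    Deterministic given the config (including its seed): the same config
    always yields a byte-identical table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pathogenic + config.n_neutral
    directions = [PATHOGENIC] * config.n_pathogenic + [BENIGN] * config.n_neutral

    genes = rng.choice(GENES, size=n, p=[0.55, 0.45])
    truth_classes = np.where(
        np.array(directions) == PATHOGENIC,
        np.where(rng.random(n) < 0.7, 5, 4),
        np.where(rng.random(n) < 0.5, 1, 2),
    )
    lrs = generate_lr_products(config, directions, rng)

    # Gaussian-copula tool calls: exchangeable latent factor per variant
    rho = config.correlation
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(TOOLS)))
    latent = math.sqrt(rho) * z[:, None] + math.sqrt(1.0 - rho) * eps
    calls = np.empty((n, len(TOOLS)), dtype=object)
    for j, tool in enumerate(TOOLS):
        sens, spec = config.tool_profiles[tool]
        for i in range(n):
            p_call = sens if directions[i] == PATHOGENIC else 1.0 - spec
            calls[i, j] = (
                PATHOGENIC if latent[i, j] > _call_threshold(p_call) else BENIGN
            )

    unobserved = rng.random(n) < config.af_unobserved_fraction
    afs = rng.beta(*config.af_beta, size=(n, 6))
    af_pops = ("afr", "eas", "sas", "fin", "nfe", "amr")
    spliceogenic = rng.random(n) < config.spliceogenic_fraction
    expert = rng.random(n) < config.expert_fraction
    families = np.minimum(rng.zipf(config.family_zipf_a, size=n), config.family_max)

    records = []
    founder_assigned = False
    for i in range(n):
        raw: dict[str, object] = {}
        for j, tool in enumerate(TOOLS):
            raw.update(_render_raw(tool, calls[i, j], rng))
        family_count = int(families[i])
        if directions[i] == PATHOGENIC and not founder_assigned:
            family_count = config.founder_count  # founder-like skew
            founder_assigned = True
        pop_afs = (
            {}
            if unobserved[i]
            else {p: float(afs[i, k]) for k, p in enumerate(af_pops)}
        )
        records.append(
            VariantRecord(
                variant_id=f"{genes[i]}:snv{i:05d}",
                gene=str(genes[i]),
                truth_class=int(truth_classes[i]),
                product_of_lrs=float(lrs[i]),
                population_afs=pop_afs,
                spliceogenic=bool(spliceogenic[i]),
                expert_override=bool(expert[i]),
                family_count=family_count,
                raw_calls=raw,
            )
        )
    return records


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Convenience: same study conditions, different random seed."""
    return replace(config, seed=seed)
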