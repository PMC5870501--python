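"""Multifactorial likelihood model for variant classification.

The multifactorial model combines a prior probability of pathogenicity
(derived from in silico missense prediction) with a product of likelihood
ratios (LRs) from segregation, co-occurrence, family-history and pathology
evidence.  Posterior odds are ``LR x prior/(1-prior)`` and the posterior
probability is ``odds/(odds+1)``; the posterior is mapped onto the standard
five-tier classification (1 benign ... 5 pathogenic) via fixed posterior
thresholds.

Because the prior itself comes from a missense predictor (Align-GVGD in
routine BRCA1/2 classification), benchmarking predictors against
multifactorially classified variants is circular.  The model can however be
inverted: for a given posterior boundary the required product of LRs is a
closed-form function of the prior, so a variant whose LR product is extreme
enough to land in the same class under both the lowest (0.03) and highest
(0.81) missense priors is classified *independently* of any prediction.
:func:`prior_independence` implements that screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PriorConfig",
    "PlonThresholds",
    "PosteriorResult",
    "posterior_probability",
    "solve_lr_threshold",
    "assign_plon_class",
    "prior_independence",
    "classify_variant",
    "INDEPENDENT_PATHOGENIC",
    "INDEPENDENT_NEUTRAL",
    "PRIOR_DEPENDENT",
]

INDEPENDENT_PATHOGENIC = "independent_pathogenic"
INDEPENDENT_NEUTRAL = "independent_neutral"
PRIOR_DEPENDENT = "prior_dependent"


def _check_probability(name: str, value: float) -> None:
    if not (0.0 < value < 1.0) or not math.isfinite(value):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value!r}")


@dataclass(frozen=True)
class PriorConfig:
    """Extreme missense-prediction priors.

    ``prior_low`` is the prior assigned to the least-damaging prediction
    (Align-GVGD class C0), ``prior_high`` to the most-damaging one (C65).
    Only the two extremes are needed for the prior-independence screen; a
    full class-to-prior map may be layered on top by callers.
    """

    prior_low: float = 0.03
    prior_high: float = 0.81

    def __post_init__(self) -> None:
        _check_probability("prior_low", self.prior_low)
        _check_probability("prior_high", self.prior_high)
        if not self.prior_low < self.prior_high:
            raise ValueError(
                f"prior_low ({self.prior_low}) must be < prior_high ({self.prior_high})"
            )


@dataclass(frozen=True)
class PlonThresholds:
    """Posterior-probability boundaries of the five-tier classification.

    Class 1 below ``c1_upper``; class 2 in [c1_upper, c2_upper); class 3
    (uncertain) in [c2_upper, c4_lower); class 4 in [c4_lower, c5_lower];
    class 5 above ``c5_lower``.  Boundary conventions are configurable only
    through the threshold values themselves; the half-open/closed choices
    reproduce the standard derived LR cut-offs (e.g. 614.33 at prior 0.03).
    """

    c1_upper: float = 0.001
    c2_upper: float = 0.05
    c4_lower: float = 0.95
    c5_lower: float = 0.99

    def __post_init__(self) -> None:
        vals = (self.c1_upper, self.c2_upper, self.c4_lower, self.c5_lower)
        for name, v in zip(("c1_upper", "c2_upper", "c4_lower", "c5_lower"), vals):
            _check_probability(name, v)
        if not (vals[0] < vals[1] < vals[2] < vals[3]):
            raise ValueError(f"thresholds must be strictly increasing, got {vals}")


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior classification of a single variant."""

    prior_p: float
    product_of_lrs: float
    posterior_odds: float
    posterior_p: float
    plon_class: int


def posterior_probability(prior_p: float, product_of_lrs: float) -> float:
    """Posterior probability of pathogenicity.

    Parameters
    ----------
    prior_p
        Prior probability of pathogenicity, strictly in (0, 1).
    product_of_lrs
        Combined likelihood ratio from prior-independent evidence
        (segregation, co-occurrence, family history, pathology); must be
        finite and > 0.

    Returns
    -------
    float
        ``odds/(odds+1)`` with ``odds = product_of_lrs * prior_p/(1-prior_p)``,
        strictly in (0, 1) and strictly increasing in both arguments.
    """
    _check_probability("prior_p", prior_p)
    if not (product_of_lrs > 0.0) or not math.isfinite(product_of_lrs):
        raise ValueError(
            f"product_of_lrs must be a finite positive real, got {product_of_lrs!r}"
        )
    odds = product_of_lrs * prior_p / (1.0 - prior_p)
    return odds / (odds + 1.0)


def solve_lr_threshold(
    prior_p: float, posterior_target: float, *, method: str = "closed_form"
) -> float:
    """Product of LRs that maps ``prior_p`` onto ``posterior_target``.

    Inverts the posterior relation.  The closed form is

        LR* = (t/(1-t)) * ((1-p)/p)

    for target ``t`` and prior ``p``.  ``method="bisection"`` solves the
    same equation numerically on the log-LR axis and exists as an
    independent cross-check of the closed form.
    """
    _check_probability("prior_p", prior_p)
    _check_probability("posterior_target", posterior_target)
    if method == "closed_form":
        return (posterior_target / (1.0 - posterior_target)) * (
            (1.0 - prior_p) / prior_p
        )
    if method == "bisection":
        return _bisect_lr(prior_p, posterior_target)
    raise ValueError(f"unknown method {method!r}")


def _bisect_lr(prior_p: float, target: float, tol: float = 1e-13) -> float:
    # posterior is monotone in log-LR; bracket generously then bisect
    lo, hi = -80.0, 80.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if posterior_probability(prior_p, math.exp(mid)) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return math.exp(0.5 * (lo + hi))


def assign_plon_class(
    posterior_p: float, thresholds: PlonThresholds = PlonThresholds()
) -> int:
    """Five-tier class (1..5) for a posterior probability."""
    _check_probability("posterior_p", posterior_p)
    t = thresholds
    if posterior_p < t.c1_upper:
        return 1
    if posterior_p < t.c2_upper:
        return 2
    if posterior_p < t.c4_lower:
        return 3
    if posterior_p <= t.c5_lower:
        return 4
    return 5


def prior_independence(
    product_of_lrs: float,
    priors: PriorConfig = PriorConfig(),
    thresholds: PlonThresholds = PlonThresholds(),
) -> str:
    """Classify an LR product as prior-independent or not.

    A variant is ``independent_pathogenic`` when even the *lowest* missense
    prior pushes its posterior to the likely-pathogenic boundary, and
    ``independent_neutral`` when even the *highest* prior leaves it below
    the likely-benign boundary.  Everything else is ``prior_dependent`` —
    its five-tier class changes with the in silico prior, so it cannot be
    used to benchmark the predictors that feed that prior.
    """
    if posterior_probability(priors.prior_low, product_of_lrs) >= thresholds.c4_lower:
        return INDEPENDENT_PATHOGENIC
    if posterior_probability(priors.prior_high, product_of_lrs) < thresholds.c2_upper:
        return INDEPENDENT_NEUTRAL
    return PRIOR_DEPENDENT


def classify_variant(
    prior_p: float,
    product_of_lrs: float,
    thresholds: PlonThresholds = PlonThresholds(),
) -> PosteriorResult:
    """Full posterior classification bundle for one variant."""
    posterior = posterior_probability(prior_p, product_of_lrs)
    odds = product_of_lrs * prior_p / (1.0 - prior_p)
    return PosteriorResult(
        prior_p=prior_p,
        product_of_lrs=product_of_lrs,
        posterior_odds=odds,
        posterior_p=posterior,
        plon_class=assign_plon_class(posterior, thresholds),
    )
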