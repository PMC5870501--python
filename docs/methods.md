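# Methods

## Posterior model and prior-independence screen

A variant's posterior probability of pathogenicity combines a prior
*p* (from in silico missense prediction) with a product of likelihood
ratios *L* (segregation, co-occurrence, family history, pathology — all
independent of missense prediction):

    odds = L · p/(1−p),   posterior = odds/(odds+1).

Five-tier classes follow fixed posterior boundaries (defaults 0.001,
0.05, 0.95, 0.99). Boundary conventions, which the five-tier scheme
itself leaves open, are: class 1 strictly below 0.001; class 2 half-open
[0.001, 0.05); class 3 [0.05, 0.95); class 4 closed [0.95, 0.99]; class
5 strictly above 0.99. This choice makes the derived pathogenic LR
cut-off at prior 0.03 exactly (0.95/0.05)·(0.97/0.03) = 614.33, the
value used in practice. All four boundaries are configurable.

Inverting the model gives the closed form
`L* = (t/(1−t))·((1−p)/p)`; a bisection solver over log-L exists purely
as an independent numerical cross-check (they agree to 1e−9 across a
prior/target grid; the closed form is authoritative). A variant is
**prior-independent pathogenic** when even the lowest prior (0.03, the
least-damaging missense prediction) puts its posterior at or above the
likely-pathogenic boundary, and **prior-independent neutral** when even
the highest prior (0.81) leaves it strictly below the likely-benign
boundary. The ≥ / < conventions mirror the class-4 closed and class-2
half-open boundaries. The likely-neutral cut-off is exactly
(0.05/0.95)·(0.19/0.81) = 0.012346; report tables conventionally print
it rounded to 0.01, so a display-rounding helper (round half up)
reproduces that — the exact value is never replaced by the rounded one
in logic. The class-2 upper boundary is taken as 0.05 (not 0.049; both
round to the same printed cut-off) and is configurable. Only the two
extreme priors are defaulted; intermediate Align-GVGD-class priors can
be supplied by callers but are not needed for the screen.

## Curation

The classified set keeps variants with a definite class (1/2/4/5), a
maximum per-cohort allele frequency < 0.01 and no known spliceogenic
effect. The AF rule uses the *maximum* over the six ancestry cohorts
(African, East Asian, South Asian, Finnish, non-Finnish European,
Latino): any single cohort at ≥ 1% disqualifies, the conservative
reading of the frequency-implies-benign rule. Variants absent from the
reference panel count as frequency zero. Exclusion reasons are logged in
filter order (class, AF, splice, prior-dependence); admission itself is
a conjunction and therefore order-insensitive.

The evaluation set admits classified variants that are prior-independent
or expert-panel classified (`expert_override`). An admitted LR direction
contradicting the truth class (e.g. an "independent pathogenic" LR on a
class-1 variant) indicates corrupted input and raises an integrity error
naming the variant rather than silently dropping it. Truth is binarized
as classes 4/5 → pathogenic, 1/2 → neutral.

Published counts for the real data set are internally divergent in the
source material (e.g. 161 vs 166 evaluation variants, 21 vs 25
pathogenic). The package takes no side: `set_composition` reports what
it counts, and nothing reconciles divergent counts silently.

## Harmonization

Binary cut-offs follow routine diagnostic usage: Align-GVGD pathogenic
at grade C ≥ 35 (boundary inclusive); SIFT pathogenic strictly below
score 0.05 (0.05 itself is tolerated) or label AFFECT PROTEIN FUNCTION;
MutationTaster2 pathogenic iff "disease causing"; PolyPhen-2 pathogenic
for possibly or probably damaging. Labels are matched after lowercasing
and collapsing whitespace/underscores; anything outside a tool's
vocabulary raises. Missing raw output harmonizes to a missing call and
the variant is excluded from that tool's confusion matrix
(pairwise-complete evaluation) — that policy is ours; ensembles instead
require complete calls and drop incomplete variants with a logged count.

## Metrics

SENS = TP/(TP+FN), SPEC = TN/(FP+TN), ACC = (TP+TN)/total, and the
Matthews correlation coefficient. Degenerate cases: a statistic with an
empty denominator is reported as undefined (None); a zero MCC marginal
yields MCC = 0 with a flag. Display rounding is half-up at two decimals
to match how such tables are printed (0.90476 → 0.90). Note the MCC
values printed for PolyPhen-2 (0.39) and Align-GVGD (0.73) in the
original report are not reproducible from any confusion matrix
consistent with its printed counts — direct evaluation gives 0.2355 and
0.7146; the formula is authoritative here and the discrepancy is
documented, not patched. Family-weighted impact counts sum, over
false-negative and false-positive variants separately, the number of
index families carrying each variant, since a single missed founder
mutation can affect hundreds of families.

## Ensembles and the independence expectation

An m-of-n scheme calls pathogenic when at least m of n tools do.
Admissible schemes satisfy m ≥ n/2 with the unanimous pair (m=2, n=2)
excluded; as m=2 is the only majority option at n=2, no two-tool scheme
exists and n ranges over {3, 4} (11 schemes for four tools).

Under the best-case assumption that tools err independently with fixed
marginals, the number of pathogenic votes is Poisson-binomial: expected
combined sensitivity is P(X ≥ m) with per-tool sensitivities as success
probabilities, and expected specificity is P(Y < m) with per-tool
false-positive rates. The pmf is computed by iterative convolution,
exact for any n (verified against brute-force 2ⁿ enumeration and, as an
independent cross-check, scipy's Poisson-binomial distribution). This is
the unique distribution consistent with independent predictions and
fixed marginals. Expected ACC and MCC are *derived* from the expected
confusion-cell fractions at the observed prevalence — a construction
layered on the vote-count model, flagged as such in the API.

## Synthetic data generator

The generator emulates a curated classified variant set so the full
pipeline runs with no download. Defaults are the study conditions:

- class balance 21 pathogenic / 140 neutral;
- tool profiles (sens, spec): Align-GVGD (0.90, 0.92), SIFT (1.00,
  0.72), MutationTaster2 (1.00, 0.79), PolyPhen-2 (0.67, 0.67) — the
  stand-alone marginals derivable from the published evaluation counts;
- inter-tool correlation ρ = 0.5, a mid-range loading reflecting that
  all four tools lean on the same conservation signal;
- log-normal LR products, log-mean ln(10⁴) (pathogenic) and ln(10⁻³)
  (neutral) with σ = 2.5, placing ≈ 85% of each direction beyond the
  prior-independence cut-offs (comparable to the real set's 151/226)
  while keeping cross-threshold contamination — which would trigger the
  curation integrity error — at negligible probability (< 10⁻⁷ per
  draw);
- 64% of variants unobserved in the frequency panel (AF 0), observed
  AFs Beta(0.5, 300); 2% spliceogenic, 4% expert-classified;
- Zipf(2) family counts capped at 368, with one pathogenic founder-like
  variant assigned 368 families to exercise the impact weighting.

Calls use a single-factor Gaussian copula: per variant z ~ N(0,1), tool
i calls pathogenic iff √ρ·z + √(1−ρ)·εᵢ exceeds Φ⁻¹(1 − pᵢ), where pᵢ
is the tool's sensitivity (pathogenic variants) or false-positive rate
(neutral). Marginals are therefore exact for every ρ (degenerate 0/1
marginals clamp the threshold to ±∞), while ρ > 0 concentrates errors on
the same variants. One exchangeable ρ rather than a full correlation
matrix: a single knob reproduces the qualitative observed-vs-expected
specificity gap, and a full matrix could be added without interface
change. Raw outputs are rendered in each tool's vocabulary (grades C65/
C0, SIFT scores drawn from [0, 0.049] / [0.05, 1] to straddle the exact
cut-off, verbatim labels) so harmonization recovers the intended call
exactly.

What the generator does *not* emulate: real conservation structure
(errors cluster by copula, not by protein domain), per-gene performance
differences, batch effects between data sources, and any relationship
between allele frequency and pathogenicity beyond the curation filter.
Passing tests on synthetic data therefore demonstrate correctness of the
pipeline's computations and calibration of its statistical machinery,
not the real-world performance of any predictor.

## Problem sizes and numerical choices

Property tests use 10⁴ variants per class for marginal-calibration
checks (3 Monte-Carlo standard errors ≈ 0.009 at p = 0.9) and 20 seeds ×
2,100 variants for the correlated-specificity sign test; both finish in
seconds and keep the full suite under a minute. The independence model
is exact, so its oracle test uses 10³ random probability vectors at
atol 10⁻¹². Bisection runs on the log-LR axis over [−80, 80], 200
iterations, tolerance 10⁻¹³. TSV floats are written with `repr` (the
shortest round-tripping decimal), so write→read is lossless.

## Known limitations

- The evaluation consumes predictor outputs; it never runs Align-GVGD,
  SIFT, MutationTaster2 or PolyPhen-2, computes LR products from family
  data, or fetches population frequencies.
- Pairwise-complete handling of missing calls can make per-tool metrics
  non-comparable across tools when missingness is informative.
- Expected ACC/MCC under independence are our derived construction (see
  above), not part of the vote-count model proper.
- The generator's single-ρ copula cannot represent tool *pairs* that are
  more correlated than others.
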