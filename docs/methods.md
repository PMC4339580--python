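# Methods

## Design and model

The pipeline targets a 2×2 factorial RNA-seq experiment: genotype (wild-type
W vs myostatin-reduced M) crossed with physical activity (inactive I vs
active A), four groups IW, AW, IM, AM with n = 3 replicates each. On the log₂
scale the group means of a gene are modeled as

```
mu_IW = b          mu_AW = b + a
mu_IM = b + g      mu_AM = b + a + g + delta
```

with `b` the baseline, `a` and `g` the marginal activity and genotype
effects, and `delta` the interaction — the deviation of the combined
condition from additivity. With `c = mu_AM - mu_IW` the combined effect and
`s = a + g` the additive prediction, `delta = c - s`. A significant
interaction is called *synergistic* when the combination is more extreme than
the additive prediction in a consistent direction (|c| > |s| and c·s > 0, or
|s| < ε so any combined effect is super-additive) and *antagonistic* when it
is weaker than or opposed to the prediction (|c| < |s|, or c·s < 0 with
|s| ≥ ε). ε defaults to 0.1 log₂ units; it exists only to stabilize the sign
comparison when the additive prediction is essentially zero, where "same
sign as s" is numerically meaningless. The boundary case |c| = |s| with
consistent signs is measure-zero and returns "none".

The interaction is also defined verbally in the literature as "more extreme
than the average of the single factors" — a non-equivalent statement; this
package implements the sum form with the ε branch, which is the version that
makes `delta` the natural test statistic.

## Statistical testing

Counts are normalized so that the trimmed column mean — dropping
`floor(0.05·n)` values from each end of the sorted column, by count rank, with
zeros participating — of the **non-mitochondrial** genes is equal across
samples. The common target is the across-sample mean of the per-sample
trimmed means; no reference sample is privileged. Mitochondrially encoded
transcripts (13 protein-coding genes in mouse) are orders of magnitude more
abundant than nuclear transcripts, so they are excluded from the factor
computation but scaled by the resulting factors. A consequence of the
symmetric target is that rescaling one input column rescales every factor
through the target; the normalized matrix is invariant only up to that single
global constant, and the property tests assert exactly that form.

Differential expression uses Welch's unequal-variance t on
log₂(normalized value + pseudocount), pseudocount 1 by default. This is a
deliberate, oracle-checkable substitute for the isoform-deconvolving
negative-binomial machinery used in the original processing chain
(Cuffdiff); it is exact, deterministic, and honest about what the repository
computes, at the cost of less power at n = 3. Degenerate zero-variance cases
are resolved deterministically (equal means → p = 1, unequal → p = 0) so
noise-free fixtures behave reproducibly. The interaction statistic is
`delta` divided by `sqrt(Σ s²_g/n_g)` over the four groups with a
Welch–Satterthwaite df. Fold changes are computed on group means of the
linear normalized scale (pseudocount-stabilized), matching the mean-ratio
convention `contrast "A-B" = log2(mean_B/mean_A)`; test statistics use the
log scale.

FDR control is Benjamini–Hochberg throughout (within each contrast; across
genes for the interaction; across reported terms for enrichment), delegated
to statsmodels behind the `bh_adjust` surface and verified against a naive
quadratic-time step-up oracle.

Main effects pool {IW, AW} vs {IM, AM} (genotype, reported as log₂ MR/WT)
and {IW, IM} vs {AW, AM} (activity, log₂ active/inactive). Genes whose
interaction q falls below the exclusion threshold (default 0.005) keep their
statistics but are flagged and omitted from reported main-effect gene lists,
since their marginal effects are not interpretable. The headline DE filter
is q ≤ 0.005 and |log₂FC| ≥ 1.3 with **inclusive** boundaries — the published
genotype list itself contains a gene at exactly 1.30.

## Profiles

Each of the six pairwise contrasts is discretized into a trit: +1 if raw
P < 10⁻⁴ and lfc > 0, −1 if P < 10⁻⁴ and lfc < 0, else 0 (alternative
thresholds — raw P < 5·10⁻⁵ or FDR-adjusted P < 0.05 — are configurable; the
literature states all three in different places). The canonical position
order is (AM-AW, AM-IM, AW-IM, IW-IM, IW-AW, IW-AM). Codes are tabulated
into clusters with a minimum reported size (default 50; clusters above 100
genes are passed to enrichment), sorted by descending size with lexicographic
tie-breaks for determinism.

## Enrichment

The EASE score of a term with k list hits among a list of n genes, K
background hits and universe N is the hypergeometric upper tail
P(X ≥ k − 1) — the Fisher exact P after removing one hit, DAVID's documented
convention; k ≤ 1 scores exactly 1, which is the point of the penalization.
Terms are clustered greedily by Cohen's kappa of their membership vectors
over the background (threshold 0.35, seed size 3, merge overlap 0.5 —
DAVID-like defaults, since the published analysis does not state its
clustering parameters), merging groups to a fixed point in lexicographic
order. A cluster's enrichment score is the mean of −log₁₀ of its members'
EASE P-values, identical to −log₁₀ of their geometric mean; scores are
reported to 2 decimals with full precision retained internally.

Gene sets arrive as standard GMT files; the background universe defaults to
the union of all members unless supplied explicitly. No external annotation
service is queried.

## Synthetic data

The simulator draws baseline log₂ means uniformly from a configurable range
(default 5–11, i.e. mean counts ~32–2048), assigns effect classes by
largest-remainder apportionment of the configured proportions (default 70%
null and 6% for each of the five effect classes), and plants marginal
effects of ±2 log₂ units with random signs; synergistic and antagonistic
genes get concordant margins and an interaction of magnitude 2 aligned with
or opposed to their sum. Counts are negative-binomial via a gamma–Poisson
mixture with variance μ + φμ² (φ = 0.05 by default, degenerating to Poisson
at φ = 0). The first 13 genes are flagged mitochondrial, forced to null, and
boosted ~10× above baseline to exercise the separate mito-normalization
path. Baselines are quantized to 1/1024 log₂ units so the planted group
means, and hence `delta`, are exactly representable and exactly recoverable
from the truth table in double precision. Per-gene random streams derive
from (seed, gene index), so outputs are byte-reproducible and independent of
gene count.

What the simulator does **not** emulate: read-level noise, isoform mixtures,
gene-length bias, library-size confounding beyond per-sample scale factors,
and mean–dispersion trends. Passing tests therefore demonstrate the
correctness and calibration of the inference chain under the stated count
model, not performance on real RNA-seq libraries.

## Problem sizes and calibration

The test and acceptance simulations use 2,000 genes at a fixed baseline of
2⁹ = 512 counts, φ = 0.05, n = 3 per group — sizes chosen so every check runs
comfortably on a laptop while leaving Monte-Carlo error well inside the
asserted bands. Under the all-null configuration the raw P < 0.05 fraction
is asserted to lie in 0.05 ± 0.03 per test; the observed fractions run
slightly conservative (~0.03–0.04), as expected for t-tests on log counts at
these group sizes. Among planted interaction genes reaching q < 0.05, the
mode classifier recovers the planted synergistic/antagonistic label for
essentially all genes (the asserted bound is ≥ 80%).

A known power limitation: with Welch tests at n = 3 and BH over thousands of
genes, the strict q < 0.005 interaction threshold is rarely attainable on
desk-scale simulations; genome-scale counts at that threshold in the original
study reflect a more powerful test on real data and are not reproducible
here. The worked example and the recovery checks therefore operate at
q < 0.05, with the strict threshold remaining the configurable default.

## Numerical and design choices

- Trim rule: count-rank trimming (`floor(0.05·n)` per end), not value
  percentiles — deterministic under ties.
- Pseudocount 1 before the log transform; fold changes from linear-scale
  group means, tests on the log scale.
- Kappa of two empty membership vectors is defined as 1 (identical vectors);
  degenerate marginals with observed agreement 1 likewise return 1.
- Deterministic orderings everywhere results are emitted: contrasts in
  canonical order, DE lists by descending |lfc| then gene id, enrichment by
  ascending EASE P then term id, profile clusters by size then code,
  term clusters by score then membership.
- The pipeline manifest echoes the full configuration, package version and
  per-stage counts; two runs from the same configuration produce
  byte-identical outputs (no timestamps are written).
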