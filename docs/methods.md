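# Methods

## Scope and model

The package tests gene sets for coordinated transcriptional change in a
two-group RNA-Seq comparison, treating a gene's signal as the combination
of two components measured on read counts:

- **Differential expression (DE)** on gene-level totals
  `Y_j = sum_i X_ij`, modelled `Y_j ~ NB(mu_j, mu_j + phi*mu_j^2)` with
  `mu_j = s_j * q_{rho(j)}`: a per-sample size factor `s_j` (sequencing
  depth) times a per-group expression level `q`.
- **Differential splicing (DS)** on sub-exon read-count fractions given
  the totals. Sub-exons are the disjoint fragments obtained by splitting
  all of a gene's annotated exons at every distinct exon start/end, so
  any annotated splice boundary (including alternative 3'/5' sites)
  begins a new fragment. Fractions are invariant to overall abundance, so
  DS is orthogonal to DE by construction.

Both scores are squared parameter differences over summed variance
estimates, hence non-negative; the direction of expression change is
deliberately discarded so that inversely regulated genes in the same
pathway reinforce rather than cancel.

## Estimation

**Size factors** are DESeq-style median-of-ratios on gene totals,
computed once from the observed data and held fixed across label
permutations (they are sample properties, independent of the grouping).
A pseudo-reference fallback (`counts + 1` geometric mean) is available
for data with no gene expressed in every sample.

**Per-group expression.** Within each group (m >= 2 samples),
`q_hat = mean(Y_j / s_j)`; dispersion by per-gene method of moments on
normalized counts, `phi_hat = max(0, (v_emp - q_hat*mean(1/s)) / q_hat^2)`,
with no trend shrinkage — each group is estimated independently, matching
the requirement that permutation designs carry replicates per group.
`V(q_hat) = (1/m^2) * sum_j (q_hat/s_j + phi_hat*q_hat^2)` propagates the
NB variance. Genes at zero in both groups score 0; all score denominators
carry an additive stabilizer of 1e-8 against exact-zero variances.

**Sub-exon fractions.** Within each group, `p_hat_i` is the pooled
fraction `sum_j X_ij / sum_j Y_j` over samples with `Y_j > 0` (samples
with zero totals are dropped, not imputed; a gene with zero totals in
every sample of a group is flagged DS-undefined and scores 0). The
variance is `max` of two components:

1. the delta-method variance of the pooled ratio given the observed
   totals, which reduces to the multinomial floor `p(1-p)/sum(Y)` —
   count-level overdispersion of the *totals* cancels exactly in a
   fraction, so propagating it would inflate the denominator in a
   depth-dependent way and bias DS scores wherever the two groups differ
   in depth (e.g. for strongly DE genes);
2. the empirical between-sample variance of the per-sample fractions
   divided by the number of contributing samples, which captures genuine
   splicing overdispersion between replicates.

Taking the larger of the two keeps the score's denominator honest in both
the sampling-noise-dominated and the biological-variability-dominated
regimes. Genes with one usable sub-exon carry no splicing information and
score 0 (flagged). Sub-exons failing the low-count filter are excluded
from both the numerator and the `1/N` divisor of the DS average, while
gene totals always keep all reads.

## Normalization and integration

DE and DS scores live on incomparable scales. Scores are computed on the
observed labelling and on `n_perm` class-label shuffles (group sizes
preserved; when the design admits fewer distinct assignments than
requested, all are enumerated with a warning; small designs are sampled
without replacement). Each gene's observed and permuted scores are then
divided by that gene's mean permutation score, after which every gene's
permutation scores average exactly 1. Genes whose permutation mean is 0
are pinned at 0 and retained, so gene-set sizes do not change across
weights.

Two integration strategies at weight `alpha` in `[0, 1]`:

- **Linear**: `S = alpha*S_DE,norm + (1-alpha)*S_DS,norm`.
- **Rank-based**: ascending mid-ranks `g_DE`, `g_DS` over the gene list;
  `S = (alpha*g_DE*S_DE + (1-alpha)*g_DS*S_DS) / (alpha*g_DE + (1-alpha)*g_DS)`,
  so the better-ranked of a gene's two signals dominates. Permutation
  columns either reuse the observed ranks (RankGlb) or recompute ranks
  per column (RankSp). At `alpha` in {0, 1} both strategies return the
  single-score vectors exactly (implemented as a short-circuit; the
  algebraic round trip leaves 1-ulp residue). Higher-order weighted
  combinations are not offered: they add parameters without changing the
  behaviour of interest.

Note a genuine property of the rank-based form: raising a gene's DE score
can raise its DE rank and thereby shift weight toward the *smaller* of
its two normalized scores, so the integrated score is not globally
monotone in either input (it is at fixed ranks, and for the linear
strategy always).

## Enrichment testing

Genes are sorted by descending integrated score (stable on ties). The
running sum gains `|S|^w / N_R` at member genes (`N_R` = total member
weight) and loses `1/(G - G_hit)` at non-members; the enrichment score
(ES) is the maximum of the running sum — one-sided, since scores carry no
sign. The weight exponent defaults to `w = 1` (score-weighted statistic)
and `w = 0` gives the classic unweighted form. A set whose members all
score 0 gets ES 0.

The same label shuffles and the same raw DE/DS permutation scores back
every (strategy, alpha) cell, so the full pipeline — group estimation,
scoring, normalization, integration, ES — is recomputed per permutation
and differences across the grid reflect the integration weight alone.
Per set:

- `p_emp = (1 + #{perm ES >= obs ES}) / (n_perm + 1)` (add-one estimator,
  bounded below by `1/(n_perm+1)`);
- `NES = ES / mean(positive permutation ES of the set)`; permutation ES
  are normalized the same way (sets with no positive permutation ES are
  flagged NES-undefined);
- `FDR(set) = [fraction of pooled permutation NES >= NES(set)] /
  [fraction of observed NES >= NES(set)]`, clipped to [0, 1], then
  monotonized q-value-style (each set reports the minimum raw FDR over
  sets with NES at or below its own) so FDR is non-increasing in NES.

Default gene-set size bounds after intersection with scored genes are
[5, 1000]; `n_perm` defaults to 1,000.

**Weight scan and saturation.** The default grid is the 11 weights
0, 0.1, ..., 1. The saturation analysis adds weights in the order
(1, 0, 0.5, 0.1, 0.9, 0.3, 0.7, 0.2, 0.4, 0.6, 0.8) — the two degenerate
extremes first, then filling inward — and reports the cumulative count of
unique significant sets, a non-decreasing curve whose plateau indicates
how many weights suffice.

## Synthetic data

The generator emulates exactly the structure the model assumes: per-gene
Dirichlet sub-exon proportions (concentration 5, i.e. moderately even
usage); per-sample gene totals NB with mean `s_j * q` and a common
dispersion `phi`; sub-exon counts multinomially thinned from the totals,
so `Y = sum(X)` holds exactly and expression truth is separated from
splicing truth. DE is planted by fold-changing `q` in group B (direction
randomized); DS by moving a fixed amount of proportion mass between two
randomly chosen sub-exons in group B, which leaves totals untouched.
Gene sets are drawn from the DE-only / DS-only / mixed / null gene pools
(planted sets take 80% of members from their effect pool by default) plus
fully null sets.

Defaults describe a moderate human-cohort design: 1,000 genes with 1–8
sub-exons, 5 vs 5 samples, log-normal baseline expression
(`exp(N(5, 1))`, a few hundred reads per gene), `phi = 0.1`, size factors
in [0.7, 1.4], 5% DE genes at 4-fold, 5% DS genes at a 0.3 proportion
shift. What the generator does *not* emulate: positional/GC bias,
correlated genes, read-level effects, annotation errors, or gene-specific
dispersions tied to expression level — so passing tests demonstrate the
statistics behave as designed under the assumed model, not robustness to
real-data artefacts.

`empirical_moments` / `fit_dispersion` validate the generator: pooled
within-group variance of normalized counts regressed (through the
origin) of `var - mean` on `mean^2` recovers `phi`.

## Numerical and design choices

- Coordinates: GTF 1-based closed on input, 0-based half-open internally;
  outputs state the convention. Overlapping genes are flattened
  independently (shared territory appears in both models); strand is
  recorded but irrelevant to boundary arithmetic. Genes annotated on
  several chromosome/strand loci are split (id-suffixed) or rejected, per
  option.
- Expression filters default to >= 10 reads per gene and >= 5 per
  sub-exon summed over samples; NB moment estimation is unstable on
  near-zero rows. Both are configurable; filters never alter gene totals.
- Rank ties use mid-ranks; sorting for ES uses a stable order so runs are
  deterministic. A single seed drives every random draw; identical
  configuration and seed reproduce all output tables byte-for-byte.
- Analysis scales used by the test suite and the acceptance script —
  1,000 genes, 5 vs 5, 200 permutations, up to 200 gene sets — are the
  package's standard desk-scale study conditions; they complete in
  seconds while leaving the permutation null dense enough for FDR
  estimation at 0.05.

## Known limitations

Two-group designs only (no covariates, batch terms or paired samples);
no read counting from BAM (counts are taken as input); no shrinkage of
dispersions across genes, which costs power at very small replicate
numbers; permutation p-values are bounded below by `1/(n_perm+1)`, so
very small FDRs require large `n_perm`; leading-edge gene reporting is
not implemented.
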