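# seqgsea

Integrated gene set enrichment analysis for two-group RNA-Seq count data
that scores each gene for **differential expression** (DE, changes in
overall transcript abundance) *and* **differential splicing** (DS, changes
in how reads distribute over a gene's sub-exons), combines the two signals
at a tunable weight, and tests gene sets with a permutation-calibrated,
Kolmogorov–Smirnov-style enrichment statistic.

The motivating observation: in disease transcriptomes a pathway can be
perturbed through abundance changes in some member genes and splicing
changes in others. An expression-only enrichment analysis misses the
splicing-driven sets, a splicing-only analysis misses the expression-driven
ones; scanning a grid of integration weights and taking the union recovers
both.

## Model

Gene-level counts are modelled as negative binomial,
`Y_j ~ NB(mu_j, sigma_j^2)` with `mu_j = s_j * q_rho(j)` (size factor ×
group-level expression) and `sigma^2 = mu + phi * mu^2`. Per gene:

- **DE score** `S_DE = (q_A - q_B)^2 / (V(q_A) + V(q_B))`, with group means
  and variances estimated separately per group (no information sharing).
- **DS score** `S_DS = (1/N) * sum_i (p_iA - p_iB)^2 / (V(p_iA) + V(p_iB))`
  over the gene's `N` sub-exons, where `p_i` is the expected read-count
  fraction of sub-exon `i`.
- Scores on observed and label-permuted data are normalized by each gene's
  mean permutation score, then combined at weight `alpha` in `[0, 1]`
  either linearly, `S = alpha*S_DE + (1-alpha)*S_DS`, or by an ascending
  rank-weighted average (variants reusing observed ranks or recomputing
  them per permutation).
- Gene sets are scored with a weighted running-sum enrichment statistic;
  class-label permutations give empirical p-values, normalized ES and a
  pooled-null FDR.

Sub-exons are disjoint exon fragments obtained by splitting every gene's
annotated exons at every splice boundary across all isoforms, so the
fragment counts are sensitive to alternative 3'/5' splice sites.

## Worked example

Each script in `examples/` demonstrates one capability end to end. The
weight-scan demonstration (`examples/03_weight_scan_enrichment.py`)
simulates 1,000 genes in a 5-vs-5 design with a gene set enriched for
4-fold expression changes and another enriched for 0.3 proportion-shift
splicing changes, then scans the default 11-weight grid:

```
significant sets (FDR <= 0.05) per weight:
  alpha=0.0: ['DS_SET_0']
  alpha=0.5: ['DE_SET_0', 'DS_SET_0']
  alpha=1.0: ['DE_SET_0']
union over all 11 weights: ['DE_SET_0', 'DS_SET_0']
```

At `alpha = 1` (expression evidence only) the splicing-driven set is
invisible; at `alpha = 0` the expression-driven set is; the union over the
grid recovers both. The accompanying saturation curve (cumulative unique
significant sets as weights are added from the extremes inward) plateaus
at 2 sets after the first two weights on this dataset.

The same analysis is available from the shell:

```sh
seqgsea simulate --seed 7 --out data/
seqgsea run --counts data/counts.tsv --pheno data/phenotype.tsv \
    --gmt data/genesets.gmt --alpha-grid 0:1:0.1 --nperm 200 \
    --seed 8 --out results/
seqgsea saturate --scan results/
```

and `seqgsea flatten --gtf annotation.gtf --out subexons.tsv` produces the
sub-exon definition table from a transcript annotation.

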