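"""Per-gene differential-splicing scores from sub-exon read-count fractions.

Splicing changes show up as shifts in how a gene's reads distribute over
its sub-exons, independent of the gene's overall abundance.  Within each
group we estimate the expected read-count fraction of every sub-exon as
the pooled fraction (total sub-exon reads over total gene reads), with a
variance that is the larger of a delta-method NB variance and the
empirical between-sample variance of the per-sample fractions.  The DS
score averages, over a gene's sub-exons, the squared fraction difference
between groups divided by the summed variances.  Genes with a single
sub-exon carry no splicing signal and score 0.

All functions are vectorized over the flat sub-exon row axis; ``gene_idx``
maps each row to its gene (0..G-1, rows of a gene contiguous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .de_score import EPS

FLAG_OK = "ok"
FLAG_UNDEFINED = "DS-undefined"
FLAG_SINGLE = "single-subexon"


@dataclass
class GroupSplicingEstimate:
    """Per-sub-exon fraction estimates within one group.

    p_hat
        Pooled read-count fraction of each sub-exon: sum_j X_ij / sum_j Y_j
        over samples with Y_j > 0.  Sums to 1 within each gene.
    var_p
        max(delta-method NB variance of the pooled fraction,
        empirical variance of per-sample fractions / n contributing samples).
    defined
        Per-gene boolean: False when every sample of the group has zero
        total count for the gene (fractions undefined).
    """

    p_hat: np.ndarray
    var_p: np.ndarray
    defined: np.ndarray
    gene_idx: np.ndarray


def estimate_splicing(
    X_group: np.ndarray,
    Y_group: np.ndarray,
    gene_idx: np.ndarray,
    s_group: np.ndarray,
) -> GroupSplicingEstimate:
    """Estimate sub-exon fraction parameters for one group.

    Parameters
    ----------
    X_group : (R, m) array
        Sub-exon counts for the group's samples, rows grouped by gene.
    Y_group : (G, m) array
        Gene totals for the same samples.
    gene_idx : (R,) int array
        Row -> gene mapping.
    s_group : (m,) array
        Size factors (used in the dispersion moment estimator).
    """
    X_group = np.asarray(X_group, dtype=float)
    Y_group = np.asarray(Y_group, dtype=float)
    m = X_group.shape[1]
    if m < 2:
        raise ValueError("each group needs >= 2 samples")

    Yrow = Y_group[gene_idx]  # (R, m) per-row gene totals
    contrib = Yrow > 0  # samples with defined fractions, per row
    n_contrib = contrib.sum(axis=1)
    defined = Y_group.sum(axis=1) > 0  # per gene: any sample with reads

    # Pooled fraction: zero-total samples contribute 0 to both sums.
    tot_x = X_group.sum(axis=1)
    tot_y = Yrow.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = np.where(tot_y > 0, tot_x / np.maximum(tot_y, 1.0), 0.0)

    # Empirical between-sample variance of per-sample fractions f_ij = X/Y.
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(contrib, X_group / np.maximum(Yrow, 1.0), 0.0)
    n_safe = np.maximum(n_contrib, 1)
    f_mean = f.sum(axis=1) / n_safe
    sq = np.where(contrib, np.square(f - f_mean[:, None]), 0.0).sum(axis=1)
    var_emp = np.where(n_contrib > 1, sq / np.maximum(n_contrib - 1, 1), 0.0) / n_safe

    # Delta-method variance of the pooled ratio sum(X)/sum(Y) given the
    # observed totals: the count-level overdispersion of the totals cancels
    # exactly in the fraction, leaving the multinomial sampling floor
    # p(1-p)/sum(Y).  Splicing overdispersion beyond that floor (proportions
    # genuinely varying between replicates) is what the empirical
    # between-sample component measures; the max() of the two keeps the
    # denominator honest in both regimes.
    var_model = np.where(tot_y > 0, p_hat * (1.0 - p_hat) / np.maximum(tot_y, 1.0), 0.0)

    var_p = np.maximum(var_model, var_emp)
    return GroupSplicingEstimate(p_hat=p_hat, var_p=var_p, defined=defined, gene_idx=gene_idx)


def ds_score(
    est_A: GroupSplicingEstimate,
    est_B: GroupSplicingEstimate,
    n_genes: int,
    ds_mask: np.ndarray | None = None,
    eps: float = EPS,
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-sub-exon fraction discrepancy, per gene.

    Sub-exons masked out by ``ds_mask`` (low-count filter) are excluded from
    both the sum and the divisor.  Returns ``(scores, flags)`` where flags
    mark genes that are DS-undefined (no reads in a group) or effectively
    single-sub-exon; both score 0.
    """
    if est_A.p_hat.shape != est_B.p_hat.shape:
        raise ValueError("group estimates cover different sub-exon indices")
    gene_idx = est_A.gene_idx
    if ds_mask is None:
        ds_mask = np.ones(est_A.p_hat.shape, dtype=bool)

    terms = np.square(est_A.p_hat - est_B.p_hat) / (est_A.var_p + est_B.var_p + eps)
    terms = np.where(ds_mask, terms, 0.0)
    sums = np.bincount(gene_idx, weights=terms, minlength=n_genes)
    n_used = np.bincount(gene_idx, weights=ds_mask.astype(float), minlength=n_genes)

    defined = est_A.defined & est_B.defined
    multi = n_used > 1
    scores = np.where(defined & multi, sums / np.maximum(n_used, 1), 0.0)

    flags = np.full(n_genes, FLAG_OK, dtype=object)
    flags[~multi] = FLAG_SINGLE
    flags[~defined] = FLAG_UNDEFINED
    return scores, flags


def ds_scores_for_labels(
    X: np.ndarray,
    Y: np.ndarray,
    gene_idx: np.ndarray,
    size_factors: np.ndarray,
    labels_A: np.ndarray,
    ds_mask: np.ndarray | None = None,
) -> np.ndarray:
    """DS scores for one assignment of samples to groups (boolean A-mask)."""
    est_A = estimate_splicing(X[:, labels_A], Y[:, labels_A], gene_idx, size_factors[labels_A])
    est_B = estimate_splicing(X[:, ~labels_A], Y[:, ~labels_A], gene_idx, size_factors[~labels_A])
    scores, _ = ds_score(est_A, est_B, n_genes=Y.shape[0], ds_mask=ds_mask)
    return scores
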