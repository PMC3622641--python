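"""Per-gene differential-expression scores from negative-binomial models.

Gene-level counts are modelled as NB with mean mu_gj = s_j * q_{g,rho(j)}
and variance sigma^2 = mu + phi * mu^2, where s_j is the sample's size
factor, q the group-level normalized expression and phi the per-gene
dispersion.  Each group is estimated separately (no information sharing
across groups: the permutation design guarantees replicates per group).
The DE score is the squared difference of the two group means divided by
the sum of their variance estimates — large when the groups differ beyond
what the count noise explains, and non-negative by construction (direction
is deliberately discarded so that inversely regulated genes in one pathway
can reinforce rather than cancel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: additive stabilizer for score denominators, guarding flat genes
EPS = 1e-8


@dataclass
class GroupExpressionEstimate:
    """Per-gene NB estimates within one group.

    q_hat
        Mean normalized expression, (1/m) sum_j Y_j / s_j.
    var_q
        Variance of q_hat propagated from the NB variance mu + phi*mu^2:
        (1/m^2) sum_j (q_hat / s_j + phi_hat * q_hat^2).
    phi_hat
        Method-of-moments dispersion on normalized counts, floored at 0.
    """

    q_hat: np.ndarray
    var_q: np.ndarray
    phi_hat: np.ndarray
    n_samples: int


def estimate_group(Y_group: np.ndarray, s_group: np.ndarray) -> GroupExpressionEstimate:
    """Estimate per-gene NB parameters from one group's gene-level counts.

    Parameters
    ----------
    Y_group : (G, m) array
        Gene-level counts of the group's m samples.
    s_group : (m,) array
        Size factors of those samples.

    Raises
    ------
    ValueError
        If the group has fewer than 2 samples.
    """
    Y_group = np.asarray(Y_group, dtype=float)
    s_group = np.asarray(s_group, dtype=float)
    m = Y_group.shape[1]
    if m < 2:
        raise ValueError("each group needs >= 2 samples (replicates are required)")
    if len(s_group) != m:
        raise ValueError("size factor vector length does not match sample count")

    Z = Y_group / s_group  # normalized counts
    q_hat = Z.mean(axis=1)
    v_emp = Z.var(axis=1, ddof=1)
    inv_s_mean = np.mean(1.0 / s_group)

    # sigma^2 = mu + phi mu^2 on the normalized scale gives
    # Var(Y_j/s_j) ~= q/s_j + phi q^2; method of moments, floored at 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = (v_emp - q_hat * inv_s_mean) / np.square(q_hat)
    phi_hat = np.where(q_hat > 0, np.maximum(phi_hat, 0.0), 0.0)

    var_terms = q_hat[:, None] / s_group[None, :] + phi_hat[:, None] * np.square(q_hat)[:, None]
    var_q = var_terms.sum(axis=1) / m**2
    var_q = np.where(q_hat > 0, var_q, 0.0)
    return GroupExpressionEstimate(q_hat=q_hat, var_q=var_q, phi_hat=phi_hat, n_samples=m)


def de_score(
    est_A: GroupExpressionEstimate, est_B: GroupExpressionEstimate, eps: float = EPS
) -> np.ndarray:
    """Squared group-mean difference over summed variance estimates, per gene.

    Genes with zero counts in both groups score exactly 0; otherwise the
    denominator is stabilized by ``eps`` against degenerate zero variances.
    Symmetric under swapping the two groups.
    """
    if est_A.q_hat.shape != est_B.q_hat.shape:
        raise ValueError("group estimates cover different gene indices")
    num = np.square(est_A.q_hat - est_B.q_hat)
    den = est_A.var_q + est_B.var_q + eps
    score = num / den
    both_zero = (est_A.q_hat == 0) & (est_B.q_hat == 0)
    return np.where(both_zero, 0.0, score)


def de_scores_for_labels(
    Y: np.ndarray, size_factors: np.ndarray, labels_A: np.ndarray
) -> np.ndarray:
    """DE scores for one assignment of samples to groups.

    ``labels_A`` is a boolean mask over the sample axis; True marks group A.
    """
    est_A = estimate_group(Y[:, labels_A], size_factors[labels_A])
    est_B = estimate_group(Y[:, ~labels_A], size_factors[~labels_A])
    return de_score(est_A, est_B)
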