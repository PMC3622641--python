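"""Normalization and integration of DE and DS scores.

Raw DE and DS scores live on incomparable scales, so each gene's scores
(observed and permuted) are first divided by that gene's mean permutation
score — after which every gene's permutation scores average exactly 1 and
"large" means large relative to the gene's own label-shuffle background.

Two integration strategies then combine the normalized scores at a weight
alpha in [0,1] (alpha=1 is DE-only, alpha=0 DS-only):

* Linear: S = alpha*DE + (1-alpha)*DS.
* Rank-based: genes are ranked ascending on each score and the weighted
  average uses rank-inflated weights, S = (a*gDE*DE + (1-a)*gDS*DS) /
  (a*gDE + (1-a)*gDS), so whichever of a gene's two signals ranks higher
  dominates.  Permutation columns either reuse the observed-data ranks
  (RankGlb) or recompute ranks within each permutation (RankSp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

LINEAR = "Linear"
RANK_SP = "RankSp"
RANK_GLB = "RankGlb"
STRATEGIES = (LINEAR, RANK_SP, RANK_GLB)


@dataclass
class ScoreSet:
    """Observed score vector plus its genes x permutations null matrix."""

    s_obs: np.ndarray  # (G,)
    T: np.ndarray  # (G, P)
    kind: str  # "DE" or "DS"

    def __post_init__(self) -> None:
        if self.T.ndim != 2 or self.T.shape[0] != self.s_obs.shape[0]:
            raise ValueError("permutation matrix shape does not match observed vector")
        if (self.s_obs < 0).any() or (self.T < 0).any():
            raise ValueError("scores must be non-negative")


@dataclass
class IntegratedScores:
    alpha: float
    strategy: str
    s_obs: np.ndarray  # (G,)
    s_perm: np.ndarray  # (G, P)


def normalize_scores(score_set: ScoreSet) -> ScoreSet:
    """Divide each gene's observed and permuted scores by its mean permutation score.

    Genes whose permutation mean is 0 (score identically zero under every
    relabelling) get normalized score 0 throughout: they are retained so
    gene-set sizes stay fixed, but cannot drive enrichment.
    """
    if score_set.T.shape[1] == 0:
        raise ValueError("empty permutation matrix")
    tbar = score_set.T.mean(axis=1)
    safe = np.where(tbar > 0, tbar, 1.0)
    s_obs = np.where(tbar > 0, score_set.s_obs / safe, 0.0)
    T = np.where(tbar[:, None] > 0, score_set.T / safe[:, None], 0.0)
    return ScoreSet(s_obs=s_obs, T=T, kind=score_set.kind)


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")


def integrate_linear(de_norm: ScoreSet, ds_norm: ScoreSet, alpha: float) -> IntegratedScores:
    """Weighted sum of normalized DE and DS scores, per gene and per permutation."""
    _check_alpha(alpha)
    if de_norm.s_obs.shape != ds_norm.s_obs.shape:
        raise ValueError("DE and DS score sets cover different gene indices")
    s_obs = alpha * de_norm.s_obs + (1.0 - alpha) * ds_norm.s_obs
    s_perm = alpha * de_norm.T + (1.0 - alpha) * ds_norm.T
    return IntegratedScores(alpha=alpha, strategy=LINEAR, s_obs=s_obs, s_perm=s_perm)


def _rank_combine(
    de: np.ndarray, ds: np.ndarray, g_de: np.ndarray, g_ds: np.ndarray, alpha: float
) -> np.ndarray:
    num = alpha * g_de * de + (1.0 - alpha) * g_ds * ds
    den = alpha * g_de + (1.0 - alpha) * g_ds
    return num / den


def integrate_rank(
    de_norm: ScoreSet, ds_norm: ScoreSet, alpha: float, variant: str = RANK_GLB
) -> IntegratedScores:
    """Rank-weighted combination of normalized DE and DS scores.

    Ranks are ascending (mid-ranks on ties), so the better-ranked of a
    gene's two signals gets the larger weight.  At alpha in {0, 1} the
    ranks cancel and the result equals the single-score vector exactly.
    """
    _check_alpha(alpha)
    if variant not in (RANK_SP, RANK_GLB):
        raise ValueError(f"variant must be {RANK_SP!r} or {RANK_GLB!r}, got {variant!r}")
    if de_norm.s_obs.shape != ds_norm.s_obs.shape:
        raise ValueError("DE and DS score sets cover different gene indices")

    # degenerate weights: ranks cancel algebraically; return the single-score
    # vectors exactly rather than through the (rank*score)/rank round trip
    if alpha == 1.0:
        return IntegratedScores(alpha=alpha, strategy=variant,
                                s_obs=de_norm.s_obs.copy(), s_perm=de_norm.T.copy())
    if alpha == 0.0:
        return IntegratedScores(alpha=alpha, strategy=variant,
                                s_obs=ds_norm.s_obs.copy(), s_perm=ds_norm.T.copy())

    g_de_obs = rankdata(de_norm.s_obs, method="average")
    g_ds_obs = rankdata(ds_norm.s_obs, method="average")
    s_obs = _rank_combine(de_norm.s_obs, ds_norm.s_obs, g_de_obs, g_ds_obs, alpha)

    if variant == RANK_GLB:
        s_perm = _rank_combine(
            de_norm.T, ds_norm.T, g_de_obs[:, None], g_ds_obs[:, None], alpha
        )
    else:  # RankSp: ranks recomputed within each permutation column
        g_de = rankdata(de_norm.T, method="average", axis=0)
        g_ds = rankdata(ds_norm.T, method="average", axis=0)
        s_perm = _rank_combine(de_norm.T, ds_norm.T, g_de, g_ds, alpha)
    return IntegratedScores(alpha=alpha, strategy=variant, s_obs=s_obs, s_perm=s_perm)


def integrate(
    de_norm: ScoreSet, ds_norm: ScoreSet, alpha: float, strategy: str
) -> IntegratedScores:
    """Dispatch to the requested integration strategy."""
    if strategy == LINEAR:
        return integrate_linear(de_norm, ds_norm, alpha)
    if strategy in (RANK_SP, RANK_GLB):
        return integrate_rank(de_norm, ds_norm, alpha, variant=strategy)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
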