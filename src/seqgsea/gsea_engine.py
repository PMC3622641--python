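"""Gene set enrichment from integrated gene scores.

A gene set's enrichment score (ES) is the maximum of a Kolmogorov-Smirnov
style running sum over the score-ranked gene list: walking genes from the
highest score down, the sum rises by the member gene's score weight and
falls by a constant at non-members, so sets concentrated at the top of the
ranking reach a high maximum.  Significance comes from class-label
permutations: the full scoring pipeline is recomputed under each label
shuffle, yielding per-set null ES values, from which empirical p-values,
normalized ES (NES) and a pooled-null FDR are derived.  The multi-weight
scan repeats the test over a grid of DE/DS integration weights and the
saturation analysis counts cumulative unique discoveries as weights are
added in a fixed order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .count_data import CountData
from .de_score import de_scores_for_labels
from .ds_score import ds_scores_for_labels
from .integration import (
    LINEAR,
    IntegratedScores,
    ScoreSet,
    integrate,
    normalize_scores,
)

logger = logging.getLogger(__name__)

#: weight-addition order for the saturation analysis: DE-only first, then
#: DS-only, then weights spiralling in from the extremes.
DEFAULT_WEIGHT_ORDER = (1.0, 0.0, 0.5, 0.1, 0.9, 0.3, 0.7, 0.2, 0.4, 0.6, 0.8)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, genes: list[str], min_size: int = 5, max_size: int = 1000
                 ) -> "GeneSetCollection":
        """Intersect memberships with the scored genes and apply size bounds."""
        universe = set(genes)
        kept: list[GeneSet] = []
        for gs in self.sets:
            eff = gs.members & universe
            if min_size <= len(eff) <= max_size:
                kept.append(GeneSet(gs.name, gs.description, frozenset(eff)))
            else:
                logger.info(
                    "skipping gene set %s (effective size %d outside [%d, %d])",
                    gs.name, len(eff), min_size, max_size,
                )
        return GeneSetCollection(kept)


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            sets.append(GeneSet(fields[0], fields[1], frozenset(f for f in fields[2:] if f)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    gene_scores: np.ndarray,
    member_mask: np.ndarray,
    weight_exp: float = 1.0,
) -> float:
    """Running-sum enrichment score of one gene set.

    Parameters
    ----------
    gene_scores : (G,) array
        Per-gene scores (non-negative); genes are internally sorted by
        descending score (stable on ties).
    member_mask : (G,) boolean array
        Set membership aligned with ``gene_scores``.
    weight_exp
        Exponent on |score| in the hit increments: 1 gives the weighted KS
        statistic, 0 the classic unweighted form.

    The running sum gains |S|^weight_exp / N_R at member genes (N_R being
    the member weight total) and loses 1/(G - n_members) at non-members;
    the ES is the maximum of the running sum (one-sided: gene scores carry
    no sign, so only positive deviations are meaningful).
    """
    gene_scores = np.asarray(gene_scores, dtype=float)
    member_mask = np.asarray(member_mask, dtype=bool)
    n = gene_scores.shape[0]
    n_hit = int(member_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set has zero intersection with the scored genes")
    if n_hit == n:
        raise ValueError("gene set equals the whole gene list; ES is undefined")
    order = np.argsort(-gene_scores, kind="stable")
    hits = member_mask[order]
    w = np.abs(gene_scores[order]) ** weight_exp
    n_r = w[hits].sum()
    if n_r == 0:
        # all member scores zero: no hit mass to distribute
        return 0.0
    steps = np.where(hits, w / n_r, -1.0 / (n - n_hit))
    return float(np.max(np.cumsum(steps)))


def enrichment_scores_matrix(
    score_columns: np.ndarray,
    membership: np.ndarray,
    weight_exp: float = 1.0,
) -> np.ndarray:
    """ES for every (gene set, score column) pair, vectorized.

    score_columns: (G, C) score matrix (e.g. observed + permutation columns);
    membership: (S, G) boolean matrix.  Returns (S, C).
    """
    score_columns = np.asarray(score_columns, dtype=float)
    membership = np.asarray(membership, dtype=bool)
    G, C = score_columns.shape
    S = membership.shape[0]
    n_hit = membership.sum(axis=1)  # (S,)
    if (n_hit == 0).any() or (n_hit == G).any():
        raise ValueError("every gene set must be a non-empty proper subset of the gene list")
    out = np.empty((S, C))
    miss_step = 1.0 / (G - n_hit)  # (S,)
    for c in range(C):
        order = np.argsort(-score_columns[:, c], kind="stable")
        w = np.abs(score_columns[order, c]) ** weight_exp  # (G,)
        hits = membership[:, order]  # (S, G)
        n_r = (hits * w[None, :]).sum(axis=1)  # (S,)
        n_r_safe = np.where(n_r > 0, n_r, 1.0)
        steps = np.where(hits, w[None, :] / n_r_safe[:, None], -miss_step[:, None])
        out[:, c] = np.where(n_r > 0, np.cumsum(steps, axis=1).max(axis=1), 0.0)
    return out


# ---------------------------------------------------------------------------
# Label permutations and raw permutation scores
# ---------------------------------------------------------------------------

def generate_label_permutations(
    n_samples: int, n_group_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_perm, n_samples) matrix of group-A masks under label shuffling.

    Group sizes are preserved, so every shuffle keeps both groups at their
    observed sizes (hence non-empty).  When the design admits fewer distinct
    assignments than requested, all distinct assignments are enumerated and
    used instead, with a warning.
    """
    n_distinct = comb(n_samples, n_group_a)
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label assignments exist "
            f"(requested {n_perm}); using all of them",
            stacklevel=2,
        )
        masks = np.zeros((n_distinct, n_samples), dtype=bool)
        for i, idx in enumerate(combinations(range(n_samples), n_group_a)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((n_perm, n_samples), dtype=bool)
    if n_distinct <= 200_000:
        # small design: sample distinct assignments without replacement
        all_idx = list(combinations(range(n_samples), n_group_a))
        chosen = rng.choice(n_distinct, size=n_perm, replace=False)
        for i, k in enumerate(chosen):
            masks[i, list(all_idx[k])] = True
    else:
        for i in range(n_perm):
            masks[i, rng.choice(n_samples, size=n_group_a, replace=False)] = True
    return masks


@dataclass
class ScoredData:
    """Observed + permutation DE/DS scores for one dataset.

    Computed once; shared by every (strategy, alpha) combination so the
    whole weight scan runs on identical label shuffles.
    """

    genes: list[str]
    de: ScoreSet
    ds: ScoreSet
    label_masks: np.ndarray  # (P, M) group-A masks used for the null
    ds_flags: np.ndarray = field(default=None)  # type: ignore[assignment]


def compute_scores(cd: CountData, n_perm: int = 1000, seed: int = 0) -> ScoredData:
    """Run per-group estimation and DE/DS scoring on observed and permuted labels.

    The full estimation (group means, dispersions, variances) is redone under
    every label shuffle; size factors stay fixed (they are sample properties,
    independent of the labels).
    """
    from .ds_score import ds_score as _ds_score, estimate_splicing

    rng = np.random.default_rng(seed)
    genes = cd.genes
    Y = cd.Y.values.astype(float)
    X = cd.X.values.astype(float)
    s = cd.size_factors.values.astype(float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    gene_idx = np.array(
        [gene_pos[g] for g in cd.X.index.get_level_values("gene_id")], dtype=np.int64
    )
    ds_mask = cd.ds_mask.values.astype(bool)

    label_a, _ = cd.group_labels
    obs_mask = np.array([cd.groups[smp] == label_a for smp in cd.samples], dtype=bool)
    m_a = int(obs_mask.sum())
    M = len(cd.samples)
    if m_a < 2 or M - m_a < 2:
        raise ValueError("both groups need >= 2 samples for permutation analysis")

    de_obs = de_scores_for_labels(Y, s, obs_mask)
    est_a = estimate_splicing(X[:, obs_mask], Y[:, obs_mask], gene_idx, s[obs_mask])
    est_b = estimate_splicing(X[:, ~obs_mask], Y[:, ~obs_mask], gene_idx, s[~obs_mask])
    ds_obs, ds_flags = _ds_score(est_a, est_b, n_genes=len(genes), ds_mask=ds_mask)

    masks = generate_label_permutations(M, m_a, n_perm, rng)
    P = masks.shape[0]
    T_de = np.empty((len(genes), P))
    T_ds = np.empty((len(genes), P))
    for p in range(P):
        mk = masks[p]
        T_de[:, p] = de_scores_for_labels(Y, s, mk)
        T_ds[:, p] = ds_scores_for_labels(X, Y, gene_idx, s, mk, ds_mask=ds_mask)

    return ScoredData(
        genes=genes,
        de=ScoreSet(s_obs=de_obs, T=T_de, kind="DE"),
        ds=ScoreSet(s_obs=ds_obs, T=T_ds, kind="DS"),
        label_masks=masks,
        ds_flags=ds_flags,
    )


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

def significance(
    obs_es: np.ndarray, perm_es: np.ndarray, set_names: list[str], set_sizes: np.ndarray
) -> pd.DataFrame:
    """Empirical p-values, NES and pooled-null FDR per gene set.

    p_emp uses the add-one estimator (1 + #{perm >= obs}) / (P + 1), bounded
    below by 1/(P+1).  NES divides each set's ES by the mean of its positive
    permutation ES values; permutation ES are normalized the same way, and
    FDR(set) is the pooled fraction of permutation NES at or above the set's
    NES divided by the fraction of observed NES at or above it, clipped to
    [0, 1].
    """
    obs_es = np.asarray(obs_es, dtype=float)
    S, P = perm_es.shape
    p_emp = (1.0 + (perm_es >= obs_es[:, None]).sum(axis=1)) / (P + 1.0)

    pos_sum = np.where(perm_es > 0, perm_es, 0.0).sum(axis=1)
    pos_cnt = (perm_es > 0).sum(axis=1)
    mean_pos = np.where(pos_cnt > 0, pos_sum / np.maximum(pos_cnt, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        nes = obs_es / mean_pos
        perm_nes = perm_es / mean_pos[:, None]
    flagged = ~np.isfinite(nes)

    pooled = perm_nes[np.isfinite(perm_nes).all(axis=1)]
    fdr = np.full(S, np.nan)
    if pooled.size:
        pool_flat = np.sort(pooled.ravel())
        obs_sorted = np.sort(nes[~flagged])
        for i in range(S):
            if flagged[i]:
                continue
            frac_pool = 1.0 - np.searchsorted(pool_flat, nes[i], side="left") / pool_flat.size
            frac_obs = 1.0 - np.searchsorted(obs_sorted, nes[i], side="left") / obs_sorted.size
            fdr[i] = min(1.0, frac_pool / frac_obs) if frac_obs > 0 else 0.0
        # q-value style monotonization: a set never reports a larger FDR
        # than any set with a smaller or equal NES
        ok_idx = np.flatnonzero(~flagged)
        order = ok_idx[np.argsort(nes[ok_idx])]  # ascending NES
        fdr[order] = np.minimum.accumulate(fdr[order])
    return pd.DataFrame(
        {
            "set_name": set_names,
            "size": set_sizes,
            "ES": obs_es,
            "NES": nes,
            "p_emp": p_emp,
            "FDR": fdr,
            "flag": np.where(flagged, "NES-undefined", "ok"),
        }
    )


# ---------------------------------------------------------------------------
# Multi-weight scan and saturation
# ---------------------------------------------------------------------------

def run_enrichment(
    scored: ScoredData,
    collection: GeneSetCollection,
    alpha: float,
    strategy: str = LINEAR,
    weight_exp: float = 1.0,
) -> pd.DataFrame:
    """Normalize, integrate at one (strategy, alpha), and test every gene set."""
    de_norm = normalize_scores(scored.de)
    ds_norm = normalize_scores(scored.ds)
    integ = integrate(de_norm, ds_norm, alpha, strategy)
    return _test_sets(integ, scored.genes, collection, weight_exp)


def run_enrichment_single(
    scored: ScoredData,
    collection: GeneSetCollection,
    kind: str = "DE",
    weight_exp: float = 1.0,
) -> pd.DataFrame:
    """DE-only or DS-only enrichment run (normalized scores, no integration)."""
    if kind not in ("DE", "DS"):
        raise ValueError("kind must be 'DE' or 'DS'")
    ss = normalize_scores(scored.de if kind == "DE" else scored.ds)
    integ = IntegratedScores(
        alpha=1.0 if kind == "DE" else 0.0,
        strategy=f"{kind}-only",
        s_obs=ss.s_obs,
        s_perm=ss.T,
    )
    return _test_sets(integ, scored.genes, collection, weight_exp)


def _test_sets(
    integ: IntegratedScores,
    genes: list[str],
    collection: GeneSetCollection,
    weight_exp: float,
) -> pd.DataFrame:
    restricted = collection.restrict(genes)
    if len(restricted) == 0:
        raise ValueError("no gene set has adequate overlap with the scored genes")
    gene_pos = {g: i for i, g in enumerate(genes)}
    membership = np.zeros((len(restricted), len(genes)), dtype=bool)
    names, sizes = [], []
    for k, gs in enumerate(restricted):
        names.append(gs.name)
        sizes.append(len(gs.members))
        membership[k, [gene_pos[g] for g in gs.members]] = True
    cols = np.column_stack([integ.s_obs[:, None], integ.s_perm])
    es = enrichment_scores_matrix(cols, membership, weight_exp=weight_exp)
    res = significance(es[:, 0], es[:, 1:], names, np.asarray(sizes))
    res.insert(0, "strategy", integ.strategy)
    res.insert(1, "alpha", integ.alpha)
    return res


def weight_scan(
    scored: ScoredData,
    collection: GeneSetCollection,
    strategies: tuple[str, ...] = (LINEAR,),
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    fdr_cutoff: float = 0.05,
    weight_exp: float = 1.0,
) -> pd.DataFrame:
    """Enrichment results over a grid of integration weights and strategies.

    The same label shuffles and raw DE/DS permutation scores back every
    (strategy, alpha) cell, so differences across the grid reflect the
    integration weight alone.  Returns the concatenated per-cell result
    tables with a boolean ``significant`` column (FDR <= cutoff).
    """
    uniq: list[float] = []
    for a in alphas:
        if a in uniq:
            warnings.warn(f"duplicate alpha {a} in grid; deduplicated", stacklevel=2)
        else:
            uniq.append(a)
    if not uniq:
        raise ValueError("empty alpha grid")

    de_norm = normalize_scores(scored.de)
    ds_norm = normalize_scores(scored.ds)
    frames = []
    for strategy in strategies:
        for alpha in uniq:
            integ = integrate(de_norm, ds_norm, alpha, strategy)
            res = _test_sets(integ, scored.genes, collection, weight_exp)
            frames.append(res)
    scan = pd.concat(frames, ignore_index=True)
    scan["significant"] = scan["FDR"] <= fdr_cutoff
    return scan


def significant_sets(scan: pd.DataFrame, strategy: str, alpha: float) -> set[str]:
    """Names of significant sets in one (strategy, alpha) cell of a scan."""
    cell = scan[(scan["strategy"] == strategy) & (np.isclose(scan["alpha"], alpha))]
    return set(cell.loc[cell["significant"], "set_name"])


def scan_union(scan: pd.DataFrame, strategy: str | None = None) -> set[str]:
    """Union of significant sets across all weights (optionally one strategy)."""
    sub = scan if strategy is None else scan[scan["strategy"] == strategy]
    return set(sub.loc[sub["significant"], "set_name"])


def saturation_analysis(
    scan: pd.DataFrame,
    weight_order: tuple[float, ...] = DEFAULT_WEIGHT_ORDER,
    strategy: str = LINEAR,
) -> pd.DataFrame:
    """Cumulative unique significant sets as weights are added in a fixed order.

    The order starts at the DE-only and DS-only extremes and fills inward;
    the resulting curve is non-decreasing by construction and its plateau
    indicates how many weights suffice to saturate discovery.
    """
    scanned = {round(float(a), 10) for a in scan.loc[scan["strategy"] == strategy, "alpha"]}
    missing = [a for a in weight_order if round(float(a), 10) not in scanned]
    if missing:
        raise ValueError(f"weights {missing} not present in the scan for strategy {strategy}")
    seen: set[str] = set()
    rows = []
    for k, a in enumerate(weight_order, start=1):
        seen |= significant_sets(scan, strategy, a)
        rows.append({"n_weights": k, "alpha_added": a, "cumulative_unique_sets": len(seen)})
    return pd.DataFrame(rows)
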