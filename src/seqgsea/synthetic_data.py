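"""Synthetic two-group sub-exon count datasets with planted DE/DS effects.

The generator emulates the count model the scoring method assumes: each
gene's per-sample total is negative binomial with mean s_j * q (size
factor times group-level expression) and variance mu + phi * mu^2, and the
total is split across the gene's sub-exons multinomially according to
per-group Dirichlet proportions.  Differential expression is planted by
fold-changing q in group B; differential splicing by moving a configured
amount of proportion mass between two sub-exons in group B, leaving the
total distribution untouched — so DE and DS truths are orthogonal by
construction.  Gene sets are assembled from the DE, DS, mixed and null
gene pools, giving planted-enrichment and null sets for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_data import CountData
from .gsea_engine import GeneSet, GeneSetCollection


@dataclass
class GeneSetSpec:
    """Composition of the generated gene-set collection.

    ``n_enriched_de/ds/mixed`` sets draw ``enriched_fraction`` of their
    members from the corresponding effect pool (the rest from null genes);
    ``n_null`` sets draw all members from genes without planted effects.
    """

    set_size: int = 20
    n_enriched_de: int = 1
    n_enriched_ds: int = 1
    n_enriched_mixed: int = 0
    n_null: int = 20
    enriched_fraction: float = 0.8


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror a moderate two-group human RNA-Seq design: ~1,000 genes
    with 1-8 sub-exons, 5 vs 5 samples, log-normal baseline expression
    around a few hundred reads, NB dispersion 0.1 (typical biological
    replicate overdispersion), size factors within 2-fold of each other,
    5% DE genes at 4-fold change and 5% DS genes with a 0.3 proportion
    shift between two sub-exons.
    """

    n_genes: int = 1000
    subexons_min: int = 1
    subexons_max: int = 8
    m_A: int = 5
    m_B: int = 5
    baseline_log_mean: float = 5.0  # log-scale mean of q (~e^5 = 148 reads)
    baseline_log_sd: float = 1.0
    phi: float = 0.1  # NB dispersion; 0 gives Poisson counts
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    de_fraction: float = 0.05
    de_fold: float = 4.0
    ds_fraction: float = 0.05
    ds_shift: float = 0.3  # proportion mass moved between two sub-exons
    dirichlet_conc: float = 5.0
    geneset_spec: GeneSetSpec = field(default_factory=GeneSetSpec)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.de_fraction <= 1 and 0 <= self.ds_fraction <= 1):
            raise ValueError("effect fractions must lie in [0, 1]")
        if self.de_fold <= 0:
            raise ValueError("fold change must be positive")
        if self.m_A < 2 or self.m_B < 2:
            raise ValueError("group sizes must be >= 2")
        if self.subexons_min < 1 or self.subexons_max < self.subexons_min:
            raise ValueError("invalid sub-exon count range")
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")
        n_de = int(round(self.de_fraction * self.n_genes))
        n_ds = int(round(self.ds_fraction * self.n_genes))
        if n_de + n_ds > self.n_genes:
            raise ValueError("more effect genes requested than genes available")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (variance mu + phi mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    # numpy NB(n, p): mean n(1-p)/p, var mean/p  =>  n = 1/phi, p = n/(n+mu)
    n = 1.0 / phi
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate(config: SimConfig) -> tuple[CountData, pd.DataFrame, GeneSetCollection]:
    """Generate counts, a per-gene truth table and a gene-set collection.

    Returns
    -------
    (CountData, truth, GeneSetCollection) where ``truth`` has columns
    gene_id, is_de, is_ds, q_A, q_B, n_subexons.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    M = config.m_A + config.m_B
    genes = [f"G{i:05d}" for i in range(G)]
    samples = [f"A{j}" for j in range(config.m_A)] + [f"B{j}" for j in range(config.m_B)]
    is_b = np.array([False] * config.m_A + [True] * config.m_B)

    n_sub = rng.integers(config.subexons_min, config.subexons_max + 1, size=G)
    q_a = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=G))

    n_de = int(round(config.de_fraction * G))
    n_ds = int(round(config.ds_fraction * G))
    effect_genes = rng.choice(G, size=n_de + n_ds, replace=False)
    de_idx = np.sort(effect_genes[:n_de])
    ds_candidates = effect_genes[n_de:]
    # DS needs >= 2 sub-exons; force those genes to have at least 2
    n_sub[ds_candidates] = np.maximum(n_sub[ds_candidates], 2)
    ds_idx = np.sort(ds_candidates)

    q_b = q_a.copy()
    # fold change split up/down at random so depth stays balanced
    up = rng.random(n_de) < 0.5
    q_b[de_idx] = np.where(up, q_a[de_idx] * config.de_fold, q_a[de_idx] / config.de_fold)

    s = rng.uniform(*config.size_factor_range, size=M)

    rows_gene, rows_idx, X_rows = [], [], []
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    is_ds = np.zeros(G, dtype=bool)
    is_ds[ds_idx] = True

    for g in range(G):
        k = int(n_sub[g])
        props_a = rng.dirichlet(np.full(k, config.dirichlet_conc))
        props_b = props_a.copy()
        if is_ds[g]:
            # move `ds_shift` mass from one sub-exon to another in group B
            i, j = rng.choice(k, size=2, replace=False)
            delta = min(config.ds_shift, props_b[i])
            props_b[i] -= delta
            props_b[j] += delta
            props_b = np.clip(props_b, 0.0, None)
            props_b /= props_b.sum()  # guard float residue for multinomial
        mu = s * np.where(is_b, q_b[g], q_a[g])
        totals = _nb_draw(rng, mu, config.phi)
        counts = np.empty((k, M), dtype=np.int64)
        for j_s in range(M):
            pr = props_b if is_b[j_s] else props_a
            counts[:, j_s] = rng.multinomial(totals[j_s], pr)
        rows_gene.extend([genes[g]] * k)
        rows_idx.extend(range(1, k + 1))
        X_rows.append(counts)

    X = pd.DataFrame(
        np.vstack(X_rows),
        index=pd.MultiIndex.from_arrays([rows_gene, rows_idx], names=["gene_id", "subexon_index"]),
        columns=samples,
    )
    Y = X.groupby(level="gene_id", sort=False).sum()
    groups = pd.Series(["A"] * config.m_A + ["B"] * config.m_B, index=samples)
    cd = CountData(X=X, Y=Y, groups=groups)

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_de": is_de,
            "is_ds": is_ds,
            "q_A": q_a,
            "q_B": q_b,
            "n_subexons": n_sub,
        }
    )
    collection = _build_genesets(config.geneset_spec, genes, is_de, is_ds, rng)
    return cd, truth, collection


def _build_genesets(
    spec: GeneSetSpec,
    genes: list[str],
    is_de: np.ndarray,
    is_ds: np.ndarray,
    rng: np.random.Generator,
) -> GeneSetCollection:
    genes_arr = np.asarray(genes)
    de_pool = genes_arr[is_de & ~is_ds]
    ds_pool = genes_arr[is_ds & ~is_de]
    null_pool = genes_arr[~is_de & ~is_ds]
    sets: list[GeneSet] = []

    def make(name: str, desc: str, pool: np.ndarray) -> GeneSet:
        n_eff = min(int(round(spec.enriched_fraction * spec.set_size)), len(pool))
        eff = rng.choice(pool, size=n_eff, replace=False) if n_eff else np.array([], dtype=object)
        filler = rng.choice(null_pool, size=spec.set_size - n_eff, replace=False)
        return GeneSet(name, desc, frozenset(map(str, np.concatenate([eff, filler]))))

    for i in range(spec.n_enriched_de):
        sets.append(make(f"DE_SET_{i}", "planted differential-expression set", de_pool))
    for i in range(spec.n_enriched_ds):
        sets.append(make(f"DS_SET_{i}", "planted differential-splicing set", ds_pool))
    mixed_pool = np.concatenate([de_pool, ds_pool])
    for i in range(spec.n_enriched_mixed):
        sets.append(make(f"MIXED_SET_{i}", "planted mixed DE/DS set", mixed_pool))
    for i in range(spec.n_null):
        members = rng.choice(null_pool, size=spec.set_size, replace=False)
        sets.append(GeneSet(f"NULL_SET_{i}", "random null set", frozenset(map(str, members))))
    return GeneSetCollection(sets)


def empirical_moments(cd: CountData) -> pd.DataFrame:
    """Per-gene empirical moments of normalized counts, for model checking.

    Returns a frame with the per-gene mean and variance of Y_j / s_j pooled
    within groups (group means subtracted so planted DE does not inflate the
    variance), plus the implied dispersion (var - mean) / mean^2.  Fitting
    variance - mean against mean^2 across genes recovers the generating
    dispersion when counts follow the assumed NB model.
    """
    labels = [cd.groups[smp] for smp in cd.samples]
    for lab in set(labels):
        if labels.count(lab) < 2:
            raise ValueError(f"group {lab!r} needs >= 2 samples for moment estimates")
    Z = cd.Y.values / cd.size_factors.values[None, :]
    a_label = cd.group_labels[0]
    mask_a = np.array([lab == a_label for lab in labels])
    parts = []
    for mk in (mask_a, ~mask_a):
        Zg = Z[:, mk]
        parts.append((Zg.mean(axis=1), Zg.var(axis=1, ddof=1), mk.sum()))
    # pooled within-group variance; overall mean for the mean column
    (m1, v1, n1), (m2, v2, n2) = parts
    var_pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mean_all = (n1 * m1 + n2 * m2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_implied = (var_pooled - mean_all) / np.square(mean_all)
    return pd.DataFrame(
        {
            "gene_id": cd.genes,
            "mean": mean_all,
            "var": var_pooled,
            "phi_implied": np.where(mean_all > 0, phi_implied, np.nan),
        }
    )


def fit_dispersion(moments: pd.DataFrame) -> float:
    """Recover the generating NB dispersion by regressing (var - mean) on mean^2."""
    x = np.square(moments["mean"].values)
    y = moments["var"].values - moments["mean"].values
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0)
    # least squares through the origin: slope = sum(xy)/sum(x^2)
    return float(np.sum(x[ok] * y[ok]) / np.sum(np.square(x[ok])))
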