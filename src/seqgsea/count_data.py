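"""Sub-exon count matrices: loading, validation, filtering, normalization.

The central container is :class:`CountData`, holding the sub-exon count
matrix X (rows = (gene, sub-exon), columns = samples), the derived
gene-level totals Y (the per-gene column sums of X), the two-group sample
assignment, and per-sample size factors capturing sequencing depth.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


@dataclass
class CountData:
    """Two-group sub-exon count data.

    Attributes
    ----------
    X : pd.DataFrame
        Integer sub-exon counts, MultiIndex rows (gene_id, subexon_index),
        one column per sample.
    Y : pd.DataFrame
        Gene-level totals, rows = gene_id, same sample columns.  Always the
        exact per-gene column sum of the *unfiltered* sub-exon counts, so
        expression analysis never loses reads to splicing-level filters.
    groups : pd.Series
        Sample -> group label, exactly two distinct labels.  The first label
        encountered in sample order is group A.
    size_factors : pd.Series
        Positive per-sample scaling factors.
    ds_mask : pd.Series
        Boolean per sub-exon row; False rows are excluded from splicing
        analysis (low-count filter) but still counted in Y.
    """

    X: pd.DataFrame
    Y: pd.DataFrame
    groups: pd.Series
    size_factors: pd.Series = field(default=None)  # type: ignore[assignment]
    ds_mask: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.size_factors is None:
            self.size_factors = pd.Series(1.0, index=self.samples)
        if self.ds_mask is None:
            self.ds_mask = pd.Series(True, index=self.X.index)
        self.validate()

    # -- derived views ------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.X.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.Y.index)

    @property
    def group_labels(self) -> tuple[str, str]:
        """(A, B) in first-occurrence order along the sample axis."""
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == label]

    # -- checks -------------------------------------------------------
    def validate(self) -> None:
        if list(self.Y.columns) != self.samples:
            raise ValueError("Y and X sample columns differ")
        if (self.X.values < 0).any():
            raise ValueError("negative counts")
        labels = set(self.groups[s] for s in self.samples)
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, got {sorted(labels)}")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        missing = [s for s in self.samples if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples missing a group assignment: {missing}")

    def check_y_consistency(self) -> None:
        """Assert Y equals the per-gene sum of all (unfiltered) sub-exon counts."""
        recomputed = self.X.groupby(level="gene_id", sort=False).sum()
        recomputed = recomputed.loc[self.Y.index]
        if not (recomputed.values == self.Y.values).all():
            raise AssertionError("gene totals Y do not equal sub-exon column sums")


def load_counts(subexon_count_tsv: str, phenotype_tsv: str) -> CountData:
    """Load a sub-exon count table and its two-group phenotype file.

    The count table has columns (gene_id, subexon_index, <sample>...).  The
    phenotype file has columns (sample, group) and must cover exactly the
    count table's samples.  Group labels are mapped to (A, B) roles by first
    occurrence along the count table's sample order.
    """
    with _open_text(subexon_count_tsv) as fh:
        counts = pd.read_csv(fh, sep="\t", comment="#")
    if counts.columns[0] != "gene_id" or counts.columns[1] != "subexon_index":
        raise ValueError(
            "count table must start with columns gene_id, subexon_index; "
            f"got {list(counts.columns[:2])}"
        )
    dup = counts.duplicated(subset=["gene_id", "subexon_index"])
    if dup.any():
        bad = counts.loc[dup, ["gene_id", "subexon_index"]].iloc[0]
        raise ValueError(
            f"duplicated (gene, subexon) row: ({bad['gene_id']}, {bad['subexon_index']})"
        )
    sample_cols = list(counts.columns[2:])
    if not sample_cols:
        raise ValueError("count table has no sample columns")

    values = counts[sample_cols]
    if not np.issubdtype(values.values.dtype, np.number):
        raise ValueError("non-numeric counts in table")
    if (values.values < 0).any():
        raise ValueError("negative counts in table")
    if not np.allclose(values.values, np.round(values.values)):
        raise ValueError("non-integer counts in table")

    X = counts.set_index(["gene_id", "subexon_index"])[sample_cols].astype(np.int64)

    with _open_text(phenotype_tsv) as fh:
        pheno = pd.read_csv(fh, sep="\t", comment="#")
    if "sample" not in pheno.columns or "group" not in pheno.columns:
        raise ValueError("phenotype file must have columns 'sample' and 'group'")
    pheno_map = pheno.set_index("sample")["group"]
    missing = [s for s in sample_cols if s not in pheno_map.index]
    if missing:
        raise ValueError(f"samples in counts missing from phenotype: {missing}")
    extra = [s for s in pheno_map.index if s not in sample_cols]
    if extra:
        raise ValueError(f"phenotype samples missing from counts: {extra}")
    labels = {pheno_map[s] for s in sample_cols}
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(map(str, labels))}")

    groups = pd.Series({s: pheno_map[s] for s in sample_cols})
    Y = X.groupby(level="gene_id", sort=False).sum()
    return CountData(X=X, Y=Y, groups=groups)


def estimate_size_factors(Y: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors from gene-level totals.

    Each sample's factor is the median, over genes with a positive geometric
    mean across samples, of that sample's count divided by the gene's
    geometric mean.  With ``pseudo_reference=True`` the geometric mean is
    computed on counts + 1 (fallback for sparse data with no gene expressed
    in every sample).
    """
    vals = Y.values.astype(float)
    if pseudo_reference:
        logref = np.log(vals + 1.0).mean(axis=1)
        usable = np.ones(len(vals), dtype=bool)
        ref = np.exp(logref)
    else:
        with np.errstate(divide="ignore"):
            logvals = np.log(vals)
        usable = np.isfinite(logvals).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no gene has positive counts in every sample; "
                "retry with pseudo_reference=True"
            )
        ref = np.exp(logvals[usable].mean(axis=1))
    ratios = vals[usable] / ref[:, None]
    s = np.median(ratios, axis=0)
    if (s <= 0).any():
        raise ValueError("non-positive size factor estimated; data too sparse")
    return pd.Series(s, index=Y.columns)


def filter_low_expression(
    cd: CountData, min_gene_total: int = 10, min_subexon_total: int = 5
) -> CountData:
    """Drop weakly expressed genes and mask low-count sub-exons.

    Genes whose total count summed over samples is below ``min_gene_total``
    are removed entirely.  Sub-exons of surviving genes whose summed count is
    below ``min_subexon_total`` are masked out of the splicing analysis only;
    gene totals Y keep all reads.
    """
    if min_gene_total < 0 or min_subexon_total < 0:
        raise ValueError("thresholds must be >= 0")
    gene_totals = cd.Y.sum(axis=1)
    keep_genes = gene_totals[gene_totals >= min_gene_total].index
    n_dropped = len(cd.Y) - len(keep_genes)
    if len(keep_genes) == 0:
        raise ValueError("gene filter removed every gene")
    if n_dropped:
        logger.info("filtered %d genes below total %d", n_dropped, min_gene_total)

    X = cd.X[cd.X.index.get_level_values("gene_id").isin(set(keep_genes))]
    Y = cd.Y.loc[keep_genes]
    subexon_totals = X.sum(axis=1)
    ds_mask = subexon_totals >= min_subexon_total
    n_masked = int((~ds_mask).sum())
    if n_masked:
        logger.info("masked %d sub-exons below total %d from DS analysis", n_masked, min_subexon_total)
    return CountData(
        X=X, Y=Y, groups=cd.groups, size_factors=cd.size_factors, ds_mask=ds_mask
    )


def attach_size_factors(cd: CountData, pseudo_reference: bool = False) -> CountData:
    """Return a copy of ``cd`` with median-of-ratios size factors attached.

    Size factors are sample properties (sequencing depth); they are computed
    once from the observed data and held fixed across label permutations.
    """
    s = estimate_size_factors(cd.Y, pseudo_reference=pseudo_reference)
    return replace(cd, size_factors=s)
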