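"""Sub-exon gene models.

Alternative splicing shuffles which parts of a gene end up in the mature
transcript, and the annotated isoforms of a gene overlap each other in
arbitrary ways (shared exons, alternative 3'/5' splice sites, retained
fragments).  To quantify splicing from exon-level read counts we flatten
every gene's isoforms into *sub-exons*: non-overlapping, contiguous exon
fragments split at every annotated splice boundary, so that each possible
donor/acceptor site starts a new fragment.  Read counts on sub-exons are
then unambiguous, and their per-gene sum recovers the gene-level count.

Coordinates are handled as 0-based half-open internally; GTF input
(1-based closed) is converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExonRecord:
    """One exon of one transcript, 0-based half-open coordinates."""

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"exon of gene {self.gene_id!r} has start >= end "
                f"({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for gene {self.gene_id!r}")


@dataclass(frozen=True)
class SubExon:
    """A disjoint exon fragment of a gene; ``index`` is 1-based, ordered by start."""

    gene_id: str
    index: int
    chrom: str
    start: int
    end: int
    strand: str

    def __len__(self) -> int:
        return self.end - self.start


def flatten_gene(exons: list[ExonRecord]) -> list[SubExon]:
    """Split a gene's exons into disjoint sub-exons at every splice boundary.

    Every distinct exon start and end that falls inside exon-covered
    territory forces a fragment boundary, so fragments never straddle a
    possible splice site.  The union of fragment bases equals the union of
    input exon bases exactly.

    Parameters
    ----------
    exons
        All exon records of one gene (across all its transcripts).

    Returns
    -------
    list of SubExon, sorted by genomic start, pairwise disjoint.

    Raises
    ------
    ValueError
        If the list is empty or mixes gene ids, chromosomes or strands.
    """
    if not exons:
        raise ValueError("flatten_gene requires at least one exon")
    gene_id = exons[0].gene_id
    chrom = exons[0].chrom
    strand = exons[0].strand
    for e in exons:
        if e.gene_id != gene_id:
            raise ValueError(f"mixed gene ids: {gene_id!r} vs {e.gene_id!r}")
        if e.chrom != chrom or e.strand != strand:
            raise ValueError(
                f"gene {gene_id!r} mixes chromosome/strand: "
                f"({chrom},{strand}) vs ({e.chrom},{e.strand})"
            )

    # Candidate boundaries: all exon starts and ends.  Sweeping adjacent
    # boundary pairs and keeping intervals covered by >=1 exon yields the
    # disjoint fragments; boundaries outside covered territory produce
    # uncovered (dropped) intervals, never spurious splits.
    bounds = sorted({e.start for e in exons} | {e.end for e in exons})
    intervals = sorted((e.start, e.end) for e in exons)
    fragments: list[tuple[int, int]] = []
    for lo, hi in zip(bounds, bounds[1:]):
        if any(s <= lo and hi <= t for s, t in intervals):
            fragments.append((lo, hi))

    # Merge nothing: adjacent fragments stay split because a boundary there
    # means an annotated splice site.
    return [
        SubExon(gene_id=gene_id, index=i, chrom=chrom, start=lo, end=hi, strand=strand)
        for i, (lo, hi) in enumerate(fragments, start=1)
    ]


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def iter_gtf_exons(gtf_path: str) -> Iterator[ExonRecord]:
    """Stream exon features from a GTF file as ExonRecord objects.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Raises ValueError with the line number for unparseable lines.
    """
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields[:9]
            if feature != "exon":
                continue
            try:
                start_i = int(start)
                end_i = int(end)
            except ValueError as exc:
                raise ValueError(f"{gtf_path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_gtf_attributes(attr)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ValueError(
                    f"{gtf_path}:{lineno}: exon lacks gene_id/transcript_id attributes"
                )
            yield ExonRecord(
                gene_id=attrs["gene_id"],
                transcript_id=attrs["transcript_id"],
                chrom=chrom,
                start=start_i - 1,  # 1-based closed -> 0-based half-open
                end=end_i,
                strand=strand,
            )


def flatten_annotation(
    gtf_path: str, on_multi_chrom: str = "split"
) -> dict[str, list[SubExon]]:
    """Flatten every gene in a GTF annotation into sub-exons.

    Parameters
    ----------
    gtf_path
        GTF file with exon features carrying gene_id and transcript_id.
    on_multi_chrom
        "split": a gene annotated on several chromosome/strand combinations
        is flattened per combination, with ids suffixed ``|chrom|strand``;
        "reject": such a gene raises.

    Returns
    -------
    dict mapping gene_id -> sorted sub-exon list.
    """
    if on_multi_chrom not in ("split", "reject"):
        raise ValueError(f"on_multi_chrom must be 'split' or 'reject', got {on_multi_chrom!r}")

    by_gene: dict[str, list[ExonRecord]] = {}
    n_exons = 0
    for rec in iter_gtf_exons(gtf_path):
        by_gene.setdefault(rec.gene_id, []).append(rec)
        n_exons += 1
    if n_exons == 0:
        warnings.warn(f"no exon features found in {gtf_path}", stacklevel=2)
        return {}

    result: dict[str, list[SubExon]] = {}
    for gene_id, exons in by_gene.items():
        locs = {(e.chrom, e.strand) for e in exons}
        if len(locs) == 1:
            result[gene_id] = flatten_gene(exons)
        elif on_multi_chrom == "reject":
            raise ValueError(
                f"gene {gene_id!r} spans multiple chromosome/strand combinations: {sorted(locs)}"
            )
        else:
            logger.warning("gene %s spans %d chrom/strand loci; splitting", gene_id, len(locs))
            for chrom, strand in sorted(locs):
                part = [e for e in exons if e.chrom == chrom and e.strand == strand]
                split_id = f"{gene_id}|{chrom}|{strand}"
                renamed = [
                    ExonRecord(split_id, e.transcript_id, e.chrom, e.start, e.end, e.strand)
                    for e in part
                ]
                result[split_id] = flatten_gene(renamed)
    return result


def write_subexon_table(subexons: dict[str, list[SubExon]], out_path: str) -> None:
    """Write the sub-exon definition table (TSV, 0-based half-open coordinates)."""
    with open(out_path, "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        fh.write("gene_id\tsubexon_index\tchrom\tstart\tend\tstrand\n")
        for gene_id in sorted(subexons):
            for se in subexons[gene_id]:
                fh.write(
                    f"{se.gene_id}\t{se.index}\t{se.chrom}\t{se.start}\t{se.end}\t{se.strand}\n"
                )
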