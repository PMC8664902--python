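"""CpG density and gene association for called DMRs.

A gene is associated with a DMR when the gap between the DMR interval
and the gene body is at most 10 kb (inclusive), a distance chosen to
take in both proximal and distal promoter regions. Association is to
the gene body, not the TSS, so strand never enters the distance; all
qualifying genes are reported, not just the nearest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dmr import DMR, DMRSet

__all__ = [
    "GeneRecord",
    "GeneAssociation",
    "cpg_density",
    "associate_genes",
    "category_tally",
    "read_genes_bed6",
    "read_genes_gff3",
    "read_category_map",
    "gene_set_overlap",
]

DEFAULT_MAX_DIST = 10_000
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    category: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")


@dataclass(frozen=True)
class GeneAssociation:
    dmr_name: str
    gene_id: str
    distance: int
    category: str = UNCLASSIFIED


def cpg_density(sequence: str) -> float:
    """CG dinucleotides per 100 bp of the given sequence.

    N bases are legal but never counted (``NG``/``CN`` are not CpGs).
    """
    if not sequence:
        raise ValueError("empty sequence has no defined CpG density")
    return sequence.upper().count("CG") / len(sequence) * 100.0


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Base pairs strictly between two half-open intervals (0 if they touch or intersect)."""
    return max(0, a_start - b_end, b_start - a_end)


def associate_genes(
    dmrs: DMRSet | Sequence[DMR],
    genes: Sequence[GeneRecord],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[GeneAssociation]:
    """All genes within ``max_dist`` bp (inclusive) of each DMR.

    Distance is the interval gap between [dmr.start, dmr.stop) and the
    gene body [gene.start, gene.end); overlapping pairs have distance 0.
    DMRs with no gene in range contribute no records.
    """
    dmr_list = list(dmrs.dmrs) if isinstance(dmrs, DMRSet) else list(dmrs)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneAssociation] = []
    for d in dmr_list:
        for g in by_chrom.get(d.chrom, ()):
            gap = _interval_gap(d.start, d.stop, g.start, g.end)
            if gap <= max_dist:
                out.append(GeneAssociation(d.name, g.gene_id, gap, g.category))
    return out


def category_tally(
    associations: Sequence[GeneAssociation],
    genes: Sequence[GeneRecord] | None = None,
) -> pd.Series:
    """DMR counts per functional gene category.

    A DMR counts once toward each *distinct* category among its
    associated genes: two signaling genes near one DMR still yield a
    single signaling count, but a DMR near both a signaling and a
    receptor gene counts in both categories.
    """
    cat_by_gene = {g.gene_id: g.category for g in genes} if genes is not None else None
    seen: set[tuple[str, str]] = set()
    for a in associations:
        cat = cat_by_gene.get(a.gene_id, a.category) if cat_by_gene else a.category
        seen.add((a.dmr_name, cat))
    tally = pd.Series([c for _, c in seen], dtype=object).value_counts().sort_index()
    tally.name = "n_dmrs"
    return tally


def read_genes_bed6(path: str | Path, category_map: Mapping[str, str] | None = None) -> list[GeneRecord]:
    """Gene bodies from BED6 (name column = gene_id)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    category_map = category_map or {}
    return [
        GeneRecord(
            gene_id=str(r["name"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
            category=category_map.get(str(r["name"]), UNCLASSIFIED),
        )
        for _, r in df.iterrows()
    ]


def read_genes_gff3(path: str | Path, category_map: Mapping[str, str] | None = None) -> list[GeneRecord]:
    """Gene features from GFF3; the ``gene_id`` (or ``ID``) attribute names the gene.

    GFF3 is 1-based inclusive; records are converted to the package's
    0-based half-open convention here, at this single boundary.
    """
    category_map = category_map or {}
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gid = attrs.get("gene_id") or attrs.get("ID")
            if gid is None:
                continue
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    category=category_map.get(gid, UNCLASSIFIED),
                )
            )
    return genes


def read_category_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV gene_id -> functional category."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"])
    return dict(zip(df["gene_id"].astype(str), df["category"].astype(str)))


def gene_set_overlap(
    associations: Sequence[GeneAssociation], gene_sets: Mapping[str, Iterable[str]]
) -> pd.Series:
    """Plain overlap counts of DMR-associated genes against named gene lists.

    Bookkeeping only — no enrichment statistic is attached.
    """
    assoc_genes = {a.gene_id for a in associations}
    counts = {name: len(assoc_genes & set(members)) for name, members in gene_sets.items()}
    out = pd.Series(counts, dtype=int).sort_index()
    out.name = "n_genes"
    return out


def annotate_dmrs(
    dmrs: DMRSet,
    genes: Sequence[GeneRecord],
    max_dist: int = DEFAULT_MAX_DIST,
) -> tuple[DMRSet, list[GeneAssociation]]:
    """Fill each DMR's gene and category lists in place; return associations."""
    assoc = associate_genes(dmrs, genes, max_dist=max_dist)
    by_dmr: dict[str, list[GeneAssociation]] = {}
    for a in assoc:
        by_dmr.setdefault(a.dmr_name, []).append(a)
    for d in dmrs.dmrs:
        mine = by_dmr.get(d.name, [])
        d.genes = sorted({a.gene_id for a in mine})
        d.categories = sorted({a.category for a in mine})
    return dmrs, assoc


def associations_to_frame(associations: Sequence[GeneAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dmr_name": [a.dmr_name for a in associations],
            "gene_id": [a.gene_id for a in associations],
            "distance": [a.distance for a in associations],
            "category": [a.category for a in associations],
        }
    )
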