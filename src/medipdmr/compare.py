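"""Cross-comparison DMR analytics.

Three views of how DMR sets from different comparisons relate:

* Venn-style membership counts at the strict threshold, where two DMRs
  overlap when their half-open intervals share at least 1 bp;
* the extended-overlap matrix, asking what fraction of one comparison's
  strict-threshold DMRs coincide with another comparison's significant
  windows at a relaxed threshold (the diagonal is 100% by construction
  whenever the row set is non-empty, since every strict window is also
  a relaxed window of its own comparison);
* chromosomal DMR clusters by single-linkage chaining of midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dmr import DMR, DMRSet

__all__ = [
    "OverlapMatrix",
    "venn_overlap",
    "extended_overlap",
    "find_clusters",
]


def _intervals(dmr_set: DMRSet) -> list[tuple[str, int, int]]:
    return [(d.chrom, d.start, d.stop) for d in dmr_set.dmrs]


def _intersects(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def _merge_intervals(ivs: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    merged: list[list] = []
    for chrom, start, end in sorted(ivs):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(m) for m in merged]


def venn_overlap(dmr_sets: Mapping[str, DMRSet]) -> pd.DataFrame:
    """Membership-pattern counts over the union of all DMR intervals.

    The union of every set's DMRs is merged into disjoint elements; each
    element is assigned the full pattern of comparisons whose DMRs it
    intersects, and patterns are counted. With identical input sets all
    mass lands on the all-sets pattern; with fully disjoint sets only
    singleton patterns are populated.
    """
    labels = list(dmr_sets)
    union = _merge_intervals([iv for s in dmr_sets.values() for iv in _intervals(s)])
    patterns: dict[tuple[str, ...], int] = {}
    for element in union:
        members = tuple(
            lab for lab in labels if any(_intersects(element, iv) for iv in _intervals(dmr_sets[lab]))
        )
        patterns[members] = patterns.get(members, 0) + 1
    rows = [
        {"pattern": "&".join(members), "n_sets": len(members), "count": n}
        for members, n in sorted(patterns.items())
    ]
    return pd.DataFrame(rows, columns=["pattern", "n_sets", "count"])


@dataclass
class OverlapMatrix:
    """Counts and percents of row-set DMRs hitting column-set relaxed windows."""

    row_labels: list[str]
    col_labels: list[str]
    counts: pd.DataFrame
    percents: pd.DataFrame
    row_totals: pd.Series

    def diagonal_percents(self) -> pd.Series:
        return pd.Series(
            {lab: self.percents.loc[lab, lab] for lab in self.row_labels if lab in self.col_labels}
        )

    def to_tsv(self, path) -> None:
        combined = self.counts.astype(str) + " (" + self.percents.round(1).astype(str) + "%)"
        combined.insert(0, "total_dmrs", self.row_totals)
        combined.to_csv(path, sep="\t", index_label="comparison")


def extended_overlap(
    strict_sets: Mapping[str, DMRSet],
    relaxed_results: Mapping[str, pd.DataFrame],
    p_strict: float = 1e-4,
    p_relaxed: float = 0.05,
) -> OverlapMatrix:
    """Overlap of strict DMR sets against relaxed significant windows.

    Entry (i, j) counts comparison-i DMRs (called at ``p_strict``) that
    intersect at least one window of comparison j with p < ``p_relaxed``,
    with the percent of row i's total alongside.
    """
    row_labels = list(strict_sets)
    col_labels = list(relaxed_results)
    for lab in row_labels:
        if lab not in relaxed_results:
            raise ValueError(f"no relaxed results supplied for comparison {lab!r}")
    counts = pd.DataFrame(0, index=row_labels, columns=col_labels, dtype=int)
    percents = pd.DataFrame(0.0, index=row_labels, columns=col_labels)
    relaxed_ivs: dict[str, list[tuple[str, int, int]]] = {}
    for lab, res in relaxed_results.items():
        sig = res.loc[res["p_value"] < p_relaxed]
        relaxed_ivs[lab] = list(
            zip(sig["chrom"].astype(str), sig["start"].astype(int), sig["end"].astype(int))
        )
    for rlab, dset in strict_sets.items():
        if abs(dset.p_threshold - p_strict) > 1e-12:
            raise ValueError(
                f"{rlab!r} was called at p={dset.p_threshold}, not the requested {p_strict}"
            )
        total = len(dset)
        for clab in col_labels:
            ivs = relaxed_ivs[clab]
            hit = sum(
                1
                for d in dset.dmrs
                if any(_intersects((d.chrom, d.start, d.stop), iv) for iv in ivs)
            )
            counts.loc[rlab, clab] = hit
            percents.loc[rlab, clab] = 100.0 * hit / total if total else 0.0
    return OverlapMatrix(row_labels, col_labels, counts, percents, pd.Series(
        {lab: len(strict_sets[lab]) for lab in row_labels}
    ))


def find_clusters(
    dmr_set: DMRSet, span: int = 2_000_000, min_dmrs: int = 3
) -> list[tuple[str, int, int, int]]:
    """Chromosomal DMR clusters by single-linkage chaining.

    Consecutive DMRs (midpoint order) at most ``span`` bp apart chain
    into one cluster; maximal chains with at least ``min_dmrs`` members
    are reported as (chrom, start, end, dmr_count) covering the member
    DMRs' full extent. The defaults (2 Mb, >=3) are package choices —
    clustering visualizations in this literature rarely state a rule.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if min_dmrs < 2:
        raise ValueError("min_dmrs must be at least 2")
    by_chrom: dict[str, list[DMR]] = {}
    for d in dmr_set.dmrs:
        by_chrom.setdefault(d.chrom, []).append(d)
    clusters = []
    for chrom in sorted(by_chrom):
        ds = sorted(by_chrom[chrom], key=lambda d: d.midpoint)
        chain = [ds[0]]
        for d in ds[1:]:
            if d.midpoint - chain[-1].midpoint <= span:
                chain.append(d)
            else:
                if len(chain) >= min_dmrs:
                    clusters.append((chrom, chain[0].start, chain[-1].stop, len(chain)))
                chain = [d]
        if len(chain) >= min_dmrs:
            clusters.append((chrom, chain[0].start, chain[-1].stop, len(chain)))
    return clusters


def clusters_to_bed4(clusters: Sequence[tuple[str, int, int, int]], path) -> None:
    pd.DataFrame(clusters, columns=["chrom", "start", "end", "dmr_count"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def karyotype_positions(dmr_sets: Mapping[str, DMRSet]) -> pd.DataFrame:
    """Long-form (comparison, chrom, midpoint) table for external plotting."""
    rows = [
        {"comparison": lab, "chrom": d.chrom, "position": d.midpoint}
        for lab, s in dmr_sets.items()
        for d in s.dmrs
    ]
    return pd.DataFrame(rows, columns=["comparison", "chrom", "position"])
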