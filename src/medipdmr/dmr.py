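"""DMR calling: threshold per-window results and merge adjacent windows.

A DMR is a maximal run of genomically contiguous significant windows
(p < threshold, strict) on one chromosome. Contiguity is zero-gap:
windows separated by a non-significant or filtered-out window form
separate DMRs. DMR boundaries are the union of the constituent
significant windows only — no extension into flanking windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .windowing import WindowSet

__all__ = [
    "DMR",
    "DMRSet",
    "call_dmrs",
    "threshold_ladder",
    "summarize_dmr",
    "size_and_density_distributions",
]

DEFAULT_P_THRESHOLD = 1e-4
LADDER_CUTOFFS = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7)


@dataclass
class DMR:
    """One merged region with the standard per-DMR summary columns.

    ``max_lfc`` is the signed log2 fold change of the constituent window
    with the largest \\|log_fc\\| (sign kept, so the direction of the
    strongest methylation change is visible); ``cpg_density`` is CG
    dinucleotides per 100 bp over [start, stop).
    """

    name: str
    chrom: str
    start: int
    stop: int
    n_sig_windows: int
    min_p: float
    min_fdr: float
    max_lfc: float
    cpg_count: int | None = None
    cpg_density: float | None = None
    genes: list[str] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"{self.name}: stop must exceed start")
        if self.n_sig_windows < 1:
            raise ValueError(f"{self.name}: needs at least one significant window")

    @property
    def length(self) -> int:
        return self.stop - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.stop) // 2


@dataclass
class DMRSet:
    comparison_label: str
    p_threshold: float
    dmrs: list[DMR]
    threshold_table: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.dmrs)

    def __iter__(self):
        return iter(self.dmrs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [d.name for d in self.dmrs],
                "chrom": [d.chrom for d in self.dmrs],
                "start": [d.start for d in self.dmrs],
                "stop": [d.stop for d in self.dmrs],
                "length": [d.length for d in self.dmrs],
                "n_sig_windows": [d.n_sig_windows for d in self.dmrs],
                "min_p": [d.min_p for d in self.dmrs],
                "min_fdr": [d.min_fdr for d in self.dmrs],
                "max_lfc": [d.max_lfc for d in self.dmrs],
                "cpg_count": [d.cpg_count for d in self.dmrs],
                "cpg_density": [d.cpg_density for d in self.dmrs],
                "genes": [";".join(d.genes) for d in self.dmrs],
                "categories": [";".join(d.categories) for d in self.dmrs],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bed6(self, path: str | Path) -> None:
        with np.errstate(divide="ignore"):
            scores = [-np.log10(d.min_p) if d.min_p > 0 else 999.0 for d in self.dmrs]
        pd.DataFrame(
            {
                "chrom": [d.chrom for d in self.dmrs],
                "start": [d.start for d in self.dmrs],
                "end": [d.stop for d in self.dmrs],
                "name": [d.name for d in self.dmrs],
                "score": scores,
                "strand": ["."] * len(self.dmrs),
            }
        ).to_csv(path, sep="\t", header=False, index=False)


def call_dmrs(
    results: pd.DataFrame,
    windows: WindowSet,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    comparison_label: str = "comparison",
    with_ladder: bool = True,
) -> DMRSet:
    """Group significant windows into maximal zero-gap runs.

    ``results`` is the difftest output (one row per tested window with
    ``window_index`` giving the genomic ordinal). Windows with
    p < ``p_threshold`` (strict) that are genomically adjacent — ordinals
    differ by 1 and lie on the same chromosome — merge into one DMR
    spanning the first window's start to the last window's end. Names
    are ``DMR_<chrom>_<k>`` in genomic order per chromosome.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    sig = results.loc[results["p_value"] < p_threshold].sort_values("window_index")
    dmrs: list[DMR] = []
    per_chrom_ordinal: dict[str, int] = {}
    run: list[pd.Series] = []

    def flush() -> None:
        if not run:
            return
        chrom = run[0]["chrom"]
        k = per_chrom_ordinal.get(chrom, 0) + 1
        per_chrom_ordinal[chrom] = k
        lfcs = [r["log_fc"] for r in run]
        dmrs.append(
            DMR(
                name=f"DMR_{chrom}_{k}",
                chrom=chrom,
                start=int(run[0]["start"]),
                stop=int(run[-1]["end"]),
                n_sig_windows=len(run),
                min_p=float(min(r["p_value"] for r in run)),
                min_fdr=float(min(r["q_value"] for r in run)),
                max_lfc=float(max(lfcs, key=abs)),
            )
        )
        run.clear()

    prev_idx = None
    prev_chrom = None
    for _, row in sig.iterrows():
        if run and not (row["window_index"] == prev_idx + 1 and row["chrom"] == prev_chrom):
            flush()
        run.append(row)
        prev_idx = row["window_index"]
        prev_chrom = row["chrom"]
    flush()

    ladder = threshold_ladder(results, windows=windows) if with_ladder else None
    return DMRSet(comparison_label, p_threshold, dmrs, threshold_table=ladder)


def threshold_ladder(
    results: pd.DataFrame,
    cutoffs: Sequence[float] = LADDER_CUTOFFS,
    windows: WindowSet | None = None,
) -> pd.DataFrame:
    """DMR counts at a ladder of p cutoffs.

    ``all_windows`` counts every DMR; ``multiple_windows`` only those
    merged from at least two adjacent significant windows. The number
    of significant windows is non-increasing as the cutoff tightens;
    DMR counts follow suit in the sparse-significance regime these
    scans operate in (a tighter cutoff can in principle split a run
    whose interior window drops out, but that requires adjacent
    significant windows straddling a marginal one).
    """
    rows = []
    for cutoff in cutoffs:
        ds = call_dmrs(results, windows, p_threshold=cutoff, with_ladder=False)
        rows.append(
            {
                "cutoff": cutoff,
                "all_windows": len(ds),
                "multiple_windows": sum(1 for d in ds if d.n_sig_windows >= 2),
            }
        )
    return pd.DataFrame(rows)


def _fetch(genome, chrom: str, start: int, stop: int) -> str:
    """Sequence accessor for GenomeModel, pyfaidx.Fasta, or a plain dict."""
    if hasattr(genome, "fetch"):
        return genome.fetch(chrom, start, stop)
    seq = genome[chrom]
    if not isinstance(seq, str):  # pyfaidx record
        if stop > len(seq):
            raise ValueError(f"{chrom}:{start}-{stop} beyond chromosome end")
        return str(seq[start:stop])
    return seq[start:stop]


def _chrom_length(genome, chrom: str) -> int:
    if hasattr(genome, "chrom_lengths"):
        return genome.chrom_lengths[chrom]
    return len(genome[chrom])


def summarize_dmr(dmr: DMR, genome) -> DMR:
    """Fill the CpG columns of a DMR from the genome sequence.

    ``genome`` may be a GenomeModel, a pyfaidx.Fasta, or a dict of
    chromosome strings. CG dinucleotides are counted by direct scan of
    [start, stop); density is per 100 bp.
    """
    if dmr.stop > _chrom_length(genome, dmr.chrom):
        raise ValueError(f"{dmr.name} extends beyond the end of {dmr.chrom}")
    seq = _fetch(genome, dmr.chrom, dmr.start, dmr.stop).upper()
    count = seq.count("CG")
    return replace(dmr, cpg_count=count, cpg_density=count / dmr.length * 100.0)


def summarize_dmrs(dmr_set: DMRSet, genome) -> DMRSet:
    return replace(dmr_set, dmrs=[summarize_dmr(d, genome) for d in dmr_set.dmrs])


def size_and_density_distributions(
    dmr_set: DMRSet,
    genome=None,
    length_bin_kb: float = 1.0,
    density_bin: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram tables of DMR lengths (kb bins) and CpG densities.

    Length falls in bin k when it lies in ((k-1), k] kilobases, so the
    canonical single-window 1 kb DMR sits in the 1 kb bin; density bin k
    covers [k*density_bin, (k+1)*density_bin). Both histograms sum to
    the number of DMRs.
    """
    lengths = np.array([d.length for d in dmr_set.dmrs], dtype=float)
    size_bins = np.ceil(lengths / (length_bin_kb * 1000.0)).astype(int) if len(lengths) else []
    size_table = (
        pd.Series(size_bins).value_counts().sort_index().rename("n_dmrs")
        .rename_axis("length_kb").reset_index()
    )

    densities = []
    for d in dmr_set.dmrs:
        if d.cpg_density is None:
            if genome is None:
                raise ValueError("density histogram needs summarized DMRs or a genome")
            d = summarize_dmr(d, genome)
        densities.append(d.cpg_density)
    dens_bins = np.floor(np.array(densities) / density_bin).astype(int) if densities else []
    dens_table = (
        pd.Series(dens_bins).value_counts().sort_index().rename("n_dmrs")
        .rename_axis("bin").reset_index()
    )
    if len(dens_table):
        dens_table["cpg_per_100bp_lo"] = dens_table["bin"] * density_bin
        dens_table["cpg_per_100bp_hi"] = (dens_table["bin"] + 1) * density_bin
        dens_table = dens_table.drop(columns="bin")
    return size_table, dens_table
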