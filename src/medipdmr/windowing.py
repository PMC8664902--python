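"""Fixed-width genomic windows and per-window fragment counting.

The genome is tiled into contiguous, non-overlapping windows (default
1 kb, BED-style 0-based half-open coordinates). Sonicated-fragment
intervals are assigned to windows by their midpoint, which makes
counting exactly invertible: re-emitting fragments whose midpoints lie
in a window and re-counting reproduces the original matrix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicWindow",
    "WindowSet",
    "CountMatrix",
    "tile_genome",
    "count_fragments",
    "filter_windows",
    "read_bed3",
    "read_chrom_sizes",
]

DEFAULT_WINDOW_SIZE = 1000


@dataclass(frozen=True)
class GenomicWindow:
    """One tiling window; ``index`` is its ordinal across the whole genome."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class WindowSet:
    """Ordered 1 kb tiling of a genome.

    Windows are contiguous within each chromosome, sorted by
    (chromosome, start), and partition the genome exactly; a trailing
    window shorter than ``window_size`` is kept (its true length is
    recorded, which matters for density arithmetic downstream).
    """

    def __init__(self, chrom_sizes: Mapping[str, int], window_size: int = DEFAULT_WINDOW_SIZE):
        if window_size < 100:
            raise ValueError(f"window_size must be >= 100, got {window_size}")
        names = list(chrom_sizes)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in chrom_sizes")
        self.window_size = int(window_size)
        self.chrom_sizes: dict[str, int] = {}
        self._offsets: dict[str, int] = {}  # ordinal of each chromosome's first window
        windows: list[GenomicWindow] = []
        for chrom, length in chrom_sizes.items():
            length = int(length)
            if length < 1:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
            self.chrom_sizes[chrom] = length
            self._offsets[chrom] = len(windows)
            for start in range(0, length, window_size):
                windows.append(
                    GenomicWindow(chrom, start, min(start + window_size, length), len(windows))
                )
        self.windows: list[GenomicWindow] = windows

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, index: int) -> GenomicWindow:
        return self.windows[index]

    def locate(self, chrom: str, pos: int) -> int | None:
        """Ordinal of the window containing base ``pos``, or None if off-genome."""
        length = self.chrom_sizes.get(chrom)
        if length is None or pos < 0 or pos >= length:
            return None
        return self._offsets[chrom] + pos // self.window_size

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
            }
        )

    def to_bed(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def tile_genome(
    chrom_sizes: Mapping[str, int] | str | Path, window_size: int = DEFAULT_WINDOW_SIZE
) -> WindowSet:
    """Tile a genome into fixed windows from a chrom.sizes mapping or file."""
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    return WindowSet(chrom_sizes, window_size=window_size)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    if df["chrom"].duplicated().any():
        raise ValueError(f"duplicate chromosome names in {path}")
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_bed3(path: str | Path) -> pd.DataFrame:
    """Read a (possibly gzipped) BED3 file into chrom/start/end columns."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(
            fh, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
        )
    df["chrom"] = df["chrom"].astype(str)
    return df


@dataclass
class CountMatrix:
    """Windows x samples fragment counts.

    ``window_index`` maps each row to its ordinal in ``windows`` so that
    filtered subsets keep their genomic identity. Library sizes are the
    column sums of the *unfiltered* matrix by construction; after
    filtering the original library sizes are retained so that
    normalization still reflects total sequencing depth.
    """

    windows: WindowSet
    samples: list[str]
    counts: np.ndarray
    window_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.samples):
            raise ValueError("counts must be a (windows, samples) matrix")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.window_index is None:
            self.window_index = np.arange(self.counts.shape[0])
        self.window_index = np.asarray(self.window_index)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def row_windows(self) -> list[GenomicWindow]:
        return [self.windows[i] for i in self.window_index]

    def to_frame(self) -> pd.DataFrame:
        labels = [self.windows[i].label for i in self.window_index]
        return pd.DataFrame(self.counts, index=labels, columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="window")


def count_fragments(
    fragments: Mapping[str, pd.DataFrame | str | Path],
    windows: WindowSet,
) -> tuple[CountMatrix, dict[str, int]]:
    """Count fragments per window per sample by the midpoint rule.

    ``fragments`` maps sample id to a BED3 path or a DataFrame with
    chrom/start/end. A fragment belongs to the window containing
    floor((start+end)/2). Fragments on unknown chromosomes or with
    off-chromosome midpoints are tallied per sample in the returned
    ``skipped`` dict, never silently dropped.
    """
    samples = list(fragments)
    counts = np.zeros((len(windows), len(samples)), dtype=np.int64)
    skipped: dict[str, int] = {}
    for j, sample in enumerate(samples):
        bed = fragments[sample]
        if not isinstance(bed, pd.DataFrame):
            bed = read_bed3(bed)
        n_skip = 0
        for chrom, sub in bed.groupby("chrom", sort=False):
            length = windows.chrom_sizes.get(str(chrom))
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            if length is None:
                n_skip += len(sub)
                continue
            ok = (mids >= 0) & (mids < length)
            n_skip += int((~ok).sum())
            idx = windows._offsets[str(chrom)] + mids[ok] // windows.window_size
            np.add.at(counts[:, j], idx, 1)
        skipped[sample] = n_skip
    return CountMatrix(windows, samples, counts), skipped


def filter_windows(counts: CountMatrix, min_avg_count: float = 5) -> CountMatrix:
    """Drop windows whose mean count across samples is below threshold.

    Retains windows with mean >= ``min_avg_count`` (inclusive). The
    returned matrix's ``window_index`` preserves genomic identity and
    original library sizes are carried over unchanged.
    """
    if min_avg_count < 0:
        raise ValueError("min_avg_count must be >= 0")
    keep = counts.counts.mean(axis=1) >= min_avg_count
    if not keep.any():
        raise ValueError(
            f"min_avg_count={min_avg_count} removes every window; lower the threshold"
        )
    return CountMatrix(
        counts.windows,
        counts.samples,
        counts.counts[keep],
        window_index=counts.window_index[keep],
        library_sizes=counts.library_sizes,
    )
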