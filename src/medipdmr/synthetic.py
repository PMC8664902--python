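"""Synthetic genome, cohort and MeDIP-style count/fragment generation.

Every downstream stage of the pipeline (counting, testing, DMR calling,
overlap, PCA) is exercised against data from this module, whose injected
differential regions are recorded in a :class:`GroundTruth` registry so
recovery can be measured exactly.

The model, briefly: a small genome is built with a designed CpG-density
landscape (defaults sit in the 1-3 CpG/100 bp "CpG desert" range typical
of the regions this pipeline targets); per-window MeDIP enrichment counts
are negative-binomial with mean proportional to window CpG density
(methylated-CpG pull-down) scaled to each sample's library size, and
variance mu + phi*mu^2; case samples have their mean multiplied by
2**lfc inside injected regions. Counts are optionally realised as
sonicated fragment intervals (150-300 bp) whose midpoints fall in the
source window, making fragment emission and midpoint counting exact
inverses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .windowing import CountMatrix, WindowSet

__all__ = [
    "ChromSpec",
    "GenomeModel",
    "CohortSample",
    "GroundTruth",
    "generate_genome",
    "simulate_cohort",
    "default_truth",
    "simulate_window_counts",
    "emit_fragments",
    "write_fasta",
    "write_sample_sheet",
    "write_fragments_bed",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
NON_G = np.frombuffer(b"ACT", dtype="S1")  # choices after a C, so no stray CG arises


@dataclass(frozen=True)
class ChromSpec:
    """Design for one chromosome: length plus CpG-density regions.

    ``regions`` is a list of (start, end, density) with density in CpG
    per 100 bp; uncovered stretches fall back to ``default_density``.
    """

    name: str
    length: int
    regions: tuple[tuple[int, int, float], ...] = ()
    default_density: float = 2.0


@dataclass
class GenomeModel:
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str]
    cpg_profile: dict[str, list[tuple[int, int, float]]]

    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chrom_lengths)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequence[chrom][start:end]


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    group: str  # "control" | "case"
    age: float
    race: str
    cell_type: str
    library_size: float

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"{self.sample_id}: library_size must be positive")
        if not self.group:
            raise ValueError("group must be non-empty")


@dataclass
class GroundTruth:
    """Registry of injected differential regions.

    ``regions`` holds (chrom, start, end, true_lfc, n_windows) tuples
    aligned to window boundaries; ``true_lfc`` is log2 case/control,
    positive meaning a methylation gain in the case arm. ``baseline_mu``
    (per-window expected control count at the mean library size) is
    filled in by :func:`simulate_window_counts`.
    """

    regions: list[tuple[str, int, int, float, int]] = field(default_factory=list)
    baseline_mu: np.ndarray | None = None
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for r in self.regions:
            if r[3] == 0:
                raise ValueError(f"injected region {r} has true_lfc == 0")
        ivs = sorted((r[0], r[1], r[2]) for r in self.regions)
        for a, b in zip(ivs, ivs[1:]):
            if a[0] == b[0] and b[1] < a[2]:
                raise ValueError(f"injected regions overlap: {a} and {b}")

    def window_lfc(self, windows: WindowSet) -> np.ndarray:
        """Per-window true log2 fold change (0 outside injected regions)."""
        lfc = np.zeros(len(windows))
        for chrom, start, end, true_lfc, _ in self.regions:
            if chrom not in windows.chrom_sizes:
                raise ValueError(f"truth region on unknown chromosome {chrom!r}")
            if start < 0 or end > windows.chrom_sizes[chrom]:
                raise ValueError(f"truth region {chrom}:{start}-{end} outside genome bounds")
            first = windows.locate(chrom, start)
            last = windows.locate(chrom, end - 1)
            lfc[first : last + 1] = true_lfc
        return lfc

    def window_indices(self, windows: WindowSet) -> np.ndarray:
        return np.flatnonzero(self.window_lfc(windows))

    def to_bed6(self, path: str | Path) -> None:
        rows = [
            (chrom, start, end, f"truth_{i}", f"{lfc:g}", ".")
            for i, (chrom, start, end, lfc, _) in enumerate(self.regions)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _place_cpgs(region_len: int, n_cpg: int, rng: np.random.Generator) -> np.ndarray:
    """Starts of n non-overlapping CG dinucleotides in [0, region_len)."""
    if n_cpg == 0:
        return np.empty(0, dtype=np.int64)
    # bijection: choose n increasing values from region_len - n slots,
    # shift the i-th by i to make room for length-2 blocks
    picks = np.sort(rng.choice(region_len - n_cpg, size=n_cpg, replace=False))
    return picks + np.arange(n_cpg)


def _cg_free_backbone(region_len: int, rng: np.random.Generator) -> np.ndarray:
    """Random A/C/G/T bytes containing no CG dinucleotide at all."""
    seq = BASES[rng.integers(0, 4, size=region_len)]
    # wherever a C..G pair appears, redraw the G from {A,C,T}; a redrawn C
    # can create a new pair with its right neighbour, so iterate
    for _ in range(64):
        bad = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        if bad.size == 0:
            return seq
        seq[bad + 1] = NON_G[rng.integers(0, 3, size=bad.size)]
    for i in np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G")):
        seq[i + 1] = b"A"
    return seq


def _fill_region(region_len: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Random A/C/G/T bytes with CG dinucleotides only at designed sites."""
    if not 0 <= density <= 50:
        raise ValueError(f"CpG density target {density} outside [0, 50] per 100 bp")
    n_cpg = rng.binomial(region_len, density / 100.0) if density > 0 else 0
    n_cpg = min(n_cpg, region_len // 2)
    seq = _cg_free_backbone(region_len, rng)
    pos = _place_cpgs(region_len, n_cpg, rng)
    if pos.size:
        seq[pos] = b"C"
        seq[pos + 1] = b"G"
        # a designed C right before a backbone G would add a stray CG
        nxt = pos + 2
        nxt = nxt[nxt < region_len]
        stray = nxt[(seq[nxt] == b"G") & ~np.isin(nxt, pos)]
        seq[stray] = b"A"
    return seq


def generate_genome(chroms: Sequence[ChromSpec], seed: int) -> GenomeModel:
    """Build a random genome realising each region's target CpG density.

    Reproducible for a fixed seed; realised density tracks the target to
    binomial accuracy (well within +/-30% for regions of 2 kb and up at
    the default 1-3 CpG/100 bp targets).
    """
    rng = np.random.default_rng(seed)
    names, lengths, seqs, profile = [], {}, {}, {}
    for spec in chroms:
        if spec.length <= 0:
            raise ValueError(f"chromosome {spec.name!r} has zero or negative length")
        # resolve the density profile into a full partition of the chromosome
        segs: list[tuple[int, int, float]] = []
        cursor = 0
        for start, end, dens in sorted(spec.regions):
            if start < cursor or end > spec.length:
                raise ValueError(f"bad region ({start}, {end}) on {spec.name}")
            if start > cursor:
                segs.append((cursor, start, spec.default_density))
            segs.append((start, end, dens))
            cursor = end
        if cursor < spec.length:
            segs.append((cursor, spec.length, spec.default_density))
        parts = [_fill_region(e - s, d, rng) for s, e, d in segs]
        seq = np.concatenate(parts) if parts else np.empty(0, dtype="S1")
        # seam repair: joining two parts can abut a trailing C and a leading G
        boundaries = np.cumsum([e - s for s, e, _ in segs])[:-1]
        for b in boundaries:
            if seq[b - 1] == b"C" and seq[b] == b"G":
                seq[b] = b"A"
        names.append(spec.name)
        lengths[spec.name] = spec.length
        seqs[spec.name] = seq.tobytes().decode("ascii")
        profile[spec.name] = [(s, e, d) for s, e, d in segs]
    return GenomeModel(names, lengths, seqs, profile)


def simulate_cohort(
    n_control: int,
    n_case: int,
    age_range: tuple[float, float] = (30.0, 75.0),
    seed: int = 0,
    mean_library_size: float = 2.5e5,
    library_cv: float = 0.2,
    race: str = "Caucasian",
    cell_type: str = "buccal",
) -> list[CohortSample]:
    """Draw a two-arm cohort with per-sample library-size variation.

    Library sizes are log-normal around ``mean_library_size`` with
    coefficient of variation ``library_cv``; ages are uniform on
    ``age_range`` and carried descriptively (they never influence
    counts). Each arm needs n >= 2 or downstream dispersion estimation
    is impossible.
    """
    if n_control < 2 or n_case < 2:
        raise ValueError("need at least 2 samples per arm (dispersion estimation)")
    rng = np.random.default_rng(seed)
    samples = []
    sigma = float(np.sqrt(np.log1p(library_cv**2)))
    for group, n, prefix in (("control", n_control, "C"), ("case", n_case, "T")):
        for i in range(n):
            lib = float(
                mean_library_size * np.exp(rng.normal(-(sigma**2) / 2, sigma))
            )
            samples.append(
                CohortSample(
                    sample_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    age=float(np.round(rng.uniform(*age_range), 1)),
                    race=race,
                    cell_type=cell_type,
                    library_size=lib,
                )
            )
    return samples


def default_truth(
    windows: WindowSet,
    n_regions: int = 8,
    lfc: float = 2.0,
    n_windows_choices: Sequence[int] = (1, 2, 3),
    dispersion: float = 0.1,
    seed: int = 0,
) -> GroundTruth:
    """Place non-overlapping differential regions on window boundaries.

    Signs alternate so roughly half the injected regions gain and half
    lose methylation; widths are drawn from ``n_windows_choices``.
    """
    rng = np.random.default_rng(seed)
    taken: list[tuple[str, int, int]] = []
    regions = []
    full = [w for w in windows if w.length == windows.window_size]
    attempts = 0
    while len(regions) < n_regions and attempts < 1000 * n_regions:
        attempts += 1
        k = int(rng.choice(list(n_windows_choices)))
        w = full[int(rng.integers(len(full)))]
        start, end = w.start, w.start + k * windows.window_size
        if end > windows.chrom_sizes[w.chrom]:
            continue
        # keep a one-window gap so injected regions never merge
        pad = windows.window_size
        if any(c == w.chrom and start < e + pad and s - pad < end for c, s, e in taken):
            continue
        sign = 1 if len(regions) % 2 == 0 else -1
        regions.append((w.chrom, start, end, sign * abs(lfc), k))
        taken.append((w.chrom, start, end))
    if len(regions) < n_regions:
        raise ValueError("could not place the requested number of truth regions")
    regions.sort()
    return GroundTruth(regions=regions, dispersion=dispersion)


def window_cpg_density(genome: GenomeModel, windows: WindowSet) -> np.ndarray:
    """Observed CG dinucleotides per 100 bp for every window."""
    dens = np.empty(len(windows))
    for w in windows:
        seq = genome.sequence[w.chrom]
        dens[w.index] = seq.count("CG", w.start, w.end) / w.length * 100.0
    return dens


def simulate_window_counts(
    genome: GenomeModel,
    windows: WindowSet,
    cohort: Sequence[CohortSample],
    truth: GroundTruth,
    seed: int = 0,
) -> CountMatrix:
    """Draw NB per-window counts for every sample.

    The baseline relative enrichment of window w is
    ``(1 + 0.5 * d_w) * len_w / window_size`` with d_w the window's CpG
    density (CpG/100 bp) — MeDIP pull-down scales with methylatable
    CpGs — normalised so a control sample's expected total equals its
    library size. Case samples have the mean multiplied by
    ``2**true_lfc`` inside injected regions. Variance is
    mu + phi*mu^2 (gamma-Poisson mixture); phi = 0 gives Poisson.
    """
    rng = np.random.default_rng(seed)
    dens = window_cpg_density(genome, windows)
    rel = (1.0 + 0.5 * dens) * np.array([w.length for w in windows]) / windows.window_size
    p = rel / rel.sum()
    lfc = truth.window_lfc(windows)
    mean_lib = float(np.mean([s.library_size for s in cohort]))
    truth.baseline_mu = p * mean_lib
    phi = truth.dispersion
    counts = np.empty((len(windows), len(cohort)), dtype=np.int64)
    for j, s in enumerate(cohort):
        mu = p * s.library_size
        if s.group == "case":
            mu = mu * np.exp2(lfc)
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    return CountMatrix(windows, [s.sample_id for s in cohort], counts)


def emit_fragments(
    counts: CountMatrix,
    windows: WindowSet,
    frag_len_range: tuple[int, int] = (150, 300),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Realise counts as sonicated-fragment BED3 intervals per sample.

    Each count becomes one fragment with length uniform on
    ``frag_len_range`` and midpoint uniform within its source window, so
    midpoint re-counting reproduces the matrix exactly. Fragments
    running off a chromosome end are shrunk symmetrically about the
    midpoint instead of shifted, preserving the midpoint rule.
    """
    lo, hi = frag_len_range
    if not (50 <= lo <= hi <= 1000):
        raise ValueError("frag_len_range must lie within [50, 1000]")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    row_windows = counts.row_windows()
    for j, sample in enumerate(counts.samples):
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        for w, c in zip(row_windows, counts.counts[:, j]):
            if c == 0:
                continue
            chrom_len = windows.chrom_sizes[w.chrom]
            mids = rng.integers(w.start, w.end, size=c)
            lens = rng.integers(lo, hi + 1, size=c)
            s = mids - lens // 2
            e = s + lens
            clip = (s < 0) | (e > chrom_len)
            if clip.any():
                h = np.minimum.reduce(
                    [lens[clip] // 2, mids[clip], chrom_len - mids[clip] - 1]
                )
                h = np.maximum(h, 0)
                s[clip] = mids[clip] - h
                e[clip] = mids[clip] + h + 1
            chroms.extend([w.chrom] * int(c))
            starts.extend(s.tolist())
            ends.extend(e.tolist())
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        out[sample] = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return out


def write_fasta(genome: GenomeModel, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequence[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sample_sheet(cohort: Sequence[CohortSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort],
            "group": [s.group for s in cohort],
            "age": [s.age for s in cohort],
            "race": [s.race for s in cohort],
            "cell_type": [s.cell_type for s in cohort],
        }
    ).to_csv(path, sep="\t", index=False)


def write_fragments_bed(fragments: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, df in fragments.items():
        p = outdir / f"{sample}.bed"
        df.to_csv(p, sep="\t", header=False, index=False)
        paths[sample] = p
    return paths
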