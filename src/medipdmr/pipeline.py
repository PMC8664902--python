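"""End-to-end orchestration, configuration and cohort descriptives.

``run_comparison`` composes the whole analysis: count fragments into
1 kb windows, filter, TMM-normalize, estimate dispersion, exact-test,
call and summarize DMRs, annotate genes, and run PCA over the DMR
windows — writing every table plus a manifest of checksums, so a rerun
with the same configuration is byte-identical.

``summarize_cohort`` reproduces the standard cohort table: per-group n,
mean age, SEM (sample SD over sqrt(n)) and a two-group Student t-test.
Per-subject ages from a published rheumatoid-arthritis case/control
cohort ship here as ``REFERENCE_AGES`` so its printed descriptive
statistics can be recomputed from first principles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import annotate as annotate_mod
from . import compare as compare_mod
from . import dmr as dmr_mod
from . import pca as pca_mod
from . import synthetic, windowing
from .difftest import estimate_dispersion, exact_test, tmm_factors

__all__ = [
    "ComparisonConfig",
    "CohortSummary",
    "REFERENCE_AGES",
    "summarize_cohort",
    "simulate_inputs",
    "run_comparison",
]

log = logging.getLogger("medipdmr")

# Per-subject ages from a published rheumatoid-arthritis EWAS cohort
# (female buccal/monocyte donors; "anw" = Caucasian clinic arm, "aa" =
# African American arm). Used to recompute the cohort table's means,
# SEMs and between-group t-tests exactly.
REFERENCE_AGES: dict[str, list[int]] = {
    "anw_control": [74, 56, 39, 56, 59, 68, 55, 70, 49, 62, 30, 51, 45],
    "anw_ra": [73, 61, 41, 56, 57, 66, 50, 74, 54, 68, 26, 48, 48],
    "aa_control": [55, 52, 55, 57, 52, 58, 65, 61, 57],
    "aa_ra": [55, 51, 53, 56, 58, 52, 53, 50, 51, 50, 52, 52, 63],
}


@dataclass
class ComparisonConfig:
    label: str = "synthetic"
    sample_sheet: str | None = None
    fragments_dir: str | None = None
    genome: str | None = None
    annotation: str | None = None
    category_map: str | None = None
    truth_bed: str | None = None  # injected-region BED6 (synthetic runs): recall goes in the manifest
    window_size: int = 1000
    p_threshold: float = 1e-4
    relaxed_threshold: float = 0.05
    gene_distance: int = 10_000
    min_avg_count: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "relaxed_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.p_threshold > self.relaxed_threshold:
            raise ValueError("p_threshold must not exceed relaxed_threshold")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ComparisonConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroupStats:
    n: int
    mean_age: float
    sem_age: float | None


@dataclass
class CohortSummary:
    groups: dict[str, GroupStats]
    t_statistic: float | None
    p_value: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.groups),
                "n": [g.n for g in self.groups.values()],
                "mean_age": [g.mean_age for g in self.groups.values()],
                "sem_age": [g.sem_age for g in self.groups.values()],
            }
        )


def summarize_cohort(
    sample_sheet: pd.DataFrame | str | Path,
    welch: bool = False,
) -> CohortSummary:
    """Per-group age mean and SEM plus a between-group Student t-test.

    SEM uses the sample standard deviation (n-1 denominator) over
    sqrt(n); a singleton group gets SEM None with a warning. The t-test
    is pooled-variance by default (``welch=True`` switches it off) and
    runs only when exactly two groups are present.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = pd.read_csv(sample_sheet, sep="\t")
    if (sample_sheet["age"] <= 0).any():
        raise ValueError("ages must be positive")
    groups: dict[str, GroupStats] = {}
    for name, sub in sample_sheet.groupby("group", sort=False):
        ages = sub["age"].to_numpy(dtype=float)
        if len(ages) < 2:
            log.warning("group %r has a single sample; SEM undefined", name)
            sem = None
        else:
            sem = float(np.std(ages, ddof=1) / np.sqrt(len(ages)))
        groups[str(name)] = GroupStats(len(ages), float(np.mean(ages)), sem)
    t_stat = p_val = None
    labels = list(groups)
    if len(labels) == 2:
        a = sample_sheet.loc[sample_sheet["group"] == labels[0], "age"]
        b = sample_sheet.loc[sample_sheet["group"] == labels[1], "age"]
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return CohortSummary(groups, t_stat, p_val)


DEFAULT_CHROMS = (
    synthetic.ChromSpec("chr1", 1_000_000),
    synthetic.ChromSpec("chr2", 1_000_000),
)


def simulate_inputs(
    outdir: str | Path,
    seed: int = 0,
    chroms: Sequence[synthetic.ChromSpec] = DEFAULT_CHROMS,
    n_control: int = 13,
    n_case: int = 13,
    n_truth_regions: int = 8,
    true_lfc: float = 2.0,
    dispersion: float = 0.1,
    window_size: int = 1000,
) -> ComparisonConfig:
    """Write a complete synthetic input directory and a matching config.

    Produces genome FASTA, chrom.sizes, per-sample fragment BED3 files,
    sample sheet, a truth BED6 (injected log2 fold change in the score
    column) and a toy gene annotation placed around the truth regions so
    the annotation stage has something to find.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_genome, s_cohort, s_truth, s_counts, s_frags = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    genome = synthetic.generate_genome(chroms, seed=s_genome)
    windows = windowing.tile_genome(genome.chrom_sizes(), window_size=window_size)
    cohort = synthetic.simulate_cohort(n_control, n_case, seed=s_cohort)
    truth = synthetic.default_truth(
        windows, n_regions=n_truth_regions, lfc=true_lfc,
        dispersion=dispersion, seed=s_truth,
    )
    counts = synthetic.simulate_window_counts(genome, windows, cohort, truth, seed=s_counts)
    frags = synthetic.emit_fragments(counts, windows, seed=s_frags)

    synthetic.write_fasta(genome, outdir / "genome.fa")
    pd.DataFrame(genome.chrom_sizes().items()).to_csv(
        outdir / "genome.chrom.sizes", sep="\t", header=False, index=False
    )
    synthetic.write_sample_sheet(cohort, outdir / "samples.tsv")
    synthetic.write_fragments_bed(frags, outdir / "fragments")
    truth.to_bed6(outdir / "truth.bed")

    # toy annotation: one gene overlapping every other truth region plus
    # a handful of background genes, with a small category vocabulary
    genes = []
    cats = ["signaling", "transcription", "metabolism", "receptor"]
    for i, (chrom, start, end, _, _) in enumerate(truth.regions):
        if i % 2 == 0:
            genes.append((chrom, max(0, start - 2000), end + 2000, f"GENE{i + 1:03d}", 0, "+"))
    rng = np.random.default_rng(s_genome + 1)
    for i in range(10):
        chrom = genome.chrom_names[i % len(genome.chrom_names)]
        g_start = int(rng.integers(0, genome.chrom_lengths[chrom] - 5000))
        genes.append((chrom, g_start, g_start + 5000, f"BG{i + 1:03d}", 0, "-"))
    pd.DataFrame(genes).to_csv(outdir / "genes.bed", sep="\t", header=False, index=False)
    pd.DataFrame(
        {"gene_id": [g[3] for g in genes], "category": [cats[i % 4] for i in range(len(genes))]}
    ).to_csv(outdir / "categories.tsv", sep="\t", header=False, index=False)

    cfg = ComparisonConfig(
        label="synthetic",
        sample_sheet=str(outdir / "samples.tsv"),
        fragments_dir=str(outdir / "fragments"),
        genome=str(outdir / "genome.fa"),
        annotation=str(outdir / "genes.bed"),
        category_map=str(outdir / "categories.tsv"),
        truth_bed=str(outdir / "truth.bed"),
        window_size=window_size,
        seed=seed,
    )
    cfg.to_yaml(outdir / "config.yaml")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_comparison(config: ComparisonConfig, outdir: str | Path) -> dict:
    """Run every stage and write the six output tables plus a manifest.

    Outputs: counts.tsv, results.tsv, dmrs.tsv (plus dmrs.bed),
    annotations.tsv, pca_scores.tsv / pca_variance.tsv,
    threshold_ladder.tsv, cohort_stats.tsv and manifest.json. Returns
    the manifest dict. Deterministic for a fixed configuration.
    """
    import pyfaidx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load-inputs"
    try:
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        frag_dir = Path(config.fragments_dir)
        fragments = {
            str(r["sample_id"]): frag_dir / f"{r['sample_id']}.bed"
            for _, r in sheet.iterrows()
        }
        genome = pyfaidx.Fasta(config.genome)
        chrom_sizes = {name: len(genome[name]) for name in genome.keys()}

        stage = "count"
        windows = windowing.tile_genome(chrom_sizes, window_size=config.window_size)
        counts, skipped = windowing.count_fragments(fragments, windows)
        log.info("counted %d windows x %d samples (skipped: %s)", counts.n_windows,
                 counts.n_samples, sum(skipped.values()))
        counts.to_tsv(outdir / "counts.tsv")

        stage = "filter"
        kept = windowing.filter_windows(counts, min_avg_count=config.min_avg_count)
        log.info("%d/%d windows pass min_avg_count=%s", kept.n_windows,
                 counts.n_windows, config.min_avg_count)

        stage = "test"
        groups = sheet.set_index("sample_id").loc[list(kept.samples), "group"].tolist()
        norm = tmm_factors(kept)
        disp = estimate_dispersion(kept, groups, norm)
        results = exact_test(kept, groups, norm, disp)
        results.to_csv(outdir / "results.tsv", sep="\t", index=False)
        log.info("common dispersion %.4f", disp.common_phi)

        stage = "call-dmrs"
        dmr_set = dmr_mod.call_dmrs(
            results, windows, p_threshold=config.p_threshold,
            comparison_label=config.label,
        )
        dmr_set = dmr_mod.summarize_dmrs(dmr_set, genome)
        dmr_set.threshold_table.to_csv(outdir / "threshold_ladder.tsv", sep="\t", index=False)
        log.info("%d DMRs at p<%g", len(dmr_set), config.p_threshold)

        stage = "annotate"
        associations = []
        if config.annotation:
            cat_map = (
                annotate_mod.read_category_map(config.category_map)
                if config.category_map
                else None
            )
            genes = annotate_mod.read_genes_bed6(config.annotation, cat_map)
            dmr_set, associations = annotate_mod.annotate_dmrs(
                dmr_set, genes, max_dist=config.gene_distance
            )
        dmr_set.to_tsv(outdir / "dmrs.tsv")
        dmr_set.to_bed6(outdir / "dmrs.bed")
        annotate_mod.associations_to_frame(associations).to_csv(
            outdir / "annotations.tsv", sep="\t", index=False
        )

        stage = "pca"
        if len(dmr_set):
            kept_set = set(kept.window_index.tolist())
            dmr_windows: set[int] = set()
            for d in dmr_set.dmrs:
                first = windows.locate(d.chrom, d.start)
                last = windows.locate(d.chrom, d.stop - 1)
                dmr_windows.update(w for w in range(first, last + 1) if w in kept_set)
            mat = pca_mod.normalize_for_pca(kept, sorted(dmr_windows), norm)
            pca_res = pca_mod.compute_pca(mat)
            pca_res.to_scores_tsv(outdir / "pca_scores.tsv", groups=groups)
            pca_res.to_variance_tsv(outdir / "pca_variance.tsv")

        stage = "cohort-stats"
        summarize_cohort(sheet).to_frame().to_csv(
            outdir / "cohort_stats.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    recall = None
    if config.truth_bed:
        truth_df = pd.read_csv(
            config.truth_bed, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "lfc", "strand"],
        )
        truth_windows: set[int] = set()
        for _, r in truth_df.iterrows():
            first = windows.locate(str(r["chrom"]), int(r["start"]))
            last = windows.locate(str(r["chrom"]), int(r["end"]) - 1)
            truth_windows.update(range(first, last + 1))
        called: set[int] = set()
        for d in dmr_set.dmrs:
            first = windows.locate(d.chrom, d.start)
            last = windows.locate(d.chrom, d.stop - 1)
            called.update(range(first, last + 1))
        recall = len(truth_windows & called) / len(truth_windows) if truth_windows else None

    stage = "manifest"
    cfg_text = yaml.safe_dump(asdict(config), sort_keys=True)
    files = sorted(p for p in outdir.glob("*.tsv")) + sorted(outdir.glob("*.bed"))
    manifest = {
        "label": config.label,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "config": asdict(config),
        "n_windows": len(windows),
        "n_tested_windows": int(kept.n_windows),
        "n_dmrs": len(dmr_set),
        "truth_window_recall": recall,
        "skipped_fragments": skipped,
        "runtime_s": round(time.time() - t0, 2),
        "outputs": {
            p.name: {"sha256": _sha256(p), "rows": sum(1 for _ in open(p))} for p in files
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
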