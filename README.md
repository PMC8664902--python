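# medipdmr

Window-based differential DNA methylation analysis for MeDIP-seq data.

MeDIP-seq (methylated-DNA immunoprecipitation sequencing) pulls down
sonicated 150–300 bp fragments with a 5-methylcytosine antibody and
sequences them, yielding genome-wide *enrichment counts* rather than
per-base methylation fractions. Epigenome-wide association studies built
on MeDIP-seq — for example comparing buccal-cell or monocyte methylomes
between disease cases and controls — tile the genome into fixed 1 kb
windows, test each window's counts between groups, and merge adjacent
significant windows into **differential DNA methylation regions (DMRs)**
that serve as candidate epigenetic biomarkers. `medipdmr` implements
that full analysis as a tested, reusable Python library:

* **synthetic data** — a generator for small genomes with designed CpG
  density landscapes, two-arm cohorts, negative-binomial window counts
  and sonicated-fragment BED files, with every injected DMR recorded in
  a ground-truth registry so recovery is measurable;
* **windowing** — 1 kb tiling and midpoint-rule fragment counting
  (exactly invertible against the generator);
* **difftest** — the two-group count test: TMM normalization, qCML
  common (plus tagwise empirical-Bayes) NB dispersion, an exact
  conditional test of group sums, and Benjamini–Hochberg FDR;
* **dmr calling** — strict-threshold window selection (default
  p < 1e-4), zero-gap merging of adjacent significant windows,
  threshold-ladder tables, CpG count/density summaries;
* **annotate** — gene association within 10 kb of the DMR (gene-body
  gap, strand-agnostic) and functional-category tallies;
* **compare** — Venn membership counts, the extended-overlap matrix
  (strict DMRs vs another comparison's relaxed p < 0.05 windows), and
  chromosomal DMR clusters;
* **pca** — log₂(CPM+1) over DMR windows, deterministic SVD scores.

## The statistical core

Counts for window *w* in sample *j* are modelled as negative binomial
with mean μ<sub>wj</sub> and variance μ + φμ² (dispersion φ). Library
composition is normalized by TMM (trimmed mean of M-values: 30% trim on
M, 5% on A, precision-weighted); counts are then mapped to a common
library size by quantile-to-quantile NB adjustment. The common φ
maximizes the conditional log-likelihood given group sums (qCML), and
each window is tested with a two-sided exact conditional test of the
case group sum given the total — doubling the smaller tail, capped
at 1. Windows with p below the strict threshold merge into DMRs when
genomically contiguous; each DMR reports its span, number of
significant windows, minimum p and FDR q, signed max log₂ fold change
(positive = methylation gain in cases), and CpG count/density. The
implementation is validated test-for-test against Bioconductor edgeR on
shared fixtures (TMM factors agree to ≤1e-5, common dispersion to <2%,
p-values to <0.1 in log10).

## Worked example

```python
import medipdmr as m
from medipdmr.synthetic import ChromSpec

genome = m.generate_genome([ChromSpec("chr1", 1_000_000), ChromSpec("chr2", 1_000_000)], seed=42)
windows = m.tile_genome(genome.chrom_sizes())          # 2,000 x 1 kb windows
cohort = m.simulate_cohort(13, 13, seed=43)            # 13 controls + 13 cases
truth = m.default_truth(windows, n_regions=8, lfc=2.0, n_windows_choices=(2, 3), seed=44)
counts = m.simulate_window_counts(genome, windows, cohort, truth, seed=45)

kept = m.filter_windows(counts, min_avg_count=5)
groups = [s.group for s in cohort]
norm = m.tmm_factors(kept)
disp = m.estimate_dispersion(kept, groups, norm)
results = m.exact_test(kept, groups, norm, disp)
dmrs = m.call_dmrs(results, windows, p_threshold=1e-4)

print(f"common dispersion: {disp.common_phi:.3f}")
print(f"{len(dmrs)} DMRs from {int((results.p_value < 1e-4).sum())} significant windows")
```

prints

```
common dispersion: 0.100
8 DMRs from 21 significant windows
```

— the generator's dispersion (φ = 0.1) is recovered and all eight
injected regions are found. The summarized DMR table begins:

```
      name  start   stop  n_sig_windows        min_p   max_lfc  cpg_density
DMR_chr1_1 245000 248000              3 4.226624e-32  2.264897     2.000000
DMR_chr1_2 324000 327000              3 6.852558e-27  2.040847     1.733333
DMR_chr1_3 516000 519000              3 8.525449e-27 -2.207568     2.066667
DMR_chr1_4 675000 677000              2 1.057184e-23  1.902038     1.800000
```

Each injected multi-window region appears as a single merged DMR with
the correct sign of its methylation change, in the low CpG-density
("CpG desert", 1–3 CpG/100 bp) landscape the genome was designed with.

The same analysis is available from the shell:

```sh
medipdmr simulate --seed 42 --outdir inputs/
medipdmr run-all --config inputs/config.yaml --outdir out/
medipdmr cohort-stats --sample-sheet inputs/samples.tsv
```

`run-all` writes counts, per-window results, the DMR table, gene
associations, PCA scores and a `manifest.json` of checksums; reruns are
byte-identical.

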