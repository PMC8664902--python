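# Methods

This note records the models, defaults and numerical choices behind
`medipdmr`, and what the synthetic data do and do not establish.

## Data model

MeDIP-seq yields, per sample, a set of sonicated fragment intervals
whose genome-wide density tracks methylated-CpG content. The analysis
unit is a fixed 1 kb window (0-based half-open coordinates throughout;
the trailing window of each chromosome is kept at its true, shorter
length so densities stay correct). A fragment belongs to the window
containing its midpoint ⌊(start+end)/2⌋ — an assignment that is
unambiguous, order-independent and exactly invertible, which is what
lets the generator's emit-then-count round trip be an identity test.
Fragments on unknown chromosomes or with off-chromosome midpoints are
tallied as skipped, never silently dropped. Windows with mean count
below 5 across samples (configurable) are removed before testing;
filtered windows also break DMR adjacency, since an untested window
between two significant ones leaves their joint behaviour unknown.

## Count model and test

Window counts are negative binomial: variance μ + φμ² (the
dispersion convention in which φ is the squared biological coefficient
of variation). The testing stack is the classic two-group count
workflow:

1. **TMM normalization.** Each sample's scaling factor is the
   precision-weighted trimmed mean of M-values against a reference
   sample (the one whose 75th CPM percentile is nearest the mean):
   30% trimmed from each tail of M, 5% of A, zero/infinite log-ratios
   excluded, weights from the delta-method variance of M. Factors are
   rescaled to geometric mean 1; effective library size =
   raw size × factor.
2. **Pseudo counts.** Counts are mapped to a common (geometric-mean)
   library size by quantile-to-quantile NB matching, averaging normal
   and gamma approximations of the NB and matching on the nearer tail
   for stability. Per-group window rates are estimated as group count
   sums over group library-size sums.
3. **Common dispersion (qCML).** φ maximizes the conditional
   log-likelihood of the pseudo counts given each window's group sums
   (the sum-conditional likelihood is free of the mean parameter for
   iid NB with equal libraries). The pseudo-count computation and the
   maximization are iterated four times from φ = 0.01; the optimizer
   works on δ = φ/(1+φ) ∈ [1e-4, 0.99], so Poisson-like data land at
   the lower bound (φ ≈ 1e-4).
4. **Tagwise dispersion (optional).** Per-window φ maximizes that
   window's conditional likelihood plus (prior_df / residual_df) times
   the genome-wide mean likelihood curve, on a log-spaced grid spanning
   ±6 octaves around the common value — weighted-likelihood empirical
   Bayes with prior_df = 10.
5. **Exact test.** With libraries equalized, the two group sums are NB
   with means proportional to group size and dispersions φ/n. The
   rounded sums are tested conditionally on their total by exact
   enumeration of the support 0..s: the p-value doubles the smaller
   tail, includes the observed outcome's mass fully in its tail, and
   is capped at 1. Poisson-limit cases are handled by a dispersion
   floor of 1e-8, where the conditional law approaches binomial.
6. **FDR.** Benjamini–Hochberg step-up with monotonicity enforcement,
   order-aligned with the input.

**Which dispersion feeds the test.** The default is the *common* qCML
estimate. In a simple two-group design with thousands of windows the
common estimate is precise, while per-window estimates at 24 residual
df — even shrunk with prior_df = 10 — retain enough noise that windows
with underestimated φ are anti-conservative, mildly inflating type-I
error under a shared-dispersion truth. Cross-checks against edgeR show
both behaviours are faithful reproductions of the reference stack
(common dispersion matches to <2%; the tagwise ranges coincide);
`use_tagwise=True` opts in for data with genuinely heterogeneous
dispersion. Log fold changes are log₂(case/control) of pseudo-count
group means moderated by a prior count of 0.125; the prior touches only
the reported fold change, never the p-value.

## DMR definition

Significant windows (p strictly below the threshold; default 1e-4)
merge into a DMR when genomically contiguous with zero gap — window
ordinals differing by 1 on the same chromosome. Boundaries are the
union of the constituent significant windows only. Each DMR carries:
span and length, number of significant windows, minimum p and minimum
BH q over constituents (q-values from the full tested set, not
recomputed within the DMR), the signed log₂ fold change of the
constituent with the largest magnitude, CpG dinucleotide count by
direct scan of the reference sequence, and CpG density per 100 bp.
Names are `DMR_<chrom>_<k>` in genomic order. The threshold-ladder
table reports DMR counts (all, and multi-window only) at cutoffs
1e-2 … 1e-7. The number of significant windows is monotone in the
cutoff; the DMR *count* is monotone only in the sparse-significance
regime these scans operate in, because a tighter cutoff can in
principle split a run whose interior window drops out.

## Annotation and comparison rules

* Gene association uses the interval gap between the DMR and the gene
  *body*, inclusive at 10 kb (a distance spanning proximal and distal
  promoters); strand never enters, all qualifying genes are reported,
  and an overlapping gene has distance 0. Category tallies count a DMR
  once per distinct category among its associated genes. The category
  vocabulary is user-supplied (gene → category TSV); unknown genes are
  "unclassified".
* Two DMRs overlap when their half-open intervals share ≥1 bp. Venn
  membership counts are taken over the merged union of all sets'
  intervals, each union element assigned the full pattern of sets it
  intersects — well-defined even for asymmetric intersections.
* The extended-overlap entry (i, j) is the count and percentage of
  comparison-i DMRs at the strict threshold that intersect ≥1 window of
  comparison j significant at the relaxed threshold (0.05). Because
  every constituent window of a strict DMR satisfies p < 1e-4 ≤ 0.05,
  the diagonal is exactly 100% whenever the row set is non-empty; the
  suite asserts this self-overlap theorem on every synthetic run.
* DMR clusters chain consecutive midpoints ≤2 Mb apart and report
  chains of ≥3; both parameters are package defaults, labeled as such,
  since cluster boxes in this literature rarely state a rule.
* PCA input is log₂(CPM+1) on effective library sizes over
  DMR-constituent windows (the usual presentation does not state its
  transform; this one is labeled). Scores come from column-centered
  SVD with each component's largest-magnitude loading forced positive,
  so output is byte-stable under reruns and sample reorderings.

## Synthetic data: what it emulates

The generator reproduces the features the analysis is sensitive to:
a CpG-density landscape (default 2 CpG/100 bp — the middle of the
1–3 CpG/100 bp "CpG desert" band where these DMRs predominantly live —
with designable regions; CG dinucleotides are placed explicitly, so a
0-density region contains none and realized density tracks the target
to binomial accuracy), NB counts whose baseline follows window CpG
density as μ ∝ 1 + 0.5·d (MeDIP signal scales with methylatable CpGs;
the exact shape is immaterial to the tests), per-sample library sizes
log-normal around 2.5×10⁵ fragments with 20% CV (a 1/100 miniature of
a real ~25 M-read library), uniform ages on [30, 75] carried only
descriptively, injected single- and multi-window DMRs with signed
log₂ fold changes (case mean × 2^lfc), and fragments of uniform length
150–300 bp with midpoints uniform in the source window (shrunk
symmetrically at chromosome ends so the midpoint rule survives
clipping).

Default desk-scale conditions — 2 chromosomes × 1 Mb (2,000 windows),
13+13 samples, φ = 0.1, eight injected |lfc| = 2 regions — keep a full
pipeline run around ten seconds while leaving the test at high power.

It does **not** emulate read-level sequence errors, alignment
ambiguity, PCR duplicates, GC/mappability bias, sex chromosomes, batch
structure, or covariate effects (age/race never influence counts). A
passing suite therefore demonstrates correctness of the statistical
machinery and the interval algebra under the stated model — not
robustness to those real-data artifacts, and not the biological
validity of any particular DMR set.

## Cohort descriptives

`summarize_cohort` reports per-group n, mean age and SEM (sample SD
with n−1 denominator over √n, rounded only at presentation), and a
pooled-variance Student t-test between two groups (Welch behind a
flag). The reference cohort table this reproduces prints "mean ± SEM"
rows while its legend says SD; the printed values match SEM, so SEM is
implemented and the discrepancy noted here. The published per-subject
ages ship in `REFERENCE_AGES` and the suite recomputes the printed
54.9 ± 3.4 (controls), 55.5 and 53.5 exactly.

## Known limitations

* Two-group exact test only: no GLM covariate adjustment, by design —
  combined multi-site cohorts are treated as plain two-group runs and
  any site/ancestry confounding is the user's to weigh.
* TMM precision weights depend on absolute library size, so p-values
  are invariant to a global depth rescaling only post-normalization
  (holding factors fixed), which is how the invariance is tested.
* The exact enumeration is O(total count per window); at desk scale
  this is a few million pmf evaluations, chunked to bound memory, but
  very deep libraries would want the usual large-count approximations.
* Gene association is gene-body anchored; TSS-anchored distances would
  shift associations for long genes.
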