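# Methods

`methdiff` compares two single-base bisulfite methylomes — a "sample A"
(e.g. a diploid) and a "sample B" (e.g. an autotetraploid derived from it)
— without biological replicates, and relates the resulting differentially
methylated regions (DMRs) to gene expression changes.

## Per-cytosine model and joint filtering

Each strand-specific cytosine carries methylated/unmethylated read counts in
one of the three plant contexts (CG, CHG, CHH; H ∈ {A, C, T}).  The
methylation level of a site is `m / (m + u)`.  Only sites covered by at
least `min_total_reads` reads (default **3**) in *both* samples enter any
cross-sample computation; low-coverage sites are retained in memory but
flagged, so the joint filter is applied once, explicitly.  Strands are never
pooled: symmetric CpG merging is deliberately absent because all downstream
statistics are defined per cytosine.

A site is called a methylcytosine (mC) when it is covered and has at least
`min_meth_reads` methylated reads (default **1**).  This is the simplest
rule consistent with per-context mC counts and rates of the magnitude seen
in real plant methylomes; a binomial test against bisulfite conversion
error would be the natural refinement, but conversion-error calibration is
out of scope, so the read-count rule is exposed as a parameter instead.

## Divergence summary

On sites that are mC in at least one sample, a site counts as *increased*
when `level_B / level_A > 1.2` and *decreased* symmetrically; ratios above
2 are tallied separately.  A zero denominator with a methylated numerator
is classified into the >2-fold class of its direction rather than dropped —
dropping would silently bias divergence downward.  All percentages share a
single denominator (the global eligible-site count), so the per-context
rows are additive shares and `pct_total = pct_increased + pct_decreased`
holds exactly, per context and overall.

## Window testing and DMR calling

The genome is tiled into **100-bp windows at 25-bp steps**.  Within a
window, the per-cytosine levels of the two samples (over jointly covered
sites of one context) form two groups for a Kruskal–Wallis rank sum test
(midranks, tie-corrected variance, chi-square tail with 1 df; an all-tied
window has H = 0, p = 1).  Windows with fewer than `min_sites` sites
(default **4**) are skipped and never enter the multiple-testing family — a
rank test on fewer observations cannot reach p < 0.05 through the
chi-square approximation and only dilutes the correction.

p-values are Benjamini–Hochberg adjusted **per context, genome-wide**: the
three contexts have very different null behaviour and are reported
separately, so pooling them into one family would be incoherent, and
per-chromosome families would make q-values depend on an arbitrary
partition.  Windows with q < 0.05 whose region fold change
(`mean(level_B) / mean(level_A)`) passes the 1.2 filter (in either
direction; the filter can be disabled) become DMRs; trend is *hyper* when
the fold change exceeds 1 (B more methylated) and *hypo* otherwise.  A zero
denominator yields an infinite fold change with trend hyper.

Adjacent same-trend DMRs are collapsed; "adjacent" means overlapping or
abutting (configurable `merge_gap`, default 0) — with a 25-bp step,
significant neighbouring windows overlap, which makes the collapse rule
effective.  The merged region's fold change is recomputed from all sites in
the merged interval, its q-value is the member minimum.  Merging is
idempotent, and swapping the two samples maps every hyper-DMR onto a
hypo-DMR with reciprocal fold change and identical coordinates.

DMRs are annotated against gene bodies and strand-aware 2-kb upstream and
downstream flanks; a DMR annotates every (gene, region) pair it overlaps by
at least one base, so boundary DMRs legitimately multi-assign.

## Expression association

Genes are classified as *non-expressed* (FPKM < 1 in both samples),
*increased* / *decreased* (FDR < 0.05, by sign of log2FC), or
*non-differential*.  Each gene region (upstream, body, downstream, and
their union "whole gene") is assigned a DMR group — hyper, hypo, both, or
none — from the trends of its overlapping DMRs.  Among DEGs with at least a
4-fold change (|log2FC| ≥ 2), the log2FC distributions of the groups are
summarised per region and compared pairwise with two-sided rank-sum tests
(BH-adjusted within each direction × region family), alongside a seeded
random control drawn from the same DEG set (size of the largest group by
default).  Changing the seed changes only the random control.  A gene
overlapped only by a flank DMR still counts as "DMR-containing" for the
per-class percentages.

## Synthetic data

The generator is first-class, tested code; it defines the study conditions
under which the pipeline is validated.

* **Genome**: iid sequence at GC fraction 0.35 (close to the *Vitis*
  genome), default two 1-Mb chromosomes.  Every cytosine on both strands is
  catalogued as CG/CHG/CHH from its trinucleotide.
* **Levels**: per-site true levels are beta-distributed with
  context-specific means — CG 0.34, CHG 0.30, CHH 0.16, the scale observed
  in grapevine methylomes — and concentration 5.  The concentration was
  chosen so that the planted effect size below is a ~2-SD shift of the
  within-context level distribution at 12× coverage, i.e. the planted truth
  is detectable by design; real WGBS levels (especially CG, which is
  bimodal) are more overdispersed than this single-beta model.
* **Pairing**: outside planted DMRs sample B shares sample A's true level
  (`paired_true_levels=True`), modelling a common underlying methylation
  state.  Because shared site effects positively correlate the two groups,
  rank-test p-values under this paired null are strongly *conservative*.
  Calibration checks therefore use `paired_true_levels=False`, where each
  sample's levels are independent draws from the same distribution and the
  test's nominal level applies.
* **Planted DMRs**: 200 CHH regions by default (none in CG/CHG, matching
  the near-absence of CG/CHG DMRs in a conserved methylome), lengths
  uniform 100–400 bp, each entirely inside one gene body or one intergenic
  gap with a 150-bp margin and ≥500 bp mutual separation, so every planted
  region has one unambiguous annotation stratum and calls cannot bridge two
  truths.  Inside a region, sample B's levels are redrawn from a beta whose
  mean is shifted by ±0.3 (clipped into [0.02, 0.98]).
* **Reads**: coverage Poisson(12) per sample per site; methylated counts
  binomial.
* **Genes and expression**: non-overlapping 2-kb genes on alternating
  strands at a 4-kb pitch; 15% non-expressed (both FPKM < 1), 50% DEGs
  (half up, half down) with |log2FC| uniform on [2.5, 3.0] — effect sizes
  deliberately ≥4-fold so the association analysis' fold-change filter does
  not truncate the planted distributions — and the rest non-differential
  (log2FC ~ N(0, 0.2)).  A planted hypo-DMR inside a gene body adds
  +1 × `coupling_strength` to that gene's log2FC (hyper: −1).  Reported
  FDRs are uniform on [0, 0.01] for planted DEGs and on [0, 1] otherwise;
  differential-expression testing itself is upstream of this pipeline, so
  its output is emulated, not recomputed.

Everything derives from one integer seed; identical config + seed yields
byte-identical files.

What the passing checks do and do not show: recovery and association
results demonstrate correctness of the statistical machinery under the
generator's assumptions (independent sites, homogeneous coverage, clean
context labels, block-constant planted effects).  They do not certify
performance on real data, where levels are spatially autocorrelated,
coverage is biased, and effects are graded.

## Recovery scoring

A planted DMR counts as recovered when a called DMR of the same context and
trend overlaps at least 50% of it; with reciprocal matching the overlap
must also cover 50% of the call.  Precision uses the same rule on the call
side.  On the default scenario the caller achieves sensitivity and
precision above 0.9 at 50% reciprocal overlap.

## Numerical choices and degenerate inputs

* BH q-values are computed by the step-up formula with a stable sort, so
  tied p-values are deterministic; q-values match a brute-force
  implementation bit-for-bit.
* The Kruskal–Wallis statistic is delegated to `scipy.stats.kruskal`; a
  round-off-negative H is clamped to (0, p = 1).  The test suite verifies
  it against an independently written midrank-formula oracle to 1e-12,
  exhaustively for all pooled sizes ≤ 8 over a three-letter value alphabet.
* Correlations over fewer than 3 shared sites, or with a zero-variance
  vector, are reported as NaN, never raised.
* Empty bins report zero density and a missing mean level; an empty
  expression class reports a missing percentage.
* Chromosome lengths come from a declared table when available and are
  otherwise inferred as max(position) + 1 per chromosome.

## Problem sizes

The shipped validation scenarios use two 1-Mb chromosomes (≈ 700k
catalogued cytosines, ≈ 80k tested CHH windows) for recovery and
association, a single 1-Mb chromosome for null calibration, and 40–200-kb
scenarios for structural and I/O checks — large enough for stable rank
statistics and window counts, small enough that the whole suite runs in a
few minutes on one CPU.

## Known limitations

* No replicate-aware dispersion modelling: the design targets one pooled
  methylome per condition, as in single-accession ploidy comparisons.
* The mC call ignores bisulfite conversion error.
* The simulator does not model spatial autocorrelation of methylation,
  read-level errors, or context miscalls.
* Whether the region fold-change filter beyond q < 0.05 should apply is a
  judgment call; it defaults on at 1.2 (mirroring the per-site rule) and
  can be disabled.
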