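# methdiff

Whole-genome bisulfite methylome comparison for paired plant samples — for
example a diploid accession and the autotetraploid induced from it.  The
package profiles per-cytosine methylation in the CG, CHG and CHH contexts,
calls differentially methylated regions (DMRs) with a sliding-window rank
test, annotates them against gene models, and asks how gene-body DMRs
relate to gene expression changes.  A seeded synthetic-data generator with
planted truth makes every stage testable end to end without any external
data.

## Method

For a cytosine covered by *m* methylated and *u* unmethylated reads the
methylation level is *m / (m + u)*; only sites covered by ≥ 3 reads in
**both** samples are compared.  A site is divergent when its level ratio
between the samples exceeds 1.2.

DMR calling tiles the genome into 100-bp windows at 25-bp steps.  Within a
window the jointly covered per-cytosine levels of the two samples are
compared with a two-group Kruskal–Wallis rank sum test (midranks,
tie-corrected, χ²₁ tail).  p-values are Benjamini–Hochberg adjusted across
all tested windows of one context genome-wide; windows with q < 0.05 whose
regional fold change `mean(level_B)/mean(level_A)` passes 1.2 become DMRs
(*hyper* = more methylated in sample B, *hypo* = less), and adjacent
same-trend DMRs are collapsed.  DMRs are annotated to gene bodies and
strand-aware 2-kb flanks.

For the expression association, genes are classified as increased /
decreased (FDR < 0.05), non-differential, or non-expressed (FPKM < 1 in
both samples), grouped by the trend of their overlapping DMRs per region
(hyper / hypo / both / none), and the log2 fold-change distributions of the
groups among ≥ 4-fold DEGs are compared with pairwise rank-sum tests plus a
seeded random control.

See `docs/methods.md` for assumptions, parameter semantics and limitations.

## Worked example

Simulate a scenario and run the full pipeline:

```sh
methdiff simulate --seed 1 --outdir sim
cat > pipeline.yaml <<EOF
report_a: sim/sample_a.cx_report.txt
report_b: sim/sample_b.cx_report.txt
gff: sim/genes.gff3
expression: sim/expression.tsv
chrom_lengths: sim/chrom_lengths.tsv
outdir: out
EOF
methdiff run --config pipeline.yaml        # or the library API below
```

```python
from methdiff.simulate import SimulationConfig, simulate_scenario, evaluate_recovery
from methdiff import profiles, dmr

bundle = simulate_scenario(SimulationConfig(seed=1))   # 2 x 1 Mb, 200 planted CHH DMRs
pair = profiles.pair_samples(bundle.sample_a, bundle.sample_b, min_total_reads=3)
windows = dmr.test_windows(pair, bundle.config.chrom_lengths, "CHH")
called = dmr.merge_adjacent(dmr.call_dmrs(windows), pair)
print(len(windows), len(called))
r = evaluate_recovery(called, bundle.truth.dmrs, reciprocal=True)
print(round(r.sensitivity, 3), round(r.precision, 3))
```

prints

```
79999 206
0.91 0.883
```

79,999 CHH windows were tested genome-wide; 206 merged DMRs were called, of
which 88.3% overlap a planted region reciprocally by ≥ 50% (precision), and
91% of the 200 planted regions were recovered (sensitivity).  On the same
scenario the per-context mean methylation levels come out at 0.339 / 0.300 /
0.160 (CG / CHG / CHH, configured 0.34 / 0.30 / 0.16), and the gene-body
hypo-DMR group of ≥ 4-fold up-regulated genes sits a median 1.00 log2 units
above the DMR-free group — the planted unit coupling between gene-body
demethylation and expression gain, recovered by the association stage.

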