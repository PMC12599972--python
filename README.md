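# ectoreg

Integrative regulatory-genomics toolkit for early embryonic enhancer
analysis: temporal classification of transcription-factor ChIP-seq peak
sets, coactivator co-occupancy, super-enhancer (SE) calling by
stitched-signal ranking, direct-target inference from knockdown RNA-seq,
qPCR quantification formulas, and single-cell expression-robustness
statistics — plus a seeded synthetic-data generator with planted ground
truth that exercises the whole pipeline end to end.

## The scientific problem

During germ-layer specification, maternal transcription factors pre-bind
cis-regulatory modules (CRMs) before zygotic genome activation, recruit
coactivators such as Ep300, and concentrate H3K27ac into super-enhancers
that drive strong, low-noise expression of lineage genes. Testing that
model computationally requires a chain of analyses that this package
implements as reusable, tested components:

* **Temporal Venn classes.** Peak sets from three stages are merged; each
  union region is classified by the subset of stages binding it (the 7
  non-empty subsets, classes I–VII).
* **Co-occupancy and overlap fractions.** Reference regions are flagged per
  partner set; `overlap_fraction(A, B) = 100·|{a ∈ A : a ∩ B ≠ ∅}| / |A|`.
* **Direct targets.** A gene is a direct target when the knockdown changes
  it at least 2-fold (|log2 FC| ≥ 1, morphant-over-WT) *and* a bound region
  lies within 20 kb of the gene body.
* **Super-enhancers.** Enhancer peaks within 12.5 kb are stitched; stitched
  loci are ranked by signal area; with both axes rescaled to [0, 1], the
  SE cutoff is the first rank where the curve's discrete slope exceeds 1,
  and loci above it are SEs.
* **qPCR formulas.** Percent input = 100 / 2^(Cp_ChIP − (Cp_input − log2 DF));
  ΔΔCp fold change = 2^−(mean ΔCp_treat − mean ΔCp_ctrl) with a two-tailed
  t test across replicates.
* **Single-cell robustness.** After a detected-genes QC cutoff and depth
  normalization, per-gene CoV = σ/μ measures expression noise; gene sets
  are compared with the two-sided Wilcoxon rank-sum test.

See `docs/methods.md` for conventions, parameter defaults, and what the
synthetic benchmarks do and do not establish.

## Worked example

The `demo` subcommand simulates a complete input bundle (three stage peak
BEDs, a coactivator BED, a bedGraph signal track, gene models, a knockdown
DE table, and a single-cell count matrix with cluster labels), runs the full
pipeline on the files it just wrote, and compares every recovered quantity
with the planted manifest:

```bash
ectoreg demo --seed 42 --out demo_out/
cat demo_out/summary.json
```

```json
{
 "seed": 42,
 "class_counts": {"I": 5, "II": 5, "III": 5, "IV": 5, "V": 5, "VI": 5, "VII": 5},
 "class_counts_match_truth": true,
 "triple_cobound_with_coactivator": 5,
 "planted_cobound_with_coactivator": 5,
 "direct_target_precision": 1.0,
 "direct_target_recall": 1.0,
 "n_super_enhancers": 7,
 "super_enhancers_match_truth": true,
 "cov_comparison": {
  "p": 1.6683701838490555e-09,
  "direction": "a_lower",
  "median_planted": 0.47355168795236635,
  "median_background": 0.9866113947397814
 }
}
```

Reading the output: all 35 planted loci land in their designed temporal
classes; every triple-bound locus carrying a coactivator peak is recovered
by the co-occupancy flags; the 12 planted knockdown targets are called with
perfect precision and recall under the 2-fold / 20 kb rule; the 7 planted
super-enhancers are exactly the loci above the rank-curve cutoff; and the
planted SE-associated gene set shows about half the expression noise of the
background (median CoV 0.47 vs 0.99, rank-sum p ≈ 2 × 10⁻⁹).

Individual steps are available as subcommands operating on standard formats
(`classify-peaks`, `cooccupy`, `assign`, `targets`, `localized`, `ddcp`,
`percent-input`, `signal-matrix`, `call-se`, `compare-se`, `sc-stats`,
`sc-zscore`, `simulate`); every one documents its flags under `--help`, and
a plain `key: value` file passed via `--config` supplies defaults that
command-line flags override.

The same functionality is importable as a library:

```python
from ectoreg import peaktools, setools
from ectoreg.formats_io import read_bed, read_bedgraph

tc = peaktools.temporal_classify(read_bed("s8.bed"), read_bed("s9.bed"),
                                 read_bed("s10.bed"))
print(tc.class_counts())

ranking = setools.rank_enhancers(setools.stitch(read_bed("h3k27ac.bed")),
                                 read_bedgraph("h3k27ac.bedgraph"))
setools.se_cutoff(ranking)
print(len(ranking.super_enhancers()), "SEs")
```

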