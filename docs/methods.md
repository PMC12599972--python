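# Methods

`ectoreg` implements the computational layer of an integrative
regulatory-genomics analysis of early germ-layer specification: how a pair
of maternal transcription factors (TFs) marks cis-regulatory modules (CRMs),
recruits a coactivator, shapes super-enhancers (SEs), and drives robust,
low-noise target-gene expression. This note describes each procedure, its
assumptions, the tunable parameters, and what the synthetic data do and do
not establish.

## Coordinates and formats

All internal coordinates are 0-based, half-open (the BED/bedGraph
convention); GFF3 (1-based, closed) is converted at the boundary and
restored on write. Chromosome names are compared by exact string equality —
no `chr` aliasing — so fixture mistakes fail loudly. Strand `.` is treated
as `+` for TSS derivation; all distance rules below are strand-free.
Overlap means ≥ 1 shared base; there is no minimum-fraction option.

## Temporal peak classification

Three stage peak sets (e.g., mid-blastula, late blastula, early gastrula
ChIP-seq peaks for one TF) are merged into union regions; each region's
membership is the subset of stages with ≥ 1 peak overlapping it, giving the
seven non-empty subsets (classes I–VII). Two conventions matter:

* **Region-level membership.** A chain of stage-specific peaks that overlap
  pairwise pools its membership even when no single base is covered by all
  stages. This matches standard merged-peak Venn practice.
* **Book-ended merging.** `merge_union` merges intervals that touch
  ([0,100) + [100,200) → [0,200)), the `bedtools merge` default, so union
  regions are exactly the maximal runs of covered bases. Pairwise
  `overlaps()` remains strict (touching intervals do not overlap).

Class labels are presentation only and remappable: different figures number
the same stage subsets differently, so the default map
({S1}=I, {S1,S2}=II, {S2}=III, {S1,S3}=IV, {S2,S3}=V, {S3}=VI,
{S1,S2,S3}=VII) can be overridden per run.

## Co-occupancy, overlap fractions, peak-to-gene assignment

Co-occupancy flags each reference region per partner set (coactivator,
second TF, histone mark); subset counts (e.g., triple co-bound) are plain
flag conjunctions. `overlap_fraction(A, B)` is 100 × |{a ∈ A overlapping
B}| / |A| and is undefined (an error) for empty A.

Peak-to-gene assignment uses edge-to-edge distance between the peak and the
**gene body** (0 when overlapping), with a 20 kb window by default: the
direct-target rule is stated as binding "within 20 kb of the gene", so the
body, not the TSS, is the default reference (TSS mode is available behind a
flag). Among candidates, the nearest gene wins; exact ties go to the
lexicographically smaller gene id for determinism. SE-to-gene association
differs deliberately: **all** genes within the window are associated, since
the question there is which genes an SE could act on, not which single gene
a peak belongs to.

## Super-enhancer calling

The classic stitch–rank–cutoff procedure:

1. **Stitch.** Consecutive enhancer peaks merge when the gap is ≤ the stitch
   distance (default 12,500 bp, the original rank-ordering default; the
   source analysis does not print its value, so it is config-exposed). A gap
   exactly equal to the distance merges. No promoter/TSS exclusion in v1;
   the flag is reserved but off because the source analysis does not mention
   one.
2. **Rank.** Locus signal is the area under the treatment track over the
   stitched span, minus the control track's area when given, floored at 0
   (negative "signal" has no rank interpretation). Loci sort ascending;
   ties keep stable input order.
3. **Cutoff.** Rank index and signal are each rescaled to [0, 1]; scanning
   ascending, the cutoff is the first index whose forward-difference slope
   to the next point strictly exceeds 1 — the tangent-slope-1 point of the
   hockey stick. Loci with signal strictly above the cutoff signal are SEs.
   A perfectly linear ramp (slope exactly 1 everywhere) and an all-equal
   vector produce zero SEs with a warning. The strict `>` and the forward
   difference are fixed by an independent brute-force oracle test.

This construction guarantees min(SE signal) > max(RE signal).

## Bulk expression logic

* **Maternal/zygotic segregation:** a gene is maternal iff its 0-hpf TPM is
  ≥ 1 (inclusive, reading "at least 1 TPM" literally); zygotic otherwise.
* **Zygotic timecourse log fold changes:** log2((TPM_t + c)/(TPM_0 + c))
  with pseudocount c = 0.1 TPM (the source is silent on zero handling;
  0.1 TPM is small against the 1 TPM maternal threshold).
* **Localized genes:** zygotic genes with |log2fc| ≥ 1 between germ-layer
  dissections, split by sign, ranked by FDR ascending (ties: larger
  |log2fc|, then gene id), truncated to the top 250 per side.
* **Direct targets:** |log2fc| ≥ 1 in the knockdown (morphant-over-WT
  convention: activated targets go *down*) **and** ≥ 1 assigned peak within
  20 kb. The log2fc column is consumed as provided — DE model fitting is
  out of scope — so whether it is shrunken is the caller's choice.
* **Joint targets:** intersection requires direction agreement; a gene
  activated in one list and repressed in the other lands in both "only"
  sets.
* **ΔΔCp:** per replicate ΔCp = Cp_target − Cp_reference; ΔΔCp =
  mean ΔCp_treatment − mean ΔCp_control; fold = 2^−ΔΔCp; sd is the sample
  sd of per-treatment-replicate folds; p is a two-sample two-tailed t test
  on replicate ΔCp values. Fewer than 2 replicates per arm flags sd/p as
  unavailable. Percent input = 100 / 2^(Cp_ChIP − (Cp_input − log2 DF));
  the input dilution factor is a required input because the source states
  the formula but not its DF.

## Single-cell statistics

Cells pass QC with ≥ 1,500 detected genes (inclusive cutoff; the default
matches real snRNA-seq scale and is overridden for the small synthetic
matrices). Counts are depth-normalized to 10,000 per cell; log(1+x) uses the
natural log. Per-cluster z-scores standardize each gene's cluster means with
the population sd; constant genes get a zero row and a flag.

CoV = sd/mean per gene uses the **population** sd (the n vs n−1 distinction
is negligible at single-cell n) and is computed on the depth-scaled,
**pre-log** values by default: the log transform compresses variance and the
source does not state which space it used, so both `scaled` and `lognorm`
modes are exposed and neither is asserted as the original's. Zero-mean
genes are flagged undefined and excluded from comparisons. Gene-set
comparisons use the two-sided Wilcoxon rank-sum test: exact null
distribution for small tie-free groups, otherwise the normal approximation
with tie and continuity corrections (verified against full-enumeration for
all group sizes ≤ 6). Clustering, doublet detection, and embeddings are
inputs, not reimplemented.

## Synthetic data

The generator emits every input the pipeline consumes from one seed, with a
planted-truth manifest:

* **Loci.** A configurable count per Venn class (default 5 × 7 = 35 loci)
  placed on 4 chromosomes of 2 Mb at an 80 kb pitch, so planted loci sit far
  beyond the stitch distance and stitching can never merge two truth loci.
  Infeasible packings raise a sizing error stating the required chromosome
  length. Regular loci are single 400–800 bp peaks; SE loci (20% by
  default) are broad ~16.8 kb domains of three book-ended 5.6 kb
  constituents, so each planted locus is one contiguous Venn region while
  stitching still reassembles parts.
* **Coactivator.** Peaks placed on triple-bound loci with probability 0.9
  (1.0 in recovery tests) plus background peaks far from any locus or gene.
* **Signal.** Background 1 everywhere; each peak adds a rectangle of height
  9 (× 5 at SE loci), with 5% multiplicative height noise by default
  (0 for the exact SE-recovery checks).
* **Genes.** One gene per locus 5 kb downstream (inside the 20 kb window)
  plus a decoy 30 kb away (outside 25 kb), making the window rule
  discriminative.
* **Knockdown table.** 12 planted targets at ±2 log2 units (half activated,
  half repressed), FDR 0.001; all other genes jitter uniformly in ±0.19
  with FDR 0.5, so the 2-fold rule separates perfectly by construction.
* **Single-cell counts.** Negative binomial with variance = m + φm²
  (φ = 0.6), per-gene baseline means uniform in [0.5, 4], a mild lognormal
  per-cluster factor (σ = 0.25) for cluster structure, 3 clusters × 100
  cells. SE-associated genes are the planted low-noise set: mean × 4 and
  φ × 0.25 in their home cluster, halving CoV there.

Each generator call consumes one seeded stream in documented order, so a
fixed design is byte-identical across runs.

**What passing tests show — and don't.** The synthetic data plant clean,
well-separated effects: rectangular signal, jitter strictly inside the
fold-change threshold, decoys strictly outside the window. Perfect recovery
therefore demonstrates the *rules* are implemented correctly, not that the
thresholds are robust to real-data ambiguity (ragged peak shapes, shrunken
fold changes near 2×, genes near the 20 kb boundary, ambient RNA and
doublets in single-cell counts). The genome-scale counts reported in the
motivating study depend on deposited raw data and are not reproduced at
this scale.

## Problem sizes and numerical checks

The default verification sizes are chosen to exercise every code path while
keeping the whole suite near interactive speed: 1,000 random three-set
instances against a per-base bitmap oracle for the Venn classifier; 500
random hockey-stick vectors (n ≤ 200) against a brute-force slope scan for
the SE cutoff; 20 seeds for exact direct-target recovery; 200 no-effect
simulations for rank-sum null calibration (a ±2-point band around 5% is a
~±3-count binomial window at this size; the test's measured true size is
≈ 5%); 50 seeds for CoV discrimination. Floating-point comparisons in
oracle tests use 1e-9 absolute tolerance; formula checks are exact to
machine precision.

## Known limitations

* No bigWig/BAM I/O; signal arrives as bedGraph.
* No between-sample scale-factor estimation; scale factors are inputs.
* Nearest-gene assignment ignores topological domains and strand.
* The SE cutoff uses the discrete forward-difference tangent; curves with
  n < 3 or no super-linear step yield zero SEs by design.
* The rank-sum normal approximation is slightly conservative for very small
  groups; the exact path covers groups ≤ 8 without ties.
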