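"""Synthetic inputs with planted ground truth, from a single seed.

The generator emulates the statistical structure of the study's inputs:

* three stage peak sets whose merged loci fall in controlled Venn membership
  classes, plus a coactivator peak set enriched at triple-bound loci;
* a per-base enhancer signal track in which a planted subset of loci carries
  a multiplied signal (the super-enhancer arm of the hockey stick), with SE
  loci built from several constituents so they are physically larger;
* one gene per locus at a fixed 5 kb offset (inside the 20 kb assignment
  window) plus a decoy gene beyond 25 kb, making the window rule
  discriminative;
* a knockdown expression table in which planted direct targets change by the
  planted log2 fold change (down in the morphant for activated targets) and
  everything else jitters within +/- 0.2;
* a cluster-structured single-cell count matrix (negative binomial with
  variance = mean + dispersion x mean^2) in which SE-associated genes get a
  higher mean and lower dispersion in their home cluster.

Planted loci are separated by far more than the stitch distance, so
stitching can never merge two distinct truth loci, and all outputs are
byte-identical for a fixed design.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse

from .errors import SizingError
from .formats_io import (
    CellMatrix,
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_cell_matrix,
    write_gff3_genes,
)
from .peaktools import DEFAULT_LABEL_MAP, merge_union

__all__ = [
    "SimulationDesign",
    "LocusTruth",
    "GroundTruth",
    "CLASS_SUBSETS",
    "simulate_peaks",
    "simulate_genes",
    "simulate_signal",
    "simulate_morphant_expression",
    "simulate_sc_counts",
    "write_all",
]

# Membership subsets in display order I..VII (matches DEFAULT_LABEL_MAP).
CLASS_SUBSETS: list[frozenset] = [
    frozenset({"S1"}),
    frozenset({"S1", "S2"}),
    frozenset({"S2"}),
    frozenset({"S1", "S3"}),
    frozenset({"S2", "S3"}),
    frozenset({"S3"}),
    frozenset({"S1", "S2", "S3"}),
]

_PITCH = 80_000  # center-to-center spacing between planted loci
_MARGIN = 10_000
# SE loci are broad domains built from book-ended constituents, so the locus
# is one contiguous covered span (a single Venn region) that stitching
# reassembles from its parts.
_N_SE_CONSTITUENTS = 3
_SE_CONSTITUENT_LEN = 5_600
_COACT_LEN = 500
_BG_COACT_OFFSET = 62_000  # background coactivator peaks, far from genes/loci


@dataclass
class SimulationDesign:
    """All knobs of the synthetic study, with the defaults used throughout."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    # loci per Venn membership class, ordered I..VII as in CLASS_SUBSETS
    class_counts: tuple = (5, 5, 5, 5, 5, 5, 5)
    coactivator_enrichment: float = 0.9
    n_coactivator_background: int = 8
    n_direct_targets: int = 12
    planted_log2fc: float = 2.0
    se_fraction: float = 0.2
    se_signal_multiplier: float = 5.0
    background_signal: float = 1.0
    peak_height: float = 9.0
    signal_noise_sd: float = 0.05
    stitch_distance: int = 12_500
    gene_offset: int = 5_000
    gene_length: int = 2_000
    decoy_offset: int = 30_000
    sc_clusters: int = 3
    sc_cells_per_cluster: int = 100
    sc_base_mean_low: float = 0.5
    sc_base_mean_high: float = 4.0
    sc_dispersion: float = 0.6
    sc_se_gene_mean_boost: float = 4.0
    sc_se_gene_dispersion_drop: float = 0.25

    def __post_init__(self) -> None:
        if len(self.class_counts) != 7:
            raise ValueError("class_counts must have 7 entries (classes I..VII)")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be >= 0")
        for prob in (self.coactivator_enrichment, self.se_fraction):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("need a positive genome")

    @property
    def n_loci(self) -> int:
        return int(sum(self.class_counts))

    @property
    def stage_peak_counts(self) -> tuple[int, int, int]:
        """Planted peak-locus count per stage, derived from the class design."""
        counts = [0, 0, 0]
        for subset, n in zip(CLASS_SUBSETS, self.class_counts):
            for i, stage in enumerate(("S1", "S2", "S3")):
                if stage in subset:
                    counts[i] += n
        return tuple(counts)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class LocusTruth:
    """One planted regulatory locus and everything derived from it."""

    chrom: str
    start: int
    end: int  # span of all constituents
    membership: tuple  # sorted stage names, e.g. ("S1", "S3")
    label: str  # display class label
    is_se: bool
    has_coactivator: bool
    gene_id: str
    decoy_gene_id: str


@dataclass
class GroundTruth:
    """Planted manifest: what a perfect analysis must recover."""

    loci: list[LocusTruth] = field(default_factory=list)
    activated: list[str] = field(default_factory=list)
    repressed: list[str] = field(default_factory=list)
    low_noise_genes: list[str] = field(default_factory=list)
    home_cluster: str = "c0"

    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in DEFAULT_LABEL_MAP.values()}
        for locus in self.loci:
            counts[locus.label] += 1
        return counts

    def cobound_loci(self) -> list[LocusTruth]:
        return [l for l in self.loci if set(l.membership) == {"S1", "S2", "S3"}]

    def se_loci(self) -> list[LocusTruth]:
        return [l for l in self.loci if l.is_se]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        loci = [LocusTruth(**{**l, "membership": tuple(l["membership"])})
                for l in data.pop("loci")]
        return cls(loci=loci, **data)


def _rng(design: SimulationDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.seed, stream]))


def simulate_peaks(
    design: SimulationDesign,
) -> tuple[PeakSet, PeakSet, PeakSet, PeakSet, GroundTruth]:
    """Emit the three stage peak sets, the coactivator set and the truth.

    Each planted locus appears, with identical coordinates, in exactly the
    stage sets of its membership class.  Super-enhancer loci are built from
    three constituents spanning ~17 kb; regular loci are single peaks.
    Coactivator peaks land on triple-bound loci with the design's enrichment
    probability, plus background peaks far from any locus.
    """
    rng = _rng(design, 0)
    n = design.n_loci
    slots_per_chrom = (design.chrom_length - 2 * _MARGIN) // _PITCH
    capacity = slots_per_chrom * design.n_chroms
    if n > capacity:
        need = 2 * _MARGIN + math.ceil(n / design.n_chroms) * _PITCH
        raise SizingError(
            f"{n} loci do not fit {design.n_chroms} chromosomes of "
            f"{design.chrom_length} bp; need chrom_length >= {need}"
        )
    chroms = design.chrom_names()

    subsets = []
    for subset, count in zip(CLASS_SUBSETS, design.class_counts):
        subsets.extend([subset] * count)
    # scatter classes over slots so genomic order carries no class signal
    slot_order = rng.permutation(n)

    n_se = int(round(design.se_fraction * n))
    se_set = set(rng.choice(n, size=n_se, replace=False).tolist()) if n_se else set()

    stages: dict[str, PeakSet] = {"S1": [], "S2": [], "S3": []}
    coactivator: PeakSet = []
    truth = GroundTruth()

    for locus_idx in range(n):
        slot = int(slot_order[locus_idx])
        chrom = chroms[slot % design.n_chroms]
        start = _MARGIN + (slot // design.n_chroms) * _PITCH
        membership = subsets[locus_idx]
        is_se = locus_idx in se_set
        if is_se:
            spans = [
                (start + k * _SE_CONSTITUENT_LEN, start + (k + 1) * _SE_CONSTITUENT_LEN)
                for k in range(_N_SE_CONSTITUENTS)
            ]
        else:
            length = int(rng.integers(400, 801))
            spans = [(start, start + length)]
        end = spans[-1][1]
        for stage in ("S1", "S2", "S3"):
            if stage in membership:
                for k, (a, b) in enumerate(spans):
                    stages[stage].append(
                        GenomicInterval(chrom, a, b, name=f"L{locus_idx}_{stage}_{k}")
                    )
        cobound = membership == frozenset({"S1", "S2", "S3"})
        has_coact = bool(cobound and rng.random() < design.coactivator_enrichment)
        if has_coact:
            coactivator.append(
                GenomicInterval(chrom, start, start + _COACT_LEN,
                                name=f"coact_L{locus_idx}")
            )
        truth.loci.append(
            LocusTruth(
                chrom=chrom, start=start, end=end,
                membership=tuple(sorted(membership)),
                label=DEFAULT_LABEL_MAP[membership],
                is_se=is_se, has_coactivator=has_coact,
                gene_id=f"gene_L{locus_idx}", decoy_gene_id=f"decoy_L{locus_idx}",
            )
        )

    if design.n_coactivator_background and n:
        bg_loci = rng.choice(n, size=min(design.n_coactivator_background, n),
                             replace=False)
        for j, locus_idx in enumerate(sorted(bg_loci.tolist())):
            locus = truth.loci[locus_idx]
            a = locus.start + _BG_COACT_OFFSET
            coactivator.append(
                GenomicInterval(locus.chrom, a, a + _COACT_LEN, name=f"coact_bg{j}")
            )

    # plant direct targets and the low-noise (SE-associated) gene list
    if design.n_direct_targets > n:
        raise SizingError(
            f"{design.n_direct_targets} direct targets requested from {n} loci"
        )
    target_loci = rng.choice(n, size=design.n_direct_targets, replace=False)
    target_genes = [truth.loci[i].gene_id for i in sorted(target_loci.tolist())]
    n_act = math.ceil(len(target_genes) / 2)
    truth.activated = target_genes[:n_act]
    truth.repressed = target_genes[n_act:]
    truth.low_noise_genes = [l.gene_id for l in truth.loci if l.is_se]
    return stages["S1"], stages["S2"], stages["S3"], coactivator, truth


def simulate_genes(truth: GroundTruth, design: SimulationDesign) -> list[GeneModel]:
    """One gene per locus at the fixed in-window offset, plus far decoys."""
    genes = []
    for locus in truth.loci:
        a = locus.end + design.gene_offset
        genes.append(
            GeneModel(
                locus.gene_id,
                GenomicInterval(locus.chrom, a, a + design.gene_length,
                                name=locus.gene_id, strand="+"),
            )
        )
        d = locus.end + design.decoy_offset
        genes.append(
            GeneModel(
                locus.decoy_gene_id,
                GenomicInterval(locus.chrom, d, d + design.gene_length,
                                name=locus.decoy_gene_id, strand="+"),
            )
        )
    return genes


def simulate_signal(
    peaks: PeakSet,
    design: SimulationDesign,
    truth: GroundTruth | None = None,
    noise_sd: float | None = None,
) -> SignalTrack:
    """Background plus rectangular peak enrichment, SE loci multiplied.

    Every base carries the background value; each merged peak adds a
    rectangle of the peak height (times the SE multiplier when the peak falls
    in a planted SE locus), with optional multiplicative height noise from
    the seeded stream.
    """
    rng = _rng(design, 1)
    sd = design.signal_noise_sd if noise_sd is None else noise_sd
    merged = merge_union([peaks])
    se_spans: dict[str, list[tuple[int, int]]] = {}
    if truth is not None:
        for locus in truth.se_loci():
            se_spans.setdefault(locus.chrom, []).append((locus.start, locus.end))
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in merged:
        if p.end > design.chrom_length:
            raise SizingError(f"peak {p} exceeds chromosome length")
        by_chrom.setdefault(p.chrom, []).append(p)
    b = design.background_signal
    runs: list[tuple[str, int, int, float]] = []
    for chrom in design.chrom_names():
        pos = 0
        for p in by_chrom.get(chrom, ()):
            if p.start > pos:
                runs.append((chrom, pos, p.start, b))
            height = design.peak_height
            for a, e in se_spans.get(chrom, ()):
                if p.start < e and a < p.end:
                    height *= design.se_signal_multiplier
                    break
            if sd > 0:
                height *= max(1.0 + rng.normal(0.0, sd), 0.0)
            runs.append((chrom, p.start, p.end, b + height))
            pos = p.end
        if pos < design.chrom_length:
            runs.append((chrom, pos, design.chrom_length, b))
    return SignalTrack(runs)


def simulate_morphant_expression(
    genes: list[GeneModel], truth: GroundTruth, design: SimulationDesign
):
    """Knockdown DE table with the planted targets at the planted effect.

    Activated targets go down in the morphant (log2fc = -planted_log2fc),
    repressed targets up; everything else jitters uniformly within +/- 0.19,
    safely inside the 2-fold rule.  FDR is 0.001 for planted targets and 0.5
    otherwise.
    """
    import pandas as pd

    rng = _rng(design, 2)
    activated, repressed = set(truth.activated), set(truth.repressed)
    rows = []
    for g in genes:
        wt = float(rng.lognormal(2.0, 1.0))
        if g.gene_id in activated:
            lfc, fdr = -design.planted_log2fc, 0.001
        elif g.gene_id in repressed:
            lfc, fdr = design.planted_log2fc, 0.001
        else:
            lfc, fdr = float(rng.uniform(-0.19, 0.19)), 0.5
        rows.append(
            {"gene_id": g.gene_id, "wt_tpm": wt,
             "morphant_tpm": wt * 2.0**lfc, "log2fc": lfc, "fdr": fdr}
        )
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_sc_counts(
    genes: list[GeneModel], truth: GroundTruth, design: SimulationDesign
) -> CellMatrix:
    """Cluster-structured negative-binomial counts, genes x cells.

    Counts for gene g in cluster c are NB with variance = m + phi * m^2,
    where m combines a per-gene baseline with a mild per-cluster multiplier.
    Planted low-noise genes get mean x boost and dispersion x drop in the
    home cluster only.
    """
    rng = _rng(design, 3)
    gene_ids = [g.gene_id for g in genes]
    low_noise = set(truth.low_noise_genes)
    n_genes = len(gene_ids)
    clusters = [f"c{i}" for i in range(design.sc_clusters)]
    cells_per = design.sc_cells_per_cluster
    base_mean = rng.uniform(design.sc_base_mean_low, design.sc_base_mean_high,
                            size=n_genes)
    cluster_factor = rng.lognormal(0.0, 0.25, size=(n_genes, design.sc_clusters))
    blocks = []
    for ci, _ in enumerate(clusters):
        block = np.zeros((n_genes, cells_per), dtype=np.int64)
        for gi, gene_id in enumerate(gene_ids):
            m = base_mean[gi] * cluster_factor[gi, ci]
            phi = design.sc_dispersion
            if gene_id in low_noise and clusters[ci] == truth.home_cluster:
                m *= design.sc_se_gene_mean_boost
                phi *= design.sc_se_gene_dispersion_drop
            if phi <= 0:
                block[gi] = rng.poisson(m, size=cells_per)
            else:
                r = 1.0 / phi
                p = r / (r + m)
                block[gi] = rng.negative_binomial(r, p, size=cells_per)
        blocks.append(block)
    matrix = scipy.sparse.csr_matrix(np.concatenate(blocks, axis=1))
    cell_ids = [f"{c}_cell{j}" for c in clusters for j in range(cells_per)]
    labels = [c for c in clusters for _ in range(cells_per)]
    return CellMatrix(matrix, gene_ids, cell_ids, labels)


def write_all(design: SimulationDesign, outdir: str | Path) -> dict:
    """Run every generator and emit the full input bundle to ``outdir``.

    Writes stage1/2/3.bed, coactivator.bed, signal.bedgraph, genes.gff3,
    morphant_de.tsv, sc.mtx (+ features/barcodes/clusters) and truth.json.
    Returns {"paths": ..., "truth": GroundTruth}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s1, s2, s3, coact, truth = simulate_peaks(design)
    genes = simulate_genes(truth, design)
    track = simulate_signal(s1 + s2 + s3, design, truth)
    de = simulate_morphant_expression(genes, truth, design)
    sc = simulate_sc_counts(genes, truth, design)

    paths = {
        "stage1": outdir / "stage1.bed",
        "stage2": outdir / "stage2.bed",
        "stage3": outdir / "stage3.bed",
        "coactivator": outdir / "coactivator.bed",
        "signal": outdir / "signal.bedgraph",
        "genes": outdir / "genes.gff3",
        "morphant_de": outdir / "morphant_de.tsv",
        "sc_mtx": outdir / "sc.mtx",
        "sc_features": outdir / "sc_features.tsv",
        "sc_barcodes": outdir / "sc_barcodes.tsv",
        "sc_clusters": outdir / "sc_clusters.tsv",
        "truth": outdir / "truth.json",
    }
    write_bed(s1, paths["stage1"])
    write_bed(s2, paths["stage2"])
    write_bed(s3, paths["stage3"])
    write_bed(coact, paths["coactivator"])
    write_bedgraph(track, paths["signal"])
    write_gff3_genes(genes, paths["genes"])
    de.to_csv(paths["morphant_de"], sep="\t")
    write_cell_matrix(sc, paths["sc_mtx"], paths["sc_features"],
                      paths["sc_barcodes"], paths["sc_clusters"])
    truth.to_json(paths["truth"])
    return {"paths": paths, "truth": truth}
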