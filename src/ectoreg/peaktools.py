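"""Interval algebra over peak sets.

Covers pairwise overlap, merged-union construction, temporal Venn
classification of three stage peak sets into the seven non-empty membership
classes, co-occupancy flagging against partner sets (e.g., a coactivator),
overlap fractions, motif co-occurrence proportions, peak-to-gene assignment
within a distance window, and a small log-odds PWM scanner.

Venn membership is computed at the merged-union-region level: a region's
membership is the set of stage peak sets having at least one peak overlapping
it.  Chained overlaps therefore pool membership even when no single base is
covered by all members — the standard merged-peak Venn convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError
from .formats_io import GeneModel, GenomicInterval, PeakSet

__all__ = [
    "overlaps",
    "merge_union",
    "TemporalClassification",
    "temporal_classify",
    "DEFAULT_LABEL_MAP",
    "CooccupancyResult",
    "cooccupancy",
    "overlap_fraction",
    "PeakGeneAssignment",
    "assign_genes",
    "MotifCooccurrence",
    "motif_cooccurrence",
    "pwm_scan",
]


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _chrom_trees(peaks: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)
    return trees


def _any_overlap(trees: Mapping[str, IntervalTree], region: GenomicInterval) -> bool:
    tree = trees.get(region.chrom)
    return bool(tree is not None and tree.overlap(region.start, region.end))


def merge_union(sets: Sequence[Sequence[GenomicInterval]]) -> list[GenomicInterval]:
    """Minimal set of disjoint intervals covering every input interval.

    Output is sorted by (chrom, start).  Book-ended intervals ([0,100) and
    [100,200)) are merged, so each output region is one maximal run of
    covered bases — the bedtools-merge convention, and exactly the connected
    components of the per-base coverage bitmap.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for peaks in sets:
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


# Display labels for the 7 non-empty subsets; purely presentational and
# overridable (different figures number the same subsets differently).
DEFAULT_LABEL_MAP: dict[frozenset, str] = {
    frozenset({"S1"}): "I",
    frozenset({"S1", "S2"}): "II",
    frozenset({"S2"}): "III",
    frozenset({"S1", "S3"}): "IV",
    frozenset({"S2", "S3"}): "V",
    frozenset({"S3"}): "VI",
    frozenset({"S1", "S2", "S3"}): "VII",
}


@dataclass
class TemporalClassification:
    """Partition of the union of three stage peak sets into 7 classes."""

    union_regions: list[GenomicInterval]
    memberships: list[frozenset]
    label_map: dict[frozenset, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP)
    )

    def class_counts(self) -> dict[str, int]:
        """Region count per display label, zero-filled over all 7 classes."""
        counts = {label: 0 for label in self.label_map.values()}
        for membership in self.memberships:
            counts[self.label_map[membership]] += 1
        return counts

    def labels(self) -> list[str]:
        return [self.label_map[m] for m in self.memberships]


def temporal_classify(
    s1: PeakSet,
    s2: PeakSet,
    s3: PeakSet,
    label_map: Mapping[frozenset, str] | None = None,
) -> TemporalClassification:
    """Classify the merged union of three stage peak sets by stage membership.

    Each merged region's membership is the subset of {S1, S2, S3} whose peak
    sets have >= 1 peak overlapping the region; every region has non-empty
    membership by construction.
    """
    union = merge_union([s1, s2, s3])
    stage_trees = {
        "S1": _chrom_trees(s1),
        "S2": _chrom_trees(s2),
        "S3": _chrom_trees(s3),
    }
    memberships = []
    for region in union:
        member = frozenset(
            stage for stage, trees in stage_trees.items()
            if _any_overlap(trees, region)
        )
        memberships.append(member)
    lm = dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP)
    return TemporalClassification(union, memberships, lm)


@dataclass
class CooccupancyResult:
    """Per-region partner overlap flags for a reference peak set."""

    reference: PeakSet
    flags: pd.DataFrame  # index: reference position, one bool column per partner

    def count(self, *partners: str) -> int:
        """Number of reference regions overlapped by every named partner."""
        if not partners:
            return len(self.reference)
        mask = np.ones(len(self.reference), dtype=bool)
        for name in partners:
            mask &= self.flags[name].to_numpy()
        return int(mask.sum())

    def subset(self, *partners: str) -> PeakSet:
        """Reference regions overlapped by every named partner."""
        mask = np.ones(len(self.reference), dtype=bool)
        for name in partners:
            mask &= self.flags[name].to_numpy()
        return [p for p, keep in zip(self.reference, mask) if keep]


def cooccupancy(
    reference: PeakSet, partners: Mapping[str, PeakSet]
) -> CooccupancyResult:
    """Flag each reference region by overlap with each named partner set."""
    data = {}
    for name, partner in partners.items():
        trees = _chrom_trees(partner)
        data[name] = [_any_overlap(trees, r) for r in reference]
    flags = pd.DataFrame(data, dtype=bool) if data else pd.DataFrame(
        index=range(len(reference))
    )
    return CooccupancyResult(list(reference), flags)


def overlap_fraction(set_a: PeakSet, set_b: PeakSet) -> float:
    """Percentage of regions in A overlapped by at least one region of B."""
    if len(set_a) == 0:
        raise ConfigError("overlap_fraction undefined for an empty reference set")
    trees = _chrom_trees(set_b)
    hits = sum(1 for a in set_a if _any_overlap(trees, a))
    return 100.0 * hits / len(set_a)


@dataclass
class PeakGeneAssignment:
    """Nearest-gene-within-window assignment of peaks, both directions."""

    peak_to_gene: dict[int, tuple[str, int]]  # peak index -> (gene_id, distance)
    gene_to_peaks: dict[str, list[tuple[int, int]]]  # gene_id -> [(peak idx, dist)]
    window: int


def _edge_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Edge-to-edge distance between two intervals; 0 if overlapping."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def assign_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    window: int = 20_000,
    use_tss: bool = False,
) -> PeakGeneAssignment:
    """Assign each peak its nearest gene within ``window`` bases.

    Distance is measured edge-to-edge between the peak and the gene body
    (0 when they overlap); with ``use_tss`` the gene is collapsed to its TSS.
    Exact distance ties go to the lexicographically smaller gene id.  Peaks
    with no candidate stay unassigned.
    """
    if window < 0:
        raise ConfigError("window must be >= 0")
    gene_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)

    peak_to_gene: dict[int, tuple[str, int]] = {}
    gene_to_peaks: dict[str, list[tuple[int, int]]] = {}
    for i, peak in enumerate(peaks):
        best: tuple[int, str] | None = None
        for g in gene_by_chrom.get(peak.chrom, ()):
            iv = g.interval
            if use_tss:
                iv = GenomicInterval(iv.chrom, g.tss, g.tss + 1, strand=iv.strand)
            dist = _edge_distance(peak, iv)
            if dist is None or dist > window:
                continue
            if best is None or (dist, g.gene_id) < best:
                best = (dist, g.gene_id)
        if best is not None:
            dist, gene_id = best
            peak_to_gene[i] = (gene_id, dist)
            gene_to_peaks.setdefault(gene_id, []).append((i, dist))
    return PeakGeneAssignment(peak_to_gene, gene_to_peaks, window)


@dataclass
class MotifCooccurrence:
    """Per-peak motif-family presence flags and combination proportions."""

    flags: pd.DataFrame  # one bool column per motif family
    proportions: dict[frozenset, float]  # family combination -> share of peaks

    def proportion(self, *families: str) -> float:
        """Share of peaks carrying exactly the named families (no others)."""
        return self.proportions.get(frozenset(families), 0.0)


def motif_cooccurrence(
    peaks: PeakSet, motif_hits: Mapping[str, PeakSet]
) -> MotifCooccurrence:
    """Per peak, flag each motif family with >= 1 hit interval overlapping it.

    Proportions are reported per exact flag combination (including the empty
    "none" combination) and sum to 1 over all peaks.
    """
    occ = cooccupancy(peaks, motif_hits)
    combos: dict[frozenset, int] = {}
    families = list(motif_hits)
    for _, row in occ.flags.iterrows():
        combo = frozenset(f for f in families if row[f])
        combos[combo] = combos.get(combo, 0) + 1
    n = max(len(peaks), 1)
    proportions = {combo: count / n for combo, count in combos.items()}
    return MotifCooccurrence(occ.flags, proportions)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_scan(
    sequence: str, pwm: np.ndarray, threshold: float
) -> list[tuple[int, str, float]]:
    """Scan both strands of a sequence with a log-odds PWM.

    ``pwm`` has 4 rows (A, C, G, T) and one column per motif position.  A
    window's score is the sum of the column log-odds of the observed bases;
    windows containing N score -inf.  Hits with score >= threshold are
    returned as ``(offset, strand, score)`` with the offset of the window's
    leftmost base in forward coordinates; at most one hit is reported per
    (offset, strand).
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ConfigError("pwm must have 4 rows ordered A, C, G, T")
    width = pwm.shape[1]
    seq = sequence.upper()
    if len(seq) < width:
        return []

    def score_at(s: str, offset: int) -> float:
        total = 0.0
        for j in range(width):
            base = s[offset + j]
            if base == "N":
                return float("-inf")
            total += pwm[_BASE_ROW[base], j]
        return total

    rc = seq.translate(_COMPLEMENT)[::-1]
    hits: list[tuple[int, str, float]] = []
    for offset in range(len(seq) - width + 1):
        fwd = score_at(seq, offset)
        if fwd >= threshold:
            hits.append((offset, "+", fwd))
        # window [offset, offset+width) on the reverse strand corresponds to
        # offset len-width-offset in the reverse-complemented string
        rev = score_at(rc, len(seq) - width - offset)
        if rev >= threshold:
            hits.append((offset, "-", rev))
    return hits
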