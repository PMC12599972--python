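import numpy as np
import pytest

from conftest import coverage_bitmap, iv, random_peak_set
from ectoreg.errors import ConfigError
from ectoreg.formats_io import GeneModel, GenomicInterval
from ectoreg.peaktools import (
    assign_genes,
    cooccupancy,
    merge_union,
    motif_cooccurrence,
    overlap_fraction,
    overlaps,
    pwm_scan,
    temporal_classify,
)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (iv("c", 0, 100), iv("c", 100, 200), False),  # abutting, half-open
        (iv("c", 0, 100), iv("c", 99, 200), True),
        (iv("chr1", 0, 100), iv("chr2", 0, 100), False),
        (iv("c", 50, 60), iv("c", 0, 100), True),  # containment
    ],
)
def test_overlaps(a, b, expected):
    assert overlaps(a, b) is expected
    assert overlaps(b, a) is expected  # symmetry


class TestMergeUnion:
    def test_overlapping_pair_merges(self):
        merged = merge_union([[iv("c", 0, 100)], [iv("c", 50, 150)]])
        assert [(m.start, m.end) for m in merged] == [(0, 150)]

    def test_disjoint_pair_stays_separate(self):
        merged = merge_union([[iv("c", 0, 100)], [iv("c", 200, 300)]])
        assert len(merged) == 2

    def test_chain_collapses_to_one_region(self):
        merged = merge_union(
            [[iv("c", 0, 100), iv("c", 90, 190), iv("c", 180, 280)]]
        )
        assert [(m.start, m.end) for m in merged] == [(0, 280)]

    def test_book_ended_intervals_merge(self):
        merged = merge_union([[iv("c", 0, 100)], [iv("c", 100, 200)]])
        assert [(m.start, m.end) for m in merged] == [(0, 200)]

    def test_matches_per_base_coverage_components(self, rng):
        for _ in range(100):
            peaks = random_peak_set(rng)
            if not peaks:
                continue
            merged = merge_union([peaks])
            cov = coverage_bitmap(peaks)
            # maximal runs of covered bases
            edges = np.flatnonzero(np.diff(np.r_[0, cov.view(np.int8), 0]))
            runs = list(zip(edges[::2], edges[1::2]))
            assert [(m.start, m.end) for m in merged] == runs


class TestTemporalClassify:
    def test_single_stage_region(self):
        tc = temporal_classify([iv("c", 0, 100)], [], [])
        assert tc.memberships == [frozenset({"S1"})]
        assert tc.class_counts()["I"] == 1

    def test_identical_sets_are_triple_bound(self):
        peak = [iv("c", 0, 100)]
        tc = temporal_classify(peak, peak, peak)
        assert tc.memberships == [frozenset({"S1", "S2", "S3"})]
        assert tc.class_counts()["VII"] == 1

    def test_chained_overlap_pools_membership(self):
        # no single base is covered by all three stages, but the merged
        # region is: membership is pooled at the region level
        tc = temporal_classify(
            [iv("c", 0, 100)], [iv("c", 90, 190)], [iv("c", 180, 280)]
        )
        assert len(tc.union_regions) == 1
        assert tc.memberships == [frozenset({"S1", "S2", "S3"})]

    def test_counts_sum_to_union_and_match_bitmap_oracle(self, rng):
        for _ in range(150):
            sets = [random_peak_set(rng) for _ in range(3)]
            tc = temporal_classify(*sets)
            assert sum(tc.class_counts().values()) == len(tc.union_regions)
            covs = [coverage_bitmap(s) for s in sets]
            for region, membership in zip(tc.union_regions, tc.memberships):
                oracle = frozenset(
                    stage
                    for stage, cov in zip(("S1", "S2", "S3"), covs)
                    if cov[region.start:region.end].any()
                )
                assert membership == oracle
                assert oracle  # non-empty by construction

    def test_custom_label_map(self):
        labels = {m: f"class{i}" for i, m in enumerate(
            [frozenset(s) for s in (
                {"S1"}, {"S1", "S2"}, {"S2"}, {"S1", "S3"},
                {"S2", "S3"}, {"S3"}, {"S1", "S2", "S3"})]
        )}
        tc = temporal_classify([iv("c", 0, 10)], [], [], label_map=labels)
        assert tc.labels() == ["class0"]


class TestCooccupancy:
    def test_flags_per_partner(self):
        ref = [iv("c", 0, 100), iv("c", 500, 600)]
        occ = cooccupancy(ref, {"x": [iv("c", 50, 70)], "y": [iv("c", 550, 560)]})
        assert list(occ.flags["x"]) == [True, False]
        assert list(occ.flags["y"]) == [False, True]
        assert occ.count("x", "y") == 0

    def test_no_partners_all_false(self):
        occ = cooccupancy([iv("c", 0, 100)], {})
        assert occ.count() == 1  # vacuous conjunction
        assert occ.flags.empty or not occ.flags.any().any()

    def test_triple_subset_contained_in_pairwise(self, rng):
        ref = random_peak_set(rng, max_peaks=10)
        partners = {k: random_peak_set(rng, max_peaks=10) for k in "abc"}
        occ = cooccupancy(ref, partners)
        triple = {id(p) for p in occ.subset("a", "b", "c")}
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            assert triple <= {id(p) for p in occ.subset(*pair)}


class TestOverlapFraction:
    def _disjoint_sets(self, n_total, n_hit):
        ref, partner = [], []
        for i in range(n_total):
            start = i * 1000
            ref.append(iv("c", start, start + 100))
            if i < n_hit:
                partner.append(iv("c", start + 50, start + 150))
        return ref, partner

    def test_printed_count_arithmetic(self):
        ref, partner = self._disjoint_sets(3050, 2901)
        assert round(overlap_fraction(ref, partner)) == 95
        ref, partner = self._disjoint_sets(4015, 2901)
        assert round(overlap_fraction(ref, partner)) == 72

    def test_identity_is_100(self):
        ref = [iv("c", 0, 10), iv("c", 50, 60)]
        assert overlap_fraction(ref, ref) == 100.0

    def test_empty_reference_is_error(self):
        with pytest.raises(ConfigError):
            overlap_fraction([], [iv("c", 0, 10)])

    def test_monotone_in_partner_set(self, rng):
        ref = random_peak_set(rng, max_peaks=10) or [iv("c", 0, 10)]
        partner = []
        last = 0.0
        for _ in range(10):
            partner += random_peak_set(rng, max_peaks=3)
            frac = overlap_fraction(ref, partner) if partner else 0.0
            assert frac >= last
            last = frac


class TestAssignGenes:
    def _gene(self, gene_id, start, end, strand="+"):
        return GeneModel(gene_id, GenomicInterval("c", start, end, strand=strand))

    def test_within_window_assigned(self):
        peaks = [iv("c", 0, 1000)]
        genes = [self._gene("g", 11_000, 12_000)]  # 10 kb downstream
        result = assign_genes(peaks, genes, window=20_000)
        assert result.peak_to_gene[0] == ("g", 10_000)

    def test_beyond_window_unassigned(self):
        peaks = [iv("c", 0, 1000)]
        genes = [self._gene("g", 26_000, 27_000)]  # 25 kb away
        result = assign_genes(peaks, genes, window=20_000)
        assert result.peak_to_gene == {}

    def test_nearest_wins_and_ties_break_lexicographically(self):
        peaks = [iv("c", 100_000, 101_000)]
        genes = [
            self._gene("far", 116_000, 117_000),   # 15 kb
            self._gene("near", 106_000, 107_000),  # 5 kb
        ]
        result = assign_genes(peaks, genes, window=20_000)
        assert result.peak_to_gene[0][0] == "near"
        tied = [self._gene("b", 106_000, 107_000),
                self._gene("a", 94_000, 95_000)]  # both 5 kb
        result = assign_genes(peaks, tied, window=20_000)
        assert result.peak_to_gene[0][0] == "a"

    def test_agrees_with_brute_force(self, rng):
        def brute(peaks, genes, window):
            out = {}
            for i, p in enumerate(peaks):
                candidates = []
                for g in genes:
                    q = g.interval
                    if p.chrom != q.chrom:
                        continue
                    if p.start < q.end and q.start < p.end:
                        d = 0
                    elif p.end <= q.start:
                        d = q.start - p.end
                    else:
                        d = p.start - q.end
                    if d <= window:
                        candidates.append((d, g.gene_id))
                if candidates:
                    out[i] = min(candidates)[1]
            return out

        for _ in range(200):
            peaks = random_peak_set(rng, max_peaks=6)
            genes = [
                GeneModel(f"g{j}", GenomicInterval("c", s, s + int(rng.integers(1, 500))))
                for j, s in enumerate(rng.integers(0, 9_000, size=4))
            ]
            window = int(rng.integers(0, 3_000))
            result = assign_genes(peaks, genes, window=window)
            got = {i: g for i, (g, _) in result.peak_to_gene.items()}
            assert got == brute(peaks, genes, window)


class TestMotifCooccurrence:
    def test_hand_enumeration(self):
        peaks = [iv("c", 0, 100), iv("c", 200, 300), iv("c", 400, 500)]
        hits = {
            "Fox": [iv("c", 10, 20), iv("c", 210, 220), iv("c", 410, 420)],
            "Sox": [iv("c", 10, 20), iv("c", 210, 220)],
            "Pou": [],
        }
        mc = motif_cooccurrence(peaks, hits)
        assert mc.proportion("Fox", "Sox") == pytest.approx(2 / 3)
        assert mc.proportion("Fox") == pytest.approx(1 / 3)
        assert mc.proportion("Pou") == 0.0

    def test_no_hits_gives_none_combination(self):
        mc = motif_cooccurrence([iv("c", 0, 10)], {"Fox": []})
        assert mc.proportion() == 1.0

    def test_proportions_partition_unity(self, rng):
        peaks = random_peak_set(rng, max_peaks=10) or [iv("c", 0, 10)]
        hits = {k: random_peak_set(rng, max_peaks=5) for k in ("a", "b")}
        mc = motif_cooccurrence(peaks, hits)
        assert sum(mc.proportions.values()) == pytest.approx(1.0)


class TestPwmScan:
    def _tata_pwm(self):
        # log-odds 1.0 for the TATA consensus base, strongly negative else
        pwm = np.full((4, 4), -10.0)
        for j, base in enumerate("TATA"):
            pwm["ACGT".index(base), j] = 1.0
        return pwm

    def test_consensus_hit_scored_by_hand(self):
        hits = pwm_scan("GGTATAGG", self._tata_pwm(), threshold=4.0)
        forward = [h for h in hits if h[1] == "+"]
        assert forward == [(2, "+", 4.0)]
        # TATA is palindromic: the same locus also scores on the minus strand
        assert (2, "-", 4.0) in hits
        assert len(hits) == len({(o, s) for o, s, _ in hits})

    def test_threshold_above_maximum_gives_no_hits(self):
        assert pwm_scan("GGTATAGG", self._tata_pwm(), threshold=5.0) == []

    def test_sequence_shorter_than_motif(self):
        assert pwm_scan("TAT", self._tata_pwm(), threshold=0.0) == []

    def test_n_bases_score_minus_infinity(self):
        assert pwm_scan("GGTANAGG", self._tata_pwm(), threshold=-100.0) != []
        hits = pwm_scan("NNNNNNNN", self._tata_pwm(), threshold=-1e9)
        assert hits == []

    def test_reverse_strand_hit(self):
        # revcomp of CCGT is ACGG; scan a motif matching ACGG on the minus strand
        pwm = np.full((4, 4), -10.0)
        for j, base in enumerate("ACGG"):
            pwm["ACGT".index(base), j] = 1.0
        hits = pwm_scan("TTCCGTTT", pwm, threshold=4.0)
        assert hits == [(2, "-", 4.0)]
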