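"""Peak calling, gene assignment, occupancy scoring, ranking, GA repeats."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from gafpause import tracks
from gafpause.targets import (
    GARepeat,
    Peak,
    PromoterScore,
    assign_peaks,
    assign_ranks,
    call_enriched_regions,
    promoter_gaf_score,
    rank_sizes,
    scan_ga_repeats,
)
from gafpause.tracks import EnrichmentProfile, GeneModel, GenomeSequence


def enr(vec):
    return EnrichmentProfile({"chr1": np.asarray(vec, dtype=float)})


class TestCallEnrichedRegions:
    def test_flat_baseline_gives_no_peaks(self):
        assert call_enriched_regions(enr(np.ones(1000))) == []

    def test_single_run(self):
        vec = np.ones(1000)
        vec[100:200] = 3.0
        (peak,) = call_enriched_regions(enr(vec))
        assert (peak.start, peak.end) == (100, 200)
        assert peak.fold_enrichment == 3.0

    def test_runs_with_small_gap_merge(self):
        vec = np.ones(1000)
        vec[100:160] = 3.0
        vec[170:230] = 3.0
        (peak,) = call_enriched_regions(enr(vec))
        assert (peak.start, peak.end) == (100, 230)

    def test_runs_with_large_gap_stay_split(self):
        vec = np.ones(1000)
        vec[100:160] = 3.0
        vec[200:260] = 3.0
        assert len(call_enriched_regions(enr(vec))) == 2

    def test_summit_leftmost_argmax(self):
        vec = np.ones(1000)
        vec[100:200] = 3.0
        vec[150:160] = 5.0
        (peak,) = call_enriched_regions(enr(vec))
        assert peak.summit == 150

    def test_narrow_run_dropped(self):
        vec = np.ones(1000)
        vec[100:130] = 3.0
        assert call_enriched_regions(enr(vec), min_width=50) == []


class TestAssignPeaks:
    g = GeneModel("g1", "chr1", 2000, 5000, "+")  # promoter window [1500, 2000)

    def peak(self, start, end):
        return Peak("chr1", start, end, start, 3.0)

    def test_promoter_only(self):
        (a,) = assign_peaks([self.g], [self.peak(1700, 1900)])
        assert a.category == "promoter_only"
        assert a.max_promoter_fold == 3.0

    def test_promoter_and_genic(self):
        (a,) = assign_peaks([self.g], [self.peak(1700, 1900), self.peak(2300, 2400)])
        assert a.category == "promoter_and_genic"

    def test_genic_only(self):
        (a,) = assign_peaks([self.g], [self.peak(2300, 2400)])
        assert a.category == "genic_only"
        assert a.max_promoter_fold == 0.0

    def test_distant_peak_counts_as_intergenic_neighbor(self):
        (a,) = assign_peaks([self.g], [self.peak(9000, 9100)])
        assert a.category == "intergenic_neighbor"

    def test_no_peaks_category_none(self):
        (a,) = assign_peaks([self.g], [])
        assert a.category == "none"

    def test_minus_strand_promoter_is_downstream_in_genomic_coords(self):
        gm = GeneModel("gm", "chr1", 2000, 5000, "-")  # tss 4999, window [5000, 5500)
        (a,) = assign_peaks([gm], [self.peak(5100, 5200)])
        assert a.category == "promoter_only"

    def test_category_counts_sum_to_gene_count(self):
        genes = [GeneModel(f"g{i}", "chr1", 2000 + 6000 * i, 5000 + 6000 * i, "+")
                 for i in range(5)]
        peaks = [self.peak(1700, 1900), self.peak(8300, 8400)]
        cats = [a.category for a in assign_peaks(genes, peaks)]
        assert len(cats) == len(genes)


class TestPromoterScore:
    def make_track(self, value, chrom_lengths={"chr1": 10_000}):
        return tracks.CoverageTrack(
            {c: np.full(L, float(value)) for c, L in chrom_lengths.items()},
            scale="per_million", total_count=1_000_000,
        )

    def test_ratio_of_sums(self, plus_gene):
        chip, inp = self.make_track(0.4), self.make_track(0.2)
        # sums: chip 200, input 100; tiny pseudocount -> ratio ~2
        s = promoter_gaf_score(plus_gene, chip, inp, pseudocount=1e-9)
        assert s.gaf_score == pytest.approx(2.0, abs=1e-6)

    def test_identity_when_chip_equals_input(self, plus_gene):
        chip = self.make_track(0.3)
        s = promoter_gaf_score(plus_gene, chip, chip)
        assert s.gaf_score == pytest.approx(1.0)

    def test_minus_strand_matches_mirrored_plus(self):
        """A minus-strand gene scores identically to the mirrored plus-strand
        construction on position-reversed tracks."""
        L = 10_000
        rng = np.random.default_rng(4)
        chip_vec, inp_vec = rng.random(L), rng.random(L) + 0.5

        def track(vec):
            return tracks.CoverageTrack({"chr1": vec.copy()}, "per_million", 1_000_000)

        gm = GeneModel("gm", "chr1", 2000, 5000, "-")
        gp = gm.mirrored(L)
        assert gp.strand == "+"
        s_minus = promoter_gaf_score(gm, track(chip_vec), track(inp_vec))
        s_plus = promoter_gaf_score(gp, track(chip_vec[::-1]), track(inp_vec[::-1]))
        assert s_minus.gaf_score == pytest.approx(s_plus.gaf_score, rel=1e-12)


class TestAssignRanks:
    def scores(self, values):
        return [PromoterScore(f"g{i}", float(v)) for i, v in enumerate(values)]

    def test_eight_scores_split_in_pairs(self):
        ranked = assign_ranks(self.scores([2, 3, 4, 5, 6, 7, 8, 9]))
        by_rank = {}
        for s in ranked:
            by_rank.setdefault(s.rank, []).append(s.gaf_score)
        assert by_rank == {"I": [2, 3], "II": [4, 5], "III": [6, 7], "IV": [8, 9]}

    def test_365_genes_split_92_91_91_91(self):
        rng = np.random.default_rng(0)
        ranked = assign_ranks(self.scores(2 + 300 * rng.random(365)))
        sizes = rank_sizes(ranked)
        assert [sizes[r] for r in ("I", "II", "III", "IV")] == [92, 91, 91, 91]

    def test_below_threshold_scores_unranked(self):
        ranked = assign_ranks(self.scores([1.0, 1.5, 2, 3, 4, 5]))
        unranked = {s.gene_id for s in ranked if s.rank == "unranked"}
        assert unranked == {"g0", "g1"}

    def test_all_below_threshold_raises(self):
        with pytest.raises(ValueError, match="score >= 2.0"):
            assign_ranks(self.scores([0.5, 1.0, 1.5, 1.9]))

    def test_groups_contiguous_in_score(self):
        rng = np.random.default_rng(1)
        ranked = assign_ranks(self.scores(2 + 50 * rng.random(101)))
        ordered = sorted((s for s in ranked if s.rank != "unranked"),
                         key=lambda s: s.gaf_score)
        labels = [s.rank for s in ordered]
        assert labels == sorted(labels, key=("I", "II", "III", "IV").index)

    @given(st.permutations(range(12)))
    def test_order_invariant_and_idempotent(self, order):
        base = self.scores(np.linspace(2, 40, 12))
        ranked = assign_ranks([base[i] for i in order])
        again = assign_ranks(ranked)
        assert {s.gene_id: s.rank for s in ranked} == {s.gene_id: s.rank for s in again}
        assert {s.gene_id: s.rank for s in ranked} == {
            s.gene_id: s.rank for s in assign_ranks(base)
        }


def brute_force_ga_runs(seq, min_units):
    """Independent enumeration: every maximal aligned (GA)n / (TC)n run."""
    found = []
    for unit in ("GA", "TC"):
        i = 0
        while i < len(seq) - 1:
            n = 0
            j = i
            while seq[j : j + 2] == unit:
                n += 1
                j += 2
            if n >= min_units:
                found.append((i, i + 2 * n, n))
                i = j
            else:
                i += 1
    return sorted(found)


class TestGARepeats:
    def genome(self, s):
        return GenomeSequence({"chr1": s})

    def test_simple_repeat(self):
        (r,) = scan_ga_repeats(self.genome("TTGAGAGATT"))
        assert (r.start, r.end, r.n_units) == (2, 8, 3)

    def test_below_minimum_ignored(self):
        assert scan_ga_repeats(self.genome("TTGAGATT"), min_units=3) == []

    def test_tc_strand_detected(self):
        (r,) = scan_ga_repeats(self.genome("TCTCTCTC"))
        assert (r.start, r.end, r.n_units) == (0, 8, 4)

    def test_span_invariant(self):
        for r in scan_ga_repeats(self.genome("AAGAGAGAGATTTCTCTCAA")):
            assert r.end - r.start == 2 * r.n_units

    @given(st.text(alphabet="GATC", min_size=0, max_size=60))
    def test_matches_brute_force_enumeration(self, seq):
        got = sorted((r.start, r.end, r.n_units)
                     for r in scan_ga_repeats(self.genome(seq)) if seq)
        assert got == brute_force_ga_runs(seq, 3)
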