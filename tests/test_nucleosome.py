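"""MNase size selection, midpoint metagenes, section KS, dinucleotide profiles."""
import numpy as np
import pytest

from gafpause import tracks
from gafpause.nucleosome import (
    filter_mnase_fragments,
    metagene,
    pooled_relative_midpoints,
    sample_nontargets,
    section_ks,
    ss_dinucleotide_profile,
)
from gafpause.tracks import FragmentSet, GeneModel, GenomeSequence
from conftest import frags_from_rel_midpoints


def frags_of_lengths(lengths, start=1000):
    arr = np.array([[start, start + ln] for ln in lengths])
    return FragmentSet("mn", "WT", "mnase", {"chr1": arr})


class TestSizeFilter:
    def test_bounds_inclusive(self):
        kept = filter_mnase_fragments(frags_of_lengths([119, 120, 150, 180, 181]))
        assert sorted(kept.lengths()) == [120, 150, 180]

    def test_empty_input(self):
        assert filter_mnase_fragments(FragmentSet("mn")).total_count == 0

    def test_mononucleosome_lengths_all_kept(self):
        kept = filter_mnase_fragments(frags_of_lengths([147] * 5))
        assert kept.total_count == 5


class TestMetagene:
    lens = {"chr1": 10_000}

    def pm_midpoints(self, frags):
        return tracks.normalize_per_million(
            tracks.build_coverage(frags, self.lens, "midpoint")
        )

    def test_plus_strand_midpoint_lands_at_relative_position(self, plus_gene):
        track = self.pm_midpoints(frags_from_rel_midpoints(plus_gene, [130]))
        prof = metagene([plus_gene], track)
        nz = np.flatnonzero(prof.values)
        assert list(prof.positions[nz]) == [130]

    def test_minus_strand_mirrors_position(self, minus_gene):
        # genomic midpoint at tss - 130 appears at r = +130
        mids = np.array([minus_gene.tss - 130])
        arr = np.column_stack([mids - 73, mids + 74])
        frags = FragmentSet("mn", "WT", "mnase", {"chr1": arr})
        prof = metagene([minus_gene], self.pm_midpoints(frags))
        nz = np.flatnonzero(prof.values)
        assert list(prof.positions[nz]) == [130]

    def test_mean_of_identical_windows(self):
        g1 = GeneModel("g1", "chr1", 2000, 5000, "+")
        g2 = GeneModel("g2", "chr1", 2000, 5000, "+")
        track = self.pm_midpoints(frags_from_rel_midpoints(g1, [50, 130]))
        single = metagene([g1], track)
        double = metagene([g1, g2], track)
        assert np.array_equal(single.values, double.values)

    def test_mass_conservation(self, plus_gene):
        rel = np.array([-400, -100, 0, 130, 305, 480])
        frags = frags_from_rel_midpoints(plus_gene, rel)
        track = self.pm_midpoints(frags)
        prof = metagene([plus_gene], track)
        expected = len(rel) * 1e6 / frags.total_count
        assert prof.values.sum() * prof.n_genes == pytest.approx(expected)

    def test_edge_window_dropped_and_counted(self):
        edge = GeneModel("e", "chr1", 100, 900, "+")
        ok = GeneModel("ok", "chr1", 2000, 5000, "+")
        track = self.pm_midpoints(frags_from_rel_midpoints(ok, [130]))
        prof = metagene([edge, ok], track)
        assert prof.n_genes == 1 and prof.n_dropped == 1

    def test_empty_gene_set_rejected(self, plus_gene):
        track = self.pm_midpoints(frags_from_rel_midpoints(plus_gene, [130]))
        with pytest.raises(ValueError, match="non-empty"):
            metagene([], track)


class TestSectionKS:
    def test_identical_samples_null(self, plus_gene):
        frags = frags_from_rel_midpoints(plus_gene, np.arange(-490, 490, 37))
        tests = section_ks([plus_gene], frags, frags, "four_sections", min_midpoints=3)
        for t in tests:
            assert t.ks_D == 0.0 and t.p_value == 1.0

    def test_disjoint_support_skipped(self, plus_gene):
        wt = frags_from_rel_midpoints(plus_gene, np.arange(-240, -10, 10))
        mut = frags_from_rel_midpoints(plus_gene, np.arange(-490, -260, 10))
        tests = section_ks([plus_gene], wt, mut, "upstream_halves")
        proximal = next(t for t in tests if t.section == (-250, 0))
        assert proximal.skipped
        assert proximal.n_mut == 0

    def test_complete_separation_d_one(self, plus_gene):
        wt = frags_from_rel_midpoints(plus_gene, [-100, -90, -80])
        mut = frags_from_rel_midpoints(plus_gene, [-60, -50, -40])
        tests = section_ks([plus_gene], wt, mut, "upstream_halves", min_midpoints=3)
        proximal = next(t for t in tests if t.section == (-250, 0))
        assert proximal.ks_D == 1.0

    def test_d_matches_brute_force_ecdf(self, plus_gene):
        rng = np.random.default_rng(8)
        wt_pos = rng.integers(-250, 0, size=18)
        mut_pos = rng.integers(-250, 0, size=15)
        wt = frags_from_rel_midpoints(plus_gene, wt_pos)
        mut = frags_from_rel_midpoints(plus_gene, mut_pos)
        tests = section_ks([plus_gene], wt, mut, "upstream_halves")
        proximal = next(t for t in tests if t.section == (-250, 0))
        grid = np.union1d(wt_pos, mut_pos)
        brute = max(
            abs((wt_pos <= v).mean() - (mut_pos <= v).mean()) for v in grid
        )
        assert proximal.ks_D == pytest.approx(brute, rel=1e-12)

    def test_pooling_respects_strand(self, minus_gene):
        mids = minus_gene.tss - np.array([130, -200])  # rel +130 and -200
        arr = np.column_stack([mids - 73, mids + 74])
        frags = FragmentSet("mn", "WT", "mnase", {"chr1": arr})
        rel = pooled_relative_midpoints([minus_gene], frags)
        assert sorted(rel) == [-200, 130]


class TestSSProfile:
    def test_all_strong_prefix(self):
        seq = "GGCC" + "AT" * 498
        genome = GenomeSequence({"chr1": seq * 2})
        gene = GeneModel("g", "chr1", 500, 1500, "+")
        prof = ss_dinucleotide_profile(genome, [gene], smooth_bp=1)
        # window starts at genomic 0: GG, GC, CC at r = -500, -499, -498
        assert list(prof.raw[:3]) == [1.0, 1.0, 1.0]
        assert prof.raw[3] == 0.0

    def test_weak_sequence_is_zero(self):
        genome = GenomeSequence({"chr1": "AT" * 1000})
        gene = GeneModel("g", "chr1", 500, 1500, "+")
        prof = ss_dinucleotide_profile(genome, [gene], smooth_bp=1)
        assert np.nanmax(prof.raw) == 0.0

    def test_minus_strand_equals_plus_by_complement_closure(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        genome = GenomeSequence({"chr1": seq})
        gm = GeneModel("gm", "chr1", 1200, 2800, "-")
        gp = gm.mirrored(4000)
        mirrored = genome.mirrored()
        p_minus = ss_dinucleotide_profile(genome, [gm], smooth_bp=1)
        p_plus = ss_dinucleotide_profile(mirrored, [gp], smooth_bp=1)
        assert np.allclose(p_minus.raw, p_plus.raw, equal_nan=True)

    def test_n_bases_excluded_from_denominator(self):
        seq = "N" * 2000
        genome = GenomeSequence({"chr1": seq})
        gene = GeneModel("g", "chr1", 600, 1400, "+")
        prof = ss_dinucleotide_profile(genome, [gene], smooth_bp=1)
        assert np.all(np.isnan(prof.raw))


class TestSampleNontargets:
    def pool(self, per_arm):
        genes = []
        for arm, n in per_arm.items():
            for i in range(n):
                genes.append(GeneModel(f"{arm}_g{i}", arm, 10_000 * i, 10_000 * i + 2000, "+"))
        return genes

    def test_whole_pool_returned(self):
        pool = self.pool({"2L": 3, "2R": 3})
        got = sample_nontargets(pool, n=6, seed=0)
        assert {g.gene_id for g in got} == {g.gene_id for g in pool}

    def test_same_seed_reproducible(self):
        pool = self.pool({a: 30 for a in ("2L", "2R", "3L", "3R", "X")})
        a = sample_nontargets(pool, n=50, seed=42)
        b = sample_nontargets(pool, n=50, seed=42)
        assert [g.gene_id for g in a] == [g.gene_id for g in b]

    def test_stratification_remainder_rule(self):
        pool = self.pool({a: 30 for a in ("2L", "2R", "3L", "3R", "X")})
        got = sample_nontargets(pool, n=12, seed=0)
        counts = {}
        for g in got:
            counts[g.chrom] = counts.get(g.chrom, 0) + 1
        assert [counts[a] for a in ("2L", "2R", "3L", "3R", "X")] == [3, 3, 2, 2, 2]

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            sample_nontargets(self.pool({"2L": 3}), n=5, seed=0)
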