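"""Coverage construction, depth normalization, enrichment and format I/O."""
import numpy as np
import pytest

from gafpause import tracks


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadGenes:
    def test_bed_strand_aware_tss(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t1000\t3000\tgA\t0\t+\nchr1\t5000\t7000\tgB\t0\t-\n")
        genes = tracks.load_genes(p)
        assert genes[0].tss == 1000
        assert genes[1].tss == 6999

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t0\t100\tgA\t0\t+\nchr1\t500\t600\tgA\t0\t+\n")
        with pytest.raises(ValueError, match="duplicate"):
            tracks.load_genes(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t0\t100\tgA\t0\t+\nchr1\tnope\t100\tgB\t0\t+\n")
        with pytest.raises(ValueError, match=":2"):
            tracks.load_genes(p)

    def test_unknown_strand_symbol(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t0\t100\tgA\t0\t*\n")
        with pytest.raises(ValueError, match="strand"):
            tracks.load_genes(p)

    def test_gff3_converts_coordinates_and_counts_tss(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t3000\t.\t+\t.\tID=gA\n"
            "chr1\tsrc\tmRNA\t1001\t3000\t.\t+\t.\tID=gA.1;Parent=gA\n"
            "chr1\tsrc\tmRNA\t1201\t3000\t.\t+\t.\tID=gA.2;Parent=gA\n"
            "chr1\tsrc\tgene\t6001\t8000\t.\t-\t.\tID=gB\n"
        )
        genes = tracks.load_genes(write(tmp_path, "g.gff3", text), "gff3")
        ga = next(g for g in genes if g.gene_id == "gA")
        gb = next(g for g in genes if g.gene_id == "gB")
        assert (ga.start, ga.end, ga.n_tss_annotated) == (1000, 3000, 2)
        assert (gb.tss, gb.n_tss_annotated) == (7999, 1)

    def test_sorted_by_chrom_start(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr2\t0\t100\tgC\t0\t+\nchr1\t500\t700\tgB\t0\t+\nchr1\t0\t100\tgA\t0\t+\n")
        assert [g.gene_id for g in tracks.load_genes(p)] == ["gA", "gB", "gC"]


class TestLoadFragments:
    def test_bed_total_count(self, tmp_path):
        p = write(tmp_path, "f.bed", "chr1\t0\t50\nchr1\t100\t200\nchr2\t5\t10\n")
        assert tracks.load_fragments(p).total_count == 3

    def test_bedpe_template_extent(self, tmp_path):
        p = write(tmp_path, "f.bedpe", "chr1\t100\t150\tchr1\t200\t260\tfrag1\t0\t+\t-\n")
        frags = tracks.load_fragments(p, "bedpe")
        assert list(frags.records()) == [("chr1", 100, 260)]

    def test_empty_file_warns_and_counts_zero(self, tmp_path, caplog):
        p = write(tmp_path, "f.bed", "")
        with caplog.at_level("WARNING"):
            frags = tracks.load_fragments(p)
        assert frags.total_count == 0
        assert any("no fragments" in m for m in caplog.messages)

    def test_inverted_interval_rejected(self, tmp_path):
        p = write(tmp_path, "f.bed", "chr1\t200\t100\n")
        with pytest.raises(ValueError, match="end"):
            tracks.load_fragments(p)

    def test_sam_proper_pairs(self, tmp_path):
        sam = (
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "r1\t99\tchr1\t101\t60\t50M\t=\t201\t150\t" + "A" * 50 + "\t*\n"
            "r1\t147\tchr1\t201\t60\t50M\t=\t101\t-150\t" + "A" * 50 + "\t*\n"
        )
        frags = tracks.load_fragments(write(tmp_path, "f.sam", sam), "sam")
        assert list(frags.records()) == [("chr1", 100, 250)]


class TestBuildCoverage:
    def test_full_fragment_fill(self, chrom_lengths):
        frags = tracks.FragmentSet("s", intervals={"chr1": [[10, 13]]})
        cov = tracks.build_coverage(frags, chrom_lengths)
        assert list(cov.data["chr1"][9:14]) == [0, 1, 1, 1, 0]
        assert cov.total_mass() == 3.0

    def test_midpoint_floor(self, chrom_lengths):
        frags = tracks.FragmentSet("s", intervals={"chr1": [[100, 250]]})
        cov = tracks.build_coverage(frags, chrom_lengths, "midpoint")
        assert cov.data["chr1"][175] == 1.0
        assert cov.total_mass() == 1.0

    def test_duplicates_are_additive(self, chrom_lengths):
        one = tracks.FragmentSet("s", intervals={"chr1": [[10, 20]]})
        two = tracks.FragmentSet("s", intervals={"chr1": [[10, 20], [10, 20]]})
        c1 = tracks.build_coverage(one, chrom_lengths)
        c2 = tracks.build_coverage(two, chrom_lengths)
        assert np.array_equal(c2.data["chr1"], 2 * c1.data["chr1"])

    def test_fragment_beyond_chromosome_end(self):
        frags = tracks.FragmentSet("s", intervals={"chr1": [[90, 120]]})
        with pytest.raises(ValueError, match="beyond"):
            tracks.build_coverage(frags, {"chr1": 100})

    def test_mass_conservation(self, chrom_lengths):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 9000, size=200)
        arr = np.column_stack([starts, starts + rng.integers(50, 200, size=200)])
        frags = tracks.FragmentSet("s", intervals={"chr1": arr})
        full = tracks.build_coverage(frags, chrom_lengths)
        mid = tracks.build_coverage(frags, chrom_lengths, "midpoint")
        assert full.total_mass() == float((arr[:, 1] - arr[:, 0]).sum())
        assert mid.total_mass() == frags.total_count


class TestNormalize:
    def test_per_million_arithmetic(self, chrom_lengths):
        cov = tracks.CoverageTrack({"chr1": np.full(10_000, 5.0)}, "raw", 2_000_000)
        pm = tracks.normalize_per_million(cov)
        assert pm.data["chr1"][0] == 2.5

    def test_identity_at_one_million(self, chrom_lengths):
        cov = tracks.CoverageTrack({"chr1": np.full(10_000, 5.0)}, "raw", 1_000_000)
        assert tracks.normalize_per_million(cov).data["chr1"][0] == 5.0

    def test_zero_track_stays_zero(self):
        cov = tracks.CoverageTrack({"chr1": np.zeros(100)}, "raw", 10)
        assert tracks.normalize_per_million(cov).total_mass() == 0.0

    def test_empty_sample_rejected(self):
        cov = tracks.CoverageTrack({"chr1": np.zeros(100)}, "raw", 0)
        with pytest.raises(ValueError, match="empty"):
            tracks.normalize_per_million(cov)


class TestEnrichment:
    def test_identity_for_any_pseudocount(self, flat_tracks):
        chip, _ = flat_tracks
        for pc in (0.1, 0.5, 7.0):
            enr = tracks.enrichment_over_input(chip, chip, pc)
            assert np.allclose(enr.data["chr1"], 1.0)

    def test_pseudocount_stabilized_ratio(self):
        chip = tracks.CoverageTrack({"chr1": np.full(10, 3.0)}, "per_million", 1)
        inp = tracks.CoverageTrack({"chr1": np.zeros(10)}, "per_million", 1)
        enr = tracks.enrichment_over_input(chip, inp, pseudocount=1.0)
        assert np.allclose(enr.data["chr1"], 4.0)

    def test_mismatched_chromosomes_rejected(self, flat_tracks):
        chip, _ = flat_tracks
        other = tracks.CoverageTrack({"chrX": np.ones(10)}, "per_million", 1)
        with pytest.raises(ValueError, match="chromosome"):
            tracks.enrichment_over_input(chip, other)

    def test_requires_per_million(self, chrom_lengths):
        raw = tracks.CoverageTrack({"chr1": np.ones(10_000)}, "raw", 10)
        with pytest.raises(ValueError, match="per_million"):
            tracks.enrichment_over_input(raw, raw)


def test_bedgraph_round_trip(tmp_path, chrom_lengths):
    rng = np.random.default_rng(3)
    vec = np.zeros(10_000)
    pos = rng.integers(0, 10_000, size=300)
    vec[pos] = rng.random(300) * 7
    cov = tracks.CoverageTrack({"chr1": vec}, "raw", 300)
    path = tmp_path / "t.bedgraph"
    tracks.write_bedgraph(cov, path)
    back = tracks.read_bedgraph(path, chrom_lengths, "raw", 300)
    assert np.abs(back.data["chr1"] - vec).max() < 1e-9


def test_depth_invariance_under_subsampling(chrom_lengths):
    """Halving a sample changes per-million coverage by <2% where raw
    coverage is deep (>=100 counts)."""
    rng = np.random.default_rng(7)
    starts = rng.integers(4000, 4050, size=20_000)  # deep pileup near 4000-4200
    arr = np.column_stack([starts, starts + 150])
    frags = tracks.FragmentSet("s", intervals={"chr1": arr})
    full = tracks.normalize_per_million(tracks.build_coverage(frags, chrom_lengths))
    half = tracks.normalize_per_million(
        tracks.build_coverage(frags.subsample(0.5, seed=11), chrom_lengths)
    )
    raw = tracks.build_coverage(frags, chrom_lengths).data["chr1"]
    deep = raw >= 100
    rel = np.abs(half.data["chr1"][deep] - full.data["chr1"][deep]) / full.data["chr1"][deep]
    assert rel.mean() < 0.02


def test_window_values_strand_aware(plus_gene, minus_gene, chrom_lengths):
    vec = np.arange(10_000, dtype=float)
    cov = tracks.CoverageTrack({"chr1": vec}, "per_million", 1)
    plus = tracks.window_values(cov, plus_gene, -3, 3)
    assert list(plus) == [1997, 1998, 1999, 2000, 2001, 2002]
    minus = tracks.window_values(cov, minus_gene, -3, 3)
    # tss = 4999; relative r sits at genomic tss - r
    assert list(minus) == [5002, 5001, 5000, 4999, 4998, 4997]
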