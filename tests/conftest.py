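import numpy as np
import pytest
from hypothesis import settings

from gafpause import tracks
from gafpause.simulate import SimConfig, Simulation

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def chrom_lengths():
    return {"chr1": 10_000}


@pytest.fixture
def flat_tracks(chrom_lengths):
    """Constant per-million ChIP (4.0) and input (2.0) tracks on chr1."""

    def make(value):
        return tracks.CoverageTrack(
            {c: np.full(L, value) for c, L in chrom_lengths.items()},
            scale="per_million",
            total_count=1_000_000,
        )

    return make(4.0), make(2.0)


@pytest.fixture
def plus_gene():
    return tracks.GeneModel("gplus", "chr1", 2000, 5000, "+")


@pytest.fixture
def minus_gene():
    return tracks.GeneModel("gminus", "chr1", 2000, 5000, "-")


def frags_from_rel_midpoints(gene, rel_positions, half=73, sample_id="mn", assay="mnase"):
    """FragmentSet of odd-length (2*half+1) fragments whose midpoints sit at the
    given TSS-relative positions of ``gene``."""
    rel = np.asarray(rel_positions)
    mids = gene.tss + rel if gene.strand == "+" else gene.tss - rel
    arr = np.column_stack([mids - half, mids + half + 1])
    return tracks.FragmentSet(sample_id, "WT", assay, {gene.chrom: arr})


@pytest.fixture(scope="session")
def study_sim():
    """The study-scale synthetic dataset: 2000 genes, 400 targets with
    occupancy-coupled WT pausing, 200 genes with a planted expression effect."""
    return Simulation(SimConfig(seed=1, n_genes=2000, fraction_targets=0.2,
                                affected_fraction=0.5))


@pytest.fixture(scope="session")
def study_tracks(study_sim):
    """Per-million full-fragment tracks keyed (assay, condition)."""
    sim = study_sim
    out = {}
    for assay, cond in [("gaf_chip", "WT"), ("input", "WT"),
                        ("pol_chip", "WT"), ("pol_chip", "mutant")]:
        raw = tracks.build_coverage(sim.chip(assay, cond), sim.genome.lengths)
        out[(assay, cond)] = tracks.normalize_per_million(raw)
    return out


@pytest.fixture(scope="session")
def genes_by_id(study_sim):
    return {g.gene_id: g for g in study_sim.genes}


@pytest.fixture(scope="session")
def target_scores(study_sim, study_tracks, genes_by_id):
    """Promoter occupancy scores for every target gene."""
    from gafpause.targets import promoter_gaf_score

    chip = study_tracks[("gaf_chip", "WT")]
    inp = study_tracks[("input", "WT")]
    tids = list(study_sim.truth[study_sim.truth.is_target].index)
    return [promoter_gaf_score(genes_by_id[g], chip, inp) for g in tids]
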