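"""Synthetic genomes, ChIP/MNase fragment sets and expression matrices with
planted structure, plus the truth table recovery tests read from.

The generator emulates the statistical structure the analysis assumes:

* per-gene upstream factor occupancy ``s_g`` spanning ~2-300-fold,
  log-uniform, for a target subset of genes;
* a paused-polymerase component near +50 whose weight grows with occupancy
  in the WT condition and is decoupled (constant, collapsed to the
  low-occupancy baseline) in the mutant;
* phased downstream nucleosomes starting at a +1 dyad near +130, sharper
  for non-targets, plus upstream nucleosome mass on [-250, 0) whose weight
  is inflated in the mutant for configured occupancy ranks;
* target promoters enriched for strong (G/C) dinucleotides flanking the
  TSS, non-targets depleted upstream (an NFR) and enriched downstream;
* (GA)n repeats planted upstream of targets, longer for higher occupancy;
* triplicate expression with a planted mutant effect on a fraction of
  targets, downward with the configured probability.

Fragment counts are Poisson, positional kernels Gaussian.  MNase fragments
are generated symmetric about the dyad (odd lengths), so the midpoint
convention floor((start+end)/2) recovers the planted dyad exactly and every
TSS-relative statistic is exactly mirror-symmetric.  All randomness derives
from ``SimConfig.seed`` through per-stage streams: regenerating from the
same config is byte-identical, and the truth table is fixed at genome
construction so no recovery test can peek at generator internals.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tracks import FragmentSet, GeneModel, GenomeSequence, write_genes_bed

log = logging.getLogger(__name__)

_STREAMS = {
    "genome": 0,
    ("gaf_chip", "WT"): 1,
    ("gaf_chip", "mutant"): 2,
    ("pol_chip", "WT"): 3,
    ("pol_chip", "mutant"): 4,
    ("input", "WT"): 5,
    ("input", "mutant"): 6,
    ("mnase", "WT"): 7,
    ("mnase", "mutant"): 8,
    "expression": 9,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_genes: int = 2000
    fraction_targets: float = 0.2
    arm_names: tuple[str, ...] = ("2L", "2R", "3L", "3R", "X")
    gene_length_range: tuple[int, int] = (1400, 3000)
    gap_range: tuple[int, int] = (2400, 4400)
    violation_fraction: float = 0.1  # genes planted to fail selection criteria

    # occupancy and sequence
    occupancy_bounds: tuple[float, float] = (2.0, 300.0)  # log-uniform, targets
    base_gc: float = 0.40
    gc_contrast: float = 1.0  # 0 flattens the target/non-target GC profiles
    ga_max_extra_units: int = 5  # repeat length grows with log occupancy

    # ChIP fragment model
    chip_frag_len: int = 151  # odd: midpoint is the true center
    input_rate: float = 0.02  # fragments per bp, uniform
    gaf_background_rate: float = 0.015
    gaf_frags_per_occupancy: float = 30.0
    gaf_offset_range: tuple[float, float] = (-10.0, -100.0)  # drift with log occupancy
    gaf_pos_sd: float = 50.0
    mutant_gaf_scale: float = 0.03

    # polymerase model
    pause_center: float = 50.0
    pause_sd: float = 30.0
    pol_promoter_scale: float = 2.0
    pause_exponent: float = 0.7  # WT promoter weight = scale * s_g ** exponent
    pol_body_rate: float = 0.05  # fragments per bp of gene body
    mutant_decoupled: bool = True

    # nucleosome model
    plus1_center: int = 130
    nucleosome_spacing: int = 175
    n_phased: int = 3
    nuc_sd_target: float = 30.0
    nuc_sd_nontarget: float = 18.0
    upstream_weight_target: float = 0.2
    upstream_weight_nontarget: float = 0.05
    upstream_region: tuple[int, int] = (-250, 0)
    background_weight: float = 0.1
    upstream_inflation: dict = field(default_factory=lambda: {"IV": 1.5})
    mnase_frags_per_gene: float = 120.0
    mnase_len_mean: float = 147.0
    mnase_len_sd: float = 15.0
    mnase_intergenic_rate: float = 0.001

    # expression model
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 2.0
    affected_fraction: float = 0.6  # of targets
    effect_size_log2: float = 1.5
    down_fraction: float = 0.8
    replicate_noise_sd: float = 0.25
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.fraction_targets < 1:
            raise ValueError("fraction_targets must be in (0, 1)")
        if not 0 <= self.down_fraction <= 1:
            raise ValueError("down_fraction must be a probability")
        if self.occupancy_bounds[0] <= 0:
            raise ValueError("occupancy bounds must be positive")
        if self.chip_frag_len % 2 == 0:
            raise ValueError("chip_frag_len must be odd (center-symmetric fragments)")

    def rng(self, stream) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            if key not in fields:
                raise ValueError(f"unknown simulation config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _rank_labels(occupancies: np.ndarray, n_ranks: int = 4) -> np.ndarray:
    """Ascending near-equal quartile labels (I lowest ... IV highest)."""
    from .targets import ROMAN

    order = np.argsort(occupancies, kind="stable")
    n = len(occupancies)
    base, rem = divmod(n, n_ranks)
    sizes = [base + 1] * rem + [base] * (n_ranks - rem)
    labels = np.empty(n, dtype=object)
    i = 0
    for r, size in enumerate(sizes):
        labels[order[i : i + size]] = ROMAN[r]
        i += size
    return labels


class Simulation:
    """A generated genome, annotation and truth table; fragment sets and the
    expression matrix are drawn on demand (deterministically per stream)."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.genome, self.genes, self.truth = _generate_genome(cfg)

    # -- assay generators ------------------------------------------------

    def chip(self, assay: str, condition: str = "WT") -> FragmentSet:
        if assay == "input":
            return self._input(condition)
        if assay == "gaf_chip":
            return self._gaf(condition)
        if assay == "pol_chip":
            return self._pol(condition)
        raise ValueError(f"unknown assay {assay!r}")

    def mnase(self, condition: str = "WT") -> FragmentSet:
        return _generate_mnase(self.cfg, self.genome, self.genes, self.truth, condition)

    def expression(self) -> pd.DataFrame:
        return _generate_expression(self.cfg, self.truth)

    # -- individual ChIP assays -----------------------------------------

    def _input(self, condition: str) -> FragmentSet:
        cfg = self.cfg
        rng = cfg.rng(("input", condition))
        half = cfg.chip_frag_len // 2
        intervals = {}
        for chrom, L in self.genome.lengths.items():
            n = rng.poisson(cfg.input_rate * L)
            centers = rng.integers(half, L - half - 1, size=n)
            intervals[chrom] = np.column_stack([centers - half, centers + half + 1])
        return FragmentSet(f"input_{condition}", condition, "input", intervals)

    def _gaf(self, condition: str) -> FragmentSet:
        cfg = self.cfg
        rng = cfg.rng(("gaf_chip", condition))
        scale = cfg.mutant_gaf_scale if condition == "mutant" else 1.0
        half = cfg.chip_frag_len // 2
        centers: dict[str, list[np.ndarray]] = {c: [] for c in self.genome.lengths}
        for chrom, L in self.genome.lengths.items():
            n_bg = rng.poisson(cfg.gaf_background_rate * L * scale)
            centers[chrom].append(rng.integers(half, L - half - 1, size=n_bg))
        lo, hi = cfg.occupancy_bounds
        for gene, row in self._target_rows():
            s = row.occupancy
            n = rng.poisson(cfg.gaf_frags_per_occupancy * s * scale)
            frac = (math.log(s) - math.log(lo)) / (math.log(hi) - math.log(lo))
            mu = cfg.gaf_offset_range[0] + frac * (cfg.gaf_offset_range[1] - cfg.gaf_offset_range[0])
            rel = rng.normal(mu, cfg.gaf_pos_sd, size=n)
            centers[gene.chrom].append(_rel_to_genomic(gene, rel))
        return self._centers_to_frags(centers, half, f"gaf_{condition}", condition, "gaf_chip")

    def _pol(self, condition: str) -> FragmentSet:
        cfg = self.cfg
        rng = cfg.rng(("pol_chip", condition))
        half = cfg.chip_frag_len // 2
        col = "pause_weight_wt" if condition == "WT" else "pause_weight_mut"
        weights = self.truth[col]
        centers: dict[str, list[np.ndarray]] = {c: [] for c in self.genome.lengths}
        for gene in self.genes:
            w = float(weights.loc[gene.gene_id])
            n_p = rng.poisson(w)
            rel_p = rng.normal(cfg.pause_center, cfg.pause_sd, size=n_p)
            n_b = rng.poisson(cfg.pol_body_rate * gene.length)
            rel_b = rng.uniform(0, gene.length, size=n_b)
            rel = np.concatenate([rel_p, rel_b])
            centers[gene.chrom].append(_rel_to_genomic(gene, rel))
        return self._centers_to_frags(centers, half, f"pol_{condition}", condition, "pol_chip")

    # -- helpers ---------------------------------------------------------

    def _target_rows(self):
        targets = self.truth[self.truth.is_target]
        by_id = {g.gene_id: g for g in self.genes}
        for gene_id, row in targets.iterrows():
            yield by_id[gene_id], row

    def _centers_to_frags(self, centers, half, sample_id, condition, assay) -> FragmentSet:
        intervals = {}
        n_dropped = 0
        for chrom, parts in centers.items():
            L = self.genome.lengths[chrom]
            c = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
            c = np.rint(c).astype(np.int64)
            keep = (c - half >= 0) & (c + half + 1 <= L)
            n_dropped += int((~keep).sum())
            c = c[keep]
            intervals[chrom] = np.column_stack([c - half, c + half + 1])
        if n_dropped:
            log.debug("%s: dropped %d fragments at chromosome edges", sample_id, n_dropped)
        frags = FragmentSet(sample_id, condition, assay, intervals)
        if frags.total_count < 1000:
            log.warning("%s: low coverage (%d fragments)", sample_id, frags.total_count)
        return frags

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.bed",
            "truth": outdir / "truth.tsv",
            "expression": outdir / "expression.tsv",
        }
        self.genome.to_fasta(paths["genome"])
        write_genes_bed(self.genes, paths["genes"])
        self.truth.to_csv(paths["truth"], sep="\t")
        self.expression().to_csv(paths["expression"], sep="\t", index=False)
        return paths


def _rel_to_genomic(gene: GeneModel, rel: np.ndarray) -> np.ndarray:
    t = gene.tss
    return t + rel if gene.strand == "+" else t - rel


# ---------------------------------------------------------------------------
# genome + annotation + truth
# ---------------------------------------------------------------------------

def _gc_profile(cfg: SimConfig, window: tuple[int, int], target: bool) -> np.ndarray:
    r = np.arange(window[0], window[1], dtype=float)
    k = cfg.gc_contrast
    if target:
        p = cfg.base_gc + k * 0.25 * np.exp(-((r + 50.0) ** 2) / (2 * 100.0**2))
    else:
        p = (
            cfg.base_gc
            + k * 0.20 * np.exp(-((r - 250.0) ** 2) / (2 * 150.0**2))
            - k * 0.15 * np.exp(-((r + 150.0) ** 2) / (2 * 100.0**2))
        )
    return np.clip(p, 0.05, 0.95)


def _generate_genome(cfg: SimConfig):
    rng = cfg.rng("genome")
    arms = list(cfg.arm_names)
    n_arm = [cfg.n_genes // len(arms)] * len(arms)
    for i in range(cfg.n_genes % len(arms)):
        n_arm[i] += 1

    n_viol = int(round(cfg.violation_fraction * cfg.n_genes))
    viol_ids = rng.choice(cfg.n_genes, size=n_viol, replace=False)
    viol_kind = {int(g): ("multi_tss", "nested", "close")[i % 3] for i, g in enumerate(sorted(viol_ids))}

    genes: list[GeneModel] = []
    violations: dict[str, str] = {}
    arm_cursors: dict[str, int] = {}
    counter = 0
    for arm, n in zip(arms, n_arm):
        cursor = 1000
        for _ in range(n):
            kind = viol_kind.get(counter, "")
            if kind == "close":
                cursor -= int(rng.integers(*cfg.gap_range)) - 500  # shrink gap to 500
                cursor = max(cursor, 1000)
            length = int(rng.integers(*cfg.gene_length_range))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{counter:05d}"
            n_tss = 2 if kind == "multi_tss" else 1
            genes.append(GeneModel(gid, arm, cursor, cursor + length, strand, n_tss))
            violations[gid] = kind
            if kind == "nested":
                child = GeneModel(f"{gid}_in", arm, cursor + 400, cursor + 700,
                                  strand, 1)
                genes.append(child)
                violations[child.gene_id] = "nested_child"
            cursor += length + int(rng.integers(*cfg.gap_range))
            counter += 1
        arm_cursors[arm] = cursor + 1000

    clean = [g for g in genes if violations[g.gene_id] == ""]
    n_targets = int(round(cfg.fraction_targets * cfg.n_genes))
    if n_targets > len(clean):
        raise ValueError("not enough selection-clean genes for the requested target count")
    target_idx = rng.choice(len(clean), size=n_targets, replace=False)
    target_ids = {clean[i].gene_id for i in target_idx}

    lo, hi = cfg.occupancy_bounds
    all_ids = [g.gene_id for g in genes]
    is_target = np.array([gid in target_ids for gid in all_ids])
    occupancy = np.ones(len(genes))
    occupancy[is_target] = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_targets))

    rank = np.full(len(genes), "", dtype=object)
    rank[is_target] = _rank_labels(occupancy[is_target])

    # pause weights: WT coupled to occupancy, mutant collapsed to the
    # low-occupancy baseline when decoupling is on
    w_wt = cfg.pol_promoter_scale * occupancy**cfg.pause_exponent
    base_w = cfg.pol_promoter_scale * lo**cfg.pause_exponent
    w_mut = w_wt.copy()
    if cfg.mutant_decoupled:
        w_mut[is_target] = base_w

    up_wt = np.where(is_target, cfg.upstream_weight_target, cfg.upstream_weight_nontarget)
    up_mut = up_wt.copy()
    for r, factor in cfg.upstream_inflation.items():
        up_mut[rank == r] = cfg.upstream_weight_target * float(factor)

    n_affected = int(round(cfg.affected_fraction * n_targets))
    affected_pos = rng.choice(np.flatnonzero(is_target), size=n_affected, replace=False)
    de_affected = np.zeros(len(genes), dtype=bool)
    de_affected[affected_pos] = True
    de_effect = np.zeros(len(genes))
    sign = np.where(rng.random(n_affected) < cfg.down_fraction, -1.0, 1.0)
    de_effect[affected_pos] = sign * cfg.effect_size_log2

    truth = pd.DataFrame(
        {
            "gene_id": all_ids,
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "tss": [g.tss for g in genes],
            "violation": [violations[g.gene_id] for g in genes],
            "is_target": is_target,
            "occupancy": occupancy,
            "rank": rank,
            "pause_weight_wt": w_wt,
            "pause_weight_mut": w_mut,
            "upstream_factor_wt": up_wt,
            "upstream_factor_mut": up_mut,
            "de_affected": de_affected,
            "de_effect_log2": de_effect,
        }
    ).set_index("gene_id")

    genome = _generate_sequence(cfg, rng, genes, truth, arm_cursors)
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    return genome, genes, truth


def _generate_sequence(cfg, rng, genes, truth, arm_lengths) -> GenomeSequence:
    window = (-500, 500)
    prof_t = _gc_profile(cfg, window, target=True)
    prof_n = _gc_profile(cfg, window, target=False)
    comp_lut = np.arange(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp_lut[a] = b
    lo, hi = cfg.occupancy_bounds

    chroms: dict[str, str] = {}
    base_p = np.array(
        [(1 - cfg.base_gc) / 2, cfg.base_gc / 2, cfg.base_gc / 2, (1 - cfg.base_gc) / 2]
    )
    for arm, L in arm_lengths.items():
        arr = _BASES[rng.choice(4, size=L, p=base_p)].copy()
        for gene in (g for g in genes if g.chrom == arm):
            row = truth.loc[gene.gene_id]
            p = prof_t if row.is_target else prof_n
            strong = rng.random(len(p)) < p
            gc_pick = rng.random(len(p)) < 0.5
            at_pick = rng.random(len(p)) < 0.5
            win = np.where(strong, np.where(gc_pick, ord("G"), ord("C")),
                           np.where(at_pick, ord("A"), ord("T"))).astype(np.uint8)
            if row.is_target:
                s = row.occupancy
                frac = (math.log(s) - math.log(lo)) / (math.log(hi) - math.log(lo))
                n_units = 3 + int(round(cfg.ga_max_extra_units * frac))
                mu = cfg.gaf_offset_range[0] + frac * (
                    cfg.gaf_offset_range[1] - cfg.gaf_offset_range[0]
                )
                pos = int(mu) - n_units + 500  # index into the window array
                if 0 <= pos and pos + 2 * n_units <= len(win):
                    win[pos : pos + 2 * n_units] = np.frombuffer(
                        b"GA" * n_units, dtype=np.uint8
                    )
            if gene.strand == "-":
                win = comp_lut[win[::-1]]
            t = gene.tss
            gs = t + window[0] if gene.strand == "+" else t - window[1] + 1
            ge = gs + len(win)
            if gs >= 0 and ge <= L:
                arr[gs:ge] = win
        chroms[arm] = arr.tobytes().decode()
    return GenomeSequence(chroms)


# ---------------------------------------------------------------------------
# MNase
# ---------------------------------------------------------------------------

def _generate_mnase(cfg, genome, genes, truth, condition) -> FragmentSet:
    rng = cfg.rng(("mnase", condition))
    up0, up1 = cfg.upstream_region
    # Upstream dyad placement follows the strong-dinucleotide propensity
    # profile (plus a floor) -- the sequence feature favoring nucleosome
    # assembly.  Where the factor is bound (WT targets, and mutant targets
    # outside the inflated ranks) the proximal part of that profile is
    # cleared around the factor's footprint; in inflated mutant ranks the
    # clearance is lifted, so occupancy reverts toward the sequence-
    # intrinsic propensity in both mass and shape.
    up_positions = np.arange(up0, up1)
    propensity = _gc_profile(cfg, (up0, up1), target=True) + 0.2
    clearance = 1.0 - 0.7 * np.exp(-((up_positions + 60.0) ** 2) / (2 * 80.0**2))
    up_w_full = propensity / propensity.sum()
    up_w_cleared = propensity * clearance
    up_w_cleared = up_w_cleared / up_w_cleared.sum()
    factor_col = "upstream_factor_wt" if condition == "WT" else "upstream_factor_mut"

    dyads: dict[str, list[np.ndarray]] = {c: [] for c in genome.lengths}
    for gene in genes:
        row = truth.loc[gene.gene_id]
        n = rng.poisson(cfg.mnase_frags_per_gene)
        if n == 0:
            continue
        u = float(row[factor_col])
        b = cfg.background_weight
        down_total = max(1.0 - cfg.upstream_weight_target - b, 0.1)
        phased = np.array([0.5, 0.3, 0.2][: cfg.n_phased])
        phased = down_total * phased / phased.sum()
        weights = np.concatenate([[u, b], phased])
        counts = rng.multinomial(n, weights / weights.sum())
        sd = cfg.nuc_sd_target if row.is_target else cfg.nuc_sd_nontarget
        if row.is_target and not (condition == "mutant" and u > row.upstream_factor_wt):
            up_w = up_w_cleared  # factor still clearing its footprint
        else:
            up_w = up_w_full
        parts = [
            up_positions[rng.choice(len(up_positions), size=counts[0], p=up_w)],
            rng.uniform(-600, 600, size=counts[1]),
        ]
        for k in range(cfg.n_phased):
            center = cfg.plus1_center + k * cfg.nucleosome_spacing
            parts.append(rng.normal(center, sd, size=counts[2 + k]))
        rel = np.concatenate(parts)
        dyads[gene.chrom].append(np.rint(_rel_to_genomic(gene, rel)).astype(np.int64))

    for chrom, L in genome.lengths.items():
        n_bg = rng.poisson(cfg.mnase_intergenic_rate * L)
        dyads[chrom].append(rng.integers(300, L - 300, size=n_bg))

    intervals = {}
    for chrom, parts in dyads.items():
        L = genome.lengths[chrom]
        d = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        # dyad-centered protection: odd lengths 2h+1, so the fragment
        # midpoint is exactly the dyad
        h = np.clip(
            np.rint((rng.normal(cfg.mnase_len_mean, cfg.mnase_len_sd, size=len(d)) - 1) / 2),
            40, 124,
        ).astype(np.int64)
        keep = (d - h >= 0) & (d + h + 1 <= L)
        d, h = d[keep], h[keep]
        intervals[chrom] = np.column_stack([d - h, d + h + 1])
    frags = FragmentSet(f"mnase_{condition}", condition, "mnase", intervals)
    if frags.total_count < 1000:
        log.warning("mnase_%s: low coverage (%d fragments)", condition, frags.total_count)
    return frags


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _generate_expression(cfg: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    rng = cfg.rng("expression")
    n = len(truth)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    effect = truth["de_effect_log2"].to_numpy()
    cols = {"gene_id": truth.index.to_numpy()}
    for i in range(cfg.n_replicates):
        cols[f"wt_{i + 1}"] = 2.0 ** (baseline + rng.normal(0, cfg.replicate_noise_sd, size=n))
    for i in range(cfg.n_replicates):
        cols[f"mut_{i + 1}"] = 2.0 ** (
            baseline + effect + rng.normal(0, cfg.replicate_noise_sd, size=n)
        )
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# functional facade
# ---------------------------------------------------------------------------

def generate_genome(cfg: SimConfig):
    """(GenomeSequence, genes, truth) for the configured study."""
    return _generate_genome(cfg)


def generate_chip(cfg: SimConfig, assay: str, condition: str = "WT") -> FragmentSet:
    return Simulation(cfg).chip(assay, condition)


def generate_mnase(cfg: SimConfig, condition: str = "WT") -> FragmentSet:
    return Simulation(cfg).mnase(condition)


def generate_expression(cfg: SimConfig) -> pd.DataFrame:
    return Simulation(cfg).expression()
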