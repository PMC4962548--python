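"""End-to-end orchestration: configuration, stage caching and the run report.

A run is described by a YAML/dict config with three top-level keys:

* ``seed``      -- integer used for every stochastic stage;
* ``simulate``  -- a :class:`~gafpause.simulate.SimConfig` mapping (the run
  generates its own inputs), OR ``inputs`` -- paths to genome FASTA, gene
  BED/GFF3, fragment BEDs per assay/condition and an expression TSV;
* ``params``    -- analysis constants; every one defaults to the study
  value (promoter window -500..0, region A -100..+150, region B +500..end,
  2 kb spacing, twofold enrichment, 120-180 bp fragments, PI > 4,
  p < 0.05 / 1.5-fold / intensity > 100).

Stages run in order select -> peaks -> targets -> pause -> nucleosome ->
express -> report.  Each stage's digest chains its config slice, the input
digests and its upstream stage digests; a re-run with unchanged digests
loads the stage's serialized outputs instead of recomputing, and the
manifest is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr
from . import nucleosome as nuc
from . import pausing as pause_mod
from . import selection
from . import targets as targets_mod
from . import tracks
from .simulate import SimConfig, Simulation

log = logging.getLogger(__name__)

DEFAULT_PARAMS: dict = {
    "promoter_window": [-500, 0],
    "region_a": [-100, 151],
    "region_b_start": 500,
    "peak_min_fold": 2.0,
    "peak_min_width": 50,
    "peak_merge_gap": 20,
    "pseudocount": 0.5,
    "min_gap_bp": 2000,
    "min_body_bp": 700,
    "n_ranks": 4,
    "min_score": 2.0,
    "mnase_len_min": 120,
    "mnase_len_max": 180,
    "metagene_window": [-500, 500],
    "smooth_bp": 50,
    "pi_threshold": 4.0,
    "de_alpha": 0.05,
    "de_fold": 1.5,
    "de_min_intensity": 100.0,
    "n_nontarget_control": 1900,
}

_STAGES = ("inputs", "select", "peaks", "targets", "pause", "nucleosome", "express", "report")


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Normalize a run config; unknown keys raise listing every offender."""
    known_top = {"seed", "simulate", "inputs", "params"}
    bad = sorted(set(config) - known_top)
    bad_params = sorted(set(config.get("params", {})) - set(DEFAULT_PARAMS))
    if bad or bad_params:
        raise ConfigError(
            f"unknown config keys: {bad + ['params.' + b for b in bad_params]}"
        )
    if ("simulate" in config) == ("inputs" in config):
        raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
    out = {
        "seed": int(config.get("seed", 0)),
        "params": {**DEFAULT_PARAMS, **config.get("params", {})},
    }
    if "simulate" in config:
        sim = dict(config["simulate"] or {})
        sim.setdefault("seed", out["seed"])
        out["simulate"] = sim
    else:
        out["inputs"] = dict(config["inputs"])
    return out


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class RunContext:
    """In-memory objects shared across stages of one run."""

    def __init__(self, outdir: Path, config: dict):
        self.outdir = outdir
        self.config = config
        self.params = config["params"]
        self.genome: tracks.GenomeSequence | None = None
        self.genes: list[tracks.GeneModel] = []
        self.frags: dict[tuple[str, str], tracks.FragmentSet] = {}
        self.expression: pd.DataFrame | None = None
        self._tracks: dict = {}
        self.results: dict = {}

    def track(self, assay: str, condition: str, mode: str = "full_fragment"):
        key = (assay, condition, mode)
        if key not in self._tracks:
            raw = tracks.build_coverage(self.frags[(assay, condition)], self.genome.lengths, mode)
            self._tracks[key] = tracks.normalize_per_million(raw)
        return self._tracks[key]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages under ``outdir``; returns the run manifest dict."""
    config = validate_config(config)
    outdir = Path(outdir)
    stage_dir = outdir / "stages"
    stage_dir.mkdir(parents=True, exist_ok=True)
    if "inputs" in config:
        missing = [p for p in config["inputs"].values() if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")

    manifest_path = outdir / "manifest.json"
    old = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            old = {s["name"]: s for s in json.load(fh).get("stages", [])}

    input_digests = {
        k: _file_digest(Path(p)) for k, p in config.get("inputs", {}).items()
    }
    ctx = RunContext(outdir, config)
    stages = []
    upstream = _digest([config, input_digests])
    cached_flags = {}
    for name in _STAGES:
        fn = globals()[f"_stage_{name}"]
        digest = _digest([name, upstream])
        outputs = fn(ctx, plan_only=True)
        prev = old.get(name)
        can_load = (
            prev is not None
            and prev["digest"] == digest
            and all((outdir / p).exists() for p in prev["outputs"])
        )
        if can_load:
            fn(ctx, load=True)
            cached_flags[name] = True
        else:
            fn(ctx)
            cached_flags[name] = False
        stages.append({"name": name, "digest": digest, "outputs": outputs})
        upstream = digest

    manifest = {
        "config_hash": _digest(config),
        "seed": config["seed"],
        "inputs": input_digests,
        "stages": stages,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["cached"] = cached_flags
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

_ASSAY_KEYS = [
    ("gaf_chip", "WT"), ("pol_chip", "WT"), ("pol_chip", "mutant"),
    ("input", "WT"), ("input", "mutant"), ("mnase", "WT"), ("mnase", "mutant"),
]


def _stage_inputs(ctx: RunContext, plan_only=False, load=False):
    outputs = ["stages/genome.fa", "stages/genes.bed", "stages/expression.tsv"] + [
        f"stages/frags_{a}_{c}.bed" for a, c in _ASSAY_KEYS
    ]
    if plan_only:
        return outputs
    stage = ctx.outdir / "stages"
    if "simulate" in ctx.config and not load:
        sim = Simulation(SimConfig(**ctx.config["simulate"]))
        ctx.genome, ctx.genes = sim.genome, sim.genes
        ctx.expression = sim.expression()
        for a, c in _ASSAY_KEYS:
            ctx.frags[(a, c)] = sim.mnase(c) if a == "mnase" else sim.chip(a, c)
        ctx.genome.to_fasta(stage / "genome.fa")
        tracks.write_genes_bed(ctx.genes, stage / "genes.bed")
        ctx.expression.to_csv(stage / "expression.tsv", sep="\t", index=False)
        sim.truth.to_csv(stage / "truth.tsv", sep="\t")
        for (a, c), f in ctx.frags.items():
            tracks.write_fragments_bed(f, stage / f"frags_{a}_{c}.bed")
        return outputs
    # load from serialized inputs (either cached simulate outputs or user files)
    paths = ctx.config.get("inputs", {})
    genome_path = paths.get("genome", stage / "genome.fa")
    genes_path = paths.get("genes", stage / "genes.bed")
    expr_path = paths.get("expression", stage / "expression.tsv")
    ctx.genome = tracks.GenomeSequence.from_fasta(genome_path)
    ctx.genes = tracks.load_genes(genes_path)
    ctx.expression = pd.read_csv(expr_path, sep="\t")
    for a, c in _ASSAY_KEYS:
        fp = paths.get(f"{a}_{c}", stage / f"frags_{a}_{c}.bed")
        ctx.frags[(a, c)] = tracks.load_fragments(fp, "bed", f"{a}_{c}", c, a)
    if "inputs" in ctx.config and not load:
        ctx.genome.to_fasta(stage / "genome.fa")
        tracks.write_genes_bed(ctx.genes, stage / "genes.bed")
        ctx.expression.to_csv(stage / "expression.tsv", sep="\t", index=False)
        for (a, c), f in ctx.frags.items():
            tracks.write_fragments_bed(f, stage / f"frags_{a}_{c}.bed")
    return outputs


def _stage_select(ctx: RunContext, plan_only=False, load=False):
    outputs = ["stages/selection.tsv"]
    if plan_only:
        return outputs
    path = ctx.outdir / "stages" / "selection.tsv"
    if load:
        df = pd.read_csv(path, sep="\t")
        kept = set(df[df.kept].gene_id)
        report = selection.SelectionReport(
            kept=sorted(kept),
            rejected={r.gene_id: r.reason for r in df[~df.kept].itertuples()},
        )
    else:
        report = selection.select_analyzable(
            ctx.genes, ctx.params["min_gap_bp"], ctx.params["min_body_bp"]
        )
        pd.DataFrame(report.to_rows()).to_csv(path, sep="\t", index=False)
    ctx.results["select"] = report
    ctx.results["kept_genes"] = [g for g in ctx.genes if g.gene_id in set(report.kept)]
    return outputs


def _stage_peaks(ctx: RunContext, plan_only=False, load=False):
    outputs = ["stages/peaks.tsv", "stages/peaks.bed"]
    if plan_only:
        return outputs
    path = ctx.outdir / "stages" / "peaks.tsv"
    if load:
        df = pd.read_csv(path, sep="\t")
        peaks = [
            targets_mod.Peak(r.chrom, r.start, r.end, r.summit, r.fold_enrichment)
            for r in df.itertuples()
        ]
    else:
        enr = tracks.enrichment_over_input(
            ctx.track("gaf_chip", "WT"), ctx.track("input", "WT"),
            ctx.params["pseudocount"],
        )
        peaks = targets_mod.call_enriched_regions(
            enr, ctx.params["peak_min_fold"], ctx.params["peak_min_width"],
            ctx.params["peak_merge_gap"],
        )
        pd.DataFrame([p.__dict__ for p in peaks]).to_csv(path, sep="\t", index=False)
        targets_mod.write_peaks_bed(peaks, ctx.outdir / "stages" / "peaks.bed")
    ctx.results["peaks"] = peaks
    return outputs


def _stage_targets(ctx: RunContext, plan_only=False, load=False):
    outputs = ["stages/assignments.tsv", "stages/scores.tsv"]
    if plan_only:
        return outputs
    stage = ctx.outdir / "stages"
    if load:
        adf = pd.read_csv(stage / "assignments.tsv", sep="\t")
        assignments = [
            targets_mod.TargetAssignment(r.gene_id, r.category, r.max_promoter_fold)
            for r in adf.itertuples()
        ]
        sdf = pd.read_csv(stage / "scores.tsv", sep="\t")
        ranked = [
            targets_mod.PromoterScore(r.gene_id, r.gaf_score, r.rank)
            for r in sdf.itertuples()
        ]
    else:
        window = tuple(ctx.params["promoter_window"])
        assignments = targets_mod.assign_peaks(ctx.genes, ctx.results["peaks"], window)
        chip = ctx.track("gaf_chip", "WT")
        inp = ctx.track("input", "WT")
        scores = [
            targets_mod.promoter_gaf_score(g, chip, inp, window, ctx.params["pseudocount"])
            for g in ctx.results["kept_genes"]
        ]
        ranked = targets_mod.assign_ranks(
            scores, ctx.params["n_ranks"], ctx.params["min_score"]
        )
        pd.DataFrame([a.__dict__ for a in assignments]).to_csv(
            stage / "assignments.tsv", sep="\t", index=False
        )
        pd.DataFrame([s.__dict__ for s in ranked]).to_csv(
            stage / "scores.tsv", sep="\t", index=False
        )
    ctx.results["assignments"] = assignments
    ctx.results["scores"] = ranked
    return outputs


def _stage_pause(ctx: RunContext, plan_only=False, load=False):
    outputs = ["stages/pausing.tsv", "stages/pause_stats.json"]
    if plan_only:
        return outputs
    stage = ctx.outdir / "stages"
    if load:
        ctx.results["pausing"] = pd.read_csv(stage / "pausing.tsv", sep="\t")
        with open(stage / "pause_stats.json") as fh:
            ctx.results["pause_stats"] = json.load(fh)
        return outputs

    ranked = {s.gene_id: s for s in ctx.results["scores"] if s.rank != "unranked"}
    analysis_genes = [
        g for g in ctx.results["kept_genes"]
        if g.gene_id in ranked and g.length > ctx.params["region_b_start"]
    ]
    rows = []
    by_condition: dict[str, list[pause_mod.PausingRecord]] = {}
    for condition in ("WT", "mutant"):
        track = ctx.track("pol_chip", condition)
        records = pause_mod.compute_pausing(analysis_genes, track, condition)
        by_condition[condition] = records
        rows += [r.__dict__ for r in records]
    detections = pause_mod.detect_pol_genes(
        ctx.results["kept_genes"], ctx.frags[("pol_chip", "WT")], ctx.frags[("input", "WT")]
    )
    det = {d.gene_id: d for d in detections}
    for row in rows:
        d = det.get(row["gene_id"])
        row.update(
            fisher_p=d.fisher_p if d else np.nan,
            fdr_q=d.fdr_q if d else np.nan,
            detected=d.detected if d else False,
        )
    pausing_df = pd.DataFrame(rows)
    pausing_df.to_csv(stage / "pausing.tsv", sep="\t", index=False)

    stats: dict = {"n_analysis_genes": len(analysis_genes), "correlations": {}, "rank_tests": {}}
    scores = [ranked[g.gene_id] for g in analysis_genes]
    for condition, records in by_condition.items():
        for metric in ("density_A", "density_B", "pi"):
            values = {r.gene_id: getattr(r, metric) for r in records}
            try:
                c = pause_mod.correlate_occupancy(scores, values, metric)
                stats["correlations"][f"{condition}:{metric}"] = {
                    "rho": c.spearman_rho, "p": c.p_value, "n": c.n,
                }
            except ValueError as exc:
                stats["correlations"][f"{condition}:{metric}"] = {"error": str(exc)}
    pis = {
        cond: {r.gene_id: r.pi for r in recs} for cond, recs in by_condition.items()
    }
    for rank in sorted({s.rank for s in scores}):
        ids = [s.gene_id for s in scores if s.rank == rank]
        try:
            cmp = pause_mod.compare_rank_pi(
                [pis["WT"][g] for g in ids], [pis["mutant"][g] for g in ids], rank
            )
            stats["rank_tests"][rank] = {
                "U": cmp.mannwhitney_U, "p": cmp.p_value,
                "n_wt": cmp.n_wt, "n_mut": cmp.n_mut,
                "wt_bounds": cmp.wt_bounds, "mut_bounds": cmp.mut_bounds,
            }
        except ValueError as exc:
            stats["rank_tests"][rank] = {"error": str(exc)}
    stats["n_detected"] = sum(1 for d in detections if d.detected)
    with open(stage / "pause_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    ctx.results["pausing"] = pausing_df
    ctx.results["pause_stats"] = stats
    return outputs


def _stage_nucleosome(ctx: RunContext, plan_only=False, load=False):
    outputs = ["stages/metagene.tsv", "stages/sections.tsv", "stages/ss_profile.tsv"]
    if plan_only:
        return outputs
    stage = ctx.outdir / "stages"
    if load:
        ctx.results["sections"] = pd.read_csv(stage / "sections.tsv", sep="\t")
        return outputs
    p = ctx.params
    window = tuple(p["metagene_window"])
    sized = {
        c: nuc.filter_mnase_fragments(
            ctx.frags[("mnase", c)], p["mnase_len_min"], p["mnase_len_max"]
        )
        for c in ("WT", "mutant")
    }
    mids = {}
    for c, frags in sized.items():
        raw = tracks.build_coverage(frags, ctx.genome.lengths, "midpoint")
        mids[c] = tracks.normalize_per_million(raw)

    ranked = {s.gene_id: s.rank for s in ctx.results["scores"] if s.rank != "unranked"}
    kept = ctx.results["kept_genes"]
    target_genes = [g for g in kept if g.gene_id in ranked]
    nontargets = [g for g in kept if g.gene_id not in ranked]
    n_ctrl = min(p["n_nontarget_control"], len(nontargets))
    control = (
        nuc.sample_nontargets(nontargets, n_ctrl, seed=ctx.config["seed"])
        if n_ctrl
        else []
    )

    meta_rows = []
    gene_sets = {"targets": target_genes, "nontargets": control}
    for rank in sorted(set(ranked.values())):
        gene_sets[f"rank_{rank}"] = [g for g in target_genes if ranked[g.gene_id] == rank]
    for set_id, genes in gene_sets.items():
        for c in ("WT", "mutant"):
            if not genes:
                continue
            prof = nuc.metagene(genes, mids[c], window, f"{set_id}:{c}")
            for pos, v in zip(prof.positions, prof.values):
                meta_rows.append(
                    {"gene_set": set_id, "condition": c, "position": int(pos), "value": v}
                )
    pd.DataFrame(meta_rows).to_csv(stage / "metagene.tsv", sep="\t", index=False)

    sec_rows = []
    for set_id, genes in gene_sets.items():
        if not genes:
            continue
        for mode in ("four_sections", "upstream_halves"):
            for t in nuc.section_ks(genes, sized["WT"], sized["mutant"], mode, window):
                sec_rows.append(
                    {
                        "gene_set": set_id, "mode": mode,
                        "section_start": t.section[0], "section_end": t.section[1],
                        "ks_D": t.ks_D, "p_value": t.p_value,
                        "n_wt": t.n_wt, "n_mut": t.n_mut, "skipped": t.skipped,
                        "mass_wt": t.mass_wt, "mass_mut": t.mass_mut,
                    }
                )
    sections_df = pd.DataFrame(sec_rows)
    sections_df.to_csv(stage / "sections.tsv", sep="\t", index=False)

    ss_rows = []
    for set_id, genes in (("targets", target_genes), ("nontargets", control)):
        if not genes:
            continue
        prof = nuc.ss_dinucleotide_profile(ctx.genome, genes, window, p["smooth_bp"])
        for pos, raw_v, sm in zip(prof.positions, prof.raw, prof.smoothed):
            ss_rows.append(
                {"gene_set": set_id, "position": int(pos), "raw": raw_v, "smoothed": sm}
            )
    pd.DataFrame(ss_rows).to_csv(stage / "ss_profile.tsv", sep="\t", index=False)
    ctx.results["sections"] = sections_df
    return outputs


def _stage_express(ctx: RunContext, plan_only=False, load=False):
    outputs = ["stages/de.tsv", "stages/de_summary.json"]
    if plan_only:
        return outputs
    stage = ctx.outdir / "stages"
    if load:
        with open(stage / "de_summary.json") as fh:
            ctx.results["de_summary"] = json.load(fh)
        return outputs
    p = ctx.params
    records = expr.differential_expression(
        ctx.expression, p["de_alpha"], p["de_fold"], p["de_min_intensity"]
    )
    expr.records_to_frame(records).to_csv(stage / "de.tsv", sep="\t")
    inter = expr.intersect_targets(records, ctx.results["assignments"], p["peak_min_fold"])
    summary = dataclasses.asdict(inter)
    with open(stage / "de_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    ctx.results["de_summary"] = summary
    return outputs


def _stage_report(ctx: RunContext, plan_only=False, load=False):
    outputs = ["report.json", "report.md"]
    if plan_only:
        return outputs
    if load:
        return outputs
    sel = ctx.results["select"]
    scores = ctx.results["scores"]
    sizes = targets_mod.rank_sizes(scores)
    report = {
        "selection": {"n_kept": sel.n_kept, "n_rejected": len(sel.rejected)},
        "peaks": {"n_peaks": len(ctx.results["peaks"])},
        "targets": {"rank_sizes": sizes, "n_scored": len(scores)},
        "pause": ctx.results["pause_stats"],
        "nucleosome": {
            "n_section_tests": int(len(ctx.results["sections"])),
        },
        "expression": ctx.results["de_summary"],
    }
    with open(ctx.outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    lines = ["# Run report", ""]
    for name, body in report.items():
        lines.append(f"## {name}")
        lines.append("```json")
        lines.append(json.dumps(body, indent=2, sort_keys=True))
        lines.append("```")
        lines.append("")
    (ctx.outdir / "report.md").write_text("\n".join(lines))
    ctx.results["report"] = report
    return outputs
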