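"""Factor-enriched regions, gene assignment, promoter occupancy ranks and
GA-repeat scanning.

Occupancy of the upstream factor at a promoter is summarized by the
cumulative enrichment score over the promoter window [-500, 0): the ratio of
the summed depth-normalized ChIP signal to the summed input signal, each
stabilized by pseudocount x window-length.  Scored genes at or above a
minimum fold are split into ascending, contiguous, near-equal-size ranks
(I = lowest occupancy ... IV = highest).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .tracks import (
    CoverageTrack,
    EnrichmentProfile,
    GeneModel,
    GenomeSequence,
    relative_window,
)

log = logging.getLogger(__name__)

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak")


@dataclass
class TargetAssignment:
    gene_id: str
    category: str  # promoter_only | promoter_and_genic | genic_only | intergenic_neighbor | none
    max_promoter_fold: float


@dataclass
class PromoterScore:
    gene_id: str
    gaf_score: float
    rank: str = "unranked"


@dataclass(frozen=True)
class GARepeat:
    chrom: str
    start: int
    end: int
    n_units: int

    def __post_init__(self) -> None:
        if self.end - self.start != 2 * self.n_units:
            raise ValueError("GA repeat span must equal 2 x n_units")


def call_enriched_regions(
    enr: EnrichmentProfile,
    min_fold: float = 2.0,
    min_width: int = 50,
    merge_gap: int = 20,
) -> list[Peak]:
    """Maximal runs of per-base enrichment >= ``min_fold``.

    Runs separated by fewer than ``merge_gap`` sub-threshold bases are merged
    first; merged regions shorter than ``min_width`` are then discarded.
    Summit is the leftmost argmax.  A deliberately simple stand-in for a
    probabilistic peak caller: downstream statistics use per-base sums, so
    peaks only serve positional categorization.
    """
    peaks: list[Peak] = []
    for chrom in sorted(enr.data):
        vec = enr.data[chrom]
        mask = vec >= min_fold
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] < merge_gap:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s < min_width:
                continue
            summit = s + int(np.argmax(vec[s:e]))
            peaks.append(Peak(chrom, s, e, summit, float(vec[s:e].max())))
    return peaks


def write_peaks_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.chrom, p.start))):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{int(round(p.fold_enrichment * 100))}\t.\n"
            )


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1


def assign_peaks(
    genes: list[GeneModel],
    peaks: list[Peak],
    promoter_window: tuple[int, int] = (-500, 0),
) -> list[TargetAssignment]:
    """Categorize each gene by where factor peaks fall relative to it.

    * promoter hit: any peak overlapping the strand-aware window [-500, 0).
    * genic hit: any peak overlapping the gene body [0, length).
    * neither, but the gene's TSS is the closest to some peak that hit no
      gene at all -> ``intergenic_neighbor``; otherwise ``none``.
    """
    assignments: list[TargetAssignment] = []
    peak_hit = [False] * len(peaks)
    gene_index: dict[str, int] = {}

    for gi, gene in enumerate(genes):
        ps, pe = relative_window(gene, *promoter_window)
        promoter_folds = []
        genic = False
        for pi, peak in enumerate(peaks):
            if peak.chrom != gene.chrom:
                continue
            if _overlaps(peak.start, peak.end, ps, pe):
                promoter_folds.append(peak.fold_enrichment)
                peak_hit[pi] = True
            if _overlaps(peak.start, peak.end, gene.start, gene.end):
                genic = True
                peak_hit[pi] = True
        if promoter_folds and genic:
            cat = "promoter_and_genic"
        elif promoter_folds:
            cat = "promoter_only"
        elif genic:
            cat = "genic_only"
        else:
            cat = "none"
        gene_index[gene.gene_id] = gi
        assignments.append(
            TargetAssignment(gene.gene_id, cat, max(promoter_folds) if promoter_folds else 0.0)
        )

    # intergenic peaks: nearest-TSS gene becomes a neighbour if otherwise empty
    for pi, peak in enumerate(peaks):
        if peak_hit[pi]:
            continue
        best, best_d = None, None
        for gene in genes:
            if gene.chrom != peak.chrom:
                continue
            d = abs(gene.tss - peak.summit)
            if best_d is None or d < best_d:
                best, best_d = gene.gene_id, d
        if best is not None and assignments[gene_index[best]].category == "none":
            assignments[gene_index[best]].category = "intergenic_neighbor"
    return assignments


def promoter_gaf_score(
    gene: GeneModel,
    chip: CoverageTrack,
    input_track: CoverageTrack,
    window: tuple[int, int] = (-500, 0),
    pseudocount: float = 0.5,
) -> PromoterScore:
    """Cumulative promoter enrichment: ratio of window sums over input.

    Both tracks must be per-million.  Windows running off a chromosome end
    are truncated (and logged); the pseudocount term scales with the number
    of positions actually used.
    """
    if chip.scale != "per_million" or input_track.scale != "per_million":
        raise ValueError("promoter score requires per_million tracks")
    gs, ge = relative_window(gene, *window)
    L = len(chip.data[gene.chrom])
    if gs < 0 or ge > L:
        log.info("gene %s: promoter window truncated at chromosome edge", gene.gene_id)
        gs, ge = max(gs, 0), min(ge, L)
    width = ge - gs
    chip_sum = float(chip.data[gene.chrom][gs:ge].sum())
    input_sum = float(input_track.data[gene.chrom][gs:ge].sum())
    score = (chip_sum + pseudocount * width) / (input_sum + pseudocount * width)
    return PromoterScore(gene.gene_id, score)


def assign_ranks(
    scores: list[PromoterScore],
    n_ranks: int = 4,
    min_score: float = 2.0,
) -> list[PromoterScore]:
    """Split genes with score >= ``min_score`` into ascending contiguous ranks.

    Group sizes are as equal as possible with earlier (lower-score) groups
    taking the extras, so 365 genes split 92/91/91/91.  Ties in score break
    by gene id.  Returns fresh records; input order is irrelevant and the
    operation is idempotent.
    """
    eligible = sorted(
        (s for s in scores if s.gaf_score >= min_score),
        key=lambda s: (s.gaf_score, s.gene_id),
    )
    if len(eligible) < n_ranks:
        raise ValueError(
            f"only {len(eligible)} genes with score >= {min_score}; need >= {n_ranks}"
        )
    out = [
        PromoterScore(s.gene_id, s.gaf_score, "unranked")
        for s in scores
        if s.gaf_score < min_score
    ]
    n = len(eligible)
    base, rem = divmod(n, n_ranks)
    sizes = [base + 1] * rem + [base] * (n_ranks - rem)
    i = 0
    for rank_idx, size in enumerate(sizes):
        for s in eligible[i : i + size]:
            out.append(PromoterScore(s.gene_id, s.gaf_score, ROMAN[rank_idx]))
        i += size
    out.sort(key=lambda s: s.gene_id)
    return out


def rank_sizes(scores: list[PromoterScore]) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for s in scores:
        sizes[s.rank] = sizes.get(s.rank, 0) + 1
    return sizes


_GA_PATTERNS = (re.compile(r"(?:GA)+"), re.compile(r"(?:TC)+"))


def scan_ga_repeats(
    seq: GenomeSequence,
    chrom: str | None = None,
    region: tuple[int, int] | None = None,
    min_units: int = 3,
) -> list[GARepeat]:
    """Maximal (GA)n / (TC)n dinucleotide runs with n >= ``min_units``.

    Strand-agnostic: (TC)n on the reference is (GA)n on the other strand.
    """
    repeats: list[GARepeat] = []
    chroms = [chrom] if chrom is not None else seq.chromosomes
    for c in chroms:
        s0, s1 = region if region is not None else (0, seq.lengths[c])
        subseq = seq.fetch(c, s0, s1)
        for pat in _GA_PATTERNS:
            for m in pat.finditer(subseq):
                n_units = (m.end() - m.start()) // 2
                if n_units >= min_units:
                    repeats.append(
                        GARepeat(c, s0 + m.start(), s0 + m.start() + 2 * n_units, n_units)
                    )
    repeats.sort(key=lambda r: (r.chrom, r.start))
    return repeats
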