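"""Gene-universe selection for unambiguous TSS-relative analysis.

A gene is analyzable when signal in its promoter window and gene body can be
attributed to that gene alone: it has a single annotated TSS, contains no
other annotated gene, sits at least ``min_gap_bp`` from every neighbour on
both sides, and is long enough for the gene-body window (+500 to the end) to
be non-empty.  Rejection reasons are assigned in that priority order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tracks import GeneModel

log = logging.getLogger(__name__)

REASONS = ("multi_tss", "internal_gene", "too_close", "too_short")


@dataclass
class SelectionReport:
    kept: list[str] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_rows(self) -> list[dict]:
        rows = [{"gene_id": g, "kept": True, "reason": ""} for g in self.kept]
        rows += [{"gene_id": g, "kept": False, "reason": r} for g, r in self.rejected.items()]
        rows.sort(key=lambda r: r["gene_id"])
        return rows


def select_analyzable(
    genes: list[GeneModel],
    min_gap_bp: int = 2000,
    min_body_bp: int = 700,
) -> SelectionReport:
    """Apply the four selection criteria; order of ``genes`` is irrelevant.

    "No internal genes" means no other gene's interval is contained within
    the candidate's interval.  Partial overlap is caught by the distance
    criterion (inter-gene gap 0 < ``min_gap_bp``).
    """
    report = SelectionReport()
    if not genes:
        log.warning("select_analyzable called with no genes")
        return report

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom_genes in by_chrom.values():
        starts = np.array([g.start for g in chrom_genes])
        ends = np.array([g.end for g in chrom_genes])
        n = len(chrom_genes)
        for i, g in enumerate(chrom_genes):
            others = np.arange(n) != i
            if g.n_tss_annotated != 1:
                report.rejected[g.gene_id] = "multi_tss"
                continue
            contained = others & (starts >= g.start) & (ends <= g.end)
            if contained.any():
                report.rejected[g.gene_id] = "internal_gene"
                continue
            # gap between half-open intervals; overlap clamps to 0
            gaps = np.maximum(0, np.maximum(starts - g.end, g.start - ends))
            if others.any() and gaps[others].min() < min_gap_bp:
                report.rejected[g.gene_id] = "too_close"
                continue
            if g.length < min_body_bp:
                report.rejected[g.gene_id] = "too_short"
                continue
            report.kept.append(g.gene_id)

    report.kept.sort()
    return report
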