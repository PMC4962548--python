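"""Polymerase densities, pausing indices and the rank/occupancy statistics.

The pausing index (PI) of a gene is the ratio of mean depth-normalized
polymerase ChIP coverage in the promoter-proximal window (region A,
TSS-relative [-100, +151), i.e. -100 through +150 inclusive) over the gene
body (region B, [+500, gene length)).  Densities are per-bp means so that
region-length differences across genes cancel, and PI is invariant to
sequencing depth.  Genes with zero body density are excluded from PI
analyses rather than pseudocounted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tracks import CoverageTrack, FragmentSet, GeneModel, window_values
from .targets import PromoterScore

log = logging.getLogger(__name__)

REGION_A: tuple[int, int] = (-100, 151)
REGION_B_START: int = 500
PI_THRESHOLD: float = 4.0


@dataclass
class PausingRecord:
    gene_id: str
    condition: str
    density_A: float
    density_B: float
    pi: float | None  # None when density_B == 0 (excluded from PI analyses)

    @property
    def paused(self) -> bool | None:
        """Strictly greater than the PI threshold; None when PI undefined."""
        if self.pi is None:
            return None
        return self.pi > PI_THRESHOLD


@dataclass
class GeneDetection:
    gene_id: str
    fisher_p: float
    fdr_q: float

    @property
    def detected(self) -> bool:
        return self.fdr_q < 0.05 and self.fisher_p < 0.01


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    n: int
    spearman_rho: float
    p_value: float


@dataclass
class RankComparison:
    rank: str
    n_wt: int
    n_mut: int
    mannwhitney_U: float
    p_value: float
    wt_bounds: tuple[float, float]  # 5th / 95th percentile
    mut_bounds: tuple[float, float]


def region_density(
    gene: GeneModel,
    track: CoverageTrack,
    region: str | tuple[int, int],
    raw_sum: bool = False,
) -> float:
    """Mean per-bp coverage over a strand-aware TSS-relative region.

    ``region`` is ``"A"``, ``"B"`` or an explicit (r0, r1) pair.  Windows
    clipped by a chromosome edge are truncated; an empty region raises.
    With ``raw_sum`` the (length-dependent) window sum is returned instead,
    for sensitivity analysis.
    """
    if region == "A":
        r0, r1 = REGION_A
    elif region == "B":
        r0, r1 = REGION_B_START, gene.length
        if gene.length <= REGION_B_START:
            raise ValueError(
                f"gene {gene.gene_id}: length {gene.length} leaves region B empty"
            )
    else:
        r0, r1 = region
    if r1 <= r0:
        raise ValueError(f"gene {gene.gene_id}: empty region [{r0},{r1})")
    vals = window_values(track, gene, r0, r1, oob="truncate")
    if vals is None or not len(vals):
        raise ValueError(f"gene {gene.gene_id}: region [{r0},{r1}) has no positions on chromosome")
    return float(vals.sum()) if raw_sum else float(vals.mean())


def pausing_index(density_A: float, density_B: float) -> float | None:
    """density_A / density_B; None (excluded, logged by callers) when B is 0."""
    if density_B == 0.0:
        return None
    return density_A / density_B


def compute_pausing(
    genes: list[GeneModel],
    track: CoverageTrack,
    condition: str,
) -> list[PausingRecord]:
    """Region densities and PI for every gene long enough for region B."""
    records = []
    n_undefined = 0
    for gene in genes:
        dA = region_density(gene, track, "A")
        dB = region_density(gene, track, "B")
        pi = pausing_index(dA, dB)
        if pi is None:
            n_undefined += 1
        records.append(PausingRecord(gene.gene_id, condition, dA, dB, pi))
    if n_undefined:
        log.info("%d genes with zero body density excluded from PI (%s)", n_undefined, condition)
    return records


# ---------------------------------------------------------------------------
# Gene detection by exact hypergeometric enrichment
# ---------------------------------------------------------------------------

def fisher_greater_pvalues(
    in_gene_chip: np.ndarray,
    total_chip: int,
    in_gene_input: np.ndarray,
    total_input: int,
) -> np.ndarray:
    """One-sided (greater) Fisher exact p for 2x2 tables, vectorized.

    Table per gene: [[chip_in, chip_out], [input_in, input_out]].  The
    one-sided Fisher p equals the hypergeometric upper tail
    P[X >= chip_in] with population total_chip + total_input, successes
    total_chip and draws chip_in + input_in.
    """
    a = np.asarray(in_gene_chip, dtype=np.int64)
    c = np.asarray(in_gene_input, dtype=np.int64)
    N = total_chip + total_input
    with np.errstate(invalid="ignore"):
        p = stats.hypergeom.sf(a - 1, N, total_chip, a + c)
    # P[X >= 0] is 1 regardless of margins (covers the empty-table case)
    return np.where(a == 0, 1.0, p)


def _count_overlapping(frags: FragmentSet, gene: GeneModel) -> int:
    arr = frags.intervals.get(gene.chrom)
    if arr is None or not arr.size:
        return 0
    starts = np.sort(arr[:, 0])
    ends = np.sort(arr[:, 1])
    # fragments with start < gene.end and end > gene.start
    n_start_ok = np.searchsorted(starts, gene.end, side="left")
    n_end_before = np.searchsorted(ends, gene.start, side="right")
    return int(n_start_ok - n_end_before)


def detect_pol_genes(
    genes: list[GeneModel],
    chip_frags: FragmentSet,
    input_frags: FragmentSet,
) -> list[GeneDetection]:
    """Per-gene enrichment of ChIP over input fragments.

    Exact one-sided test per gene on raw fragment counts, Benjamini-
    Hochberg correction across the tested genes; a gene is detected when
    q < 0.05 and p < 0.01.
    """
    n_chip, n_input = chip_frags.total_count, input_frags.total_count
    if n_chip == 0 or n_input == 0:
        raise ValueError("cannot test gene detection with an empty sample")
    a = np.array([_count_overlapping(chip_frags, g) for g in genes])
    c = np.array([_count_overlapping(input_frags, g) for g in genes])
    pvals = fisher_greater_pvalues(a, n_chip, c, n_input)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        GeneDetection(g.gene_id, float(p), float(q))
        for g, p, q in zip(genes, pvals, qvals)
    ]


# ---------------------------------------------------------------------------
# Rank / occupancy statistics
# ---------------------------------------------------------------------------

def correlate_occupancy(
    scores: list[PromoterScore],
    values: dict[str, float],
    value_name: str = "density_A",
) -> CorrelationResult:
    """Spearman correlation between promoter occupancy scores and a per-gene
    metric, over genes with both values defined.

    Average ranks on ties; p from the large-sample t approximation.
    """
    pairs = [
        (s.gaf_score, values[s.gene_id])
        for s in scores
        if s.gene_id in values and values[s.gene_id] is not None
    ]
    if len(pairs) < 10:
        raise ValueError(f"only {len(pairs)} genes with both values; need >= 10")
    x, y = map(np.asarray, zip(*pairs))
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(("gaf_score", value_name), len(pairs), float(rho), float(p))


def compare_rank_pi(
    wt_pis: list[float],
    mut_pis: list[float],
    rank: str,
) -> RankComparison:
    """Two-sided Mann-Whitney U between condition PI distributions in a rank.

    Exact null distribution for small groups (n <= 8 both sides), otherwise
    the tie-corrected normal approximation with continuity correction.
    Box-plot whisker bounds (5th/95th percentile, linear interpolation) are
    reported per condition.
    """
    wt = np.asarray([v for v in wt_pis if v is not None], dtype=float)
    mut = np.asarray([v for v in mut_pis if v is not None], dtype=float)
    if len(wt) < 3 or len(mut) < 3:
        raise ValueError(f"rank {rank}: need >= 3 defined PIs per condition")
    method = "exact" if (len(wt) <= 8 and len(mut) <= 8 and not _has_ties(wt, mut)) else "asymptotic"
    res = stats.mannwhitneyu(wt, mut, alternative="two-sided", method=method)
    return RankComparison(
        rank=rank,
        n_wt=len(wt),
        n_mut=len(mut),
        mannwhitney_U=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        wt_bounds=(float(np.percentile(wt, 5)), float(np.percentile(wt, 95))),
        mut_bounds=(float(np.percentile(mut, 5)), float(np.percentile(mut, 95))),
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)
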