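"""Nucleosome midpoint metagenes, section-wise condition comparison and
strong-dinucleotide sequence propensity.

Mononucleosome-sized MNase fragments (120-180 bp inclusive) report a
nucleosome position through their midpoint.  Metagene profiles average the
depth-normalized midpoint track over TSS-relative [-500, +500) across a gene
set.  Condition differences are tested per section with a two-sample
Kolmogorov-Smirnov test on the pooled TSS-relative midpoint positions
restricted to the section -- midpoint coordinates are the natural sample
observations for KS, and pooling across genes follows the metagene logic.
Occupancy-level (mass) shifts are reported separately per section since KS
only sees positional shape.

SS dinucleotides (GG, GC, CC, CG: both bases strong) predict nucleosome-
favoring sequence; the set is closed under reverse complement, so the
profile is strand-consistent by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tracks import (
    CoverageTrack,
    FragmentSet,
    GeneModel,
    GenomeSequence,
    relative_positions,
    relative_window,
    reverse_complement,
    window_values,
)

log = logging.getLogger(__name__)

SS_DINUCLEOTIDES = frozenset({"GG", "GC", "CC", "CG"})

FOUR_SECTIONS = ((-500, -250), (-250, 0), (0, 250), (250, 500))
UPSTREAM_HALVES = ((-500, -250), (-250, 0))


@dataclass
class MetageneProfile:
    gene_set_id: str
    window: tuple[int, int]
    values: np.ndarray  # per-position mean normalized midpoint count
    n_genes: int
    n_midpoints_total: float  # summed per-million mass over all gene windows
    n_dropped: int = 0

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1])


@dataclass
class SectionTest:
    section: tuple[int, int]
    ks_D: float
    p_value: float
    n_wt: int
    n_mut: int
    skipped: str = ""
    mass_wt: float = 0.0  # per-million midpoint mass in section
    mass_mut: float = 0.0


@dataclass
class DinucleotideProfile:
    window: tuple[int, int]
    raw: np.ndarray  # per-dinucleotide-start frequency across genes
    smoothed: np.ndarray
    smooth_bp: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] - 1)


def filter_mnase_fragments(
    frags: FragmentSet, min_len: int = 120, max_len: int = 180
) -> FragmentSet:
    """Keep mononucleosome-sized fragments, bounds inclusive."""
    out = {}
    for chrom, arr in frags.intervals.items():
        lengths = arr[:, 1] - arr[:, 0]
        out[chrom] = arr[(lengths >= min_len) & (lengths <= max_len)]
    return FragmentSet(frags.sample_id + ":sized", frags.condition, frags.assay, out)


def metagene(
    genes: list[GeneModel],
    midpoint_track: CoverageTrack,
    window: tuple[int, int] = (-500, 500),
    gene_set_id: str = "genes",
) -> MetageneProfile:
    """Average strand-aware midpoint signal over TSS-relative ``window``.

    The track should be midpoint-mode and per-million normalized.  Genes
    whose window leaves the chromosome are dropped and counted.
    """
    if not genes:
        raise ValueError("metagene requires a non-empty gene set")
    width = window[1] - window[0]
    acc = np.zeros(width)
    n_used = n_dropped = 0
    for gene in genes:
        vals = window_values(midpoint_track, gene, window[0], window[1], oob="drop")
        if vals is None:
            n_dropped += 1
            continue
        acc += vals
        n_used += 1
    if n_used == 0:
        raise ValueError("every gene window left its chromosome; no metagene")
    if n_dropped:
        log.info("metagene %s: dropped %d genes at chromosome edges", gene_set_id, n_dropped)
    return MetageneProfile(
        gene_set_id=gene_set_id,
        window=window,
        values=acc / n_used,
        n_genes=n_used,
        n_midpoints_total=float(acc.sum()),
        n_dropped=n_dropped,
    )


def pooled_relative_midpoints(
    genes: list[GeneModel],
    frags: FragmentSet,
    window: tuple[int, int] = (-500, 500),
) -> np.ndarray:
    """TSS-relative midpoint positions pooled over the gene set.

    Each gene contributes the fragments whose midpoint falls inside its
    strand-aware window; with the selection stage's >= 2 kb spacing a
    midpoint lands in at most one window.
    """
    sorted_mid: dict[str, np.ndarray] = {
        c: np.sort(frags.midpoints(c)) for c in frags.intervals
    }
    rel: list[np.ndarray] = []
    for gene in genes:
        mids = sorted_mid.get(gene.chrom)
        if mids is None or not mids.size:
            continue
        gs, ge = relative_window(gene, *window)
        lo = np.searchsorted(mids, max(gs, 0), side="left")
        hi = np.searchsorted(mids, ge, side="left")
        if hi > lo:
            rel.append(relative_positions(gene, mids[lo:hi]))
    if not rel:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(rel)


def section_ks(
    genes: list[GeneModel],
    wt_frags: FragmentSet,
    mut_frags: FragmentSet,
    mode: str = "four_sections",
    window: tuple[int, int] = (-500, 500),
    min_midpoints: int = 10,
) -> list[SectionTest]:
    """Two-sample KS per section on pooled TSS-relative midpoint positions.

    ``mode``: ``four_sections`` splits the 1 kb window into 250-bp quarters;
    ``upstream_halves`` tests the distal [-500,-250) and proximal [-250,0)
    upstream halves only.  A section with fewer than ``min_midpoints`` in
    either condition is reported as skipped.  Per-section per-million mass
    is reported so occupancy-level shifts are visible alongside the
    positional test.
    """
    if mode == "four_sections":
        sections = FOUR_SECTIONS
    elif mode == "upstream_halves":
        sections = UPSTREAM_HALVES
    else:
        raise ValueError(f"unknown section mode {mode!r}")

    wt_rel = pooled_relative_midpoints(genes, wt_frags, window)
    mut_rel = pooled_relative_midpoints(genes, mut_frags, window)
    wt_scale = 1e6 / wt_frags.total_count if wt_frags.total_count else 0.0
    mut_scale = 1e6 / mut_frags.total_count if mut_frags.total_count else 0.0

    out = []
    for s0, s1 in sections:
        wt_sec = wt_rel[(wt_rel >= s0) & (wt_rel < s1)]
        mut_sec = mut_rel[(mut_rel >= s0) & (mut_rel < s1)]
        mass_wt = len(wt_sec) * wt_scale
        mass_mut = len(mut_sec) * mut_scale
        if len(wt_sec) < min_midpoints or len(mut_sec) < min_midpoints:
            out.append(
                SectionTest(
                    (s0, s1), np.nan, np.nan, len(wt_sec), len(mut_sec),
                    skipped=f"fewer than {min_midpoints} midpoints in a condition",
                    mass_wt=mass_wt, mass_mut=mass_mut,
                )
            )
            continue
        res = stats.ks_2samp(wt_sec, mut_sec, method="asymp")
        out.append(
            SectionTest(
                (s0, s1), float(res.statistic), float(res.pvalue),
                len(wt_sec), len(mut_sec), mass_wt=mass_wt, mass_mut=mass_mut,
            )
        )
    return out


def ss_dinucleotide_profile(
    seq: GenomeSequence,
    genes: list[GeneModel],
    window: tuple[int, int] = (-500, 500),
    smooth_bp: int = 50,
) -> DinucleotideProfile:
    """Cross-gene frequency of strong-strong dinucleotides per TSS-relative
    dinucleotide start position.

    Minus-strand genes contribute their reverse-complemented window; since
    {GG, GC, CC, CG} is closed under reverse complement this equals testing
    the reference sequence directly.  Positions with N in either base are
    excluded from that position's denominator.  A centered moving average of
    ``smooth_bp`` is applied last; raw values are retained.
    """
    width = window[1] - window[0]
    counts = np.zeros(width - 1)
    denom = np.zeros(width - 1)
    n_used = 0
    for gene in genes:
        gs, ge = relative_window(gene, window[0], window[1])
        if gs < 0 or ge > seq.lengths[gene.chrom]:
            continue
        sub = seq.fetch(gene.chrom, gs, ge)
        if gene.strand == "-":
            sub = reverse_complement(sub)
        arr = np.frombuffer(sub.encode(), dtype=np.uint8)
        is_s = (arr == ord("G")) | (arr == ord("C"))
        is_n = arr == ord("N")
        ok = ~(is_n[:-1] | is_n[1:])
        counts += np.where(ok, is_s[:-1] & is_s[1:], 0)
        denom += ok
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene window fully on its chromosome")
    with np.errstate(invalid="ignore"):
        raw = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
    return DinucleotideProfile(window, raw, _smooth(raw, smooth_bp), smooth_bp)


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; shrinks the window at the edges."""
    if width <= 1:
        return values.copy()
    filled = np.nan_to_num(values)
    weight = (~np.isnan(values)).astype(float)
    kernel = np.ones(width)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(weight, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def sample_nontargets(
    nontarget_genes: list[GeneModel],
    n: int = 1900,
    seed: int = 0,
    arms: list[str] | None = None,
) -> list[GeneModel]:
    """Random non-target control set, stratified near-equally across arms.

    Per-arm quotas are n // n_arms with the remainder given to the first
    arms in sorted name order; an arm short of its quota passes the deficit
    to later arms deterministically.  Sampling is without replacement and
    reproducible under a fixed seed.
    """
    if len(nontarget_genes) < n:
        raise ValueError(f"pool of {len(nontarget_genes)} genes < requested {n}")
    if arms is None:
        arms = sorted({g.chrom for g in nontarget_genes})
    by_arm = {arm: sorted((g for g in nontarget_genes if g.chrom == arm),
                          key=lambda g: g.gene_id) for arm in arms}
    k = len(arms)
    base, rem = divmod(n, k)
    quotas = {arm: base + (1 if i < rem else 0) for i, arm in enumerate(arms)}
    # deterministic redistribution of deficits
    deficit = 0
    for arm in arms:
        avail = len(by_arm[arm])
        if quotas[arm] > avail:
            deficit += quotas[arm] - avail
            quotas[arm] = avail
    for arm in arms:
        if deficit == 0:
            break
        room = len(by_arm[arm]) - quotas[arm]
        take = min(room, deficit)
        quotas[arm] += take
        deficit -= take
    if deficit:
        raise ValueError("declared arms cannot supply the requested sample size")
    rng = np.random.default_rng(seed)
    chosen: list[GeneModel] = []
    for arm in arms:
        pool = by_arm[arm]
        idx = rng.choice(len(pool), size=quotas[arm], replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return chosen
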