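"""Replicate-based differential expression filtering and target intersection.

Inputs are pre-normalized linear-scale intensities with replicate columns
per condition.  A gene is called significant when it passes the expression
floor (mean WT intensity > 100), the Welch t-test on log2 intensities gives
p < 0.05, and the linear fold change exceeds 1.5x in either direction.  No
multiple-testing correction is applied by default (the filtering criterion
is a raw-p threshold); Benjamini-Hochberg is available as an option.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .targets import TargetAssignment

log = logging.getLogger(__name__)


@dataclass
class ExpressionRecord:
    gene_id: str
    mean_wt: float
    mean_mut: float
    log2_fc: float  # log2(mean_mut / mean_wt)
    p_value: float
    passes_intensity: bool
    significant: bool
    direction: str  # up | down | none


@dataclass
class TargetIntersection:
    n_significant: int
    n_direct_targets: int
    n_direct_down: int
    n_direct_up: int
    direct_down_fraction: float  # NaN when no direct targets
    global_down_fraction: float  # NaN when nothing significant


def _split_columns(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    wt = [c for c in df.columns if c.lower().startswith("wt")]
    mut = [c for c in df.columns if c.lower().startswith("mut")]
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("need >= 2 replicate columns per condition (wt_*/mut_*)")
    return wt, mut


def differential_expression(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    fold: float = 1.5,
    min_intensity: float = 100.0,
    bh_correct: bool = False,
) -> list[ExpressionRecord]:
    """Welch t-test on log2 intensities with fold-change and intensity filters.

    ``matrix`` is indexed by gene_id (or has a ``gene_id`` column) with
    replicate columns named ``wt_*`` and ``mut_*``.  Intensities must be
    strictly positive.  Fold change is computed on condition means of the
    linear intensities.
    """
    df = matrix.set_index("gene_id") if "gene_id" in matrix.columns else matrix
    wt_cols, mut_cols = _split_columns(df)
    wt = df[wt_cols].to_numpy(dtype=float)
    mut = df[mut_cols].to_numpy(dtype=float)
    bad = np.where((wt <= 0).any(axis=1) | (mut <= 0).any(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-positive intensity for gene {df.index[bad[0]]!r}")

    t, p = stats.ttest_ind(np.log2(wt), np.log2(mut), axis=1, equal_var=False)
    p = np.asarray(p)
    if bh_correct:
        p = multipletests(p, method="fdr_bh")[1]
    mean_wt = wt.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    log2_fc = np.log2(mean_mut / mean_wt)
    log_fold = math.log2(fold)

    records = []
    for i, gene_id in enumerate(df.index):
        passes = bool(mean_wt[i] > min_intensity)
        sig = bool(passes and p[i] < alpha and abs(log2_fc[i]) > log_fold)
        direction = "none"
        if sig:
            direction = "down" if log2_fc[i] < 0 else "up"
        records.append(
            ExpressionRecord(
                str(gene_id), float(mean_wt[i]), float(mean_mut[i]),
                float(log2_fc[i]), float(p[i]), passes, sig, direction,
            )
        )
    return records


def records_to_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]).set_index("gene_id")


def intersect_targets(
    de_records: list[ExpressionRecord],
    assignments: list[TargetAssignment],
    min_fold: float = 2.0,
) -> TargetIntersection:
    """Direct targets: significant genes whose best promoter peak exceeds
    ``min_fold`` enrichment (strictly).  Reports the down/up split among
    direct targets and the global down-fraction among all significant genes.
    """
    promoter_fold = {a.gene_id: a.max_promoter_fold for a in assignments}
    significant = [r for r in de_records if r.significant]
    direct = [r for r in significant if promoter_fold.get(r.gene_id, 0.0) > min_fold]
    n_down = sum(1 for r in direct if r.direction == "down")
    n_up = sum(1 for r in direct if r.direction == "up")
    if not significant:
        log.warning("no significant genes; down-fractions undefined")
    n_global_down = sum(1 for r in significant if r.direction == "down")
    return TargetIntersection(
        n_significant=len(significant),
        n_direct_targets=len(direct),
        n_direct_down=n_down,
        n_direct_up=n_up,
        direct_down_fraction=(n_down / len(direct)) if direct else float("nan"),
        global_down_fraction=(n_global_down / len(significant)) if significant else float("nan"),
    )
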