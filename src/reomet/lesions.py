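"""Mutation / copy-number lesion comparisons between sample groups.

Copy-number gains and losses of the same region are treated as distinct
binary lesions ("<region>:amp" tests call == +1, "<region>:del" tests
call == -1).  Per-lesion Fisher tests are BH-adjusted within each lesion
family (mutations and CNAs separately by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import CNAMatrix, ExpressionMatrix, MutationMatrix, RegionGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "LesionTest",
    "BurdenSummary",
    "ExprCnaCorrelation",
    "binarize_cna",
    "prevalence_filter",
    "lesion_tests",
    "burden_compare",
    "expr_cna_correlation",
]

HIGHER_IN_MET = "higher_in_met"
HIGHER_IN_NONMET = "higher_in_nonmet"


@dataclass(frozen=True)
class LesionTest:
    lesion_id: str
    lesion_type: str  # mutation | amplification | deletion
    freq_met: float
    freq_nonmet: float
    fisher_p: float
    fdr: float
    direction: str


@dataclass(frozen=True)
class BurdenSummary:
    counts_met: np.ndarray
    counts_nonmet: np.ndarray
    median_met: float
    median_nonmet: float
    t_stat: float
    p: float


@dataclass(frozen=True)
class ExprCnaCorrelation:
    gene_id: str
    rho: float
    p: float
    fdr: float
    positive_significant: bool


def binarize_cna(cna: CNAMatrix) -> tuple[pd.DataFrame, dict[str, str]]:
    """Split a {-1,0,+1} matrix into binary amp/del lesions.

    Returns the stacked binary frame and a lesion_id -> source region map.
    Only directions actually observed for a region become lesions.
    """
    rows, sources = [], {}
    for region in cna.calls.index:
        vals = cna.calls.loc[region]
        if (vals == 1).any():
            lid = f"{region}:amp"
            rows.append(pd.Series((vals == 1).astype(int), name=lid))
            sources[lid] = str(region)
        if (vals == -1).any():
            lid = f"{region}:del"
            rows.append(pd.Series((vals == -1).astype(int), name=lid))
            sources[lid] = str(region)
    frame = pd.DataFrame(rows) if rows else pd.DataFrame(columns=cna.calls.columns)
    return frame, sources


def prevalence_filter(
    calls: pd.DataFrame | MutationMatrix,
    min_fraction: float = 0.05,
) -> list[str]:
    """Lesions altered (nonzero) in strictly more than ``min_fraction`` of
    all samples."""
    frame = calls.calls if isinstance(calls, MutationMatrix) else calls
    if frame.empty:
        return []
    altered = (frame != 0).sum(axis=1) / frame.shape[1]
    return [str(l) for l in frame.index[altered > min_fraction]]


def _lesion_type(lesion_id: str, family: str) -> str:
    if family == "mutation":
        return "mutation"
    if lesion_id.endswith(":amp"):
        return "amplification"
    if lesion_id.endswith(":del"):
        return "deletion"
    return "cna"


def lesion_tests(
    calls: pd.DataFrame | MutationMatrix,
    met_samples: Sequence[str],
    nonmet_samples: Sequence[str],
    family: str = "mutation",
    min_prevalence: float = 0.05,
) -> list[LesionTest]:
    """Two-sided Fisher tests of lesion presence against group membership,
    BH-adjusted across the tested lesions of this family.

    Frequencies are computed over the samples of each group present in the
    assay (per-assay denominators may differ from the full cohort).
    """
    frame = calls.calls if isinstance(calls, MutationMatrix) else calls
    met = [s for s in met_samples if s in frame.columns]
    non = [s for s in nonmet_samples if s in frame.columns]
    if not met or not non:
        raise ValueError("both groups must have at least one sample in the assay")
    keep = prevalence_filter(frame[met + non], min_prevalence)
    rows = []
    for lesion in keep:
        vals = frame.loc[lesion]
        a = int((vals[met] != 0).sum())
        c = int((vals[non] != 0).sum())
        fm, fn = a / len(met), c / len(non)
        _, p = stats.fisher_exact(
            [[a, len(met) - a], [c, len(non) - c]], alternative="two-sided"
        )
        rows.append((lesion, fm, fn, float(p)))
    fdrs = bh_adjust([p for *_, p in rows])
    return [
        LesionTest(
            lesion_id=lesion,
            lesion_type=_lesion_type(lesion, family),
            freq_met=fm,
            freq_nonmet=fn,
            fisher_p=p,
            fdr=float(f),
            direction=HIGHER_IN_MET if fm >= fn else HIGHER_IN_NONMET,
        )
        for (lesion, fm, fn, p), f in zip(rows, fdrs)
    ]


def burden_compare(
    calls: pd.DataFrame | MutationMatrix,
    met_samples: Sequence[str],
    nonmet_samples: Sequence[str],
) -> BurdenSummary:
    """Per-sample altered-lesion totals compared between groups.

    Medians are reported; the test is a two-sided pooled t-test on the raw
    counts.
    """
    frame = calls.calls if isinstance(calls, MutationMatrix) else calls
    met = [s for s in met_samples if s in frame.columns]
    non = [s for s in nonmet_samples if s in frame.columns]
    if len(met) < 2 or len(non) < 2:
        raise ValueError("each group needs at least 2 samples")
    cm = (frame[met] != 0).sum(axis=0).to_numpy()
    cn = (frame[non] != 0).sum(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(cm, cn, equal_var=True)
    if np.isnan(p):
        t, p = 0.0, 1.0
    return BurdenSummary(
        counts_met=cm,
        counts_nonmet=cn,
        median_met=float(np.median(cm)),
        median_nonmet=float(np.median(cn)),
        t_stat=float(t),
        p=float(p),
    )


def expr_cna_correlation(
    expr: ExpressionMatrix | pd.DataFrame,
    cna: CNAMatrix,
    region_map: RegionGeneMap | None = None,
    alpha_fdr: float = 0.05,
) -> list[ExprCnaCorrelation]:
    """Spearman correlation of each mapped gene's expression with its CNA
    call across shared samples; BH over tested genes.

    Gene-level CNA rows pass through as their own region.  Genes with a
    constant CNA vector are skipped (rho undefined).
    """
    frame = expr.values_frame if isinstance(expr, ExpressionMatrix) else expr
    shared = [s for s in frame.columns if s in cna.calls.columns]
    if len(shared) < 10:
        raise ValueError(f"need >=10 shared samples, got {len(shared)}")
    rmap = region_map or RegionGeneMap(members={})
    pairs: list[tuple[str, str]] = []  # (gene, lesion/region row)
    for region in cna.calls.index:
        for gene in rmap.genes_for(str(region)):
            if gene in frame.index:
                pairs.append((gene, str(region)))
    rows, skipped = [], 0
    for gene, region in pairs:
        cn_vals = cna.calls.loc[region, shared].to_numpy(dtype=float)
        if np.all(cn_vals == cn_vals[0]):
            skipped += 1
            continue
        ex_vals = frame.loc[gene, shared].to_numpy(dtype=float)
        rho, p = stats.spearmanr(ex_vals, cn_vals)
        rows.append((gene, float(rho), float(p)))
    if skipped:
        logger.warning("skipped %d gene(s) with constant CNA vector", skipped)
    fdrs = bh_adjust([p for _, _, p in rows])
    return [
        ExprCnaCorrelation(
            gene_id=g,
            rho=r,
            p=p,
            fdr=float(f),
            positive_significant=bool(r > 0 and f < alpha_fdr),
        )
        for (g, r, p), f in zip(rows, fdrs)
    ]
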