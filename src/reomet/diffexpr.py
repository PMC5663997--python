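"""Two-group differential expression with CV pre-filtering and BH-FDR,
plus list concordance, proliferation scoring, hypergeometric gene-set
enrichment, and subtype association."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "DEGene",
    "ConcordanceResult",
    "EnrichmentResult",
    "ProliferationScore",
    "bh_adjust",
    "cv_filter",
    "de_test",
    "direction_concordance",
    "proliferation_scores",
    "enrich",
    "subtype_association",
]

UP = "up_in_met"
DOWN = "down_in_met"


@dataclass(frozen=True)
class DEGene:
    gene_id: str
    mean_met: float
    mean_nonmet: float
    t_stat: float
    p: float
    fdr: float
    direction: str  # up_in_met | down_in_met


@dataclass(frozen=True)
class ConcordanceResult:
    overlap_count: int
    same_direction_count: int
    fraction: float
    binomial_p: float


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    fdr: float


@dataclass(frozen=True)
class ProliferationScore:
    sample_id: str
    score: float


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def cv_filter(
    expr: ExpressionMatrix | pd.DataFrame,
    threshold: float = 0.10,
) -> list[str]:
    """Genes whose coefficient of variation (sample sd / mean) exceeds the
    threshold.  Genes with mean <= 0 cannot have a meaningful CV on this
    scale and are excluded with a logged count."""
    frame = expr.values_frame if isinstance(expr, ExpressionMatrix) else expr
    if frame.shape[1] < 2:
        raise ValueError("CV filter needs at least 2 samples")
    means = frame.mean(axis=1)
    sds = frame.std(axis=1, ddof=1)
    nonpositive = means <= 0
    if nonpositive.any():
        logger.warning("excluding %d gene(s) with non-positive mean from CV filter", int(nonpositive.sum()))
    cv = sds / means
    keep = (~nonpositive) & (cv > threshold)
    return [str(g) for g in frame.index[keep]]


def _pooled_t(
    x: np.ndarray, y: np.ndarray, equal_var: bool
) -> tuple[float, float]:
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if np.isnan(p):  # zero variance in both groups
        return 0.0, 1.0
    return float(t), float(p)


def de_test(
    expr: ExpressionMatrix | pd.DataFrame,
    met_samples: Iterable[str],
    nonmet_samples: Iterable[str],
    alpha_fdr: float = 0.05,
    genes: Sequence[str] | None = None,
    equal_var: bool = True,
) -> list[DEGene]:
    """Per-gene two-sided Student's t-test (pooled variance by default)
    between the two groups, BH-adjusted over the tested genes.

    ``genes`` restricts testing (normally the CV-filtered list).  Direction
    is the sign of mean(met) - mean(nonmet).
    """
    frame = expr.values_frame if isinstance(expr, ExpressionMatrix) else expr
    met = [s for s in met_samples if s in frame.columns]
    non = [s for s in nonmet_samples if s in frame.columns]
    if len(met) < 2 or len(non) < 2:
        raise ValueError("each group needs at least 2 samples")
    if genes is not None:
        frame = frame.loc[[g for g in genes if g in frame.index]]
    a = frame[met].to_numpy()
    b = frame[non].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tstats, pvals = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    flat = np.isnan(pvals)  # zero variance in both groups, equal means
    tstats = np.where(flat, 0.0, tstats)
    pvals = np.where(flat, 1.0, pvals)
    fdrs = bh_adjust(pvals)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    out = []
    for i, gene in enumerate(frame.index):
        out.append(
            DEGene(
                gene_id=str(gene),
                mean_met=float(mean_a[i]),
                mean_nonmet=float(mean_b[i]),
                t_stat=float(tstats[i]),
                p=float(pvals[i]),
                fdr=float(fdrs[i]),
                direction=UP if mean_a[i] >= mean_b[i] else DOWN,
            )
        )
    return out


def significant(de_genes: Sequence[DEGene], alpha_fdr: float = 0.05) -> list[DEGene]:
    return [g for g in de_genes if g.fdr < alpha_fdr]


def direction_concordance(
    list_a: Sequence[DEGene],
    list_b: Sequence[DEGene],
    alternative: str = "two-sided",
) -> ConcordanceResult:
    """Overlap two DE lists by gene id and test direction agreement against
    a fair coin with an exact binomial test."""
    dir_b = {g.gene_id: g.direction for g in list_b}
    overlap = [g for g in list_a if g.gene_id in dir_b]
    same = sum(1 for g in overlap if g.direction == dir_b[g.gene_id])
    if not overlap:
        logger.warning("empty overlap between DE lists; concordance undefined")
        return ConcordanceResult(0, 0, float("nan"), float("nan"))
    p = stats.binomtest(same, len(overlap), 0.5, alternative=alternative).pvalue
    return ConcordanceResult(len(overlap), same, same / len(overlap), float(p))


def binomial_direction_test(
    n_same: int, n_total: int, alternative: str = "two-sided"
) -> float:
    """Exact binomial p that ``n_same`` of ``n_total`` directions agree by chance."""
    return float(stats.binomtest(n_same, n_total, 0.5, alternative=alternative).pvalue)


def proliferation_scores(
    expr: ExpressionMatrix | pd.DataFrame,
    gene_set: Iterable[str],
    group_a: Iterable[str] | None = None,
    group_b: Iterable[str] | None = None,
) -> tuple[list[ProliferationScore], tuple[float, float] | None]:
    """Per-sample mean expression over the (present) proliferation genes,
    with an optional pooled t-test comparing two sample groups."""
    frame = expr.values_frame if isinstance(expr, ExpressionMatrix) else expr
    wanted = list(dict.fromkeys(gene_set))
    present = [g for g in wanted if g in frame.index]
    if not present:
        raise ValueError("no proliferation gene present in the matrix")
    if len(present) < len(wanted):
        logger.warning("%d of %d proliferation genes missing", len(wanted) - len(present), len(wanted))
    scores = frame.loc[present].mean(axis=0)
    out = [ProliferationScore(str(s), float(v)) for s, v in scores.items()]
    comparison = None
    if group_a is not None and group_b is not None:
        va = scores[[s for s in group_a if s in scores.index]].to_numpy()
        vb = scores[[s for s in group_b if s in scores.index]].to_numpy()
        comparison = _pooled_t(va, vb, equal_var=True)
    return out, comparison


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of the query in each set,
    BH-adjusted across sets.  Sets are intersected with the universe."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    rows = []
    for sid, (_, genes) in sets.items():
        s = set(genes) & uni
        k = len(q & s)
        # P(X >= k) with M=|universe|, n=|set|, N=|query|
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))
        rows.append((sid, k, len(s), p))
    fdrs = bh_adjust([p for _, _, _, p in rows])
    return [
        EnrichmentResult(
            set_id=sid,
            overlap=k,
            set_size=ns,
            query_size=len(q),
            universe_size=len(uni),
            p=p,
            fdr=float(f),
        )
        for (sid, k, ns, p), f in zip(rows, fdrs)
    ]


def subtype_association(
    labels: Sequence[str],
    subtypes: Sequence[str],
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on labels x subtype."""
    table = pd.crosstab(pd.Series(labels), pd.Series(subtypes))
    if table.shape[1] < 2:
        raise ValueError("need at least 2 subtype levels")
    stat, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 1).any():
        logger.warning("expected cell count < 1; consider an exact test")
    return float(stat), float(p)
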