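"""Metastasis-state reclassification from strict-rule risk calls, and the
risk-call x clinical-metastasis association tables.

The reclassification rule is one-directional: a sample stays nonmetastatic
only when it is both clinically nonmetastatic and called low risk; every
other sample (clinically metastatic, or called high risk) is relabelled
metastatic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .io_formats import ClinicalTable
from .reo_classifier import RiskCall

logger = logging.getLogger(__name__)

__all__ = ["ReclassifiedLabels", "AssociationTable", "reclassify", "fisher_association"]

METASTATIC = "metastatic"
NONMETASTATIC = "nonmetastatic"


@dataclass
class ReclassifiedLabels:
    labels: dict[str, str]  # sample_id -> metastatic | nonmetastatic
    provenance: dict[str, str]  # clinical_met | signature_high | both | neither

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.provenance.values():
            out[p] = out.get(p, 0) + 1
        return out

    @property
    def metastatic_ids(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == METASTATIC]

    @property
    def nonmetastatic_ids(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == NONMETASTATIC]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.labels),
                "label": [self.labels[s] for s in self.labels],
                "provenance": [self.provenance[s] for s in self.labels],
            }
        )


@dataclass(frozen=True)
class AssociationTable:
    """2x2 table [[high&met, low&met], [high&nonmet, low&nonmet]]."""

    table: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float
    odds_ratio: float
    sidedness: str

    def to_dict(self) -> dict:
        return {
            "table": [list(self.table[0]), list(self.table[1])],
            "fisher_p": self.fisher_p,
            "odds_ratio": self.odds_ratio,
            "sidedness": self.sidedness,
        }


def reclassify(clinical: ClinicalTable, calls: Sequence[RiskCall]) -> ReclassifiedLabels:
    """Apply the one-directional relabelling rule to every called sample."""
    cf = clinical.frame
    labels: dict[str, str] = {}
    provenance: dict[str, str] = {}
    skipped = 0
    for call in calls:
        if call.sample_id not in cf.index:
            raise KeyError(f"risk call for unknown sample {call.sample_id!r}")
        met = cf.loc[call.sample_id].get("metastasis_clinical")
        if pd.isna(met):
            skipped += 1
            continue
        clinical_met = met == "yes"
        high = call.label == "high"
        if clinical_met and high:
            provenance[call.sample_id] = "both"
        elif clinical_met:
            provenance[call.sample_id] = "clinical_met"
        elif high:
            provenance[call.sample_id] = "signature_high"
        else:
            provenance[call.sample_id] = "neither"
        labels[call.sample_id] = (
            METASTATIC if (clinical_met or high) else NONMETASTATIC
        )
    if skipped:
        logger.warning("%d sample(s) lacked clinical metastasis status; excluded", skipped)
    return ReclassifiedLabels(labels=labels, provenance=provenance)


def fisher_association(
    high_risk: Sequence[bool],
    clinical_met: Sequence[bool],
    sidedness: str = "two",
) -> AssociationTable:
    """Fisher's exact test of high-risk calls against clinical metastasis.

    Two-sided p sums tables with probability at most the observed one;
    one-sided tests enrichment of high risk among metastatic samples.
    Degenerate margins return p = 1.
    """
    if sidedness not in ("one", "two"):
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    if len(high_risk) != len(clinical_met):
        raise ValueError("inputs must align")
    a = sum(1 for h, m in zip(high_risk, clinical_met) if h and m)
    b = sum(1 for h, m in zip(high_risk, clinical_met) if not h and m)
    c = sum(1 for h, m in zip(high_risk, clinical_met) if h and not m)
    d = sum(1 for h, m in zip(high_risk, clinical_met) if not h and not m)
    return fisher_from_table(((a, b), (c, d)), sidedness)


def fisher_from_table(
    table: Sequence[Sequence[int]],
    sidedness: str = "two",
) -> AssociationTable:
    """Fisher's exact test on an explicit [[a,b],[c,d]] table."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("negative count in contingency table")
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        return AssociationTable(((a, b), (c, d)), 1.0, float("nan"), sidedness)
    alternative = "two-sided" if sidedness == "two" else "greater"
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return AssociationTable(((a, b), (c, d)), float(p), float(odds), sidedness)
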