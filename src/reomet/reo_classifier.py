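"""Within-sample gene-pair ordering classifier with k-of-n voting.

A signature is an ordered list of gene pairs (gene_a, gene_b).  Within one
sample, expression(gene_a) > expression(gene_b) is a vote for the high-risk
class and the reverse ordering votes for low risk.  A sample is labelled low
risk when at least ``k`` of the ``n`` pairs vote low; otherwise high risk.
Because only within-sample orderings are consulted, labels are invariant to
any strictly monotone per-sample transform of the expression values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenePairSignature",
    "VotingRule",
    "RiskCall",
    "CalibrationReport",
    "pair_votes",
    "classify",
    "select_k",
    "calibrate_threshold",
]

HIGH = "high"
LOW = "low"
TIE = "tie"
NOT_EVALUABLE = "na"


@dataclass(frozen=True)
class GenePairSignature:
    """Ordered gene pairs; first gene above second is a high-risk vote."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("signature must contain at least one gene pair")
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a!r}, {b!r}): genes must differ")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a!r}, {b!r})")
            seen.add((a, b))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}


@dataclass(frozen=True)
class VotingRule:
    """Low-risk label requires at least ``min_low_votes`` low votes of ``n``."""

    min_low_votes: int
    n: int
    name: str = "strict-k"

    def __post_init__(self) -> None:
        if not 1 <= self.min_low_votes <= self.n:
            raise ValueError(
                f"min_low_votes must satisfy 1 <= k <= n, got k={self.min_low_votes} n={self.n}"
            )

    @classmethod
    def majority(cls, n: int) -> "VotingRule":
        # more than half of n votes; for odd n this is ceil((n+1)/2)
        return cls(min_low_votes=n // 2 + 1, n=n, name="majority")

    @classmethod
    def strict(cls, k: int, n: int) -> "VotingRule":
        return cls(min_low_votes=k, n=n, name=f"strict-{k}of{n}")


@dataclass(frozen=True)
class RiskCall:
    sample_id: str
    evaluable_pairs: int
    high_votes: int
    low_votes: int
    tie_votes: int
    label: str  # "high" | "low"

    def __post_init__(self) -> None:
        if self.high_votes + self.low_votes + self.tie_votes != self.evaluable_pairs:
            raise ValueError("vote counts must sum to evaluable_pairs")
        if self.label not in (HIGH, LOW):
            raise ValueError(f"label must be 'high' or 'low', got {self.label!r}")


@dataclass(frozen=True)
class CalibrationReport:
    """High-risk fractions per candidate k and the selected threshold."""

    fractions: Mapping[int, float]
    selected_k: int
    target_interval: tuple[float, float]
    n_samples: int = 0


def _interval_distance(x: float, interval: tuple[float, float]) -> float:
    lo, hi = interval
    if lo <= x <= hi:
        return 0.0
    return lo - x if x < lo else x - hi


def select_k(
    fractions: Mapping[int, float],
    target_interval: tuple[float, float] = (0.35, 0.50),
) -> int:
    """Pick the candidate k whose high-risk fraction is closest to the target
    interval (distance 0 inside; else distance to the nearer endpoint),
    breaking ties toward the larger (stricter) k."""
    if not fractions:
        raise ValueError("no candidate thresholds")
    # distances rounded so equidistant candidates tie despite float error
    return max(
        fractions,
        key=lambda k: (-round(_interval_distance(fractions[k], tuple(target_interval)), 9), k),
    )


def pair_votes(
    expr: pd.DataFrame | "object",
    sig: GenePairSignature,
    sample_id: str,
) -> list[str]:
    """Per-pair votes for one sample: 'high', 'low', 'tie', or 'na'.

    ``expr`` is a genes x samples frame (or an object exposing ``.values``
    as one).  Pairs whose genes are absent from the matrix are 'na'.
    """
    values = getattr(expr, "values_frame", None)
    frame = values if values is not None else expr
    if sample_id not in frame.columns:
        raise KeyError(f"sample {sample_id!r} not in expression matrix")
    col = frame[sample_id]
    votes = []
    for a, b in sig.pairs:
        if a not in frame.index or b not in frame.index:
            votes.append(NOT_EVALUABLE)
            continue
        ea, eb = col[a], col[b]
        if ea > eb:
            votes.append(HIGH)
        elif ea < eb:
            votes.append(LOW)
        else:
            votes.append(TIE)
    return votes


def _vote_matrix(frame: pd.DataFrame, sig: GenePairSignature) -> np.ndarray:
    """(n_pairs, n_samples) int matrix: +1 high, -1 low, 0 tie, -9 not evaluable."""
    out = np.full((sig.n_pairs, frame.shape[1]), -9, dtype=np.int8)
    index = frame.index
    for i, (a, b) in enumerate(sig.pairs):
        if a not in index or b not in index:
            continue
        diff = frame.loc[a].to_numpy() - frame.loc[b].to_numpy()
        out[i] = np.sign(diff)
    return out


def classify(
    expr: pd.DataFrame | "object",
    sig: GenePairSignature,
    rule: VotingRule,
    min_evaluable: int = 6,
) -> list[RiskCall]:
    """Label every sample under the voting rule.

    When pairs are non-evaluable the low-vote threshold is rescaled
    proportionally: effective_k = ceil(k * evaluable / n).  Samples with
    fewer than ``min_evaluable`` evaluable pairs raise.
    """
    values = getattr(expr, "values_frame", None)
    frame = values if values is not None else expr
    if rule.n != sig.n_pairs:
        raise ValueError(f"rule.n={rule.n} does not match signature size {sig.n_pairs}")
    votes = _vote_matrix(frame, sig)
    calls = []
    for j, sample_id in enumerate(frame.columns):
        col = votes[:, j]
        evaluable = int((col != -9).sum())
        if evaluable < min_evaluable:
            raise ValueError(
                f"sample {sample_id!r}: only {evaluable} of {sig.n_pairs} pairs "
                f"evaluable (< min_evaluable={min_evaluable})"
            )
        high = int((col == 1).sum())
        low = int((col == -1).sum())
        tie = int((col == 0).sum())
        effective_k = math.ceil(rule.min_low_votes * evaluable / rule.n)
        label = LOW if low >= effective_k else HIGH
        calls.append(
            RiskCall(
                sample_id=str(sample_id),
                evaluable_pairs=evaluable,
                high_votes=high,
                low_votes=low,
                tie_votes=tie,
                label=label,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[RiskCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "evaluable_pairs": [c.evaluable_pairs for c in calls],
            "high_votes": [c.high_votes for c in calls],
            "low_votes": [c.low_votes for c in calls],
            "tie_votes": [c.tie_votes for c in calls],
            "label": [c.label for c in calls],
        }
    )


def calibrate_threshold(
    expr: pd.DataFrame | "object",
    sig: GenePairSignature,
    candidate_ks: Iterable[int] = (6, 7, 8, 9),
    target_interval: tuple[float, float] = (0.35, 0.50),
    min_evaluable: int = 6,
) -> CalibrationReport:
    """Pick the low-vote threshold whose high-risk fraction is closest to the
    target interval (distance 0 inside it, else distance to the nearer
    endpoint); ties broken toward the larger, stricter k."""
    ks = sorted(set(int(k) for k in candidate_ks))
    if not ks:
        raise ValueError("candidate_ks is empty")
    values = getattr(expr, "values_frame", None)
    frame = values if values is not None else expr
    if frame.shape[1] < 10:
        raise ValueError("calibration requires at least 10 samples")
    fractions: dict[int, float] = {}
    for k in ks:
        calls = classify(frame, sig, VotingRule.strict(k, sig.n_pairs), min_evaluable)
        fractions[k] = sum(c.label == HIGH for c in calls) / len(calls)
    best = select_k(fractions, tuple(target_interval))
    return CalibrationReport(
        fractions=fractions,
        selected_k=best,
        target_interval=(float(target_interval[0]), float(target_interval[1])),
        n_samples=frame.shape[1],
    )
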