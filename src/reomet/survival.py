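"""Survival machinery: Kaplan-Meier curves, log-rank test, Cox models,
Harrell's concordance index, and event rate at a fixed horizon.

Times are in months throughout; 5 years = 60 months.  Cox fitting uses
lifelines (Efron tie handling).  Samples with adjuvant therapy recorded as
'yes' are excluded from survival frames by default; 'unknown' is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.exceptions import ConvergenceError

from .io_formats import ClinicalTable
from .reo_classifier import RiskCall

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxResult",
    "SurvivalComparison",
    "km_fit",
    "logrank",
    "cox",
    "c_index",
    "rate_at",
    "compare_groups",
    "survival_frame",
]

FIVE_YEARS_MONTHS = 60.0


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: step function right-continuous in time."""

    times: np.ndarray  # event times where the estimate drops
    survival: np.ndarray  # S(t) just after each time
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t) using the last estimate at time <= t (S=1 before the first drop)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxResult:
    covariate: str
    hr: float
    ci: tuple[float, float]
    p: float
    log_hr: float
    se: float


@dataclass
class SurvivalComparison:
    km_curves: dict[str, KMCurve]
    logrank_stat: float
    logrank_p: float
    hr: float
    ci: tuple[float, float]
    cox_p: float
    c_index: float
    rate_at_horizon: dict[str, float]
    horizon: float
    n_per_group: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "hr": self.hr,
            "ci": list(self.ci),
            "cox_p": self.cox_p,
            "c_index": self.c_index,
            "rate_at_horizon": self.rate_at_horizon,
            "horizon": self.horizon,
            "n_per_group": self.n_per_group,
        }


def km_fit(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator (events before censorings at ties)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size < 1:
        raise ValueError("km_fit needs at least one sample")
    if (t == 0).all() and (e == 0).all():
        warnings.warn("all samples censored at t=0; degenerate KM curve")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    event_times = np.unique(t[e == 1])
    surv = np.array([float(sf.loc[sf.index <= ti].iloc[-1, 0]) for ti in event_times])
    at_risk = np.array([(t >= ti).sum() for ti in event_times])
    return KMCurve(times=event_times, survival=surv, n_at_risk=at_risk)


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square stat on 1 df, two-sided p)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if (g == labels[0]).sum() == 0 or (g == labels[1]).sum() == 0:
        raise ValueError("empty group")
    if e.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    mask = g == labels[0]
    res = logrank_test(t[mask], t[~mask], e[mask], e[~mask])
    return float(res.test_statistic), float(res.p_value)


def cox(
    frame: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: Sequence[str] | None = None,
) -> dict[str, CoxResult]:
    """Cox proportional hazards fit (Efron ties); Wald CI and p per covariate.

    ``covariates=None`` uses every column other than time/event.  Constant
    covariates raise; separation is surfaced as a warning by lifelines.
    """
    covs = list(covariates) if covariates is not None else [
        c for c in frame.columns if c not in (duration_col, event_col)
    ]
    if not covs:
        raise ValueError("no covariates to fit")
    for c in covs:
        if frame[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant across samples")
    n_events = int(frame[event_col].sum())
    if n_events < len(covs):
        raise ValueError(f"{n_events} events < {len(covs)} covariates")
    fitter = CoxPHFitter()
    data = frame[[duration_col, event_col, *covs]].dropna()
    try:
        fitter.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    summary = fitter.summary
    out = {}
    for c in covs:
        row = summary.loc[c]
        out[c] = CoxResult(
            covariate=c,
            hr=float(row["exp(coef)"]),
            ci=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
            p=float(row["p"]),
            log_hr=float(row["coef"]),
            se=float(row["se(coef)"]),
        )
    return out


def c_index(
    risk_scores: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
) -> float:
    """Harrell's concordance index.

    Comparable pairs: the sample with the shorter time had an event.
    Concordant pairs (higher score fails earlier) count 1, score ties 0.5.
    """
    s = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("scores, times, events must align")
    conc = 0.0
    comparable = 0
    for i in range(len(t)):
        if e[i] != 1:
            continue
        mask = (t > t[i]) | ((t == t[i]) & (e == 0))
        comparable += int(mask.sum())
        conc += (s[mask] < s[i]).sum() + 0.5 * (s[mask] == s[i]).sum()
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return float(conc / comparable)


def rate_at(
    times: Sequence[float],
    events: Sequence[int],
    horizon: float = FIVE_YEARS_MONTHS,
) -> float:
    """Event rate 1 - S(horizon) from the KM curve."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t = np.asarray(times, dtype=float)
    if t.max() < horizon:
        warnings.warn(
            f"no follow-up reaches horizon {horizon}; rate extrapolates the last estimate"
        )
    return 1.0 - km_fit(times, events).at(horizon)


def survival_frame(
    clinical: ClinicalTable,
    calls: Sequence[RiskCall],
    endpoint: str = "os",
    exclude_adjuvant: bool = True,
) -> pd.DataFrame:
    """Join risk calls to survival columns; one row per evaluable sample.

    Drops samples missing the endpoint; drops adjuvant=='yes' samples by
    default ('unknown' and missing retained).
    """
    if endpoint not in ("os", "rfs"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    cf = clinical.frame
    if tcol not in cf.columns or ecol not in cf.columns:
        raise ValueError(f"clinical table lacks {tcol}/{ecol}")
    rows = []
    for call in calls:
        if call.sample_id not in cf.index:
            continue
        rec = cf.loc[call.sample_id]
        if exclude_adjuvant and str(rec.get("adjuvant", "")) == "yes":
            continue
        if pd.isna(rec[tcol]) or pd.isna(rec[ecol]):
            continue
        rows.append(
            {
                "sample_id": call.sample_id,
                "time": float(rec[tcol]),
                "event": int(rec[ecol]),
                "group": call.label,
                "age": rec.get("age", np.nan),
                "gender": rec.get("gender", None),
                "stage": rec.get("stage", None),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    frame: pd.DataFrame,
    horizon: float = FIVE_YEARS_MONTHS,
) -> SurvivalComparison:
    """Full two-group evaluation: KM per group, log-rank, univariate Cox HR
    (high vs low), C-index of the group indicator, event rate at horizon."""
    if frame.empty:
        raise ValueError("empty survival frame")
    curves, rates, n_per = {}, {}, {}
    for label, grp in frame.groupby("group"):
        curves[str(label)] = km_fit(grp["time"], grp["event"])
        rates[str(label)] = rate_at(grp["time"], grp["event"], horizon)
        n_per[str(label)] = len(grp)
    stat, p = logrank(frame["time"], frame["event"], frame["group"])
    indicator = (frame["group"] == "high").astype(float)
    cox_frame = pd.DataFrame(
        {"time": frame["time"], "event": frame["event"], "high": indicator}
    )
    fit = cox(cox_frame, covariates=["high"])["high"]
    ci_val = c_index(indicator, frame["time"], frame["event"])
    return SurvivalComparison(
        km_curves=curves,
        logrank_stat=stat,
        logrank_p=p,
        hr=fit.hr,
        ci=fit.ci,
        cox_p=fit.p,
        c_index=ci_val,
        rate_at_horizon=rates,
        horizon=horizon,
        n_per_group=n_per,
    )
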