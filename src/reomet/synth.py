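"""Seeded synthetic cohort generator.

Produces an expression matrix whose signature-pair orderings track a latent
metastasis state, clinical labels with occult false negatives, risk-dependent
exponential survival, mutation/CNA matrices with planted differential
lesions, a regulatory network with a planted driver wired to planted DE
genes, and the ground truth needed to score recovery.

Pair orderings are generated from Gaussian log-expression with a per-sample
random effect: for pair (a, b) the within-sample difference is
N(offset_state + u, 2) with u ~ N(0, tau^2), and the state offset is solved
from the marginal orthant probability so that P(Ea > Eb | state) equals the
requested theta exactly.  The random effect correlates votes within a
sample, which is what makes the strict and majority rules separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .io_formats import (
    ClinicalTable,
    CNAMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    MutationMatrix,
    RegionGeneMap,
    write_clinical,
    write_cna_matrix,
    write_expression,
    write_gmt,
    write_mutation_matrix,
    write_network,
    write_region_map,
    write_signature,
)
from .reo_classifier import GenePairSignature, RiskCall

__all__ = ["CohortParams", "SyntheticCohort", "generate_cohort", "evaluate_recovery", "write_cohort"]


@dataclass(frozen=True)
class CohortParams:
    n_samples: int = 400
    n_genes: int = 2000
    n_pairs: int = 9
    pi_met: float = 0.4
    phi_occult: float = 0.2
    theta1: float = 0.85  # P(Ea > Eb | latent metastatic)
    theta0: float = 0.35  # P(Ea > Eb | latent nonmetastatic)
    pair_tau: float = 1.0  # sd of the per-sample vote random effect
    n_de: int = 100
    delta_de: float = 1.0
    hr_true: float = 2.5
    baseline_hazard: float = 0.02  # per month
    censor_window: float = 120.0
    n_mut_lesions: int = 30
    n_planted_mut: int = 10
    n_cna_regions: int = 10
    n_planted_cna: int = 5
    genes_per_region: int = 2
    f1: float = 0.4  # planted lesion frequency, latent metastatic
    f0: float = 0.1  # planted lesion frequency, latent nonmetastatic
    cna_coupling: float = 0.8  # expression shift per copy-number call
    n_regulators: int = 20
    out_degree: int = 15
    adjuvant_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_met", "phi_occult", "theta1", "theta0", "f1", "f0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.theta1 > self.theta0:
            raise ValueError("theta1 must exceed theta0")
        if self.hr_true <= 0:
            raise ValueError("hr_true must be positive")
        for name in ("theta1", "theta0"):
            v = getattr(self, name)
            if v <= 0.0 or v >= 1.0:
                raise ValueError(
                    f"{name}={v} is infeasible: no finite mean offset achieves it"
                )
        if self.n_genes < 2 * self.n_pairs + self.n_de + self.n_cna_regions * self.genes_per_region:
            raise ValueError("n_genes too small for signature + DE + CNA blocks")

    @classmethod
    def occult_scenario(cls, seed: int = 0, phi_occult: float = 0.2, **overrides) -> "CohortParams":
        """Parameterization where occult contamination visibly weakens the
        clinical-label DE contrast and reclassification recovers it: high
        latent prevalence, a sharply separating signature (low false-positive
        vote rate), and a moderate planted effect size."""
        base = dict(
            pi_met=0.6,
            theta1=0.90,
            theta0=0.10,
            delta_de=0.4,
            phi_occult=phi_occult,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationMatrix
    cna: CNAMatrix
    region_map: RegionGeneMap
    edges: list[tuple[str, str]]
    gene_sets: GeneSetCollection
    signature: GenePairSignature
    latent_met: pd.Series  # sample_id -> 0/1 ground truth
    planted_de: list[str]
    planted_mut: list[str]
    planted_cna: list[str]
    driver_genes: list[str]
    params: CohortParams


def _pair_offset(theta: float, tau: float) -> float:
    # marginal P(diff > 0) = Phi(offset / sqrt(2 + tau^2))
    return float(ndtri(theta) * math.sqrt(2.0 + tau * tau))


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Generate a full cohort from one master seed (bit-reproducible)."""
    streams = np.random.SeedSequence(params.seed).spawn(6)
    rng_latent, rng_expr, rng_surv, rng_lesion, rng_net, rng_clin = (
        np.random.default_rng(s) for s in streams
    )
    p = params
    samples = [f"S{i:04d}" for i in range(p.n_samples)]
    genes = [f"G{i:04d}" for i in range(p.n_genes)]

    latent = rng_latent.binomial(1, p.pi_met, p.n_samples)
    met = latent.astype(bool)

    # ---- gene blocks
    sig_a = genes[: p.n_pairs]
    sig_b = genes[p.n_pairs : 2 * p.n_pairs]
    signature = GenePairSignature(tuple(zip(sig_a, sig_b)))
    de_start = 2 * p.n_pairs
    planted_de = genes[de_start : de_start + p.n_de]
    cna_start = de_start + p.n_de
    n_cna_genes = p.n_cna_regions * p.genes_per_region
    cna_genes = genes[cna_start : cna_start + n_cna_genes]

    # ---- expression
    base = rng_expr.uniform(5.0, 9.0, size=p.n_genes)
    values = base[:, None] + rng_expr.normal(0.0, 1.0, size=(p.n_genes, p.n_samples))
    gene_idx = {g: i for i, g in enumerate(genes)}

    off1 = _pair_offset(p.theta1, p.pair_tau)
    off0 = _pair_offset(p.theta0, p.pair_tau)
    u = rng_expr.normal(0.0, p.pair_tau, size=p.n_samples)
    d = np.where(met, off1, off0) + u
    for a, b in signature.pairs:
        mu = base[gene_idx[a]]
        values[gene_idx[a]] = mu + d / 2.0 + rng_expr.normal(0.0, 1.0, p.n_samples)
        values[gene_idx[b]] = mu - d / 2.0 + rng_expr.normal(0.0, 1.0, p.n_samples)

    half = len(planted_de) // 2
    for j, g in enumerate(planted_de):
        shift = p.delta_de if j < half or half == 0 else -p.delta_de
        values[gene_idx[g], met] += shift

    # ---- lesions
    mut_genes = [f"MG{i:03d}" for i in range(p.n_mut_lesions)]
    planted_mut = mut_genes[: p.n_planted_mut]
    mut_calls = np.zeros((p.n_mut_lesions, p.n_samples), dtype=int)
    for i, g in enumerate(mut_genes):
        if g in planted_mut:
            probs = np.where(met, p.f1, p.f0)
        else:
            probs = np.full(p.n_samples, p.f0)
        mut_calls[i] = rng_lesion.binomial(1, probs)
    mutations = MutationMatrix(pd.DataFrame(mut_calls, index=mut_genes, columns=samples))

    regions = [f"reg{i:02d}" for i in range(p.n_cna_regions)]
    planted_cna = regions[: p.n_planted_cna]
    region_members: dict[str, tuple[str, ...]] = {}
    cna_calls = np.zeros((p.n_cna_regions, p.n_samples), dtype=int)
    for i, region in enumerate(regions):
        sign = 1 if i % 2 == 0 else -1  # alternate amp / del regions
        if region in planted_cna:
            probs = np.where(met, p.f1, p.f0)
        else:
            probs = np.full(p.n_samples, p.f0)
        cna_calls[i] = sign * rng_lesion.binomial(1, probs)
        members = tuple(
            cna_genes[i * p.genes_per_region : (i + 1) * p.genes_per_region]
        )
        region_members[region] = members
        for g in members:  # copy-number dosage effect on expression
            values[gene_idx[g]] += p.cna_coupling * cna_calls[i]
    cna = CNAMatrix(pd.DataFrame(cna_calls, index=regions, columns=samples))
    region_map = RegionGeneMap(region_members)

    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples)
    )

    # ---- regulatory network with planted drivers
    driver_mut = planted_mut[0] if planted_mut else mut_genes[0]
    driver_cna = region_members[planted_cna[0]][0] if planted_cna else cna_genes[0]
    drivers = [driver_mut, driver_cna]
    other_regs = [f"REG{i:03d}" for i in range(p.n_regulators)]
    edges: list[tuple[str, str]] = []
    de_arr = list(planted_de)
    for drv in drivers:
        k = min(p.out_degree, len(de_arr))
        targets = rng_net.choice(de_arr, size=k, replace=False)
        edges.extend((drv, str(t)) for t in targets)
    pool = [g for g in genes if g not in planted_de]
    for reg in other_regs:
        k = rng_net.integers(1, max(2, p.out_degree // 3))
        targets = rng_net.choice(pool, size=k, replace=False)
        edges.extend((reg, str(t)) for t in targets)
    edges = sorted(set(edges))

    # ---- gene sets: one enriched in planted DE genes plus random sets
    n_set = max(5, len(planted_de) // 4)
    planted_set = tuple(planted_de[:n_set])
    sets = {"planted_set": ("planted DE genes", planted_set)}
    for i in range(4):
        members = tuple(
            str(g) for g in rng_net.choice(genes, size=25, replace=False)
        )
        sets[f"random_set_{i}"] = (f"random set {i}", members)
    gene_sets = GeneSetCollection(sets)

    # ---- clinical table
    stages = rng_clin.choice(
        ["IA", "IB", "II", "III", "IV"], size=p.n_samples, p=[0.3, 0.25, 0.2, 0.15, 0.1]
    )
    occult = rng_clin.random(p.n_samples) < p.phi_occult
    clinical_met = np.where(met & ~occult, "yes", "no")
    age = np.clip(rng_clin.normal(65, 10, p.n_samples).round(1), 30, 95)
    gender = rng_clin.choice(["male", "female"], size=p.n_samples)
    adjuvant = rng_clin.choice(
        ["unknown", "none", "yes"],
        size=p.n_samples,
        p=[0.8 - p.adjuvant_rate, 0.2, p.adjuvant_rate],
    )
    subtype_p_met = [0.2, 0.45, 0.35]  # bronchioid, squamoid, magnoid
    subtype_p_non = [0.6, 0.25, 0.15]
    subtype = np.array(
        [
            rng_clin.choice(
                ["bronchioid", "squamoid", "magnoid"],
                p=subtype_p_met if m else subtype_p_non,
            )
            for m in met
        ]
    )

    hazard = p.baseline_hazard * np.where(met, p.hr_true, 1.0)
    os_t = rng_surv.exponential(1.0 / hazard)
    os_c = rng_surv.uniform(0.0, p.censor_window, p.n_samples)
    os_time = np.minimum(os_t, os_c)
    os_event = (os_t <= os_c).astype(int)
    rfs_haz = 1.5 * hazard
    rfs_t = rng_surv.exponential(1.0 / rfs_haz)
    rfs_c = rng_surv.uniform(0.0, p.censor_window, p.n_samples)
    rfs_time = np.minimum(rfs_t, rfs_c)
    rfs_event = (rfs_t <= rfs_c).astype(int)

    clin_frame = pd.DataFrame(
        {
            "stage": stages,
            "age": age,
            "gender": gender,
            "os_time": np.round(os_time, 3),
            "os_event": os_event,
            "rfs_time": np.round(rfs_time, 3),
            "rfs_event": rfs_event,
            "metastasis_clinical": clinical_met,
            "adjuvant": adjuvant,
            "subtype": subtype,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    return SyntheticCohort(
        expression=expression,
        clinical=ClinicalTable(clin_frame),
        mutations=mutations,
        cna=cna,
        region_map=region_map,
        edges=edges,
        gene_sets=gene_sets,
        signature=signature,
        latent_met=pd.Series(latent, index=samples, name="latent_met"),
        planted_de=list(planted_de),
        planted_mut=list(planted_mut),
        planted_cna=list(planted_cna),
        driver_genes=drivers,
        params=p,
    )


def evaluate_recovery(
    cohort: SyntheticCohort,
    risk_calls: Sequence[RiskCall] | None = None,
    log_hr_estimate: float | None = None,
    de_genes: Sequence | None = None,
    lesion_results: Sequence | None = None,
    driver_target_counts: dict[str, int] | None = None,
    alpha_fdr: float = 0.05,
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    Any argument left as None is skipped in the report.
    """
    report: dict = {"seed": cohort.params.seed}
    latent = cohort.latent_met
    if risk_calls is not None:
        tp = fn = tn = fp = 0
        for call in risk_calls:
            truth = bool(latent.get(call.sample_id, 0))
            high = call.label == "high"
            if truth and high:
                tp += 1
            elif truth:
                fn += 1
            elif high:
                fp += 1
            else:
                tn += 1
        report["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        report["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    if log_hr_estimate is not None:
        report["log_hr_error"] = float(
            log_hr_estimate - math.log(cohort.params.hr_true)
        )
    if de_genes is not None:
        sig = {g.gene_id for g in de_genes if g.fdr < alpha_fdr}
        planted = set(cohort.planted_de)
        report["de_recovery"] = len(sig & planted) / len(planted) if planted else float("nan")
        report["de_significant"] = len(sig)
    if lesion_results is not None:
        sig_lesions = {l.lesion_id.split(":")[0] for l in lesion_results if l.fdr < alpha_fdr}
        planted = set(cohort.planted_mut) | set(cohort.planted_cna)
        report["lesion_recovery"] = (
            len(sig_lesions & planted) / len(planted) if planted else float("nan")
        )
    if driver_target_counts is not None and driver_target_counts:
        ranked = sorted(driver_target_counts, key=driver_target_counts.get, reverse=True)
        ranks = [ranked.index(d) + 1 for d in cohort.driver_genes if d in ranked]
        report["best_driver_rank"] = min(ranks) if ranks else None
    return report


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, str]:
    """Write every cohort layer in the standard dialects; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "mutations": out / "mutations.tsv",
        "cna": out / "cna.tsv",
        "region_map": out / "region_map.tsv",
        "edges": out / "edges.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "signature": out / "signature.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_mutation_matrix(cohort.mutations, paths["mutations"])
    write_cna_matrix(cohort.cna, paths["cna"])
    write_region_map(cohort.region_map, paths["region_map"])
    write_network(cohort.edges, paths["edges"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    write_signature(cohort.signature, paths["signature"])
    truth = pd.DataFrame({"latent_met": cohort.latent_met})
    truth.to_csv(paths["ground_truth"], sep="\t", index_label="sample_id")
    return {k: str(v) for k, v in paths.items()}
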