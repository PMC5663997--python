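"""End-to-end orchestration: classify -> associate -> survival ->
reclassify -> differential expression -> lesions -> driver network.

``run_pipeline`` executes whichever stages its config provides inputs for,
writes every stage output as TSV/JSON under the output directory, and
finishes with a manifest (inputs, thresholds, seed, parameter hash) from
which any number in the bundle can be reproduced.  Stage failures halt the
run with the stage name in the error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import diffexpr, io_formats, lesions, network, reclassification, survival
from .reo_classifier import (
    VotingRule,
    calibrate_threshold,
    calls_to_frame,
    classify,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]

DEFAULTS = {
    "cv_threshold": 0.10,
    "fdr": 0.05,
    "prevalence": 0.05,
    "horizon": 60.0,
    "min_evaluable": 6,
    "endpoint": "os",
    "seed": 0,
}


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _resolve_rule(config: dict, expr, sig, min_evaluable: int):
    spec = config.get("rule", "majority")
    if isinstance(spec, dict) and "calibrate" in spec:
        cal = spec["calibrate"]
        report = calibrate_threshold(
            expr,
            sig,
            candidate_ks=cal.get("ks", range(6, sig.n_pairs + 1)),
            target_interval=tuple(cal.get("interval", (0.35, 0.50))),
            min_evaluable=min_evaluable,
        )
        return VotingRule.strict(report.selected_k, sig.n_pairs), report
    if spec == "majority":
        return VotingRule.majority(sig.n_pairs), None
    if isinstance(spec, dict):
        return VotingRule.strict(int(spec["k"]), int(spec.get("n", sig.n_pairs))), None
    if isinstance(spec, str) and ":" in spec:  # "7:9" / "k:of:n"
        parts = [p for p in spec.split(":") if p.isdigit()]
        return VotingRule.strict(int(parts[0]), int(parts[-1])), None
    raise ValueError(f"unrecognized rule spec {spec!r}")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage the config supplies inputs for; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULTS, **config}
    inputs = cfg.get("inputs", {})
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "thresholds": {
            k: cfg[k] for k in ("cv_threshold", "fdr", "prevalence", "horizon", "min_evaluable")
        },
        "seed": cfg["seed"],
        "inputs": dict(inputs),
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        def deco(fn):
            t0 = time.monotonic()
            try:
                result = fn()
            except Exception as err:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(name, err) from err
            manifest["stages"][name] = round(time.monotonic() - t0, 3)
            logger.info("stage %s done in %.2fs", name, manifest["stages"][name])
            return result

        return deco

    @stage("load")
    def loaded():
        expr = io_formats.read_expression(inputs["expression"])
        clin = io_formats.read_clinical(inputs["clinical"])
        sig = io_formats.read_signature(inputs["signature"])
        return expr, clin, sig

    expr, clin, sig = loaded

    @stage("classify")
    def called():
        rule, cal = _resolve_rule(cfg, expr, sig, cfg["min_evaluable"])
        calls = classify(expr, sig, rule, cfg["min_evaluable"])
        frame = calls_to_frame(calls)
        frame.to_csv(out / "calls.tsv", sep="\t", index=False)
        manifest["outputs"]["calls"] = "calls.tsv"
        manifest["rule"] = {"k": rule.min_low_votes, "n": rule.n, "name": rule.name}
        if cal is not None:
            _dump_json(
                {"fractions": cal.fractions, "selected_k": cal.selected_k,
                 "target_interval": list(cal.target_interval)},
                out / "calibration.json",
            )
            manifest["outputs"]["calibration"] = "calibration.json"
        return calls

    calls = called

    @stage("associate")
    def assoc():
        cf = clin.frame
        ids = [c.sample_id for c in calls if c.sample_id in cf.index
               and pd.notna(cf.loc[c.sample_id].get("metastasis_clinical"))]
        label_of = {c.sample_id: c.label for c in calls}
        high = [label_of[s] == "high" for s in ids]
        met = [cf.loc[s, "metastasis_clinical"] == "yes" for s in ids]
        table = reclassification.fisher_association(high, met, sidedness="two")
        _dump_json(table.to_dict(), out / "association.json")
        manifest["outputs"]["association"] = "association.json"
        return table

    _ = assoc

    endpoint = cfg["endpoint"]
    surv_frame = survival.survival_frame(clin, calls, endpoint=endpoint)
    if not surv_frame.empty and surv_frame["event"].sum() > 0 and surv_frame["group"].nunique() == 2:

        @stage("survival")
        def surv():
            comparison = survival.compare_groups(surv_frame, horizon=cfg["horizon"])
            _dump_json(comparison.to_dict(), out / f"survival_{endpoint}.json")
            rows = []
            for grp, curve in comparison.km_curves.items():
                for t, s, r in zip(curve.times, curve.survival, curve.n_at_risk):
                    rows.append({"group": grp, "time": t, "at_risk": int(r), "survival": s})
            pd.DataFrame(rows).to_csv(out / f"km_{endpoint}.tsv", sep="\t", index=False)
            manifest["outputs"]["survival"] = f"survival_{endpoint}.json"
            manifest["outputs"]["km"] = f"km_{endpoint}.tsv"
            return comparison

        _ = surv

    @stage("reclassify")
    def relabelled():
        labels = reclassification.reclassify(clin, calls)
        labels.to_frame().to_csv(out / "labels.tsv", sep="\t", index=False)
        manifest["outputs"]["labels"] = "labels.tsv"
        return labels

    labels = relabelled

    @stage("differential_expression")
    def de_stage():
        tested = diffexpr.cv_filter(expr, cfg["cv_threshold"])
        cf = clin.frame
        with_status = [s for s in expr.sample_ids
                       if s in cf.index and pd.notna(cf.loc[s].get("metastasis_clinical"))]
        clin_met = [s for s in with_status if cf.loc[s, "metastasis_clinical"] == "yes"]
        clin_non = [s for s in with_status if cf.loc[s, "metastasis_clinical"] == "no"]
        de_clin = diffexpr.de_test(expr, clin_met, clin_non, cfg["fdr"], genes=tested)
        de_recl = diffexpr.de_test(
            expr, labels.metastatic_ids, labels.nonmetastatic_ids, cfg["fdr"], genes=tested
        )
        sig_clin = diffexpr.significant(de_clin, cfg["fdr"])
        sig_recl = diffexpr.significant(de_recl, cfg["fdr"])
        conc = diffexpr.direction_concordance(sig_clin, sig_recl)
        for name, de in (("de_clinical", sig_clin), ("de_reclassified", sig_recl)):
            pd.DataFrame([asdict(g) for g in de]).to_csv(out / f"{name}.tsv", sep="\t", index=False)
            manifest["outputs"][name] = f"{name}.tsv"
        _dump_json(
            {
                "n_de_clinical": len(sig_clin),
                "n_de_reclassified": len(sig_recl),
                "overlap": conc.overlap_count,
                "same_direction": conc.same_direction_count,
                "fraction": conc.fraction,
                "binomial_p": conc.binomial_p,
            },
            out / "concordance.json",
        )
        manifest["outputs"]["concordance"] = "concordance.json"
        enrichment = None
        if "gene_sets" in inputs:
            sets = io_formats.read_gmt(inputs["gene_sets"])
            enrichment = diffexpr.enrich([g.gene_id for g in sig_recl], sets, tested)
            pd.DataFrame([asdict(e) for e in enrichment]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
            manifest["outputs"]["enrichment"] = "enrichment.tsv"
        return tested, sig_recl

    tested_genes, sig_recl = de_stage

    lesion_results: list = []
    corr: list = []
    region_map = (
        io_formats.read_region_map(inputs["region_map"])
        if "region_map" in inputs
        else io_formats.RegionGeneMap(members={})
    )
    if "maf" in inputs or "cna" in inputs:

        @stage("lesions")
        def lesion_stage():
            results = []
            met_ids, non_ids = labels.metastatic_ids, labels.nonmetastatic_ids
            if "maf" in inputs:
                muts = io_formats.read_maf(inputs["maf"])
                mres = lesions.lesion_tests(
                    muts, met_ids, non_ids, family="mutation",
                    min_prevalence=cfg["prevalence"],
                )
                results.extend(mres)
                burden = lesions.burden_compare(muts, met_ids, non_ids)
                _dump_json(
                    {"median_met": burden.median_met, "median_nonmet": burden.median_nonmet,
                     "t_stat": burden.t_stat, "p": burden.p},
                    out / "burden_mutation.json",
                )
                manifest["outputs"]["burden_mutation"] = "burden_mutation.json"
            local_corr = []
            if "cna" in inputs:
                cna = io_formats.read_gistic(inputs["cna"])
                binary, _ = lesions.binarize_cna(cna)
                results.extend(
                    lesions.lesion_tests(
                        binary, met_ids, non_ids, family="cna",
                        min_prevalence=cfg["prevalence"],
                    )
                )
                local_corr = lesions.expr_cna_correlation(expr, cna, region_map)
                pd.DataFrame([asdict(c) for c in local_corr]).to_csv(
                    out / "expr_cna_corr.tsv", sep="\t", index=False
                )
                manifest["outputs"]["expr_cna_corr"] = "expr_cna_corr.tsv"
            pd.DataFrame([asdict(l) for l in results]).to_csv(
                out / "lesions.tsv", sep="\t", index=False
            )
            manifest["outputs"]["lesions"] = "lesions.tsv"
            return results, local_corr

        lesion_results, corr = lesion_stage

    if "edges" in inputs and lesion_results:

        @stage("network")
        def net_stage():
            edges = io_formats.read_network(inputs["edges"])
            regulators = {a for a, _ in edges}
            drivers = network.select_drivers(
                lesion_results, region_map, corr, regulators, alpha_fdr=cfg["fdr"]
            )
            net = network.build_network(drivers, sig_recl, edges)
            hop2 = network.two_hop_targets(drivers, sig_recl, edges)
            io_formats.write_network(net.edges, out / "network.tsv")
            report = {
                "drivers": [asdict(d) for d in drivers.drivers],
                "direct_targets": {d: sorted(t) for d, t in net.direct_targets.items()},
                "two_hop_targets": {d: sorted(t) for d, t in hop2.items()},
            }
            if "gene_sets" in inputs:
                sets = io_formats.read_gmt(inputs["gene_sets"])
                enr = network.per_driver_enrichment(net, sets, tested_genes)
                report["enrichment"] = {
                    d: [asdict(e) for e in res] for d, res in enr.items()
                }
            _dump_json(report, out / "driver_report.json")
            manifest["outputs"]["network"] = "network.tsv"
            manifest["outputs"]["driver_report"] = "driver_report.json"
            return net

        _ = net_stage

    _dump_json(manifest, out / "manifest.json")
    return manifest
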