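"""Driver selection and the directed regulator->target subnetwork linking
driver lesions to differentially expressed genes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .diffexpr import DEGene, EnrichmentResult, enrich
from .io_formats import GeneSetCollection, RegionGeneMap
from .lesions import HIGHER_IN_MET, ExprCnaCorrelation, LesionTest

logger = logging.getLogger(__name__)

__all__ = [
    "DriverGene",
    "DriverSet",
    "DriverNetwork",
    "select_drivers",
    "build_network",
    "two_hop_targets",
    "per_driver_enrichment",
]


@dataclass(frozen=True)
class DriverGene:
    gene_id: str
    provenance: str  # mutated | amplified | deleted
    source_lesion: str


@dataclass
class DriverSet:
    lesions: list[LesionTest]
    drivers: list[DriverGene]

    @property
    def driver_genes(self) -> list[str]:
        return [d.gene_id for d in self.drivers]


@dataclass
class DriverNetwork:
    edges: list[tuple[str, str]]
    direct_targets: dict[str, set[str]]
    two_hop: dict[str, set[str]] = field(default_factory=dict)


_PROVENANCE = {"mutation": "mutated", "amplification": "amplified", "deletion": "deleted"}


def select_drivers(
    lesion_results: Sequence[LesionTest],
    region_map: RegionGeneMap,
    correlations: Sequence[ExprCnaCorrelation],
    network_regulators: Iterable[str],
    alpha_fdr: float = 0.05,
) -> DriverSet:
    """Map qualifying lesions (significant, enriched in the metastatic
    group) to candidate driver genes.

    Mutated-gene lesions contribute the gene itself.  CNA lesions contribute
    member genes that are regulators in the network and whose expression is
    significantly positively coupled to the copy-number call.
    """
    regulators = set(network_regulators)
    pos_corr = {c.gene_id for c in correlations if c.positive_significant}
    qualifying = [
        l for l in lesion_results if l.fdr < alpha_fdr and l.direction == HIGHER_IN_MET
    ]
    drivers: dict[tuple[str, str], DriverGene] = {}
    for lesion in qualifying:
        if lesion.lesion_type == "mutation":
            drivers.setdefault(
                (lesion.lesion_id, "mutated"),
                DriverGene(lesion.lesion_id, "mutated", lesion.lesion_id),
            )
            continue
        region = lesion.lesion_id.rsplit(":", 1)[0]
        members = region_map.genes_for(region)
        if not members:
            logger.warning("region %s has no mapped genes", region)
            continue
        prov = _PROVENANCE.get(lesion.lesion_type, lesion.lesion_type)
        for gene in members:
            if gene in regulators and gene in pos_corr:
                drivers.setdefault(
                    (gene, prov), DriverGene(gene, prov, lesion.lesion_id)
                )
    return DriverSet(lesions=qualifying, drivers=list(drivers.values()))


def build_network(
    drivers: DriverSet | Sequence[str],
    de_genes: Sequence[DEGene] | Sequence[str],
    edges: Sequence[tuple[str, str]],
) -> DriverNetwork:
    """Keep the input edges whose source is a driver and whose target is a
    DE gene; no edges are inferred."""
    driver_ids = (
        set(drivers.driver_genes) if isinstance(drivers, DriverSet) else set(drivers)
    )
    de_ids = {g.gene_id if isinstance(g, DEGene) else str(g) for g in de_genes}
    kept = [
        (a, b) for a, b in edges if a in driver_ids and b in de_ids and a != b
    ]
    direct: dict[str, set[str]] = {d: set() for d in driver_ids}
    for a, b in kept:
        direct[a].add(b)
    return DriverNetwork(edges=sorted(set(kept)), direct_targets=direct)


def two_hop_targets(
    drivers: DriverSet | Sequence[str],
    de_genes: Sequence[DEGene] | Sequence[str],
    edges: Sequence[tuple[str, str]],
    intermediates: str = "any",
) -> dict[str, set[str]]:
    """DE genes reachable from each driver in exactly two directed steps,
    excluding its direct targets and the driver itself.

    ``intermediates='driver'`` restricts the middle node to driver genes.
    """
    if intermediates not in ("any", "driver"):
        raise ValueError(f"unknown intermediates mode {intermediates!r}")
    driver_ids = (
        set(drivers.driver_genes) if isinstance(drivers, DriverSet) else set(drivers)
    )
    de_ids = {g.gene_id if isinstance(g, DEGene) else str(g) for g in de_genes}
    graph = nx.DiGraph()
    graph.add_edges_from(edges)
    out: dict[str, set[str]] = {}
    for d in driver_ids:
        direct = set(graph.successors(d)) if d in graph else set()
        hop2: set[str] = set()
        for mid in direct:
            if intermediates == "driver" and mid not in driver_ids:
                continue
            if mid in graph:
                hop2.update(graph.successors(mid))
        out[d] = (hop2 & de_ids) - direct - {d}
    return out


def per_driver_enrichment(
    network: DriverNetwork,
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> dict[str, list[EnrichmentResult]]:
    """Hypergeometric enrichment of each driver's direct target set."""
    out = {}
    for driver, targets in network.direct_targets.items():
        if not targets:
            logger.info("driver %s has no direct DE targets; skipped", driver)
            continue
        out[driver] = enrich(targets, sets, universe)
    return out
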