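"""Loaders for the packaged worked-example fixtures.

Two fully worked compounds ship with the package: akaeolide (whose carbon
skeleton contains one post-assembly C-C bond, C16-C17) and lorneic acid A
(a linear assignment).  Each comes as a cluster description, the published
per-carbon enrichment table, and the compound's carbon bond graph.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

from .cluster import ClusterSpec, DomainSpec, ModuleSpec, read_cluster
from .labeling import read_enrichment_tables
from .tiling import CarbonGraph, read_graph

#: designated unlabeled reference carbon per compound
REFERENCE_POSITIONS = {"akaeolide": 2, "lorneic": 16}


def _data_path(name: str):
    return resources.files("pksline").joinpath("data", name)


def akaeolide_cluster() -> ClusterSpec:
    with resources.as_file(_data_path("akaeolide_cluster.yaml")) as path:
        return read_cluster(path)


def lorneic_cluster(m4_er_active: bool = True) -> ClusterSpec:
    """Lorneic acid cluster; ``m4_er_active=False`` gives the polyolefinic
    intermediate scenario in which module 4's ER does not act."""
    with resources.as_file(_data_path("lorneic_cluster.yaml")) as path:
        cluster = read_cluster(path)
    if m4_er_active:
        return cluster
    modules = []
    for m in cluster.modules:
        if m.index == 4:
            domains = [
                replace(d, active=False) if d.kind == "ER" else d
                for d in m.domains
            ]
            m = ModuleSpec(index=m.index, loading=m.loading, domains=domains)
        modules.append(m)
    return ClusterSpec(
        id=cluster.id, modules=modules, compound_hint=cluster.compound_hint
    )


def akaeolide_enrichment() -> dict:
    """Experiment -> EnrichmentTable for 17-chloroakaeolide (22 carbons)."""
    with resources.as_file(_data_path("akaeolide_table1.csv")) as path:
        return read_enrichment_tables(
            path, reference=REFERENCE_POSITIONS["akaeolide"],
            compound="17-chloroakaeolide",
        )


def lorneic_enrichment() -> dict:
    """Experiment -> EnrichmentTable for lorneic acid A (17 carbons)."""
    with resources.as_file(_data_path("lorneic_table1.csv")) as path:
        return read_enrichment_tables(
            path, reference=REFERENCE_POSITIONS["lorneic"],
            compound="lorneic acid A",
        )


def akaeolide_graph() -> CarbonGraph:
    with resources.as_file(_data_path("akaeolide_graph.yaml")) as path:
        return read_graph(path)


def lorneic_graph() -> CarbonGraph:
    with resources.as_file(_data_path("lorneic_graph.yaml")) as path:
        return read_graph(path)
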