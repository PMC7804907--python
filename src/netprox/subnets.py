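"""Annotated subnetwork views: EGO, LCC, and mechanism-of-action (MOA).

The three views differ only by their node-inclusion rule; all are induced
subgraphs of the source interactome, so every interactome edge between two
retained nodes is present with its evidence labels.

* EGO — the radius-r neighborhood of a center gene, restricted to
  brain-expressed genes (optionally further to genes with positive brain
  specificity, z_E(gene, brain) > 0).
* LCC — the largest connected component of the subgraph induced by a
  disease module.
* MOA — the subgraph induced by a drug's targets plus a disease module,
  showing the interactions through which the drug may perturb the module.

Nodes carry a role (center/target/module/neighbor/both), a ``targetable``
flag (the gene is targeted by at least one drug in the curated table), and
the gene's brain-specificity score when available.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graphio import DrugTargetSet, GeneSet, Interactome, normalize_symbol

EGO_RADIUS_DEFAULT = 1


@dataclass
class AnnotatedSubnetwork:
    """A node/edge view ready for export, with annotations for viewers."""

    view_kind: str  # EGO | LCC | MOA
    graph: nx.Graph
    center: str | None = None  # EGO
    drug_id: str | None = None  # MOA
    set_id: str | None = None  # LCC / MOA

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> set[tuple[str, str]]:
        return {(min(a, b), max(a, b)) for a, b in self.graph.edges}


def _annotate_nodes(
    g: nx.Graph,
    roles: dict[str, str],
    targetable_genes: set[str] | None,
    brain_z=None,
) -> None:
    zlookup = {}
    if brain_z is not None:
        zlookup = brain_z if isinstance(brain_z, dict) else dict(brain_z)
    for node in g.nodes:
        g.nodes[node]["role"] = roles.get(node, "neighbor")
        g.nodes[node]["targetable"] = bool(targetable_genes and node in targetable_genes)
        g.nodes[node]["brain_z"] = (
            float(zlookup[node]) if node in zlookup else None
        )
        g.nodes[node]["isolated"] = g.degree[node] == 0


def ego_view(
    graph: Interactome,
    center: str,
    radius: int = EGO_RADIUS_DEFAULT,
    brain_expressed: set[str] | None = None,
    brain_z=None,
    specificity_filter: bool = False,
    targetable_genes: set[str] | None = None,
) -> AnnotatedSubnetwork:
    """Brain-filtered ego neighborhood of *center*.

    The induced subgraph on all nodes within *radius* hops of the center,
    intersected with ``brain_expressed`` (when given); with
    ``specificity_filter`` on, further restricted to nodes with positive
    brain specificity (brain_z > 0).  The center is always retained, but a
    center that is not brain-expressed is refused outright — the view exists
    only for genes expressed in brain.
    """
    center = normalize_symbol(center)
    if center not in graph:
        raise ValueError(f"center gene {center!r} is not in the interactome")
    if brain_expressed is not None and center not in brain_expressed:
        raise ValueError(
            f"center gene {center!r} is not expressed in brain; "
            "EGO views are generated only for brain-expressed genes"
        )
    ball = set(nx.ego_graph(graph.g, center, radius=radius).nodes)
    keep = ball if brain_expressed is None else (ball & set(brain_expressed)) | {center}
    if specificity_filter:
        if brain_z is None:
            raise ValueError("specificity_filter requires brain_z scores")
        zlookup = brain_z if isinstance(brain_z, dict) else dict(brain_z)
        keep = {n for n in keep if zlookup.get(n, 0.0) > 0} | {center}
    sub = graph.g.subgraph(keep).copy()
    roles = {n: "neighbor" for n in sub.nodes}
    roles[center] = "center"
    _annotate_nodes(sub, roles, targetable_genes, brain_z)
    return AnnotatedSubnetwork("EGO", sub, center=center)


def lcc_view(
    graph: Interactome,
    module: GeneSet,
    targetable_genes: set[str] | None = None,
    brain_z=None,
) -> AnnotatedSubnetwork:
    """Largest connected component of the subgraph induced by a module.

    Component-size ties break toward the component containing the
    lexicographically smallest gene, for determinism.
    """
    in_graph = graph.restrict(module.genes)
    if not in_graph:
        raise ValueError(f"no gene of module {module.set_id!r} maps into the interactome")
    induced = graph.g.subgraph(in_graph)
    comps = sorted(nx.connected_components(induced), key=lambda c: (-len(c), min(c)))
    sub = induced.subgraph(comps[0]).copy()
    roles = {n: "module" for n in sub.nodes}
    _annotate_nodes(sub, roles, targetable_genes, brain_z)
    return AnnotatedSubnetwork("LCC", sub, set_id=module.set_id)


def moa_view(
    graph: Interactome,
    drug: DrugTargetSet,
    module: GeneSet,
    prune_isolated: bool = False,
    targetable_genes: set[str] | None = None,
    brain_z=None,
) -> AnnotatedSubnetwork:
    """Mechanism-of-action view for a (drug, module) pair.

    Node set = (targets in graph) | (module genes in graph); edge set = every
    interactome edge with both endpoints retained.  Roles partition into
    target / module / both; isolated nodes are kept (and flagged) unless
    ``prune_isolated`` is set.
    """
    targets_in = graph.restrict(drug.targets)
    module_in = graph.restrict(module.genes)
    keep = targets_in | module_in
    if not keep:
        raise ValueError(
            f"no target of {drug.drug_id!r} and no gene of {module.set_id!r} "
            "maps into the interactome"
        )
    sub = graph.g.subgraph(keep).copy()
    roles = {}
    for n in sub.nodes:
        if n in targets_in and n in module_in:
            roles[n] = "both"
        elif n in targets_in:
            roles[n] = "target"
        else:
            roles[n] = "module"
    _annotate_nodes(sub, roles, targetable_genes, brain_z)
    if prune_isolated:
        isolated = [n for n in sub.nodes if sub.degree[n] == 0]
        sub.remove_nodes_from(isolated)
        if sub.number_of_nodes() == 0:
            raise ValueError("pruning isolated nodes emptied the MOA view")
    return AnnotatedSubnetwork("MOA", sub, drug_id=drug.drug_id, set_id=module.set_id)
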