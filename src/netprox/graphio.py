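"""Interactome and gene-set I/O.

The interactome is an undirected, evidence-typed graph of gene symbols.
It is the universe for every shortest-path distance and every
degree-preserving permutation in the proximity screen.  Gene symbols are
upper-cased and whitespace-stripped on ingest so that identifiers coming
from different tables compare equal; genes referenced by a gene set or a
drug-target set but absent from the graph are never added to it — they are
tracked as unmapped by the callers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

log = logging.getLogger(__name__)

#: Evidence classes for physical protein-protein interactions: interfaces from
#: 3D structures, binary yeast-two-hybrid interactions, kinase-substrate
#: pairs, signaling interactions, and literature-curated interactions.
#: The enumeration is open: pass ``allowed_evidence`` to the loader to accept
#: other labels so non-default interactomes load without code changes.
DEFAULT_EVIDENCE_TYPES = frozenset(
    {"structure3D", "Y2H", "kinase_substrate", "signaling", "literature"}
)

VIEW_KINDS = ("EGO", "LCC", "MOA")


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped and upper-cased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A disease module or dataset gene list (the B of the proximity measure)."""

    set_id: str
    description: str
    genes: frozenset[str]
    source_kind: str = "other"  # expression | literature | other

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        object.__setattr__(self, "genes", frozenset(normalize_symbol(g) for g in self.genes))


@dataclass(frozen=True)
class DrugTargetSet:
    """A drug and its curated human targets (the A of the proximity measure)."""

    drug_id: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"drug {self.drug_id!r} has no targets")
        object.__setattr__(
            self, "targets", frozenset(normalize_symbol(g) for g in self.targets)
        )


class Interactome:
    """Undirected evidence-typed PPI graph.

    Wraps a :class:`networkx.Graph` whose edges carry an ``evidence``
    attribute holding a frozenset of evidence-type labels.  Self-loops are
    never stored; symmetric duplicates are merged with their evidence labels
    unioned.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.g = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------------

    def add_edge(self, a: str, b: str, evidence: str | set[str] = "literature") -> bool:
        """Add an undirected edge; returns False (and skips) for self-loops."""
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            return False
        labels = {evidence} if isinstance(evidence, str) else set(evidence)
        if self.g.has_edge(a, b):
            merged = set(self.g.edges[a, b]["evidence"]) | labels
            self.g.edges[a, b]["evidence"] = frozenset(merged)
        else:
            self.g.add_edge(a, b, evidence=frozenset(labels))
        return True

    # -- queries -------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.g.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.g

    def number_of_nodes(self) -> int:
        return self.g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.g.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.g.degree[gene]

    def neighbors(self, gene: str) -> set[str]:
        return set(self.g.neighbors(gene))

    def evidence(self, a: str, b: str) -> frozenset[str]:
        return self.g.edges[a, b]["evidence"]

    def restrict(self, genes) -> set[str]:
        """The subset of *genes* present in the graph."""
        return {g for g in (normalize_symbol(x) for x in genes) if g in self.g}

    def largest_connected_component(self) -> "Interactome":
        """New interactome restricted to the largest connected component.

        Ties on component size break toward the component containing the
        lexicographically smallest gene, for determinism.
        """
        comps = sorted(
            nx.connected_components(self.g), key=lambda c: (-len(c), min(c))
        )
        return Interactome(self.g.subgraph(comps[0]).copy())

    def check_invariants(self) -> None:
        """Assert structural invariants (no self-loops, handshake lemma)."""
        assert nx.number_of_selfloops(self.g) == 0, "self-loop present"
        degsum = sum(d for _, d in self.g.degree())
        assert degsum == 2 * self.g.number_of_edges(), "handshake lemma violated"


@dataclass
class LoadReport:
    """Per-load bookkeeping: what was read, merged, and rejected."""

    n_rows: int = 0
    n_self_loops: int = 0
    n_duplicates: int = 0
    n_rejected_evidence: int = 0
    rejected_lines: list[int] = field(default_factory=list)


def load_interactome(
    path,
    allowed_evidence: frozenset[str] | set[str] = DEFAULT_EVIDENCE_TYPES,
    restrict_to_lcc: bool = False,
) -> Interactome:
    """Load an interactome from an edge-list TSV (gene_a, gene_b[, evidence]).

    Rows whose evidence label is not in ``allowed_evidence`` are rejected and
    counted in the log; the evidence column defaults to ``"literature"`` when
    absent.  Self-loops are dropped with a warning; symmetric duplicates are
    merged with evidence labels unioned.  By default the full graph is used as
    the proximity universe; pass ``restrict_to_lcc=True`` to keep only its
    largest connected component.

    Raises
    ------
    ValueError
        On a malformed row (fewer than two columns), naming the line number,
        or if the resulting graph is empty.
    """
    path = Path(path)
    allowed = frozenset(allowed_evidence)
    inter = Interactome()
    report = LoadReport()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}")
            a, b = fields[0], fields[1]
            evidence = fields[2].strip() if len(fields) >= 3 and fields[2].strip() else "literature"
            report.n_rows += 1
            if evidence not in allowed:
                report.n_rejected_evidence += 1
                report.rejected_lines.append(lineno)
                continue
            na, nb = normalize_symbol(a), normalize_symbol(b)
            if na == nb:
                report.n_self_loops += 1
                log.warning("%s:%d: self-loop %s-%s dropped", path, lineno, a, b)
                continue
            if inter.g.has_edge(na, nb):
                report.n_duplicates += 1
            inter.add_edge(na, nb, evidence)
    if report.n_rejected_evidence:
        log.warning(
            "%s: rejected %d row(s) with unknown evidence labels (lines %s)",
            path,
            report.n_rejected_evidence,
            report.rejected_lines[:20],
        )
    if inter.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty graph after loading")
    inter.check_invariants()
    inter.load_report = report
    if restrict_to_lcc:
        inter = inter.largest_connected_component()
        inter.load_report = report
    return inter


def load_gene_sets(path, source_kind: str = "other") -> list[GeneSet]:
    """Load gene sets from a GMT file (set_id <TAB> description <TAB> gene ...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs set_id, description, >=1 gene")
            genes = frozenset(g for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} has no genes")
            sets.append(GeneSet(fields[0], fields[1], genes, source_kind=source_kind))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    with Path(path).open("w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.genes)]) + "\n")


# -- annotated view export ---------------------------------------------------
#
# JSON graph dialect (documented schema, consumed by downstream viewers):
# {
#   "view_kind": "EGO" | "LCC" | "MOA",
#   "center": str | null,          # EGO only
#   "drug_id": str | null,         # MOA only
#   "set_id": str | null,          # LCC / MOA
#   "nodes": [{"id": str, "role": str, "targetable": bool,
#              "brain_z": float | null, "isolated": bool}],
#   "edges": [{"source": str, "target": str, "evidence": [str, ...]}]
# }


def write_graph(view, path, format: str = "graphml") -> None:
    """Write an annotated subnetwork view to GraphML or the JSON dialect above.

    Refuses empty views: a view with no nodes carries no information and is
    treated as an upstream error rather than silently producing an empty file.
    """
    g = view.graph
    if g.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty view")
    path = Path(path)
    if format == "graphml":
        out = nx.Graph()
        out.graph["view_kind"] = view.view_kind
        for meta in ("center", "drug_id", "set_id"):
            val = getattr(view, meta, None)
            if val is not None:
                out.graph[meta] = val
        for n, attrs in sorted(g.nodes(data=True)):
            flat = dict(attrs)
            if flat.get("brain_z") is None:
                flat.pop("brain_z", None)
            out.add_node(n, **flat)
        for a, b, attrs in sorted(g.edges(data=True)):
            out.add_edge(a, b, evidence="|".join(sorted(attrs.get("evidence", ()))))
        nx.write_graphml(out, path)
    elif format == "json":
        payload = {
            "view_kind": view.view_kind,
            "center": getattr(view, "center", None),
            "drug_id": getattr(view, "drug_id", None),
            "set_id": getattr(view, "set_id", None),
            "nodes": [
                {
                    "id": n,
                    "role": attrs.get("role", "module"),
                    "targetable": bool(attrs.get("targetable", False)),
                    "brain_z": attrs.get("brain_z"),
                    "isolated": bool(attrs.get("isolated", False)),
                }
                for n, attrs in sorted(g.nodes(data=True))
            ],
            "edges": [
                {
                    "source": a,
                    "target": b,
                    "evidence": sorted(attrs.get("evidence", ())),
                }
                for a, b, attrs in sorted(
                    ((min(a, b), max(a, b), d) for a, b, d in g.edges(data=True))
                )
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (use 'graphml' or 'json')")


def read_graph_json(path):
    """Read a view written by :func:`write_graph` (JSON dialect) back.

    Returns an :class:`~netprox.subnets.AnnotatedSubnetwork`; used for
    round-trip validation and by downstream consumers of exported views.
    """
    from .subnets import AnnotatedSubnetwork  # local import: avoid cycle

    payload = json.loads(Path(path).read_text())
    g = nx.Graph()
    for node in payload["nodes"]:
        g.add_node(
            node["id"],
            role=node["role"],
            targetable=node["targetable"],
            brain_z=node["brain_z"],
            isolated=node["isolated"],
        )
    for edge in payload["edges"]:
        g.add_edge(edge["source"], edge["target"], evidence=frozenset(edge["evidence"]))
    return AnnotatedSubnetwork(
        view_kind=payload["view_kind"],
        graph=g,
        center=payload.get("center"),
        drug_id=payload.get("drug_id"),
        set_id=payload.get("set_id"),
    )
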