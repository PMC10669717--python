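"""Disease protein–protein interaction network construction.

The disease network is the subgraph of a reference interaction catalogue
(SIF or two-column TSV edge list) induced on the mined protein list.
Graphs are undirected and simple: self-loops and duplicate edges are
dropped at load, and each edge is stored once with its endpoints in
lexicographic order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "InteractionEdge",
    "ProteinNetwork",
    "CatalogueReport",
    "load_edge_catalogue",
    "induce_disease_network",
    "network_summary",
    "read_sif_network",
    "write_sif",
]


@dataclass(frozen=True)
class InteractionEdge:
    """One undirected interaction, canonicalized so ``a <= b``."""

    a: str
    b: str
    source: str = ""
    weight: float | None = None

    @staticmethod
    def make(a: str, b: str, source: str = "", weight: float | None = None):
        a, b = a.strip().upper(), b.strip().upper()
        if a == b:
            raise ValueError("self-loop")
        if b < a:
            a, b = b, a
        return InteractionEdge(a, b, source, weight)


@dataclass
class CatalogueReport:
    edges: list[InteractionEdge]
    n_lines: int
    n_self_loops: int
    n_duplicates: int


class ProteinNetwork:
    """Undirected simple graph of protein symbols, backed by networkx."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(
        cls, edges: Iterable[InteractionEdge], extra_nodes: Iterable[str] = ()
    ) -> "ProteinNetwork":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for e in edges:
            g.add_edge(e.a, e.b, source=e.source, weight=e.weight)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def adjacency(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProteinNetwork)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


def load_edge_catalogue(path: str | Path, format: str = "auto") -> CatalogueReport:
    """Load a reference interaction catalogue.

    ``format`` is "sif" (``nodeA<TAB>interaction<TAB>nodeB``), "tsv"
    (two whitespace-separated columns), or "auto" (sniffed from the column
    count of the first data line).  Self-loops and exact duplicate edges
    are removed and counted.  An unparseable line raises with its number;
    unknown SIF interaction types are accepted and recorded in ``source``.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    fmt = format
    if fmt == "auto":
        fmt = "tsv"
        for line in lines:
            if line.strip() and not line.startswith("#"):
                fmt = "sif" if len(line.split()) >= 3 else "tsv"
                break
    seen: set[tuple[str, str]] = set()
    edges: list[InteractionEdge] = []
    n_self = n_dup = n_lines = 0
    for i, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        n_lines += 1
        parts = line.split()
        try:
            if fmt == "sif":
                if len(parts) == 1:  # isolated node, no edge
                    continue
                if len(parts) < 3:
                    raise ValueError("SIF line needs >= 3 columns")
                a, rel, bs = parts[0], parts[1], parts[2:]
            else:
                if len(parts) != 2:
                    raise ValueError("TSV edge line needs exactly 2 columns")
                a, rel, bs = parts[0], "", parts[1:]
            for b in bs:
                try:
                    e = InteractionEdge.make(a, b, source=rel)
                except ValueError:
                    n_self += 1
                    continue
                key = (e.a, e.b)
                if key in seen:
                    n_dup += 1
                    continue
                seen.add(key)
                edges.append(e)
        except ValueError as err:
            raise ValueError(f"{path}:{i}: {err}") from None
    return CatalogueReport(edges, n_lines, n_self, n_dup)


def induce_disease_network(
    proteins: Sequence[str],
    catalogue: Iterable[InteractionEdge],
    keep_isolated: bool = True,
) -> ProteinNetwork:
    """Induce the disease network on the mined protein list.

    Edges are catalogue edges with BOTH endpoints in the mined list.
    Mined proteins touching no retained edge are kept as degree-0 nodes
    by default (they remain part of enrichment universes); pass
    ``keep_isolated=False`` to drop them.
    """
    if not proteins:
        raise ValueError("empty protein list")
    members = {p.upper() for p in proteins}
    kept = [e for e in catalogue if e.a in members and e.b in members]
    extra = members if keep_isolated else ()
    net = ProteinNetwork.from_edges(kept, extra_nodes=extra)
    if not keep_isolated:
        net.graph.remove_nodes_from(list(nx.isolates(net.graph)))
    return net


def network_summary(net: ProteinNetwork) -> dict:
    """Node/edge counts, degree min/median/max and component sizes."""
    g = net.graph
    degrees = [d for _, d in g.degree()]
    components = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "degree_min": min(degrees) if degrees else 0,
        "degree_median": float(median(degrees)) if degrees else 0.0,
        "degree_max": max(degrees) if degrees else 0,
        "n_components": len(components),
        "component_sizes": components,
    }


def read_sif_network(path: str | Path) -> ProteinNetwork:
    """Rebuild a network from a SIF file, including isolated nodes
    (single-column lines)."""
    isolates = [
        line.split()[0].upper()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#") and len(line.split()) == 1
    ]
    report = load_edge_catalogue(path, format="sif")
    return ProteinNetwork.from_edges(report.edges, extra_nodes=isolates)


def write_sif(net: ProteinNetwork, path: str | Path, interaction: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for node in sorted(net.nodes):
            if net.graph.degree(node) == 0:
                fh.write(f"{node}\n")
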