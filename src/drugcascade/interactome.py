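"""Drug interactome extraction and shortest signal-cascade discovery.

A drug is anchored in the disease network at its target receptor(s); its
interactome is the union of all simple receptor→anchor paths within a hop
budget, and its signal cascade is the set of minimum-hop simple paths,
the lexicographically smallest of which is reported as canonical.  All
path notions are hop counts on the undirected network; "downstream" order
is path order from receptor to anchor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .network import ProteinNetwork

__all__ = [
    "DrugTargetMap",
    "DrugInteractome",
    "SignalPath",
    "extract_interactome",
    "shortest_cascade",
    "intermediaries",
    "read_drug_targets",
    "write_interactome_json",
]


@dataclass(frozen=True)
class DrugTargetMap:
    """A drug name and its target receptor symbols (canonicalized)."""

    drug: str
    receptors: tuple[str, ...]

    @staticmethod
    def make(drug: str, receptors: Sequence[str]) -> "DrugTargetMap":
        recs = tuple(r.strip().upper() for r in receptors if r.strip())
        if not recs:
            raise ValueError(f"drug {drug!r} has no receptors")
        return DrugTargetMap(drug, recs)


@dataclass(frozen=True)
class SignalPath:
    """An ordered receptor→anchor path; length counts edges."""

    nodes: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    @property
    def receptor(self) -> str:
        return self.nodes[0]

    @property
    def anchor(self) -> str:
        return self.nodes[-1]


@dataclass
class DrugInteractome:
    drug: str
    receptors: tuple[str, ...]
    anchor: str
    nodes: set[str]
    edges: set[tuple[str, str]]
    max_path_len: int
    connected: bool  # False => no receptor→anchor path within budget


def intermediaries(path: SignalPath) -> list[str]:
    """The path's nodes excluding the receptor and the anchor, in order."""
    return list(path.nodes[1:-1])


def _receptors_in_net(net: ProteinNetwork, targets: DrugTargetMap, anchor: str):
    if anchor not in net:
        raise ValueError(f"anchor {anchor!r} not in network")
    present = [r for r in targets.receptors if r in net]
    if not present:
        raise ValueError(f"no receptor of {targets.drug!r} in network")
    return present


def shortest_cascade(
    net: ProteinNetwork,
    targets: DrugTargetMap,
    anchor: str,
    per_receptor: bool = False,
) -> list[SignalPath]:
    """All minimum-hop simple paths from the drug's receptors to the anchor.

    The global minimum over all receptors is used (``per_receptor=True``
    instead returns the per-receptor minima pooled).  Paths are sorted by
    (length, lexicographic node sequence); the first element is the
    canonical cascade.  A receptor equal to the anchor yields the trivial
    length-0 path.  Disconnected drugs yield an empty list.
    """
    anchor = anchor.upper()
    receptors = _receptors_in_net(net, targets, anchor)
    g = net.graph
    per_rec: dict[str, list[SignalPath]] = {}
    for r in receptors:
        if r == anchor:
            per_rec[r] = [SignalPath((anchor,))]
            continue
        if not nx.has_path(g, r, anchor):
            continue
        per_rec[r] = [
            SignalPath(tuple(p)) for p in nx.all_shortest_paths(g, r, anchor)
        ]
    if not per_rec:
        return []
    if per_receptor:
        paths = [p for ps in per_rec.values() for p in ps]
    else:
        best = min(ps[0].length for ps in per_rec.values())
        paths = [p for ps in per_rec.values() for p in ps if p.length == best]
    return sorted(paths, key=lambda p: (p.length, p.nodes))


def extract_interactome(
    net: ProteinNetwork,
    targets: DrugTargetMap,
    anchor: str,
    max_path_len: int | None = None,
) -> DrugInteractome:
    """The receptor-anchored subnetwork of all bounded receptor→anchor paths.

    Nodes are exactly those lying on >= 1 simple receptor→anchor path of
    length <= ``max_path_len``; edges are network edges appearing on such a
    path.  The default budget is the shortest-path length + 2 — unbounded
    "all possible connections" explodes combinatorially.  If no path fits
    the budget an empty interactome is returned with ``connected=False``.
    """
    anchor = anchor.upper()
    receptors = _receptors_in_net(net, targets, anchor)
    cascades = shortest_cascade(net, targets, anchor)
    if max_path_len is None:
        if not cascades:
            return DrugInteractome(
                targets.drug, targets.receptors, anchor, set(), set(), 0, False
            )
        max_path_len = cascades[0].length + 2
    if max_path_len < 1 and not any(r == anchor for r in receptors):
        raise ValueError("max_path_len must be >= 1")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    g = net.graph
    for r in receptors:
        if r == anchor:
            nodes.add(anchor)
            continue
        for p in nx.all_simple_paths(g, r, anchor, cutoff=max_path_len):
            nodes.update(p)
            edges.update(tuple(sorted(e)) for e in zip(p, p[1:]))
    connected = bool(nodes)
    return DrugInteractome(
        targets.drug, targets.receptors, anchor, nodes, edges, max_path_len, connected
    )


def read_drug_targets(path: str | Path) -> list[DrugTargetMap]:
    """Read a drug→receptor TSV (columns: drug, receptor; one row per pair)."""
    pairs: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "drug":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected drug<TAB>receptor")
            pairs.setdefault(parts[0], []).append(parts[1])
    return [DrugTargetMap.make(d, rs) for d, rs in pairs.items()]


def write_interactome_json(
    interactome: DrugInteractome, cascades: Sequence[SignalPath], path: str | Path
) -> None:
    payload = {
        "drug": interactome.drug,
        "receptors": list(interactome.receptors),
        "anchor": interactome.anchor,
        "max_path_len": interactome.max_path_len,
        "connected": interactome.connected,
        "nodes": sorted(interactome.nodes),
        "edges": sorted(list(e) for e in interactome.edges),
        "cascades": [
            {
                "nodes": list(p.nodes),
                "length": p.length,
                "intermediaries": intermediaries(p),
            }
            for p in cascades
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
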