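"""Disassembly ordering of particle classes by ordered-feature inclusion.

Salt-washed ribosomal particles form a ladder of classes in which the
set of ordered structural features of a smaller particle tends to be a
subset of a larger one's.  This module makes that notion explicit:
each class gets an ordered-feature set (normalized occupancy above a
presence threshold), the strict-inclusion relation between those sets
is reduced to its covering relations (a Hasse diagram), and the
maximal chains of the diagram are the candidate disassembly paths,
read from the smallest particle to the largest (the reverse of
disassembly, exactly as an assembly-intermediate ladder is read).

The construction is a deliberate, parameterized formalization of what
is usually drawn by expert judgment; it makes no claim to reproduce
any manually curated figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .errors import ParameterError, ResourceError
from .occupancy import OccupancyMatrix

__all__ = [
    "DEFAULT_PRESENCE_THRESHOLD",
    "DisassemblyGraph",
    "ordered_feature_set",
    "inclusion_order",
    "maximal_paths",
]

DEFAULT_PRESENCE_THRESHOLD = 0.5


@dataclass
class DisassemblyGraph:
    """Hasse diagram of classes ordered by feature-set inclusion.

    Edges point from the smaller class to the larger; each edge is
    annotated with the features gained.  ``feature_sets`` keeps the
    per-class ordered-feature sets the order was derived from.
    """

    graph: nx.DiGraph
    feature_sets: dict[str, frozenset]
    slack: int = 0

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def gained(self, small: str, large: str) -> frozenset:
        return self.graph.edges[small, large]["gained"]

    def to_dict(self) -> dict:
        return {
            "slack": self.slack,
            "nodes": {cid: sorted(self.feature_sets[cid]) for cid in self.nodes},
            "edges": [
                {"from": a, "to": b, "gained": sorted(self.gained(a, b))}
                for a, b in self.edges
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_dot(self) -> str:
        lines = ["digraph disassembly {", "  rankdir=BT;"]
        for cid in self.nodes:
            lines.append(f'  "{cid}" [label="{cid}\\n({len(self.feature_sets[cid])} features)"];')
        for a, b in self.edges:
            gained = ",".join(sorted(self.gained(a, b)))
            lines.append(f'  "{a}" -> "{b}" [label="+{gained}"];')
        lines.append("}")
        return "\n".join(lines)


def ordered_feature_set(
    m: OccupancyMatrix,
    class_id: str,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> frozenset:
    """Features called present in a class.

    A feature is present when its *normalized* occupancy is at or
    above ``presence_threshold``.
    """
    if not m.normalized:
        raise ParameterError("ordered_feature_set requires a normalized matrix")
    column = m.column(class_id)
    return frozenset(
        fid for fid, v in zip(m.feature_ids, column) if v >= presence_threshold
    )


def inclusion_order(feature_sets: dict[str, frozenset], slack: int = 0) -> DisassemblyGraph:
    """Hasse diagram of the (slack-tolerant) inclusion order.

    Class A precedes class B when at most ``slack`` of A's features are
    missing from B and B's set is strictly larger.  At ``slack=0`` this
    is exact strict inclusion and the relation is a genuine partial
    order; the transitive reduction keeps covering relations only.
    Classes with identical feature sets are incomparable (no edge).
    """
    if len(feature_sets) < 2:
        raise ParameterError("need at least 2 classes to order")
    sets = {cid: frozenset(s) for cid, s in feature_sets.items()}
    order = nx.DiGraph()
    order.add_nodes_from(sorted(sets))
    for a in sorted(sets):
        for b in sorted(sets):
            if a == b:
                continue
            if len(sets[a] - sets[b]) <= slack and len(sets[b]) > len(sets[a]):
                order.add_edge(a, b)
    # strict size increase on every edge keeps the relation acyclic for any slack
    hasse = nx.transitive_reduction(order)
    for a, b in hasse.edges:
        hasse.edges[a, b]["gained"] = sets[b] - sets[a]
    return DisassemblyGraph(hasse, sets, slack=slack)


def maximal_paths(g: DisassemblyGraph, max_paths: int = 10_000) -> list[list[str]]:
    """All maximal chains of the diagram, smallest class first.

    Chains run from a source (no smaller comparable class) to a sink
    (no larger one), enumerated depth-first and returned sorted
    lexicographically by class-id sequence.  Isolated classes count as
    single-node chains.
    """
    graph = g.graph
    sources = [n for n in graph.nodes if graph.in_degree(n) == 0]
    paths: list[list[str]] = []

    def extend(path: list[str]) -> None:
        if len(paths) > max_paths:
            raise ResourceError(
                f"more than {max_paths} maximal chains; raise the presence "
                "threshold or lower the slack"
            )
        succ = sorted(graph.successors(path[-1]))
        if not succ:
            paths.append(path)
            return
        for nxt in succ:
            extend(path + [nxt])

    for src in sorted(sources):
        extend([src])
    return sorted(paths)
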