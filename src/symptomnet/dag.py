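"""Directed acyclic graphs over named variables, with GraphML/DOT export."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

Arc = tuple[str, str]


class Dag:
    """A labelled DAG: ordered node tuple plus a set of directed arcs.

    Node order is preserved (it fixes reporting order and the deterministic
    tie-breaks used elsewhere); arcs are stored as a set of ``(parent,
    child)`` pairs.  Construction validates acyclicity, bans self-loops,
    and rejects arcs over undeclared nodes.
    """

    def __init__(self, nodes: Sequence[str], arcs: Iterable[Arc] = ()) -> None:
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        arc_list = [tuple(a) for a in arcs]
        if len(set(arc_list)) != len(arc_list):
            raise ValueError("duplicate arcs")
        for u, v in arc_list:
            if u == v:
                raise ValueError(f"self-loop {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"arc ({u!r}, {v!r}) over undeclared node")
        self.arcs: set[Arc] = set(arc_list)
        if not self.is_acyclic():
            raise ValueError("graph contains a directed cycle")

    # -- structure queries ---------------------------------------------
    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(u for u, v in sorted(self.arcs) if v == node)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(v for u, v in sorted(self.arcs) if u == node)

    def parent_sets(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.arcs:
            out[v].add(u)
        return {n: frozenset(s) for n, s in out.items()}

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(a) for a in self.arcs}

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def topological_order(self) -> list[str]:
        g = self.to_networkx()
        # stable: prefer declared node order among ready nodes
        order = list(nx.lexicographical_topological_sort(
            g, key=lambda n: self.nodes.index(n)))
        return order

    # -- conversions ----------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def to_undirected(self) -> nx.Graph:
        return self.to_networkx().to_undirected()

    def copy(self) -> "Dag":
        return Dag(self.nodes, set(self.arcs))

    def with_arc(self, u: str, v: str) -> "Dag":
        return Dag(self.nodes, self.arcs | {(u, v)})

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Dag) and self.nodes == other.nodes
                and self.arcs == other.arcs)

    def __hash__(self) -> int:
        return hash((self.nodes, frozenset(self.arcs)))

    def __repr__(self) -> str:
        return f"Dag(|V|={len(self.nodes)}, |A|={len(self.arcs)})"

    # -- export ---------------------------------------------------------
    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_dot(self, path: str | Path) -> None:
        lines = ["digraph G {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.arcs):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_graphml(cls, path: str | Path) -> "Dag":
        g = nx.read_graphml(str(path))
        return cls(list(g.nodes()), [(str(u), str(v)) for u, v in g.edges()])


def shd_skeleton(a: Dag, b: Dag) -> int:
    """Structural Hamming distance between the two skeletons (edge
    insertions + deletions, orientation ignored)."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("node sets differ")
    return len(a.skeleton() ^ b.skeleton())


def shd(a: Dag, b: Dag) -> int:
    """Directed structural Hamming distance: insertions, deletions and
    reorientations each count one."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("node sets differ")
    dist = 0
    for pair in a.skeleton() | b.skeleton():
        in_a = pair in a.skeleton()
        in_b = pair in b.skeleton()
        if in_a != in_b:
            dist += 1
        else:
            u, v = sorted(pair)
            if ((u, v) in a.arcs) != ((u, v) in b.arcs):
                dist += 1
    return dist
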