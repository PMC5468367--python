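"""Dynamic communities and remote-to-gorge communication routes.

The residue network has one node per (chain-qualified) residue and one
edge per eligible residue pair with positive mutual information I (nats,
read as kT). Communities are found Girvan-Newman style: repeatedly remove
the edge of largest weighted betweenness (edge length 1/I, so strongly
coupled residues are close), and keep the partition along the removal
sequence that maximizes weighted modularity on the original network. For
dimers both chains live in one graph, so communities may span chains.

Communication routes start at a gorge residue and expand layer by layer
over supra-threshold edges (I > 1 kT by default); every maximal
origin-to-leaf path in the resulting breadth-first tree is a candidate
route, and routes of fewer than five residues are discarded as local.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InputError
from .torsmi import MIMatrix

__all__ = [
    "CommunityPartition",
    "CommunicationRoute",
    "build_network",
    "girvan_newman",
    "community_summary",
    "find_routes",
]

Node = tuple[str, int]


@dataclass
class CommunityPartition:
    """Residue → community assignment with inter-community MI totals."""

    assignment: dict[Node, int]
    sizes: dict[int, int]
    inter_mi: dict[tuple[int, int], float]
    modularity: float

    def communities(self) -> dict[int, list[Node]]:
        out: dict[int, list[Node]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return out


@dataclass
class CommunicationRoute:
    """Ordered residue path from a gorge residue over supra-threshold edges."""

    residues: tuple[Node, ...]
    edge_mi: tuple[float, ...]
    origin: Node

    def __len__(self) -> int:
        return len(self.residues)


def build_network(mi: MIMatrix, mode: str = "monomer") -> nx.Graph:
    """Residue network from an MI matrix: edges for eligible pairs with I > 0.

    ``mode`` is "monomer" or "dimer"; both build one graph over every
    residue present (the matrix already carries chain-qualified nodes, so
    a dimer matrix yields a two-chain network).
    """
    if mode not in ("monomer", "dimer"):
        raise InputError(f"unknown network mode {mode!r}")
    g = nx.Graph()
    g.add_nodes_from(mi.residues)
    n = len(mi.residues)
    for i in range(n):
        for j in range(i + 1, n):
            if not mi.eligible[i, j]:
                continue
            w = mi.mi[i, j]
            if np.isfinite(w) and w > 0:
                g.add_edge(mi.residues[i], mi.residues[j],
                           weight=float(w), length=1.0 / float(w))
    if g.number_of_nodes() == 0:
        raise InputError("empty residue network")
    return g


def _partition_of(graph: nx.Graph) -> list[set[Node]]:
    return [set(c) for c in nx.connected_components(graph)]


def girvan_newman(net: nx.Graph) -> CommunityPartition:
    """Max-modularity partition along the Girvan-Newman removal sequence.

    Betweenness is weighted by edge length 1/I; ties in betweenness break
    on the lexicographically smallest edge. Modularity is weighted by I on
    the original network. Components of a disconnected input are handled
    independently by construction (removals never merge components).
    """
    if net.number_of_nodes() == 0:
        raise InputError("empty network")
    work = net.copy()
    best_part = _partition_of(work)
    best_q = nx.algorithms.community.modularity(net, best_part, weight="weight") \
        if net.number_of_edges() else 0.0
    while work.number_of_edges():
        eb = nx.edge_betweenness_centrality(work, weight="length")
        top = max(eb.values())
        candidates = [tuple(sorted(e)) for e, v in eb.items()
                      if abs(v - top) < 1e-12]
        work.remove_edge(*min(candidates))
        part = _partition_of(work)
        q = nx.algorithms.community.modularity(net, part, weight="weight")
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    ordered = sorted(best_part, key=lambda c: min(c))
    assignment = {node: cid for cid, comm in enumerate(ordered) for node in comm}
    sizes = {cid: len(comm) for cid, comm in enumerate(ordered)}
    inter: dict[tuple[int, int], float] = {}
    for a, b, data in net.edges(data=True):
        ca, cb = assignment[a], assignment[b]
        if ca == cb:
            continue
        key = (min(ca, cb), max(ca, cb))
        inter[key] = inter.get(key, 0.0) + data["weight"]
    return CommunityPartition(assignment=assignment, sizes=sizes,
                              inter_mi=inter, modularity=float(best_q))


def community_summary(
    part: CommunityPartition, net: nx.Graph,
) -> nx.Graph:
    """Community graph: node size = residue count, edge weight = total cross-MI."""
    g = nx.Graph()
    for cid, size in part.sizes.items():
        g.add_node(cid, size=size)
    for (ca, cb), w in part.inter_mi.items():
        g.add_edge(ca, cb, weight=w)
    return g


def _bfs_tree_paths(net: nx.Graph, origin: Node, threshold: float) -> list[list[Node]]:
    """Maximal origin-to-leaf paths of the layered supra-threshold expansion.

    Nodes are visited once per origin (a tree, not a DAG); each node's
    parent is its lexicographically smallest supra-threshold neighbour in
    the previous layer, which makes the tree deterministic.
    """
    parent: dict[Node, Node | None] = {origin: None}
    children: dict[Node, list[Node]] = {origin: []}
    layer = [origin]
    while layer:
        nxt: dict[Node, Node] = {}
        for u in sorted(layer):
            for v in sorted(net.neighbors(u)):
                if v in parent or v in nxt:
                    continue
                if net.edges[u, v]["weight"] > threshold:
                    nxt[v] = u
        for v, u in nxt.items():
            parent[v] = u
            children[u].append(v)
            children[v] = []
        layer = list(nxt)
    paths = []
    for node, kids in children.items():
        if kids:
            continue
        path = []
        cur: Node | None = node
        while cur is not None:
            path.append(cur)
            cur = parent[cur]
        paths.append(path[::-1])
    return paths


def find_routes(
    net: nx.Graph,
    origins: set[Node] | list[Node],
    threshold: float = 1.0,
    min_len: int = 5,
) -> list[CommunicationRoute]:
    """Communication routes from gorge residues over edges with I > threshold.

    Routes shorter than ``min_len`` residues are ignored; duplicates across
    origins (identical residue sequences) collapse. Absent origins are
    skipped with a warning.
    """
    routes: dict[tuple[Node, ...], CommunicationRoute] = {}
    for origin in sorted(set(origins)):
        if origin not in net:
            warnings.warn(f"route origin {origin} not in network; skipped",
                          stacklevel=2)
            continue
        for path in _bfs_tree_paths(net, origin, threshold):
            if len(path) < min_len:
                continue
            key = tuple(path)
            if key in routes:
                continue
            weights = tuple(
                float(net.edges[a, b]["weight"]) for a, b in zip(path, path[1:])
            )
            routes[key] = CommunicationRoute(residues=key, edge_mi=weights,
                                             origin=origin)
    return [routes[k] for k in sorted(routes)]
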