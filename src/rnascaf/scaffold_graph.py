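"""Edge-weighted contig adjacency graph and greedy path enumeration.

Each vertex is a contig; an edge is a denoised contig pair weighted by its
number of agreeing joining-pairs. Edges below a minimum support K (default 5)
are removed. Candidate scaffolding paths are produced by greedy walks that
always follow the highest-weighted edge to an unvisited neighbour: one walk
per leaf (degree-1 vertex) in components that have leaves, and one walk per
vertex in leafless components (e.g. cycles), recording all possible orders
for later reconciliation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .denoiser import EdgeCandidate

DEFAULT_K = 5


@dataclass
class CandidatePath:
    """An ordered greedy walk with the edge used at each step."""

    vertices: list[str]
    edges: list[EdgeCandidate]  # len == len(vertices) - 1
    start_vertex: str

    @property
    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges)

    def __len__(self) -> int:
        return len(self.vertices)


class WeightedGraph:
    """Thin wrapper around an undirected networkx graph of EdgeCandidates."""

    def __init__(self, K: int = DEFAULT_K):
        self.K = K
        self.g = nx.Graph()

    def add_vertex(self, name: str) -> None:
        self.g.add_node(name)

    def add_edge(self, cand: EdgeCandidate) -> None:
        if cand.contig_a == cand.contig_b:
            raise ValueError("self-loop edge")
        self.g.add_edge(cand.contig_a, cand.contig_b, cand=cand, weight=cand.weight)

    def edge(self, u: str, v: str) -> EdgeCandidate:
        return self.g.edges[u, v]["cand"]

    def neighbors(self, v: str) -> list[str]:
        return sorted(self.g.neighbors(v))

    def components(self, exclude: Optional[set] = None) -> list[set]:
        """Connected components with >= 2 vertices among non-excluded vertices."""
        sub = self.g if not exclude else self.g.subgraph(set(self.g.nodes) - exclude)
        comps = [set(c) for c in nx.connected_components(sub) if len(c) >= 2]
        comps.sort(key=lambda c: min(c))
        return comps


def build_graph(
    candidates: Iterable[EdgeCandidate],
    K: int = DEFAULT_K,
    vertices: Optional[Iterable[str]] = None,
) -> WeightedGraph:
    """Build the adjacency graph keeping only edges with weight >= K.

    Isolated vertices (contigs with no surviving edge) are retained so they
    pass through scaffolding unplaced but unmodified.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    graph = WeightedGraph(K)
    if vertices is not None:
        for v in vertices:
            graph.add_vertex(v)
    for cand in candidates:
        graph.add_vertex(cand.contig_a)
        graph.add_vertex(cand.contig_b)
        if cand.weight >= K:
            graph.add_edge(cand)
    return graph


def greedy_walk(
    graph: WeightedGraph, start: str, excluded: Optional[set] = None
) -> CandidatePath:
    """Walk from `start`, stepping to the unvisited neighbour of maximum edge
    weight (ties broken by lexicographic vertex name), until stuck."""
    excluded = excluded or set()
    if start in excluded:
        raise ValueError(f"start vertex {start!r} is excluded")
    visited = {start}
    vertices = [start]
    edges: list[EdgeCandidate] = []
    current = start
    while True:
        options = [
            n
            for n in graph.neighbors(current)
            if n not in visited and n not in excluded
        ]
        if not options:
            break
        nxt = min(options, key=lambda n: (-graph.edge(current, n).weight, n))
        edges.append(graph.edge(current, nxt))
        vertices.append(nxt)
        visited.add(nxt)
        current = nxt
    return CandidatePath(vertices=vertices, edges=edges, start_vertex=start)


def enumerate_candidates(
    graph: WeightedGraph, exclude: Optional[set] = None
) -> list[list[CandidatePath]]:
    """Candidate path groups, one group per connected component.

    Components with leaves are walked from each leaf (lexicographic order);
    leafless components (every vertex degree >= 2) are walked from every
    vertex, recording all possible orders. Each group is the unit handed to
    reconciliation/selection.
    """
    exclude = exclude or set()
    groups: list[list[CandidatePath]] = []
    for comp in graph.components(exclude):
        sub = graph.g.subgraph(comp)
        leaves = sorted(v for v in comp if sub.degree(v) == 1)
        starts = leaves if leaves else sorted(comp)
        walks = [greedy_walk(graph, s, exclude | (set(graph.g.nodes) - comp)) for s in starts]
        groups.append(walks)
    return groups
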