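"""The Connecting Spectroscopic Components (CSC) ranking algorithm.

Given the internal network's component partition (H0 containing the root,
plus floating components H1, H2, ...) and a set of *external* candidate
transitions, CSC asks: which candidate lines, if measured accurately,
reconnect the most quantum states to the root per new measurement?

The machinery:

1.  **Contraction.**  Collapse every component Hi to a single vertex hi.
    External transitions internal to one component become self-loops and
    are dropped; parallel external edges between the same vertex pair are
    merged into one *pooled* edge (measuring any one line of the pool
    realises the edge).  States touched only by external transitions
    ("grey" states) stay as singleton vertices.  The result G' is a small
    simple graph whose edges all correspond to candidate measurements.

2.  **All shortest paths.**  Unweighted BFS from h0 gives, for every
    floating component, the minimum number of new measurements l_i needed
    to reach it, together with *every* minimum-length path family S_i.

3.  **Utility factor.**  u_i = |Hi| / l_i — newly connectable states per
    required new measurement.  Suggestions are ranked by u_i.

4.  **Global solution.**  A spanning tree of G' connects every reachable
    component with the overall minimum number of new measurements, at the
    cost of robustness: one failed measurement can strand several
    components at once, which :func:`compare_local_global` quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import pairwise

import networkx as nx

from .linelist import Transition
from .network import (
    ComponentPartition,
    SpectroscopicNetwork,
    build_network,
    connected_components,
)

__all__ = [
    "ContractedGraph",
    "PathFamily",
    "ExpandedEdge",
    "ExpandedPath",
    "Suggestion",
    "GlobalSolution",
    "LocalGlobalReport",
    "CSCResult",
    "contract",
    "all_shortest_paths",
    "utility_factors",
    "rank_suggestions",
    "global_solution",
    "compare_local_global",
    "run_csc",
]

#: Default size filter: floating components smaller than this are not
#: ranked.  Tiny components cost a measurement each for little gain and
#: dominate the output of real databases, so they are filtered by default;
#: pass 1 to rank everything.
DEFAULT_MIN_COMPONENT_SIZE = 8

H0 = ("h", 0)


def _edge_key(u, v):
    """Canonical (sorted) vertex pair for an undirected contracted edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class ContractedGraph:
    """G': components contracted to vertices hi, plus grey singleton states.

    Vertices are ``("h", i)`` for component Hi and ``("g", label)`` for a
    grey state (one absent from the internal network).  Edges are simple;
    each carries a non-empty ``pool`` of the external transitions it
    represents, sorted by tag.
    """

    graph: nx.Graph
    partition: ComponentPartition
    n_dropped_internal: int = 0  # external lines internal to one component

    @property
    def component_nodes(self):
        return [n for n in self.graph.nodes if n[0] == "h"]

    @property
    def grey_nodes(self):
        return [n for n in self.graph.nodes if n[0] == "g"]

    def pool(self, u, v) -> tuple[Transition, ...]:
        return self.graph.edges[u, v]["pool"]


@dataclass(frozen=True)
class PathFamily:
    """All shortest contracted paths from h0 to one floating component.

    ``length`` is the number of contracted edges (new measurements needed);
    ``math.inf`` with an empty path set marks an unreachable component.
    Paths are stored as vertex sequences, sorted lexicographically.
    """

    index: int
    length: float
    node_paths: tuple

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.length)

    def edge_paths(self):
        """Each path as a tuple of canonical edge keys."""
        return tuple(
            tuple(_edge_key(a, b) for a, b in pairwise(p)) for p in self.node_paths
        )


@dataclass(frozen=True)
class ExpandedEdge:
    """One contracted edge with its full candidate-transition pool."""

    edge: tuple
    pool: tuple


@dataclass(frozen=True)
class ExpandedPath:
    """One shortest path, expanded edge by edge to transition pools.

    ``bonus_vertices`` counts the states of intermediate floating
    components along the path: realising the path connects those too, a
    gain the utility factor deliberately leaves out to stay simple.
    """

    edges: tuple
    bonus_vertices: int = 0


@dataclass(frozen=True)
class Suggestion:
    """One ranked recommendation for a floating component."""

    index: int
    size: int
    length: int
    utility: Fraction
    paths: tuple  # of ExpandedPath

    def __post_init__(self):
        assert self.utility * self.length == self.size


@dataclass
class GlobalSolution:
    """Spanning tree of the h0-component of G' (unit edge weights)."""

    tree_edges: tuple
    reachable: tuple  # component indices connected by the tree
    unreachable: tuple  # component indices with no external path to h0


@dataclass
class LocalGlobalReport:
    """Local (per-component shortest path) vs global (spanning tree) costs.

    ``path_lengths`` maps component index -> (local length, global
    tree-path length).  The impact maps give, for each edge an approach
    selects, the number of target components stranded if that single
    measurement fails.
    """

    path_lengths: dict
    local_edges: tuple
    global_edges: tuple
    local_impact: dict
    global_impact: dict


def _map_vertex(partition: ComponentPartition, state):
    i = partition.index_of(state)
    return ("h", i) if i is not None else ("g", state)


def contract(partition: ComponentPartition, external) -> ContractedGraph:
    """Contract internal components and pool parallel external edges.

    External transitions whose endpoints fall in the same component map to
    self-loops and are discarded (this also covers candidates duplicating
    an existing internal adjacency, since such endpoints share a
    component).  Every component contributes a vertex even if no external
    line touches it, so unreachable components stay visible.
    """
    g = nx.Graph()
    for i in range(len(partition)):
        g.add_node(("h", i))
    pools: dict = {}
    dropped = 0
    for t in external:
        u = _map_vertex(partition, t.upper)
        v = _map_vertex(partition, t.lower)
        if u == v:
            dropped += 1
            continue
        pools.setdefault(_edge_key(u, v), []).append(t)
    for (u, v), pool in pools.items():
        g.add_edge(u, v, pool=tuple(sorted(pool, key=lambda t: t.tag)))
    return ContractedGraph(g, partition, dropped)


def all_shortest_paths(gprime: ContractedGraph) -> dict[int, PathFamily]:
    """BFS from h0: length and *all* shortest paths to every component.

    Grey vertices may appear as path interiors (each costs one edge, i.e.
    one measurement) but are never targets themselves.  Unreachable
    components get length inf and an empty family.
    """
    g = gprime.graph
    lengths = nx.single_source_shortest_path_length(g, H0)
    families: dict[int, PathFamily] = {}
    for i in range(1, len(gprime.partition)):
        node = ("h", i)
        if node not in lengths:
            families[i] = PathFamily(i, math.inf, ())
            continue
        paths = sorted(tuple(p) for p in nx.all_shortest_paths(g, H0, node))
        families[i] = PathFamily(i, lengths[node], tuple(paths))
    return families


def utility_factors(
    families: dict[int, PathFamily], partition: ComponentPartition
) -> dict[int, Fraction]:
    """u_i = |Hi| / l_i as exact rationals; unreachable components omitted."""
    return {
        i: Fraction(partition.size(i), int(fam.length))
        for i, fam in families.items()
        if fam.reachable
    }


def _expand_path(gprime: ContractedGraph, node_path) -> ExpandedPath:
    edges = tuple(
        ExpandedEdge(_edge_key(a, b), gprime.pool(a, b)) for a, b in pairwise(node_path)
    )
    bonus = sum(
        gprime.partition.size(n[1]) for n in node_path[1:-1] if n[0] == "h"
    )
    return ExpandedPath(edges, bonus)


def rank_suggestions(
    gprime: ContractedGraph,
    families: dict[int, PathFamily],
    min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE,
    min_utility: float = 0,
) -> list[Suggestion]:
    """Filter, score and order the floating components.

    Ordering: utility factor descending, then component size descending,
    then component index ascending (the tie-breaks make the ranking a
    deterministic total order).  Each suggestion's shortest paths are
    expanded so every contracted edge lists its full candidate pool.
    """
    part = gprime.partition
    out = []
    for i, fam in sorted(families.items()):
        if not fam.reachable:
            continue
        size = part.size(i)
        u = Fraction(size, int(fam.length))
        if size < min_component_size or u < min_utility:
            continue
        paths = tuple(_expand_path(gprime, p) for p in fam.node_paths)
        out.append(Suggestion(i, size, int(fam.length), u, paths))
    out.sort(key=lambda s: (-s.utility, -s.size, s.index))
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def global_solution(gprime: ContractedGraph) -> GlobalSolution:
    """Minimum-cardinality edge set connecting every reachable hi to h0.

    With unit edge weights the minimum spanning tree of the h0-component
    of G' is any spanning tree; Kruskal over lexicographically sorted
    edges makes the choice deterministic.
    """
    g = gprime.graph
    reachable_nodes = nx.node_connected_component(g, H0)
    uf = _UnionFind(reachable_nodes)
    tree = []
    for u, v in sorted(_edge_key(u, v) for u, v in g.edges):
        if u in reachable_nodes and uf.union(u, v):
            tree.append((u, v))
    reachable = tuple(
        i for i in range(1, len(gprime.partition)) if ("h", i) in reachable_nodes
    )
    unreachable = tuple(
        i for i in range(1, len(gprime.partition)) if ("h", i) not in reachable_nodes
    )
    return GlobalSolution(tuple(tree), reachable, unreachable)


def _impact(edge_set, targets, removed) -> int:
    """How many target vertices lose their h0 connection without `removed`."""
    g = nx.Graph()
    g.add_node(H0)
    g.add_edges_from(e for e in edge_set if e != removed)
    reach = nx.node_connected_component(g, H0) if g.number_of_nodes() else {H0}
    return sum(1 for t in targets if t not in reach)


def compare_local_global(
    suggestions, tree_edges, gprime: ContractedGraph
) -> LocalGlobalReport:
    """Contrast the per-component (local) and spanning-tree (global) picks.

    The local edge set takes the lexicographically first shortest path of
    each suggestion.  For every selected edge, the single-edge-failure
    impact is the number of target components stranded from h0 if only
    that one measurement fails — the robustness argument for the local
    strategy.
    """
    tree_edges = tuple(_edge_key(u, v) for u, v in tree_edges)
    local_edges = tuple(
        sorted({e.edge for s in suggestions for e in s.paths[0].edges})
    )
    tree_graph = nx.Graph(tree_edges)
    targets_local = [("h", s.index) for s in suggestions]
    targets_global = [n for n in tree_graph.nodes if n[0] == "h" and n != H0]

    path_lengths = {}
    for s in suggestions:
        node = ("h", s.index)
        if node in tree_graph and nx.has_path(tree_graph, H0, node):
            glen = nx.shortest_path_length(tree_graph, H0, node)
        else:
            glen = None
        path_lengths[s.index] = (s.length, glen)

    local_impact = {e: _impact(local_edges, targets_local, e) for e in local_edges}
    global_impact = {e: _impact(tree_edges, targets_global, e) for e in tree_edges}
    return LocalGlobalReport(
        path_lengths, local_edges, tree_edges, local_impact, global_impact
    )


@dataclass
class CSCResult:
    """Everything one CSC run produces, from network to ranked output."""

    network: SpectroscopicNetwork
    partition: ComponentPartition
    gprime: ContractedGraph
    families: dict
    utilities: dict
    suggestions: list
    unconnectable: tuple  # component indices with no external path to h0


def run_csc(
    internal,
    external,
    root,
    min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE,
    min_utility: float = 0,
) -> CSCResult:
    """Full pipeline: build, partition, contract, rank."""
    net = build_network(internal, root)
    partition = connected_components(net)
    gprime = contract(partition, external)
    families = all_shortest_paths(gprime)
    utilities = utility_factors(families, partition)
    suggestions = rank_suggestions(gprime, families, min_component_size, min_utility)
    unconnectable = tuple(i for i, f in sorted(families.items()) if not f.reachable)
    return CSCResult(
        net, partition, gprime, families, utilities, suggestions, unconnectable
    )
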