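"""Spectroscopic networks: multigraphs of quantum states and transitions.

A spectroscopic network (SN) has one vertex per quantum state and one
undirected edge per assigned transition; parallel edges (several lines
between the same state pair) are kept.  A designated *root* state — the
lowest-energy state, assigned energy zero by convention — anchors the
absolute energy scale: every state connected to the root by a path of
transitions obtains an absolute energy by chaining the Ritz principle
E(upper) = E(lower) + wavenumber along the path.

Connectivity is all that measurement-selection needs, so the graph is
undirected throughout; energy propagation reintroduces the direction from
the stored upper/lower assignment of each line.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .linelist import StateLabel, Transition, as_label

__all__ = [
    "SpectroscopicNetwork",
    "ComponentPartition",
    "EnergyAssignment",
    "build_network",
    "connected_components",
    "propagate_energies",
    "floating_components",
]


@dataclass
class SpectroscopicNetwork:
    """Undirected multigraph of state labels with a designated root."""

    graph: nx.MultiGraph
    root: StateLabel

    @property
    def states(self):
        return set(self.graph.nodes)

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_transitions(self) -> int:
        return self.graph.number_of_edges()

    def transitions(self) -> list[Transition]:
        return [d["transition"] for _, _, d in self.graph.edges(data=True)]


@dataclass
class ComponentPartition:
    """Connected components H0, H1, ... of a network; H0 contains the root.

    Components after H0 are ordered by decreasing size, ties broken by the
    lexicographically smallest member label, so the partition — and every
    report derived from it — is byte-stable across runs.
    """

    components: list[frozenset]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.components = [frozenset(c) for c in self.components]
        self._index = {s: i for i, comp in enumerate(self.components) for s in comp}

    def __len__(self) -> int:
        return len(self.components)

    def index_of(self, state) -> int | None:
        """Component index of a state, or None if the state is unknown."""
        return self._index.get(as_label(state))

    def size(self, i: int) -> int:
        return len(self.components[i])


@dataclass
class EnergyAssignment:
    """Absolute energies (and propagated uncertainties) per state, cm^-1."""

    energies: dict
    uncertainties: dict


def build_network(transitions, root) -> SpectroscopicNetwork:
    """Build the SN from a transition list; the root is always a vertex.

    The vertex set is the union of all transition endpoints plus the root
    (added isolated if no line touches it).  Node and edge iteration order
    is insertion order, which makes downstream reports deterministic.
    """
    root = as_label(root)
    g = nx.MultiGraph()
    g.add_node(root)
    for t in transitions:
        g.add_edge(t.upper, t.lower, transition=t)
    return SpectroscopicNetwork(g, root)


def connected_components(net: SpectroscopicNetwork) -> ComponentPartition:
    """Partition the SN into components with the root's component first."""
    comps = [frozenset(c) for c in nx.connected_components(net.graph)]
    h0 = next(c for c in comps if net.root in c)
    rest = sorted((c for c in comps if c is not h0), key=lambda c: (-len(c), min(c)))
    return ComponentPartition([h0] + rest)


def floating_components(partition: ComponentPartition) -> list[int]:
    """Indices of all components with no path to the root (everything but H0)."""
    return list(range(1, len(partition)))


def _best_parallel_transition(keydict) -> Transition:
    # Among parallel lines between a state pair, propagate along the most
    # accurate one; ties broken by tag for determinism.
    return min(
        (d["transition"] for d in keydict.values()),
        key=lambda t: (t.uncertainty, t.tag),
    )


def propagate_energies(
    net: SpectroscopicNetwork, anchor, anchor_energy: float = 0.0
) -> EnergyAssignment:
    """Chain Ritz-principle energies outward from an anchor state.

    Breadth-first traversal from the anchor assigns every state in the
    anchor's component ``anchor_energy`` plus the signed sum of wavenumbers
    along the tree path (a wavenumber adds when stepping lower -> upper and
    subtracts otherwise).  Uncertainties combine in quadrature along the
    path, treating the 95% intervals of individual lines as independent.
    States outside the anchor's component stay unassigned.  Cycle
    inconsistencies are not reconciled: the first (BFS-tree) path wins.
    """
    anchor = as_label(anchor)
    g = net.graph
    if anchor not in g:
        raise KeyError(f"anchor state {anchor!r} not in network")
    energies = {anchor: float(anchor_energy)}
    var = {anchor: 0.0}
    queue = deque([anchor])
    while queue:
        x = queue.popleft()
        for nbr, keydict in g.adj[x].items():
            if nbr in energies:
                continue
            t = _best_parallel_transition(keydict)
            sign = 1.0 if x == t.lower else -1.0
            energies[nbr] = energies[x] + sign * t.wavenumber
            var[nbr] = var[x] + t.uncertainty**2
            queue.append(nbr)
    return EnergyAssignment(energies, {s: math.sqrt(v) for s, v in var.items()})
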