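"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's graph machinery (and
networkx) so they can serve as independent cross-checks: connectivity via
union-find, path enumeration via DFS over adjacency dicts, energies via
recursive tree path sums.
"""

from __future__ import annotations

import itertools

import pytest

from cscnet import make_fig2_fixture, run_csc

# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def fig2():
    """(internal, external, root) of the hand-built worked example."""
    return make_fig2_fixture()


@pytest.fixture(scope="session")
def fig2_result(fig2):
    internal, external, root = fig2
    return run_csc(internal, external, root, min_component_size=1)


@pytest.fixture(scope="session")
def fig_index(fig2_result):
    """Map figure component number -> partition index.

    Fixture state labels carry the figure component number as their first
    token, so the component containing state (str(k), "0") is figure Hk.
    """
    part = fig2_result.partition
    return {
        k: part.index_of((str(k), "0")) for k in range(6)
    }


# ---------------------------------------------------------------------------
# oracles


def union_find_components(transitions, root):
    """Connected components of a transition list by plain union-find."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(b)] = find(a)

    find(root)
    for t in transitions:
        union(t.upper, t.lower)
    groups = {}
    for s in list(parent):
        groups.setdefault(find(s), set()).add(s)
    return [frozenset(g) for g in groups.values()]


def tree_energy_oracle(transitions, anchor, anchor_energy=0.0):
    """Signed path-sum energies on a tree, by recursive DFS."""
    adj = {}
    for t in transitions:
        adj.setdefault(t.upper, []).append((t.lower, -t.wavenumber))
        adj.setdefault(t.lower, []).append((t.upper, +t.wavenumber))
    energies = {anchor: anchor_energy}
    stack = [anchor]
    while stack:
        x = stack.pop()
        for nbr, dw in adj.get(x, []):
            if nbr not in energies:
                energies[nbr] = energies[x] + dw
                stack.append(nbr)
    return energies


def enumerate_shortest_paths(edges, src, dst):
    """All shortest src-dst paths by exhaustive simple-path DFS.

    Returns (length, sorted tuple of node-sequence paths); (inf, ()) when
    unreachable.  Only usable on small graphs.
    """
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    all_paths = []

    def dfs(node, path):
        if node == dst:
            all_paths.append(tuple(path))
            return
        for nbr in adj.get(node, ()):
            if nbr not in path:
                dfs(nbr, path + [nbr])

    if src in adj or src == dst:
        dfs(src, [src])
    if not all_paths:
        return float("inf"), ()
    best = min(len(p) for p in all_paths) - 1
    return best, tuple(sorted(p for p in all_paths if len(p) - 1 == best))


def connects(edges, nodes, src):
    """True iff `edges` connect every node in `nodes` to `src`."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen = {src}
    stack = [src]
    while stack:
        x = stack.pop()
        for nbr in adj.get(x, ()):
            if nbr not in seen:
                seen.add(nbr)
                stack.append(nbr)
    return set(nodes) <= seen


def min_connector_size(edges, nodes, src):
    """Smallest edge-subset cardinality connecting `nodes` to `src`."""
    edges = list(edges)
    for k in range(len(edges) + 1):
        for subset in itertools.combinations(edges, k):
            if connects(subset, nodes, src):
                return k
    raise AssertionError("nodes not connectable with all edges")
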