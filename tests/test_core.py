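"""Contraction, shortest-path families, utility factors, ranking, MST."""

import math
from fractions import Fraction

import pytest

from cscnet import (
    all_shortest_paths,
    build_network,
    compare_local_global,
    connected_components,
    contract,
    global_solution,
    rank_suggestions,
    run_csc,
    utility_factors,
)
from cscnet.core import H0, _edge_key
from cscnet.synth import SynthConfig, generate
from conftest import enumerate_shortest_paths, min_connector_size


def test_contract_fig2_structure(fig2_result, fig_index):
    g = fig2_result.gprime.graph
    assert g.number_of_nodes() == 7
    assert g.number_of_edges() == 7
    h = {k: ("h", i) for k, i in fig_index.items()}
    grey = fig2_result.gprime.grey_nodes[0]
    expected = {
        _edge_key(h[0], h[1]),
        _edge_key(h[0], h[2]),
        _edge_key(h[1], h[2]),
        _edge_key(h[2], h[3]),
        _edge_key(h[0], grey),
        _edge_key(grey, h[4]),
        _edge_key(h[0], h[5]),
    }
    assert {_edge_key(u, v) for u, v in g.edges} == expected


def test_contract_no_external_gives_edgeless_graph(fig2):
    internal, _, root = fig2
    part = connected_components(build_network(internal, root))
    gp = contract(part, [])
    assert gp.graph.number_of_edges() == 0
    assert gp.graph.number_of_nodes() == len(part)


def test_contract_pool_sizes_conserve_transitions(fig2_result, fig2):
    _, external, _ = fig2
    g = fig2_result.gprime.graph
    total = sum(len(d["pool"]) for _, _, d in g.edges(data=True))
    assert total + fig2_result.gprime.n_dropped_internal == len(external)
    assert total == 8


def test_contract_drops_within_component_candidates(fig2):
    internal, external, root = fig2
    part = connected_components(build_network(internal, root))
    from cscnet import Transition

    inside = Transition(55.0, 1e-2, ("1", "0"), ("1", "3"), "LOOP")
    gp = contract(part, external + [inside])
    assert gp.n_dropped_internal == 1
    assert gp.graph.number_of_edges() == 7


def test_parallel_candidates_pool_on_one_edge(fig2_result, fig_index):
    """The two H0-H5 candidate lines merge into one contracted edge."""
    pool = fig2_result.gprime.pool(H0, ("h", fig_index[5]))
    assert len(pool) == 2
    assert [t.tag for t in pool] == ["EXT.7", "EXT.8"]


def test_shortest_path_lengths_fig2(fig2_result, fig_index):
    fams = fig2_result.families
    lengths = {k: fams[fig_index[k]].length for k in range(1, 6)}
    assert lengths == {1: 1, 2: 1, 3: 2, 4: 2, 5: 1}


def test_single_edge_target_has_single_path(fig2_result):
    for fam in fig2_result.families.values():
        if fam.length == 1:
            assert len(fam.node_paths) == 1


def test_grey_vertex_is_interior_not_target(fig2_result, fig_index):
    fam = fig2_result.families[fig_index[4]]
    (path,) = fam.node_paths
    assert path[1][0] == "g"  # one BFS hop through the grey state
    assert path[0] == H0 and path[-1][0] == "h"
    # grey states are never ranked targets
    assert all(("h", i) in fig2_result.gprime.graph for i in fig2_result.families)


def test_unreachable_component_reported_infinite(fig2):
    internal, external, root = fig2
    # remove both H0-H5 candidates: figure component H5 becomes unconnectable
    external = [t for t in external if t.tag not in ("EXT.7", "EXT.8")]
    res = run_csc(internal, external, root, min_component_size=1)
    i5 = res.partition.index_of(("5", "0"))
    assert math.isinf(res.families[i5].length)
    assert res.families[i5].node_paths == ()
    assert res.unconnectable == (i5,)
    assert i5 not in res.utilities


@pytest.mark.parametrize("seed", range(8))
def test_all_shortest_paths_match_exhaustive_enumeration(seed):
    internal, external, root = generate(
        SynthConfig(seed=seed, n_components=5, size_range=(1, 4), n_external=7,
                    grey_fraction=0.3)
    )
    res = run_csc(internal, external, root, min_component_size=1)
    g = res.gprime.graph
    assert g.number_of_nodes() <= 9
    for i, fam in res.families.items():
        length, paths = enumerate_shortest_paths(list(g.edges), H0, ("h", i))
        assert fam.length == length
        assert fam.node_paths == paths


def test_utility_factors_fig2(fig2_result, fig_index):
    u = {k: fig2_result.utilities[fig_index[k]] for k in range(1, 6)}
    assert u == {1: 4, 2: 3, 3: 1, 4: 2, 5: 4}
    assert all(isinstance(v, Fraction) for v in u.values())


@pytest.mark.parametrize("seed", range(5))
def test_utility_identity_u_times_l_is_size(seed):
    internal, external, root = generate(SynthConfig(seed=seed, n_external=9))
    res = run_csc(internal, external, root, min_component_size=1)
    for i, u in res.utilities.items():
        fam = res.families[i]
        assert u * fam.length == res.partition.size(i)


def test_ranking_order_fig2(fig2_result, fig_index):
    fig_of = {v: k for k, v in fig_index.items()}
    order = [fig_of[s.index] for s in fig2_result.suggestions]
    # H1/H5 tie at u=4 (each reaches 4 new states), then H2, H4, H3
    assert set(order[:2]) == {1, 5}
    assert order[2:] == [2, 4, 3]
    assert [s.size for s in fig2_result.suggestions[:2]] == [4, 4]


def test_ranking_is_deterministic_total_order(fig2):
    internal, external, root = fig2
    a = run_csc(internal, external, root, min_component_size=1).suggestions
    b = run_csc(internal, external, root, min_component_size=1).suggestions
    assert [(s.index, s.utility) for s in a] == [(s.index, s.utility) for s in b]


def test_size_filter_dominates_fig2(fig2_result):
    out = rank_suggestions(fig2_result.gprime, fig2_result.families,
                           min_component_size=5)
    assert out == []


def test_min_utility_filter(fig2_result):
    out = rank_suggestions(fig2_result.gprime, fig2_result.families,
                           min_component_size=1, min_utility=3)
    assert all(s.utility >= 3 for s in out)
    assert len(out) == 3  # u = 4, 4, 3


def test_bonus_vertices_annotation(fig2_result, fig_index):
    """The route to H3 passes through H2: its 3 states are annotated as a
    bonus, never folded into the utility factor."""
    s3 = next(s for s in fig2_result.suggestions if s.index == fig_index[3])
    assert s3.paths[0].bonus_vertices == 3
    assert s3.utility == 1


def test_global_solution_fig2_is_spanning_tree(fig2_result):
    sol = global_solution(fig2_result.gprime)
    assert len(sol.tree_edges) == 6  # 7 reachable vertices
    assert sol.unreachable == ()


def test_global_solution_on_tree_returns_all_edges(fig2):
    internal, external, root = fig2
    keep = ("EXT.1", "EXT.2", "EXT.4", "EXT.5", "EXT.6", "EXT.7")
    external = [t for t in external if t.tag in keep]
    res = run_csc(internal, external, root, min_component_size=1)
    sol = global_solution(res.gprime)
    g = res.gprime.graph
    assert sorted(sol.tree_edges) == sorted(_edge_key(u, v) for u, v in g.edges)


@pytest.mark.parametrize("seed", range(6))
def test_global_solution_matches_bruteforce_min_connector(seed):
    internal, external, root = generate(
        SynthConfig(seed=seed, n_components=4, size_range=(1, 3), n_external=6)
    )
    res = run_csc(internal, external, root, min_component_size=1)
    g = res.gprime.graph
    assert g.number_of_nodes() <= 7
    sol = global_solution(res.gprime)
    import networkx as nx

    reachable = nx.node_connected_component(g, H0)
    assert len(sol.tree_edges) == len(reachable) - 1
    assert len(sol.tree_edges) == min_connector_size(
        list(g.edges), reachable, H0
    )


def _scenario_graph():
    """Star-vs-chain scenario: h0-h1, h0-h2, h1-h2, h2-h3."""
    from cscnet import Transition

    internal = []
    labels = {}
    for c, size in enumerate([2, 2, 2, 2]):
        for j in range(size - 1):
            internal.append(
                Transition(10.0 + c, 1e-6, (str(c), str(j + 1)), (str(c), str(j)),
                           f"I{c}.{j}")
            )
    ext = [
        Transition(100.0, 1e-2, ("1", "0"), ("0", "0"), "E1"),  # h0-h1
        Transition(110.0, 1e-2, ("2", "0"), ("0", "0"), "E2"),  # h0-h2
        Transition(120.0, 1e-2, ("2", "1"), ("1", "1"), "E3"),  # h1-h2
        Transition(130.0, 1e-2, ("3", "0"), ("2", "1"), "E4"),  # h2-h3
    ]
    return internal, ext, ("0", "0")


def test_local_strategy_limits_single_failure_impact():
    """In the chain-through-h2 global tree, losing the h0-h2 measurement
    strands three components; the local picks lose at most two."""
    internal, ext, root = _scenario_graph()
    res = run_csc(internal, ext, root, min_component_size=1)
    part = res.partition
    h = {k: ("h", part.index_of((str(k), "0"))) for k in range(4)}
    chain_tree = [
        _edge_key(h[0], h[2]),
        _edge_key(h[2], h[1]),
        _edge_key(h[2], h[3]),
    ]
    report = compare_local_global(res.suggestions, chain_tree, res.gprime)
    e02 = _edge_key(h[0], h[2])
    assert report.global_impact[e02] == 3
    assert report.local_impact[e02] < 3
    # the h1 connection survives the failed h0-h2 measurement locally
    assert report.local_impact[_edge_key(h[0], h[1])] <= 1


def test_identical_local_global_sets_have_identical_impacts():
    internal, ext, root = _scenario_graph()
    ext = [t for t in ext if t.tag != "E3"]  # G' becomes a tree
    res = run_csc(internal, ext, root, min_component_size=1)
    sol = global_solution(res.gprime)
    report = compare_local_global(res.suggestions, sol.tree_edges, res.gprime)
    assert set(report.local_edges) == set(report.global_edges)
    assert report.local_impact == report.global_impact
    assert all(l == g for l, g in report.path_lengths.values())


@pytest.mark.parametrize("seed", range(4))
def test_failure_impacts_match_deletion_recount(seed):
    from conftest import connects

    internal, external, root = generate(
        SynthConfig(seed=seed, n_components=5, n_external=8)
    )
    res = run_csc(internal, external, root, min_component_size=1)
    sol = global_solution(res.gprime)
    report = compare_local_global(res.suggestions, sol.tree_edges, res.gprime)
    targets = [("h", s.index) for s in res.suggestions]
    for removed, impact in report.local_impact.items():
        remaining = [e for e in report.local_edges if e != removed]
        stranded = sum(
            0 if connects(remaining, [t], H0) else 1 for t in targets
        )
        assert impact == stranded


def pick_one_per_edge(path):
    return [edge.pool[0] for edge in path.edges]


@pytest.mark.parametrize("seed", range(10))
def test_connectivity_guarantee(seed):
    """Adding one pooled line per edge of any suggested path merges the
    target component (and intermediate ones) into H0."""
    internal, external, root = generate(SynthConfig(seed=seed, n_external=10))
    res = run_csc(internal, external, root, min_component_size=1)
    for s in res.suggestions:
        for path in s.paths:
            target_states = res.partition.components[s.index]
            added = pick_one_per_edge(path)
            part2 = connected_components(build_network(internal + added, root))
            assert target_states <= part2.components[0]
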