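"""Interaction-hierarchy DAG: structure, backtracking, classification, export."""

from collections import Counter

import networkx as nx
import pytest
from hypothesis import given, strategies as st

import linemol as lm
from linemol.errors import GraphValidationError, InternalConsistencyError

from conftest import random_graph_from_seed


def _check_dag_invariants(g, h):
    degrees_by_level = {n + 1: lvl.graph for n, lvl in enumerate(h.levels)}
    for node in h.dag.nodes:
        n, lab = node
        indeg = h.dag.in_degree(node)
        outdeg = h.dag.out_degree(node)
        if n == 1:
            assert indeg == 0, "atoms are the only sources"
        else:
            assert indeg == 2, "every non-source vertex has exactly two parents"
        if n < h.n_levels:
            assert outdeg == degrees_by_level[n].degree(lab), "outdegree = degree in L^{n-1}"
        else:
            assert outdeg == 0, "top-level vertices are sinks"
    for (n1, _), (n2, _) in h.dag.edges:
        assert n2 == n1 + 1, "arcs connect consecutive levels only"
    expected_arcs = sum(2 * h.levels[n].graph.p for n in range(1, h.n_levels))
    assert h.dag.number_of_edges() == expected_arcs


def test_hierarchy_toy_structure(toy):
    h = lm.build_hierarchy(toy, nu=4)
    assert [lvl.graph.p for lvl in h.levels] == [4, 4, 5, 8]
    sinks = [v for v in h.dag.nodes if h.dag.out_degree(v) == 0]
    assert len(sinks) == 8 and all(n == 4 for n, _ in sinks)
    _check_dag_invariants(toy, h)


def test_hierarchy_taurocholate_structure(tauro):
    h = lm.build_hierarchy(tauro, nu=4)
    assert [lvl.graph.p for lvl in h.levels] == [12, 12, 16, 34]
    _check_dag_invariants(tauro, h)


def test_hierarchy_single_bond():
    h = lm.build_hierarchy(lm.path_graph(2), nu=2)
    sources = [v for v in h.dag.nodes if h.dag.in_degree(v) == 0]
    sinks = [v for v in h.dag.nodes if h.dag.out_degree(v) == 0]
    assert len(sources) == 2 and len(sinks) == 1
    assert h.dag.number_of_edges() == 2


def test_backtrack_sequences(toy):
    h = lm.build_hierarchy(toy, nu=4)
    assert lm.backtrack_sequence(h, 1, "3") == ("3",)
    assert lm.backtrack_sequence(h, 2, "(2,3)") == ("2", "3")
    # bend of bonds {1,2} and {2,3}: single repeated hinge atom 2
    assert lm.backtrack_sequence(h, 3, "((1,2),(2,3))") == ("1", "2", "2", "3")
    with pytest.raises(GraphValidationError, match="no vertex"):
        lm.backtrack_sequence(h, 3, "((9,9),(9,9))")


@given(st.integers(0, 10**5))
def test_sequence_lengths_are_powers_of_two(seed):
    g = random_graph_from_seed(seed, p_max=8)
    h = lm.build_hierarchy(g, nu=4)
    for n in range(1, h.n_levels + 1):
        for lab in h.level_vertices(n):
            assert len(lm.backtrack_sequence(h, n, lab)) == 2 ** (n - 1)


@pytest.mark.parametrize(
    "seq, expected",
    [
        (("i", "j", "j", "j", "k", "k", "k", "n"), "proper"),
        (("i", "j", "j", "j", "j", "k", "k", "n"), "improper"),
        (("i", "i", "j", "j", "j", "k", "k", "k"), "three_cycle"),
    ],
)
def test_classify_sequence_patterns(seq, expected):
    assert lm.classify_sequence(seq) == expected


def test_classify_sequence_rejects_impossible_patterns():
    with pytest.raises(InternalConsistencyError, match="impossible"):
        lm.classify_sequence(("a",) * 8)
    with pytest.raises(ValueError, match="length 8"):
        lm.classify_sequence(("a", "b"))


def test_interaction_table_toy_physical_records(toy):
    recs = lm.interaction_table(toy, nu=4)
    order4 = [r for r in recs if r.order == 4]
    by_type = Counter(r.itype for r in order4)
    assert by_type == {"proper": 2, "improper": 1, "three_cycle": 1}
    props = sorted(r.participants for r in order4 if r.itype == "proper")
    assert props == [("1", "2", "3", "4"), ("1", "2", "4", "3")]
    (impr,) = (r for r in order4 if r.itype == "improper")
    assert impr.participants == ("2", "1", "3", "4")  # hinge atom 2 first
    (cyc,) = (r for r in order4 if r.itype == "three_cycle")
    assert cyc.participants == ("2", "3", "4")


def test_interaction_table_taurocholate(tauro):
    recs = lm.interaction_table(tauro, nu=4)
    by_type = Counter(r.itype for r in recs if r.order == 4)
    assert by_type == {"proper": 22, "improper": 4}
    raw = lm.interaction_table(tauro, nu=4, dedupe=False)
    assert sum(1 for r in raw if r.order == 4) == 34
    groups = Counter(r.variant_group for r in raw if r.variant_group)
    assert set(groups.values()) == {3}, "each improper appears as 3 rotational variants"


@given(st.integers(0, 10**5))
def test_raw_record_counts_match_line_graph_orders(seed):
    g = random_graph_from_seed(seed, p_max=10)
    raw = lm.interaction_table(g, nu=4, dedupe=False)
    counts = Counter(r.order for r in raw)
    for n in range(1, 5):
        assert counts.get(n, 0) == lm.count_via_line_graphs(g, n)


@given(st.integers(0, 10**5))
def test_order4_census_reproduces_closed_forms(seed):
    g = random_graph_from_seed(seed, p_max=10)
    s = lm.closed_form_counts(g)
    raw = Counter(r.itype for r in lm.interaction_table(g, nu=4, dedupe=False) if r.order == 4)
    assert raw.get("proper", 0) == s.n_prop
    assert raw.get("improper", 0) == 3 * s.n_impr
    assert raw.get("three_cycle", 0) == 3 * s.n_3cyc
    assert sum(raw.values()) == s.n4


@given(st.integers(0, 10**5))
def test_hinge_properties_of_sequences(seed):
    """Bends repeat their hinge; proper hinges form a bond; improper hinges
    are adjacent to every peripheral atom."""
    g = random_graph_from_seed(seed, p_max=10)
    nbrs = g.neighbor_sets
    for r in lm.interaction_table(g, nu=4, dedupe=False):
        if r.order == 3:
            sig = sorted(Counter(r.sequence).values(), reverse=True)
            assert sig == [2, 1, 1]
            i, hinge, k = r.participants
            assert i in nbrs[hinge] and k in nbrs[hinge]
        elif r.itype == "proper":
            _, j, k, _ = r.participants
            assert k in nbrs[j], "the two triply-repeated atoms form an edge"
        elif r.itype == "improper":
            hinge, *periphery = r.participants
            assert all(x in nbrs[hinge] for x in periphery)


@given(st.integers(0, 10**5))
def test_hierarchy_invariants_random_graphs(seed):
    g = random_graph_from_seed(seed, p_max=9)
    _check_dag_invariants(g, lm.build_hierarchy(g, nu=4))


def test_higher_orders_unclassified(toy):
    recs = lm.interaction_table(toy, nu=5)
    fifth = [r for r in recs if r.order == 5]
    assert fifth and all(r.itype == "unclassified" for r in fifth)
    assert all(len(r.sequence) == 16 for r in fifth)


def test_export_dag_p3():
    h = lm.build_hierarchy(lm.path_graph(3), nu=3)
    assert [lvl.graph.p for lvl in h.levels] == [3, 2, 1]
    # indegree-2 arcs: 2 per bend (level 2) and 2 per bend pair (level 3)
    dot = lm.export_dag(h, "dot")
    assert dot.count("->") == 2 * 2 + 2 * 1
    gml = nx.parse_graphml(lm.export_dag(h, "graphml"))
    assert gml.number_of_nodes() == 6 and gml.number_of_edges() == 6
    tsv = lm.export_dag(h, "tsv")
    assert tsv.count("vertex\t") == 6
    assert "block_Z(L^0)_row0\t1\t1\t0" in tsv
    with pytest.raises(ValueError, match="unknown"):
        lm.export_dag(h, "yaml")


def test_block_tridiagonal_blocks_are_incidence_matrices(toy):
    """Arcs from level n to n+1 realise Z(L^{n-1}) as a biadjacency block."""
    import numpy as np

    h = lm.build_hierarchy(toy, nu=4)
    for n in range(1, h.n_levels):
        Z = lm.matrices(h.levels[n - 1].graph).incidence
        rows = {lab: i for i, lab in enumerate(h.level_vertices(n))}
        cols = {lab: j for j, lab in enumerate(h.level_vertices(n + 1))}
        block = np.zeros_like(Z)
        for (m1, a), (m2, b) in h.dag.edges:
            if m1 == n and m2 == n + 1:
                block[rows[a], cols[b]] = 1
        np.testing.assert_array_equal(block, Z)
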