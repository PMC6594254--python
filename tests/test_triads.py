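"""Triad census, dyad-conditioned expectations and chi-square."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqvis3d import (
    TRIAD_TYPES,
    VisibilityGraph,
    build_visibility_graph_3d,
    chi_square,
    chi_square_statistic,
    expected_triads,
    feature_vector,
    summary_stats,
    triad_census,
)
from seqvis3d.reference import classify_triple, triad_census_bruteforce
from seqvis3d.triads import FEATURE_LAYOUT
from seqvis3d.visibility import Dyad


def empty_graph(n):
    return VisibilityGraph(nodes=tuple(range(n)))


def random_digraph(n, p, seed):
    return VisibilityGraph.from_networkx(
        nx.gnp_random_graph(n, p, seed=seed, directed=True)
    )


def test_census_arc_free_and_complete_mutual():
    c = triad_census(empty_graph(10))
    assert c["003"] == 120 and sum(c.counts.values()) == 120
    vg = VisibilityGraph(nodes=(0, 1, 2))
    for u, v in itertools.combinations(range(3), 2):
        vg.add(Dyad(u, v, "mutual", "2"))
    assert triad_census(vg)["300"] == 1


def test_census_requires_three_nodes():
    with pytest.raises(ValueError):
        triad_census(empty_graph(2))


def test_census_matches_bruteforce_classifier():
    for s in range(8):
        vg = random_digraph(12, 0.3, s)
        c = triad_census(vg)
        assert c.counts == triad_census_bruteforce(vg)


def test_classifier_covers_all_64_three_node_digraphs():
    """Every labelled 3-node digraph classifies consistently with networkx."""
    for bits in range(64):
        arcs = set()
        for i, (u, v) in enumerate([(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]):
            if bits >> i & 1:
                arcs.add((u, v))
        g = nx.DiGraph(arcs)
        g.add_nodes_from(range(3))
        counts = nx.triadic_census(g)
        expected = next(t for t, c in counts.items() if c == 1)
        assert classify_triple(arcs, (0, 1, 2)) == expected


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10**6))
def test_census_conservation_and_relabeling(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 10))
    vg = random_digraph(n, float(rng.uniform(0.1, 0.7)), int(rng.integers(2**31)))
    c = triad_census(vg)
    assert sum(c.counts.values()) == math.comb(n, 3)
    # isomorphism invariance under a random relabeling
    perm = {i: int(p) for i, p in enumerate(rng.permutation(n))}
    g2 = nx.relabel_nodes(vg.to_networkx(), perm, copy=True)
    assert triad_census(VisibilityGraph.from_networkx(g2)).counts == c.counts


def test_undirected_specialization():
    g = nx.gnp_random_graph(9, 0.4, seed=2)  # undirected
    vg = VisibilityGraph(nodes=tuple(g.nodes()))
    for u, v in g.edges():
        vg.add(Dyad(u, v, "mutual", "2"))
    c = triad_census(vg)
    for t in TRIAD_TYPES:
        if t not in ("003", "102", "201", "300"):
            assert c[t] == 0


def test_expected_triads_degenerate_cases():
    n = 7
    m = expected_triads(empty_graph(n))
    assert m.mu["003"] == math.comb(n, 3)
    assert all(m.sigma2[t] == 0 for t in TRIAD_TYPES)
    vg = VisibilityGraph(nodes=tuple(range(5)))
    for u, v in itertools.combinations(range(5), 2):
        vg.add(Dyad(u, v, "mutual", "2"))
    m = expected_triads(vg)
    assert m.mu["300"] == math.comb(5, 3)


def test_expected_triads_mu_sums_and_nonnegative_variance():
    for s in range(4):
        vg = random_digraph(7, 0.4, s)
        m = expected_triads(vg)
        assert sum(m.mu.values()) == math.comb(7, 3)
        assert all(v >= 0 for v in m.sigma2.values())
        u = expected_triads(vg, null="uniform")
        assert sum(u.mu.values()) == math.comb(7, 3)


def test_chi_square_zero_when_observed_equals_expected():
    vg = random_digraph(8, 0.4, 1)
    c = triad_census(vg)
    model = expected_triads(vg)
    mu_census = c  # build a synthetic "observed = mu" via statistic directly
    assert chi_square_statistic(
        [model.mu[t] for t in TRIAD_TYPES],
        [model.mu[t] for t in TRIAD_TYPES],
        [model.sigma2[t] for t in TRIAD_TYPES],
    ) == 0.0
    assert chi_square(c, model) >= 0.0


def test_chi_square_direct_substitution():
    assert chi_square_statistic([10, 20, 30], [15, 15, 30], [5, 5, 1]) == 10.0


def test_chi_square_zero_variance_mismatch_errors():
    with pytest.raises(ValueError):
        chi_square_statistic([1], [2], [0])
    assert chi_square_statistic([2], [2], [0]) == 0.0


def test_chi_square_matches_independent_summation():
    rng = np.random.default_rng(0)
    vg = random_digraph(9, 0.35, 4)
    c = triad_census(vg)
    model = expected_triads(vg)
    got = chi_square(c, model)
    # independent float summation
    exp = sum(
        (c[t] - float(model.mu[t])) ** 2 / float(model.sigma2[t])
        for t in TRIAD_TYPES
        if float(model.sigma2[t]) != 0
    )
    assert got == pytest.approx(exp, rel=1e-12)


def test_chi_square_pearson_variant():
    vg = random_digraph(8, 0.3, 6)
    c = triad_census(vg)
    model = expected_triads(vg)
    exp = sum(
        (c[t] - float(model.mu[t])) ** 2 / float(model.mu[t])
        for t in TRIAD_TYPES
        if model.mu[t] != 0
    )
    assert chi_square(c, model, variant="pearson") == pytest.approx(exp, rel=1e-12)


def test_summary_stats_flat_lattice(flat_lattice_5):
    stats = summary_stats(build_visibility_graph_3d(flat_lattice_5))
    assert stats.edge_count == 56


def test_summary_stats_arc_free():
    stats = summary_stats(empty_graph(6))
    assert stats.edge_count == 0 and stats.chi_square == 0.0


def test_feature_vector_arc_free_layout():
    vec = feature_vector(empty_graph(6), "1111")
    assert vec.shape == (len(FEATURE_LAYOUT),)
    # TP order: 102, 003, 012, 021C, 111D, 111U
    assert list(vec[:6]) == [0, math.comb(6, 3), 0, 0, 0, 0]
    assert list(vec[8:12]) == [4, 0, 0, 0]
    assert vec[12] == 4
    assert np.array_equal(vec, feature_vector(empty_graph(6), "1111"))
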