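"""Geometry of the 2D/3D visibility constructions against brute-force oracles."""

import numpy as np
import pytest

from seqvis3d import (
    BuildConfig,
    TerrainSurface,
    axis_profile_visibility,
    build_visibility_graph_3d,
    lattice_adjacency,
    line_of_sight_visibility,
    natural_visibility_2d,
    quadrilateral_diagonals,
)
from seqvis3d.embedding import Lattice3D, LatticeNode
from seqvis3d.reference import (
    adjacency_pairs_bruteforce,
    axis_pairs_bruteforce,
    build_pairs_bruteforce,
    diagonal_pairs_bruteforce,
    graph_pair_view,
    natural_visibility_pairs_bruteforce,
    segment_clears_surface_bruteforce,
)
from seqvis3d.synthetic import random_lattice


def make_lattice(zgrid):
    """Lattice from a row-major z matrix (row index = y)."""
    side = max(len(zgrid), len(zgrid[0]))
    nodes = {}
    pos = 1
    for y, row in enumerate(zgrid):
        for x, z in enumerate(row):
            if z is not None:
                nodes[(x, y)] = LatticeNode(z=z, seq_pos=pos, base="A")
                pos += 1
    return Lattice3D(side=side, nodes=nodes)


# -- 2D natural visibility ---------------------------------------------------


def test_nv2d_two_points_and_errors():
    assert natural_visibility_2d([(0, 1), (1, 5)]).edge_count == 1
    with pytest.raises(ValueError):
        natural_visibility_2d([(1, 0), (1, 1)])
    with pytest.raises(ValueError):
        natural_visibility_2d([])


def test_nv2d_convex_series_fully_connected():
    series = [(x, (x - 2) ** 2) for x in range(5)]
    assert natural_visibility_2d(series).edge_count == 10


def test_nv2d_flat_series_minimal():
    """Strict inequality fails through equal heights: only consecutive pairs."""
    vg = natural_visibility_2d([(x, 3.0) for x in range(6)])
    assert vg.pairs() == {(i, i + 1) for i in range(5)}


def test_nv2d_edge_count_bounds():
    n = 20
    rng = np.random.default_rng(1)
    series = list(zip(range(n), rng.uniform(0, 1, n)))
    m = natural_visibility_2d(series).edge_count
    assert n - 1 <= m <= n * (n - 1) // 2


def test_nv2d_matches_bruteforce_oracle():
    for s in range(5):
        rng = np.random.default_rng(s)
        xs = np.sort(rng.uniform(0, 100, 50))
        series = list(zip(xs, rng.uniform(0, 10, 50)))
        got = natural_visibility_2d(series).pairs()
        assert got == {tuple(sorted(p)) for p in natural_visibility_pairs_bruteforce(series)}


# -- step 2: adjacency -------------------------------------------------------


def test_adjacency_full_grid_counts(flat_lattice_5):
    dyads = lattice_adjacency(flat_lattice_5)
    assert len(dyads) == 40  # 2 * 5 * 4
    assert all(d.mode == "mutual" and d.step == "2" for d in dyads)
    degree = {}
    for d in dyads:
        for c in (d.u, d.v):
            degree[c] = degree.get(c, 0) + 1
    assert degree[(0, 0)] == 2 and degree[(2, 0)] == 3 and degree[(2, 2)] == 4


def test_adjacency_with_absent_cell():
    lat = make_lattice([[1, 1, 1], [1, None, 1], [1, 1, 1]])
    pairs = {d.key() for d in lattice_adjacency(lat)}
    assert ((1, 0), (1, 1)) not in pairs
    assert pairs == adjacency_pairs_bruteforce(lat)


# -- step 3: diagonals -------------------------------------------------------


def test_diagonals_flat_lattice_tie_rule(flat_lattice_5):
    dyads = quadrilateral_diagonals(flat_lattice_5)
    assert len(dyads) == 16
    # all-tied corners resolve to the lexicographically smallest -> main diagonal
    assert {d.key() for d in dyads} == {
        ((x, y), (x + 1, y + 1)) for x in range(4) for y in range(4)
    }


def test_diagonals_unique_max_and_incomplete():
    lat = make_lattice([[1, 2], [3, 4]])  # max corner (1,1) -> main diagonal
    (d,) = quadrilateral_diagonals(lat)
    assert d.key() == ((0, 0), (1, 1))
    lat2 = make_lattice([[1, 2], [3, None]])
    assert quadrilateral_diagonals(lat2) == []


def test_diagonals_match_argmax_oracle():
    for s in range(30):
        lat = random_lattice(4, seed=s)
        got = {d.key() for d in quadrilateral_diagonals(lat)}
        assert got == diagonal_pairs_bruteforce(lat)


# -- step 4: axis profiles ---------------------------------------------------


def test_axis_profile_flat_is_consecutive(flat_lattice_5):
    dyads = axis_profile_visibility(flat_lattice_5, "x")
    assert {d.key() for d in dyads} == {
        ((x, y), (x + 1, y)) for x in range(4) for y in range(5)
    }


def test_axis_profile_convex_row_all_pairs():
    lat = make_lattice([[4, 2, 1, 2, 4]])
    got = {d.key() for d in axis_profile_visibility(lat, "x")}
    cells = [(x, 0) for x in range(5)]
    import itertools

    assert got == {tuple(sorted(p)) for p in itertools.combinations(cells, 2)}


def test_axis_profiles_match_bruteforce():
    for s in range(20):
        lat = random_lattice(6, seed=100 + s)
        for axis in "xy":
            got = {d.key() for d in axis_profile_visibility(lat, axis)}
            assert got == axis_pairs_bruteforce(lat, axis)


# -- step 5: line of sight ---------------------------------------------------


def test_step5_flat_adds_nothing(flat_lattice_5):
    surface = TerrainSurface.from_lattice(flat_lattice_5)
    prior = {d.key() for d in lattice_adjacency(flat_lattice_5)}
    prior |= {d.key() for d in quadrilateral_diagonals(flat_lattice_5)}
    assert line_of_sight_visibility(surface, "surface", exclude=prior) == []


def test_step5_blocked_by_higher_middle_node():
    lat = make_lattice([[1, 4, 1]])
    surface = TerrainSurface.from_lattice(lat)
    for policy in ("surface", "node"):
        dyads = line_of_sight_visibility(surface, policy)
        assert ((0, 0), (2, 0)) not in {d.key() for d in dyads}


def test_step5_node_policy_sees_over_dip():
    """A lower middle node does not lie on the segment: node policy connects."""
    lat = make_lattice([[2, 1, 2]])
    surface = TerrainSurface.from_lattice(lat)
    pairs = {d.key() for d in line_of_sight_visibility(surface, "node")}
    assert ((0, 0), (2, 0)) in pairs


def test_step5_matches_sampling_oracle_dense():
    """Implementation agrees with the >=10^3-point sampling oracle on 4x4 terrains."""
    for s in range(6):
        lat = random_lattice(4, seed=500 + s)
        surface = TerrainSurface.from_lattice(lat)
        import itertools

        got = {d.key() for d in line_of_sight_visibility(surface, "surface")}
        exp = set()
        for u, v in itertools.combinations(lat.cells(), 2):
            if segment_clears_surface_bruteforce(surface, u, v, samples=1009):
                exp.add(tuple(sorted((u, v))))
        assert got == exp


# -- full build --------------------------------------------------------------


def test_build_flat_lattice_closed_form(flat_lattice_5):
    g = build_visibility_graph_3d(flat_lattice_5)
    assert g.edge_count == 56
    steps = {d.step for d in g.dyads.values()}
    assert steps == {"2", "3"}  # steps 4 and 5 contribute nothing on flat terrain


def test_build_superset_of_adjacency_and_unique():
    for s in range(10):
        lat = random_lattice(5, seed=s)
        g = build_visibility_graph_3d(lat)
        adj = {d.key() for d in lattice_adjacency(lat)}
        assert adj <= g.pairs()
        keys = [d.key() for d in g.dyads.values()]
        assert len(keys) == len(set(keys))


def test_build_matches_bruteforce_small_batch():
    rng = np.random.default_rng(42)
    for _ in range(25):
        side = int(rng.integers(2, 6))
        lat = random_lattice(side, seed=int(rng.integers(2**31)))
        g = build_visibility_graph_3d(lat)
        assert graph_pair_view(g) == build_pairs_bruteforce(lat, samples=60)


def test_build_adjacency_invariant_under_elevation_change():
    lat = random_lattice(4, seed=9)
    g1 = build_visibility_graph_3d(lat)
    nodes = dict(lat.nodes)
    cell = (1, 1)
    old = nodes[cell]
    nodes[cell] = LatticeNode(z=4, seq_pos=old.seq_pos, base="A")
    g2 = build_visibility_graph_3d(Lattice3D(side=4, nodes=nodes))
    adj = {d.key() for d in lattice_adjacency(lat)}
    assert adj <= g1.pairs() and adj <= g2.pairs()


def test_build_mirror_symmetry_of_steps_2_and_4():
    lat = random_lattice(5, seed=77)
    side = lat.side

    def mirror(c):
        return (side - 1 - c[0], c[1])

    mirrored = Lattice3D(
        side=side,
        nodes={mirror(c): n for c, n in lat.nodes.items()},
    )
    for fn, arg in ((lattice_adjacency, None), (axis_profile_visibility, "x"),
                    (axis_profile_visibility, "y")):
        orig = {d.key() for d in (fn(lat) if arg is None else fn(lat, arg))}
        refl = {d.key() for d in (fn(mirrored) if arg is None else fn(mirrored, arg))}
        assert refl == {tuple(sorted((mirror(a), mirror(b)))) for a, b in orig}


def test_build_orientation_policies():
    lat = random_lattice(4, seed=3)
    g = build_visibility_graph_3d(lat, BuildConfig(orientation="all-mutual"))
    assert all(d.mode == "mutual" for d in g.dyads.values())
    g = build_visibility_graph_3d(lat, BuildConfig(orientation="default"))
    for d in g.dyads.values():
        if d.step == "2":
            assert d.mode == "mutual"
        elif d.mode == "asym":
            assert lat.z(d.u) > lat.z(d.v)
        else:
            assert lat.z(d.u) == lat.z(d.v)
    g = build_visibility_graph_3d(lat, BuildConfig(orientation="temporal"))
    for d in g.dyads.values():
        assert d.mode == "asym"
        assert lat.nodes[d.u].seq_pos < lat.nodes[d.v].seq_pos


def test_build_deterministic():
    lat = random_lattice(5, seed=11)
    a = build_visibility_graph_3d(lat)
    b = build_visibility_graph_3d(lat)
    assert graph_pair_view(a) == graph_pair_view(b)
    assert list(a.dyads) == list(b.dyads)
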