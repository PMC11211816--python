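"""Edge-support rules and the exhaustive-scan oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metassemble.clustering import Cluster
from metassemble.edge_support import (
    compose_support,
    compute_supports,
    edge_support,
    support_adjacent,
    support_boundary,
    support_junction,
)
from metassemble.splice_graph import COMBINED, SOURCE, SINK, SpliceGraph
from conftest import make_graph, random_splice_graph


def test_junction_support_exact_coordinates_only():
    g = make_graph([(100, 150), (1150, 1200)], junctions=[(0, 1, 3)])
    gj = make_graph([(100, 150), (1150, 1200)], junctions=[(0, 1, 7)])
    e = (0, 1)
    assert support_junction(e, g, gj) == 7.0
    gj2 = make_graph([(100, 150), (1200, 1260)], junctions=[(0, 1, 7)])
    assert support_junction(e, g, gj2) == 0.0
    gj3 = make_graph([(0, 50)])
    assert support_junction(e, g, gj3) == 0.0


def test_adjacent_support_vertex_containment():
    """A vertex of gj spanning the boundary supports with its coverage."""
    g = make_graph([(100, 200), (200, 260)], adjacents=[(0, 1, 2)])
    gj = make_graph([(100, 300)], vertex_weights=[4.5])
    assert support_adjacent((0, 1), g, gj) == 4.5


def test_adjacent_support_edge_beats_vertex():
    g = make_graph([(100, 200), (200, 260)], adjacents=[(0, 1, 2)])
    gj = make_graph([(100, 200), (200, 300)], adjacents=[(0, 1, 6)], vertex_weights=[4.5, 4.5])
    assert support_adjacent((0, 1), g, gj) == 6.0


def test_adjacent_support_vertex_starting_at_boundary_fails():
    """A gj vertex whose left end sits exactly on the boundary does not
    span it and gives no support."""
    g = make_graph([(100, 200), (200, 260)], adjacents=[(0, 1, 2)])
    gj = make_graph([(200, 300)], vertex_weights=[9.0])
    assert support_adjacent((0, 1), g, gj) == 0.0


def _boundary_pair():
    # g: one exon [100,200) with starting edge; gj variants probe the rules
    g = make_graph([(100, 200), (300, 400)], junctions=[(0, 1, 2)])
    return g


def test_boundary_support_direct():
    g = _boundary_pair()
    gj = make_graph([(120, 200), (300, 400)], junctions=[(0, 1, 8)])
    # gj's starting edge (s',v') where v' contains position 199
    assert support_boundary((SOURCE, 0), g, gj) == 8.0


def test_boundary_support_one_adjacent_hop_within_limit():
    g = _boundary_pair()
    # gj splits the first exon at 160 with an adjacent edge; starting edge
    # enters the left piece; extension 200-160=40 <= 200
    gj = make_graph([(120, 160), (160, 200), (300, 400)],
                    adjacents=[(0, 1, 3)], junctions=[(1, 2, 8)])
    assert support_boundary((SOURCE, 0), g, gj) == gj.edges[(SOURCE, 0)]


def test_boundary_extension_threshold_is_strict():
    """A left-extension of 201 bp yields zero; exactly 200 passes."""
    def gj_with_cut(cut):
        return make_graph([(0, cut), (cut, 500), (700, 800)],
                          adjacents=[(0, 1, 3)], junctions=[(1, 2, 8)])

    g = make_graph([(0, 500), (700, 800)], junctions=[(0, 1, 2)])
    ok = gj_with_cut(300)   # extension 500-300=200
    too_far = gj_with_cut(299)  # extension 201
    assert support_boundary((SOURCE, 0), g, ok, max_ext=200) == ok.edges[(SOURCE, 0)]
    assert support_boundary((SOURCE, 0), g, too_far, max_ext=200) == 0.0


def test_boundary_support_missing_is_zero():
    g = _boundary_pair()
    gj = make_graph([(600, 700)])
    assert support_boundary((SOURCE, 0), g, gj) == 0.0
    assert support_boundary((1, SINK), g, gj) == 0.0


def test_compose_support_examples():
    a, b = np.array([3.0, 0.0, 5.0]), np.array([2.0, 4.0, 1.0])
    assert list(compose_support(a, b)) == [2.0, 0.0, 1.0]
    assert list(compose_support(a, a)) == list(a)
    z = np.zeros(3)
    assert list(compose_support(a, z)) == [0.0, 0.0, 0.0]
    with pytest.raises(ValueError):
        compose_support(a, np.zeros(2))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0, 1e6), min_size=1, max_size=8).flatmap(
        lambda xs: st.tuples(
            st.just(np.array(xs)),
            st.lists(st.floats(0, 1e6), min_size=len(xs), max_size=len(xs)).map(np.array),
            st.lists(st.floats(0, 1e6), min_size=len(xs), max_size=len(xs)).map(np.array),
        )
    )
)
def test_compose_support_algebra(xyz):
    """Composition is commutative, associative, idempotent, and monotone
    non-increasing in each argument."""
    x, y, z = xyz
    assert np.array_equal(compose_support(x, y), compose_support(y, x))
    assert np.array_equal(
        compose_support(compose_support(x, y), z),
        compose_support(x, compose_support(y, z)),
    )
    assert np.array_equal(compose_support(x, x), x)
    assert np.all(compose_support(x, y) <= x)


def test_single_member_cluster_self_support():
    g = make_graph([(0, 100), (200, 300)], junctions=[(0, 1, 5)])
    cluster = Cluster(members=[(0, g)], member_fragments=[[]])
    sup = compute_supports(cluster)
    assert sup.members[0][(0, 1)].tolist() == [5.0]


# ---------------------------------------------------------------- oracle
def oracle_support(e, g, gj, max_ext=200):
    """Independent exhaustive scan over gj's edges and vertices."""
    u, v = e
    if u == SOURCE:
        pos = g.vertices[v][1] - 1
        for i, (L, R) in enumerate(gj.vertices):
            if L <= pos < R:
                if (SOURCE, i) in gj.edges:
                    return gj.edges[(SOURCE, i)]
                for (a, b), w in gj.edges.items():
                    if b == i and a >= 0 and gj.vertices[a][1] == gj.vertices[i][0]:
                        if (pos + 1) - gj.vertices[a][1] <= max_ext and (SOURCE, a) in gj.edges:
                            return gj.edges[(SOURCE, a)]
                return 0.0
        return 0.0
    if v == SINK:
        pos = g.vertices[u][0]
        for i, (L, R) in enumerate(gj.vertices):
            if L <= pos < R:
                if (i, SINK) in gj.edges:
                    return gj.edges[(i, SINK)]
                for (a, b), w in gj.edges.items():
                    if a == i and b >= 0 and gj.vertices[b][0] == gj.vertices[i][1]:
                        if gj.vertices[b][0] - pos <= max_ext and (b, SINK) in gj.edges:
                            return gj.edges[(b, SINK)]
                return 0.0
        return 0.0
    d, a_ = g.edge_coords(e)
    if a_ > d:  # junction
        for (x, y), w in gj.edges.items():
            if x >= 0 and y >= 0 and gj.edge_coords((x, y)) == (d, a_) and gj.vertices[x][1] < gj.vertices[y][0]:
                return w
        return 0.0
    # adjacent
    for (x, y), w in gj.edges.items():
        if x >= 0 and y >= 0 and gj.vertices[x][1] == gj.vertices[y][0] == d:
            return w
    for i, (L, R) in enumerate(gj.vertices):
        if L < d < R:
            return gj.vertex_weights[i]
    return 0.0


def test_compute_supports_matches_oracle_on_random_clusters(rng):
    """Exhaustive-scan oracle equality on random 3-sample clusters."""
    for _ in range(40):
        members = [(j, random_splice_graph(rng, max_vertices=8, sample_id=j)) for j in range(3)]
        cluster = Cluster(members=members, member_fragments=[[], [], []])
        sup = compute_supports(cluster)
        for k, (_, g) in enumerate(members):
            for e in g.edges:
                expected = [oracle_support(e, g, gj) for _, gj in members]
                assert sup.members[k][e].tolist() == expected, (e, g.to_text())
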