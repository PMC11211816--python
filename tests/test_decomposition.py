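"""Phase-preserving decomposition: examples, invariants, properties."""

import numpy as np
import pytest

from metassemble.bridging import PhasingPath
from metassemble.decomposition import (
    BipartiteResolver,
    decompose_graph,
    resolve_isolated,
)
from metassemble.splice_graph import SOURCE, SINK
from conftest import make_graph, random_phasing_paths, random_splice_graph


def _total_source_weight(g):
    return sum(w for (u, _), w in g.edges.items() if u == SOURCE)


def test_chain_graph_yields_single_transcript():
    g = make_graph([(0, 100), (200, 300), (400, 500)],
                   junctions=[(0, 1, 4), (1, 2, 4)])
    ts = decompose_graph(g)
    assert len(ts) == 1
    t = ts[0]
    assert t.vertex_path == (0, 1, 2)
    assert t.intron_chain == ((100, 200), (300, 400))
    assert t.abundance == pytest.approx(4.0)


def test_trivial_split_allocates_proportionally():
    """In-edge 5 against out-edges 2 and 3 yields transcripts of 2 and 3."""
    g = make_graph([(0, 100), (200, 300), (400, 500), (600, 700)],
                   junctions=[(0, 1, 5), (1, 2, 2), (1, 3, 3)])
    ts = decompose_graph(g)
    got = sorted(round(t.abundance, 6) for t in ts)
    assert got == [2.0, 3.0]


def test_phased_diamond_keeps_two_isoforms():
    """Counts 3 and 2 on the two phased paths; crossing artifacts excluded."""
    g = make_graph(
        [(0, 100), (200, 300), (400, 500), (600, 700)],
        junctions=[(0, 1, 3), (0, 2, 2), (1, 3, 3), (2, 3, 2)],
    )
    phasing = [
        PhasingPath(graph_ref=0, vertex_seq=(0, 1, 3), count=3),
        PhasingPath(graph_ref=0, vertex_seq=(0, 2, 3), count=2),
    ]
    ts = decompose_graph(g, phasing=phasing)
    chains = {t.vertex_path: round(t.abundance, 6) for t in ts}
    assert set(chains) == {(0, 1, 3), (0, 2, 3)}
    assert chains[(0, 1, 3)] == pytest.approx(3.0)
    assert chains[(0, 2, 3)] == pytest.approx(2.0)


def test_resolve_isolated_argmax_and_ties():
    sup = {
        1: np.array([1.0, 1.0, 1.0]),
        4: np.array([1.0, 0.0, 0.0]),
        5: np.array([0.0, 6.0, 1.0]),
        6: np.array([1.0, 0.0, 0.0]),
    }
    b = BipartiteResolver(in_side=[1], out_side=[4, 5, 6])
    resolve_isolated(b, sup)
    # composed sums: 1, 2, 1 -> middle candidate wins
    assert (1, 5) in b.links
    # all-zero supports: first candidate by edge order
    sup0 = {k: np.zeros(2) for k in (1, 4, 5)}
    b0 = BipartiteResolver(in_side=[1], out_side=[4, 5])
    resolve_isolated(b0, sup0)
    assert (1, 4) in b0.links
    b1 = BipartiteResolver(in_side=[1], out_side=[4])
    resolve_isolated(b1, {1: np.zeros(1), 4: np.zeros(1)})
    assert (1, 4) in b1.links


def test_three_by_three_vertex_isolated_edge_links_to_argmax():
    """One isolated in-edge at a 3x3 vertex links to the out-edge with the
    largest summed composed support; the resulting transcript follows it."""
    # vertices: three left exons -> shared middle exon -> three right exons
    g = make_graph(
        [(0, 50), (100, 150), (200, 250), (300, 400), (500, 550), (600, 650), (700, 750)],
        junctions=[
            (0, 3, 5), (1, 3, 5), (2, 3, 5),
            (3, 4, 5), (3, 5, 5), (3, 6, 5),
        ],
    )
    supports = {e: np.full(3, 9.0) for e in g.edges}
    # phase two of the three in-edges; in-edge (2,3) stays isolated
    phasing = [
        PhasingPath(graph_ref=0, vertex_seq=(0, 3, 4), count=2),
        PhasingPath(graph_ref=0, vertex_seq=(1, 3, 6), count=2),
    ]
    supports[(2, 3)] = np.array([4.0, 4.0, 0.0])
    supports[(3, 4)] = np.array([0.0, 1.0, 0.0])
    supports[(3, 5)] = np.array([9.0, 3.0, 0.0])  # argmax: sum(min)=7
    supports[(3, 6)] = np.array([0.0, 0.0, 8.0])
    ts = decompose_graph(g, supports=supports, phasing=phasing)
    assert any(t.vertex_path == (2, 3, 5) for t in ts)
    # the phased pairings survive untouched
    assert any(t.vertex_path == (0, 3, 4) for t in ts)
    assert any(t.vertex_path == (1, 3, 6) for t in ts)


def test_unphased_two_by_two_uses_support_argmax():
    g = make_graph(
        [(0, 50), (100, 150), (200, 300), (400, 450), (500, 550)],
        junctions=[(0, 2, 3), (1, 2, 3), (2, 3, 3), (2, 4, 3)],
    )
    supports = {e: np.full(2, 5.0) for e in g.edges}
    supports[(0, 2)] = np.array([5.0, 0.0])
    supports[(1, 2)] = np.array([0.0, 5.0])
    supports[(2, 3)] = np.array([5.0, 0.0])
    supports[(2, 4)] = np.array([0.0, 5.0])
    ts = decompose_graph(g, supports=supports)
    paths = {t.vertex_path for t in ts}
    assert (0, 2, 3) in paths and (1, 2, 4) in paths
    assert (0, 2, 4) not in paths and (1, 2, 3) not in paths


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_random_graph_invariants(seed):
    """Conservation, junction coverage, phase preservation, termination."""
    rng = np.random.default_rng(seed)
    for _ in range(80):
        g = random_splice_graph(rng)
        phasing = random_phasing_paths(rng, g, n_paths=int(rng.integers(0, 8)))
        total_before = _total_source_weight(g)
        ts = decompose_graph(g, phasing=phasing)
        assert ts, g.to_text()
        # weight conservation
        assert sum(t.abundance for t in ts) == pytest.approx(total_before, rel=1e-6)
        # junction coverage
        covered = set()
        for t in ts:
            covered.update(zip(t.vertex_path, t.vertex_path[1:]))
        for e in g.junction_edges():
            assert e in covered
        # phase preservation
        for h in phasing:
            seq = h.vertex_seq
            assert any(_contig(seq, t.vertex_path) for t in ts), (seq, [t.vertex_path for t in ts])
        # supports propagate by min
        for t in ts:
            for e in zip(t.vertex_path, t.vertex_path[1:]):
                pass  # original-edge membership checked above


def _contig(sub, seq):
    n, m = len(sub), len(seq)
    return any(tuple(seq[i:i + n]) == tuple(sub) for i in range(m - n + 1))


def test_support_vectors_bounded_by_constituents(rng):
    for _ in range(20):
        g = random_splice_graph(rng, max_vertices=8)
        supports = {e: rng.integers(0, 9, size=3).astype(float) for e in g.edges}
        ts = decompose_graph(g, supports=supports)
        for t in ts:
            path = (SOURCE,) + t.vertex_path + (SINK,)
            for e in zip(path, path[1:]):
                assert np.all(t.support <= supports[e] + 1e-12)


def test_single_vertex_graph_single_exon_candidate():
    g = make_graph([(0, 300)], vertex_weights=[6.0])
    ts = decompose_graph(g)
    assert len(ts) == 1
    assert ts[0].exons == [(0, 300)]
    assert ts[0].intron_chain == ()
    assert ts[0].abundance == pytest.approx(6.0)


def test_decomposition_requires_augmented_graph():
    g = make_graph([(0, 100)], augment=False)
    with pytest.raises(ValueError):
        decompose_graph(g)
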