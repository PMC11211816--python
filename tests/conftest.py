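"""Shared builders: hand-made splice graphs and randomized fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from metassemble.splice_graph import SOURCE, SINK, SpliceGraph, augment_source_sink


def make_graph(
    vertices,
    junctions=(),
    adjacents=(),
    vertex_weights=None,
    sample_id=0,
    strand="+",
    chrom="chr1",
    augment=True,
) -> SpliceGraph:
    """Hand-build a splice graph from vertex intervals and edge lists.

    ``junctions``/``adjacents`` are (u_idx, v_idx, weight) triples.
    """
    vertices = [tuple(v) for v in vertices]
    if vertex_weights is None:
        vertex_weights = [1.0] * len(vertices)
    g = SpliceGraph(
        chrom=chrom, strand=strand, sample_id=sample_id,
        vertices=vertices, vertex_weights=list(map(float, vertex_weights)),
    )
    for u, v, w in junctions:
        assert vertices[u][1] < vertices[v][0], "junction endpoints must be separated"
        g.edges[(u, v)] = float(w)
    for u, v, w in adjacents:
        assert vertices[u][1] == vertices[v][0], "adjacent vertices must touch"
        g.edges[(u, v)] = float(w)
    if augment:
        augment_source_sink(g)
    g.invalidate_caches()
    return g


def random_splice_graph(rng: np.random.Generator, max_vertices: int = 15, sample_id: int = 0) -> SpliceGraph:
    """A random connected splice graph with <= max_vertices exons.

    A forward backbone guarantees connectivity; extra skip junctions add
    branching.  Roughly a third of consecutive vertex pairs touch and
    get adjacent edges instead of junctions.
    """
    n = int(rng.integers(2, max_vertices + 1))
    vertices = []
    pos = int(rng.integers(0, 1000))
    for _ in range(n):
        length = int(rng.integers(50, 300))
        vertices.append((pos, pos + length))
        pos += length + (0 if rng.random() < 0.33 else int(rng.integers(100, 2000)))
    weights = [float(rng.integers(1, 30)) for _ in range(n)]
    g = SpliceGraph(chrom="chrT", strand="+", sample_id=sample_id,
                    vertices=vertices, vertex_weights=weights)
    for i in range(n - 1):
        w = float(rng.integers(1, 20))
        g.edges[(i, i + 1)] = w
    for _ in range(int(rng.integers(0, n))):
        u = int(rng.integers(0, n - 1))
        v = int(rng.integers(u + 1, n))
        if (u, v) in g.edges or vertices[u][1] == vertices[v][0]:
            continue
        g.edges[(u, v)] = float(rng.integers(1, 20))
    augment_source_sink(g)
    g.invalidate_caches()
    return g


def random_phasing_paths(rng: np.random.Generator, g: SpliceGraph, n_paths: int = 5):
    """Consistent phasing paths: random forward walks along graph edges."""
    from metassemble.bridging import PhasingPath

    out_map: dict[int, list[int]] = {}
    for (u, v) in g.edges:
        if u >= 0 and v >= 0:
            out_map.setdefault(u, []).append(v)
    paths = []
    interior = [i for i in range(len(g.vertices)) if out_map.get(i)]
    if not interior:
        return paths
    for _ in range(n_paths):
        cur = int(rng.choice(interior))
        seq = [cur]
        for _ in range(int(rng.integers(1, 5))):
            nxts = out_map.get(seq[-1])
            if not nxts:
                break
            seq.append(int(rng.choice(sorted(nxts))))
        if len(seq) >= 2:
            paths.append(PhasingPath(graph_ref=g.sample_id, vertex_seq=tuple(seq), count=int(rng.integers(1, 5))))
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
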