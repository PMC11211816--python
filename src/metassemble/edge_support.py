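"""Cross-sample edge support vectors.

For every edge e of every graph in a cluster (individual graphs and the
combined graph) a length-N vector M_e is computed, where M_e[j]
quantifies how strongly member graph G_j corroborates e:

* junction edge — weight of G_j's junction at identical coordinates;
* adjacent edge — weight of G_j's adjacent edge at the same boundary,
  else the coverage of a G_j vertex strictly spanning the boundary
  (the explicit edge wins when both exist);
* starting/ending edge — weight of a G_j boundary edge at the matching
  terminal exon, allowing one adjacent hop outward bounded by a
  maximum extension (200 bp by default, strict).

Supports compose across merged edges by elementwise minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Cluster
from .splice_graph import COMBINED, SOURCE, SINK, SpliceGraph


def support_junction(e: tuple[int, int], g: SpliceGraph, gj: SpliceGraph) -> float:
    """Support from gj for a junction edge of g: weight of the junction
    with identical (donor, acceptor) coordinates, else 0."""
    coords = g.edge_coords(e)
    return gj.junction_weight_map().get(coords, 0.0)


def support_adjacent(e: tuple[int, int], g: SpliceGraph, gj: SpliceGraph) -> float:
    """Support from gj for an adjacent edge of g at boundary b: an
    adjacent edge of gj at b wins; otherwise a gj vertex covering both
    b-1 and b supports with its coverage."""
    b = g.edge_coords(e)[0]
    adj = gj.adjacent_weight_map()
    if b in adj:
        return adj[b]
    vi = gj.vertex_at(b)
    if vi is not None:
        L, R = gj.vertices[vi]
        if L < b < R:
            return gj.vertex_weights[vi]
    return 0.0


def support_boundary(e: tuple[int, int], g: SpliceGraph, gj: SpliceGraph, max_ext: int = 200) -> float:
    """Support from gj for a starting or ending edge of g.

    For a starting edge (s, v): locate the last base of v's exon in gj;
    a starting edge into that vertex supports directly, else one
    incoming adjacent hop to a vertex with a starting edge supports if
    the extension stays within ``max_ext`` bases (strict)."""
    u, v = e
    if u == SOURCE:
        pos = g.vertices[v][1] - 1  # last base of the first exon
        vi = gj.vertex_at(pos)
        if vi is None:
            return 0.0
        w = gj.start_edge_weight(vi)
        if w is not None:
            return w
        if vi > 0 and gj.vertices[vi - 1][1] == gj.vertices[vi][0] and (vi - 1, vi) in gj.edges:
            if (pos + 1) - gj.vertices[vi - 1][1] <= max_ext:
                w2 = gj.start_edge_weight(vi - 1)
                if w2 is not None:
                    return w2
        return 0.0
    if v == SINK:
        pos = g.vertices[u][0]  # first base of the last exon
        vi = gj.vertex_at(pos)
        if vi is None:
            return 0.0
        w = gj.end_edge_weight(vi)
        if w is not None:
            return w
        nxt = vi + 1
        if nxt < len(gj.vertices) and gj.vertices[nxt][0] == gj.vertices[vi][1] and (vi, nxt) in gj.edges:
            if gj.vertices[nxt][0] - pos <= max_ext:
                w2 = gj.end_edge_weight(nxt)
                if w2 is not None:
                    return w2
        return 0.0
    raise ValueError("not a boundary edge")


def edge_support(e: tuple[int, int], g: SpliceGraph, gj: SpliceGraph, max_ext: int = 200) -> float:
    u, v = e
    if u == SOURCE or v == SINK:
        return support_boundary(e, g, gj, max_ext=max_ext)
    if g.edge_kind(e) == "junction":
        return support_junction(e, g, gj)
    return support_adjacent(e, g, gj)


@dataclass
class ClusterSupports:
    members: list[dict[tuple[int, int], np.ndarray]]
    combined: dict[tuple[int, int], np.ndarray]

    def for_graph(self, member_index: int | None):
        """Support map of one member graph, or of the combined graph
        when ``member_index`` is None."""
        return self.combined if member_index is None else self.members[member_index]


def supports_for_graph(g: SpliceGraph, cluster: Cluster, max_ext: int = 200) -> dict[tuple[int, int], np.ndarray]:
    n = cluster.n
    out: dict[tuple[int, int], np.ndarray] = {}
    member_graphs = [mg for _, mg in cluster.members]
    for e in g.edges:
        vec = np.zeros(n)
        for j, gj in enumerate(member_graphs):
            vec[j] = edge_support(e, g, gj, max_ext=max_ext)
        out[e] = vec
    return out


def compute_supports(cluster: Cluster, max_ext: int = 200) -> ClusterSupports:
    """Support vectors for every edge of every member graph and of the
    combined graph, indexed over the N member graphs."""
    members = [supports_for_graph(g, cluster, max_ext=max_ext) for _, g in cluster.members]
    combined = {}
    if cluster.combined is not None:
        combined = supports_for_graph(cluster.combined, cluster, max_ext=max_ext)
    return ClusterSupports(members=members, combined=combined)


def compose_support(mi: np.ndarray, mo: np.ndarray) -> np.ndarray:
    """Elementwise minimum — the support a concatenated edge inherits."""
    if len(mi) != len(mo):
        raise ValueError(f"support length mismatch: {len(mi)} vs {len(mo)}")
    return np.minimum(mi, mo)
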