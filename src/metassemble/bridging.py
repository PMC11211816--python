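"""Two-stage paired-end fragment bridging and graph refinement.

Bridging infers the unsequenced middle of a paired-end fragment as a
path in a splice graph.  Stage 1 bridges each fragment in its own
sample's graph; only fragments that fail there are retried against the
cluster's combined graph, whose junction set pools every sample.  A
stage-2 success indicates a junction missing from the individual graph,
which refinement then restores (with weight equal to the number of
fragments rescued across it) before phasing paths are finalized.

The bridging objective among candidate connecting paths: maximize the
minimum edge weight along the connecting segment (bottleneck), break
ties by fewer junctions, then by shorter exonic length — computed by
dynamic programming over the DAG in coordinate order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment_io import Fragment
from .clustering import Cluster
from .splice_graph import COMBINED, SpliceGraph, augment_source_sink, build_graph

_INF = float("inf")


@dataclass(frozen=True)
class PhasingPath:
    """A graph path realized by (bridged) fragments, with multiplicity."""

    graph_ref: int  # sample_id or COMBINED
    vertex_seq: tuple[int, ...]
    count: int = 1

    def edge_seq(self) -> list[tuple[int, int]]:
        return list(zip(self.vertex_seq, self.vertex_seq[1:]))


@dataclass
class BridgeResult:
    h_members: list[list[PhasingPath]]
    h_combined: list[PhasingPath]
    rescued_junctions: list[dict[tuple[int, int], int]]
    n_stage1: int = 0
    n_stage2: int = 0
    n_unbridged: int = 0


def _connect(g: SpliceGraph, u: int, v: int) -> Optional[list[int]]:
    """Bottleneck-optimal connecting path from vertex u to vertex v
    (u, v interior, u < v in coordinate order).  Returns the full vertex
    list u..v inclusive, or None when no path exists."""
    # DP state per vertex: (bottleneck, -n_junctions, -exonic_length)
    best: dict[int, tuple[float, int, int]] = {u: (_INF, 0, 0)}
    pred: dict[int, int] = {}
    order = range(u, v + 1)
    out_by_vertex: dict[int, list[tuple[int, float, bool]]] = {}
    for (a, b), w in g.edges.items():
        if a >= 0 and b >= 0 and u <= a and b <= v:
            out_by_vertex.setdefault(a, []).append((b, w, g.edge_kind((a, b)) == "junction"))
    for x in order:
        if x not in best:
            continue
        bx, nx, lx = best[x]
        for y, w, is_junc in sorted(out_by_vertex.get(x, [])):
            cand = (
                min(bx, w),
                nx - (1 if is_junc else 0),
                lx - (g.vertices[y][1] - g.vertices[y][0]),
            )
            if y not in best or cand > best[y]:
                best[y] = cand
                pred[y] = x
    if v not in best:
        return None
    path = [v]
    while path[-1] != u:
        path.append(pred[path[-1]])
    return path[::-1]


def bridge_fragment(f: Fragment, g: SpliceGraph, max_span: int = 500_000) -> Optional[PhasingPath]:
    """Bridge one fragment in graph ``g``; None on failure.

    Both mates' junction chains must be representable in ``g``.  The
    returned path concatenates read1's forced path, the bottleneck-
    optimal connecting segment, and read2's forced path.
    """
    p1 = g.read_vertex_path(f.read1)
    if p1 is None:
        return None
    if f.read2 is None:
        return PhasingPath(graph_ref=g.sample_id, vertex_seq=tuple(p1))
    if f.end - f.start > max_span:
        return None
    p2 = g.read_vertex_path(f.read2)
    if p2 is None:
        return None
    if p1[-1] < p2[0]:
        mid = _connect(g, p1[-1], p2[0])
        if mid is None:
            return None
        seq = p1 + mid[1:-1] + p2
    else:
        # mates overlap: their vertex paths must agree on the overlap
        if p2[0] not in p1:
            return None
        k = p1.index(p2[0])
        tail = p1[k:]
        if p2[: len(tail)] != tail:
            return None
        seq = p1 + p2[len(tail):]
    return PhasingPath(graph_ref=g.sample_id, vertex_seq=tuple(seq))


def refine_graph(
    g: SpliceGraph,
    rescued: Sequence[PhasingPath],
    gm: SpliceGraph,
    fragments: Sequence[Fragment],
    min_junction_support: int = 1,
    bundle_gap: int = 50,
) -> tuple[SpliceGraph, dict[tuple[int, int], int]]:
    """Rebuild ``g`` restoring junctions recovered by stage-2 bridging.

    ``rescued`` holds combined-graph paths of this sample's fragments.
    Every junction those paths traverse that is absent from ``g`` is
    inserted with weight equal to the number of rescued fragments
    crossing it; exon partition and coverages are recomputed over the
    updated junction set.
    """
    own = set(g.junction_weight_map())
    restored: Counter[tuple[int, int]] = Counter()
    cover: Counter[tuple[int, int]] = Counter()
    for p in rescued:
        hit = False
        for u, v in p.edge_seq():
            if u < 0 or v < 0:
                continue
            if gm.edge_kind((u, v)) != "junction":
                continue
            coords = gm.edge_coords((u, v))
            if coords not in own:
                restored[coords] += p.count
                hit = True
        if hit:
            # inferred exonic footprint of the rescued fragment: makes the
            # restored junction's endpoints exon boundaries and corrects
            # vertex weights over the unsequenced middle
            for vid in p.vertex_seq:
                s, e = gm.vertices[vid]
                cover[(int(s), int(e))] += p.count
    if not restored:
        return g, {}
    g2 = build_graph(
        fragments,
        min_junction_support=min_junction_support,
        bundle_gap=bundle_gap,
        extra_junctions={j: float(c) for j, c in restored.items()},
        extra_cover=[(s, e, c) for (s, e), c in sorted(cover.items())],
        chrom=g.chrom,
        strand=g.strand,
        sample_id=g.sample_id,
    )
    augment_source_sink(g2)
    return g2, dict(restored)


def _compress(paths: list[PhasingPath], graph_ref: int) -> list[PhasingPath]:
    c: Counter[tuple[int, ...]] = Counter()
    for p in paths:
        c[p.vertex_seq] += p.count
    return [PhasingPath(graph_ref=graph_ref, vertex_seq=seq, count=n) for seq, n in sorted(c.items())]


def _mate_paths(f: Fragment, g: SpliceGraph) -> list[PhasingPath]:
    out = []
    for r in f.reads():
        p = g.read_vertex_path(r)
        if p is not None:
            out.append(PhasingPath(graph_ref=g.sample_id, vertex_seq=tuple(p)))
    return out


def bridge_all(
    cluster: Cluster,
    max_span: int = 500_000,
    min_junction_support: int = 1,
    bundle_gap: int = 50,
) -> BridgeResult:
    """Run the full two-stage bridging + refinement over one cluster.

    Member graphs inside ``cluster`` are replaced by their refined
    versions.  Fragments bridged at stage 1 are never retried against
    the combined graph; fragments failing both stages contribute their
    two mate paths separately as short phasing paths.
    """
    gm = cluster.combined
    if gm is None:
        raise ValueError("cluster has no combined graph; call build_combined first")
    res = BridgeResult(h_members=[], h_combined=[], rescued_junctions=[])

    rescued_per_member: list[list[PhasingPath]] = []
    for k, ((sid, g), frags) in enumerate(zip(cluster.members, cluster.member_fragments)):
        failures = []
        for f in frags:
            p = bridge_fragment(f, g, max_span=max_span)
            if p is None:
                failures.append(f)
            else:
                res.n_stage1 += 1
        rescued = []
        for f in failures:
            pm = bridge_fragment(f, gm, max_span=max_span)
            if pm is not None:
                f.bridged_path = pm
                rescued.append(pm)
                res.n_stage2 += 1
            else:
                res.n_unbridged += 1
        rescued_per_member.append(rescued)

    for k, ((sid, g), frags) in enumerate(zip(cluster.members, cluster.member_fragments)):
        g2, restored = refine_graph(
            g, rescued_per_member[k], gm, frags,
            min_junction_support=min_junction_support, bundle_gap=bundle_gap,
        )
        cluster.members[k] = (sid, g2)
        res.rescued_junctions.append(restored)
        paths: list[PhasingPath] = []
        for f in frags:
            p = bridge_fragment(f, g2, max_span=max_span)
            if p is not None:
                paths.append(p)
            else:
                paths.extend(_mate_paths(f, g2))
        res.h_members.append(_compress(paths, sid))

    pooled_paths: list[PhasingPath] = []
    for frags in cluster.member_fragments:
        for f in frags:
            pm = bridge_fragment(f, gm, max_span=max_span)
            if pm is not None:
                pooled_paths.append(pm)
            else:
                pooled_paths.extend(_mate_paths(f, gm))
    res.h_combined = _compress(pooled_paths, COMBINED)
    return res
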