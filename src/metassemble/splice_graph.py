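"""Weighted splice graphs: one per sample per locus, plus combined graphs.

A splice graph is a weighted DAG whose vertices are (partial) exons —
maximal covered intervals cut at every splice position — and whose edges
are junctions (intron gaps), adjacencies (shared exon boundaries with
continuous coverage), and, after augmentation, source/sink edges.
Vertex weight is the average per-base coverage of the exon; junction
edge weight is the number of reads spanning the junction; adjacent edge
weight is the number of read blocks spanning the boundary.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment_io import Fragment

SOURCE = -1
SINK = -2
COMBINED = -100  # sample_id of a combined (pooled) graph


@dataclass
class SpliceGraph:
    chrom: str
    strand: str
    sample_id: int
    vertices: list[tuple[int, int]]  # sorted, non-overlapping half-open intervals
    vertex_weights: list[float]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)
    augmented: bool = False
    _jmap: Optional[dict] = field(default=None, repr=False, compare=False)
    _amap: Optional[dict] = field(default=None, repr=False, compare=False)
    _starts_cache: Optional[list] = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------ kinds
    def edge_kind(self, e: tuple[int, int]) -> str:
        u, v = e
        if u == SOURCE:
            return "source"
        if v == SINK:
            return "sink"
        if self.vertices[u][1] == self.vertices[v][0]:
            return "adjacent"
        return "junction"

    def edge_coords(self, e: tuple[int, int]) -> tuple[int, int]:
        """(donor, acceptor) of an interior edge: end of the left exon,
        start of the right exon (half-open convention)."""
        u, v = e
        return self.vertices[u][1], self.vertices[v][0]

    # -------------------------------------------------------------- iterators
    def junction_edges(self) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[0] >= 0 and e[1] >= 0 and self.edge_kind(e) == "junction"]

    def adjacent_edges(self) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[0] >= 0 and e[1] >= 0 and self.edge_kind(e) == "adjacent"]

    def interior_edges(self) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[0] >= 0 and e[1] >= 0]

    def source_edges(self) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[0] == SOURCE]

    def sink_edges(self) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[1] == SINK]

    # ---------------------------------------------------------------- lookups
    @property
    def _starts(self) -> list[int]:
        if self._starts_cache is None:
            self._starts_cache = [v[0] for v in self.vertices]
        return self._starts_cache

    def vertex_at(self, pos: int) -> Optional[int]:
        """Index of the vertex whose interval contains ``pos``."""
        i = bisect_right(self._starts, pos) - 1
        if i >= 0 and self.vertices[i][0] <= pos < self.vertices[i][1]:
            return i
        return None

    def vertex_ending_at(self, pos: int) -> Optional[int]:
        for i, (_, e) in enumerate(self.vertices):
            if e == pos:
                return i
        return None

    def vertex_starting_at(self, pos: int) -> Optional[int]:
        i = bisect_right(self._starts, pos) - 1
        if i >= 0 and self.vertices[i][0] == pos:
            return i
        return None

    def junction_weight_map(self) -> dict[tuple[int, int], float]:
        if self._jmap is None:
            self._jmap = {
                self.edge_coords(e): w
                for e, w in self.edges.items()
                if e[0] >= 0 and e[1] >= 0 and self.edge_kind(e) == "junction"
            }
        return self._jmap

    def adjacent_weight_map(self) -> dict[int, float]:
        if self._amap is None:
            self._amap = {
                self.edge_coords(e)[0]: w
                for e, w in self.edges.items()
                if e[0] >= 0 and e[1] >= 0 and self.edge_kind(e) == "adjacent"
            }
        return self._amap

    def invalidate_caches(self) -> None:
        """Call after mutating ``edges`` or ``vertices`` by hand."""
        self._jmap = None
        self._amap = None
        self._starts_cache = None

    def in_edges(self, v: int) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[1] == v]

    def out_edges(self, v: int) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[0] == v]

    def start_edge_weight(self, v: int) -> Optional[float]:
        return self.edges.get((SOURCE, v))

    def end_edge_weight(self, v: int) -> Optional[float]:
        return self.edges.get((v, SINK))

    # ------------------------------------------------------------- read paths
    def _block_chain(self, bs: int, be: int) -> Optional[list[int]]:
        """Vertex chain covering block [bs, be); None if unrepresentable."""
        vi = self.vertex_at(bs)
        if vi is None:
            return None
        chain = [vi]
        while self.vertices[chain[-1]][1] < be:
            nxt = chain[-1] + 1
            if nxt >= len(self.vertices):
                return None
            if self.vertices[nxt][0] != self.vertices[chain[-1]][1]:
                return None
            if (chain[-1], nxt) not in self.edges:
                return None
            chain.append(nxt)
        return chain

    def read_vertex_path(self, read) -> Optional[list[int]]:
        """The vertex path a read's blocks + junction chain trace through the
        graph, or None if any block or junction is absent."""
        path: list[int] = []
        for bi, (bs, be) in enumerate(read.blocks):
            chain = self._block_chain(bs, be)
            if chain is None:
                return None
            if bi > 0:
                d, a = read.junctions[bi - 1]
                u, v = path[-1], chain[0]
                if self.vertices[u][1] != d or self.vertices[v][0] != a:
                    return None
                if (u, v) not in self.edges:
                    return None
            path.extend(chain)
        return path

    # ------------------------------------------------------------------ debug
    def to_text(self) -> str:
        lines = [f"# graph sample={self.sample_id} {self.chrom}{self.strand} augmented={self.augmented}"]
        for i, ((s, e), w) in enumerate(zip(self.vertices, self.vertex_weights)):
            lines.append(f"v {i} [{s},{e}) {w:.3f}")
        for (u, v), w in sorted(self.edges.items(), key=lambda kv: (kv[0][1] == SINK, kv[0])):
            kind = self.edge_kind((u, v))
            lines.append(f"e {u} {v} {kind} {w:.3f}")
        return "\n".join(lines)


def build_graph(
    locus_fragments: Sequence[Fragment],
    region: Optional[tuple[int, int]] = None,
    min_junction_support: int = 1,
    bundle_gap: int = 50,
    extra_junctions: Optional[dict[tuple[int, int], float]] = None,
    extra_cover: Optional[Sequence[tuple[int, int, int]]] = None,
    chrom: str = "",
    strand: str = ".",
    sample_id: int = 0,
) -> SpliceGraph:
    """Build a splice graph from the fragments of one locus.

    ``extra_junctions`` maps (donor, acceptor) -> additional spanning
    count, and ``extra_cover`` lists (start, end, count) intervals of
    inferred exonic coverage; together they are how refinement
    re-inserts junctions recovered by bridging against the combined
    graph — the inferred coverage closes the unsequenced mate gap so
    the restored junction's endpoints become exon boundaries.
    """
    reads = [r for f in locus_fragments for r in f.reads()]
    if not reads and not extra_junctions:
        return SpliceGraph(chrom=chrom, strand=strand, sample_id=sample_id, vertices=[], vertex_weights=[])
    if reads:
        chrom = reads[0].chrom
    lo = min((r.start for r in reads), default=None)
    hi = max((r.end for r in reads), default=None)
    if extra_junctions:
        jlo = min(d for d, _ in extra_junctions)
        jhi = max(a for _, a in extra_junctions)
        lo = jlo if lo is None else min(lo, jlo)
        hi = jhi if hi is None else max(hi, jhi)
    if extra_cover:
        lo = min([lo] + [s for s, _, _ in extra_cover])
        hi = max([hi] + [e for _, e, _ in extra_cover])
    if region is not None:
        lo, hi = min(lo, region[0]), max(hi, region[1])

    cov = np.zeros(hi - lo, dtype=np.int64)
    for r in reads:
        for bs, be in r.blocks:
            cov[bs - lo : be - lo] += 1
    if extra_cover:
        # inferred coverage fills only the unsequenced gaps: where real
        # reads align they already count
        inferred = np.zeros_like(cov)
        for s, e, c in extra_cover:
            inferred[s - lo : e - lo] += c
        inferred[cov > 0] = 0
        cov += inferred

    jcount: Counter[tuple[int, int]] = Counter()
    for r in reads:
        for j in r.junctions:
            jcount[j] += 1
    junctions = {j: float(c) for j, c in jcount.items() if c >= min_junction_support}
    if extra_junctions:
        for j, c in extra_junctions.items():
            junctions[j] = junctions.get(j, 0.0) + float(c)

    # Maximal covered runs, filling sub-bundle_gap dips so a sequencing
    # dip inside an exon does not fracture the vertex set.
    covered = cov > 0
    runs = _runs(covered)
    runs = _fill_gaps(runs, bundle_gap)

    splice = sorted({d for d, _ in junctions} | {a for _, a in junctions})
    vertices: list[tuple[int, int]] = []
    for rs, re_ in runs:
        cuts = [rs] + [p - lo for p in splice if rs < p - lo < re_] + [re_]
        for a, b in zip(cuts, cuts[1:]):
            vertices.append((a + lo, b + lo))
    vertex_weights = [float(cov[s - lo : e - lo].mean()) for s, e in vertices]

    g = SpliceGraph(chrom=chrom, strand=strand, sample_id=sample_id, vertices=vertices, vertex_weights=vertex_weights)

    end_at = {e: i for i, (_, e) in enumerate(vertices)}
    start_at = {s: i for i, (s, _) in enumerate(vertices)}

    for (d, a), w in junctions.items():
        u = end_at.get(d)
        v = start_at.get(a)
        if u is None or v is None:
            continue
        g.edges[(u, v)] = g.edges.get((u, v), 0.0) + w

    # adjacent edges where coverage is continuous across the boundary
    boundaries = sorted({e for _, e in vertices})
    span_count: Counter[int] = Counter()
    spanning_blocks: list[tuple[int, int, int]] = [
        (bs, be, 1) for r in reads for bs, be in r.blocks
    ]
    if extra_cover:
        spanning_blocks.extend(extra_cover)
    for bs, be, c in spanning_blocks:
        i = bisect_right(boundaries, bs)
        while i < len(boundaries) and boundaries[i] < be:
            span_count[boundaries[i]] += c
            i += 1
    for i in range(len(vertices) - 1):
        b = vertices[i][1]
        if vertices[i + 1][0] != b:
            continue
        if cov[b - 1 - lo] > 0 and cov[b - lo] > 0:
            g.edges[(i, i + 1)] = float(span_count.get(b, 0))
    return g


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as [start, end) index pairs."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _fill_gaps(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return runs
    out = [runs[0]]
    for s, e in runs[1:]:
        if s - out[-1][1] < gap:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def augment_source_sink(g: SpliceGraph) -> SpliceGraph:
    """Connect in-degree-0 vertices to the source and out-degree-0 vertices
    to the sink.  The source edge carries the sum of the vertex's out-edge
    weights (mirrored for sink edges); a fully isolated vertex carries its
    own coverage on both, so single-exon loci remain extractable."""
    if g.augmented:
        return g
    n = len(g.vertices)
    indeg = [0.0] * n
    outdeg = [0.0] * n
    has_in = [False] * n
    has_out = [False] * n
    for (u, v), w in g.edges.items():
        if u >= 0:
            outdeg[u] += w
            has_out[u] = True
        if v >= 0:
            indeg[v] += w
            has_in[v] = True
    for v in range(n):
        if not has_in[v]:
            w = outdeg[v] if has_out[v] else g.vertex_weights[v]
            g.edges[(SOURCE, v)] = w
        if not has_out[v]:
            w = indeg[v] if has_in[v] else g.vertex_weights[v]
            g.edges[(v, SINK)] = w
    g.augmented = True
    g.invalidate_caches()
    return g


def splice_positions(g: SpliceGraph) -> set[int]:
    """Union of donor/acceptor positions over junction edges."""
    pos: set[int] = set()
    for e in g.junction_edges():
        d, a = g.edge_coords(e)
        pos.add(d)
        pos.add(a)
    return pos
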