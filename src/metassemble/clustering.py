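"""Cross-sample clustering of individual splice graphs.

Graphs from different samples that describe the same gene locus are
grouped by single-linkage agglomeration on the Jaccard similarity of
their splice-position sets; a cluster stops growing at a size cap
(typically the number of samples).  Each cluster is then given a
combined graph built from the pooled reads of all its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment_io import Fragment
from .splice_graph import COMBINED, SpliceGraph, augment_source_sink, build_graph, splice_positions


@dataclass
class Cluster:
    members: list[tuple[int, SpliceGraph]]
    member_fragments: list[list[Fragment]]
    combined: Optional[SpliceGraph] = None

    @property
    def n(self) -> int:
        return len(self.members)


def graph_similarity(gi: SpliceGraph, gj: SpliceGraph) -> float:
    """Jaccard index of the two graphs' splice-position sets (0 when both
    are junction-free: such graphs only co-cluster via genomic overlap)."""
    si, sj = splice_positions(gi), splice_positions(gj)
    union = si | sj
    if not union:
        return 0.0
    return len(si & sj) / len(union)


def cluster_graphs(
    graphs: Sequence[tuple[int, SpliceGraph]],
    size_cap: int,
    min_similarity: float = 0.1,
    fragments: Optional[Sequence[list[Fragment]]] = None,
) -> list[Cluster]:
    """Single-linkage clustering in decreasing-similarity order.

    A merge whose union would exceed ``size_cap`` is skipped; linkage
    stops below ``min_similarity``.  Similarity ties break on the
    smaller (index, index) pair so the partition is deterministic.
    """
    m = len(graphs)
    if fragments is None:
        fragments = [[] for _ in range(m)]
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    size = [1] * m
    pairs = []
    pos = [splice_positions(g) for _, g in graphs]
    for i in range(m):
        for j in range(i + 1, m):
            union = pos[i] | pos[j]
            sim = len(pos[i] & pos[j]) / len(union) if union else 0.0
            if sim >= min_similarity:
                pairs.append((-sim, i, j))
    pairs.sort()
    for _, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if size[ri] + size[rj] > size_cap:
            continue
        parent[rj] = ri
        size[ri] += size[rj]
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for root in sorted(groups):
        idx = groups[root]
        clusters.append(
            Cluster(
                members=[graphs[i] for i in idx],
                member_fragments=[list(fragments[i]) for i in idx],
            )
        )
    return clusters


def build_combined(
    cluster: Cluster,
    min_junction_support: int = 1,
    bundle_gap: int = 50,
) -> SpliceGraph:
    """Build and attach the cluster's combined graph from pooled reads."""
    pooled: list[Fragment] = []
    for frs in cluster.member_fragments:
        pooled.extend(frs)
    chrom = cluster.members[0][1].chrom
    strand = cluster.members[0][1].strand
    gm = build_graph(
        pooled,
        min_junction_support=min_junction_support,
        bundle_gap=bundle_gap,
        chrom=chrom,
        strand=strand,
        sample_id=COMBINED,
    )
    augment_source_sink(gm)
    cluster.combined = gm
    return gm
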