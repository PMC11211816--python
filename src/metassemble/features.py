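"""The 50-feature description of a candidate transcript.

Features fall into four groups — abundance (14), graph-structural (12),
boundary (14) and intron (10) — mixing raw read-count magnitudes with
cross-protocol-comparable ratios.  Each feature is declared as one of:

* ``count``  — scales with sequencing depth (doubles if every read is
  duplicated);
* ``size``   — structural quantity, invariant to depth;
* ``ratio``  — normalized to [0, ~], invariant to depth;
* ``binary`` — indicator, invariant to depth;
* ``log``    — log-scaled count (monotone in depth, not proportional).

The declared schema is hashed and stored with every trained model so a
scorer is never applied to feature rows produced by a different
extractor layout.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Optional, Sequence

import numpy as np

from .clustering import Cluster
from .decomposition import CandidateTranscript
from .splice_graph import SOURCE, SINK, SpliceGraph

# (name, class) in fixed order; order is part of the model schema.
FEATURE_SCHEMA: list[tuple[str, str]] = [
    # --- abundance (14)
    ("abundance", "count"),
    ("support_samples", "size"),
    ("support_total", "count"),
    ("phased_merge_frac", "ratio"),
    ("support_max", "count"),
    ("bottleneck_weight", "count"),
    ("bottleneck_support_samples", "size"),
    ("bottleneck_support_total", "count"),
    ("guess_margin_min", "ratio"),
    ("n_guessed_merges", "size"),
    ("junction_weight_min", "count"),
    ("exon_coverage_mean", "count"),
    ("locus_fragments_log", "log"),
    ("abundance_fraction", "ratio"),
    # --- graph structural (12)
    ("n_vertices_graph", "size"),
    ("n_junctions_graph", "size"),
    ("n_vertices_combined", "size"),
    ("n_junctions_combined", "size"),
    ("n_samples", "size"),
    ("n_exons", "size"),
    ("transcript_length", "size"),
    ("n_paths_graph", "size"),
    ("assembled_in_both", "binary"),
    ("counterpart_abundance", "count"),
    ("origin_is_combined", "binary"),
    ("junctions_multi_sample_frac", "ratio"),
    # --- boundary (14)
    ("start_edge_weight", "count"),
    ("end_edge_weight", "count"),
    ("start_support_samples", "size"),
    ("start_support_total", "count"),
    ("end_support_samples", "size"),
    ("end_support_total", "count"),
    ("start_exon_length", "size"),
    ("end_exon_length", "size"),
    ("start_exon_coverage", "count"),
    ("end_exon_coverage", "count"),
    ("start_is_leftmost", "binary"),
    ("end_is_rightmost", "binary"),
    ("start_weight_ratio", "ratio"),
    ("end_weight_ratio", "ratio"),
    # --- intron (10)
    ("retention_ratio_max", "ratio"),
    ("retention_ratio_mean", "ratio"),
    ("n_retention_vertices", "size"),
    ("intron_length_mean", "size"),
    ("intron_length_max", "size"),
    ("intron_length_min", "size"),
    ("junction_support_samples_mean", "size"),
    ("junction_support_samples_min", "size"),
    ("junction_weight_combined_mean", "count"),
    ("junction_weight_combined_min", "count"),
]

FEATURE_NAMES: list[str] = [n for n, _ in FEATURE_SCHEMA]
FEATURE_CLASSES: dict[str, str] = dict(FEATURE_SCHEMA)
N_FEATURES = len(FEATURE_SCHEMA)
assert N_FEATURES == 50


def schema_hash() -> str:
    text = ";".join(f"{n}:{c}" for n, c in FEATURE_SCHEMA)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def compute_features(
    t: CandidateTranscript,
    g: SpliceGraph,
    gm: SpliceGraph,
    cluster: Cluster,
    supports: Optional[dict[tuple[int, int], np.ndarray]] = None,
    counterpart_abundance: Optional[float] = None,
    locus_fragments: Optional[int] = None,
    n_graph_paths: int = 1,
) -> np.ndarray:
    """Populate the 50-vector for one candidate transcript.

    ``supports`` is the edge->vector map of the graph the candidate was
    decomposed from; ``counterpart_abundance`` is the abundance of the
    identical intron chain assembled from the other graph type (None if
    it was not assembled there); ``n_graph_paths`` is how many candidate
    paths the origin graph decomposed into — the more parallel paths a
    locus yields, the weaker the prior on any one of them.
    """
    f = dict.fromkeys(FEATURE_NAMES, 0.0)
    path = t.vertex_path
    n = cluster.n

    def vec(edge: tuple[int, int]) -> np.ndarray:
        if supports is not None and edge in supports:
            return np.asarray(supports[edge], dtype=float)
        return np.zeros(n)

    interior = list(zip(path, path[1:]))
    junction_edges = [e for e in interior if g.edge_kind(e) == "junction"]
    jweights = [g.edges[e] for e in junction_edges]
    int_weights = [g.edges[e] for e in interior]

    # abundance group
    sup = np.asarray(t.support, dtype=float)
    f["abundance"] = float(t.abundance)
    f["support_samples"] = float(np.sum(sup > 0))
    f["support_total"] = float(np.sum(sup))
    f["phased_merge_frac"] = float(t.n_phased_merges / t.n_merges) if t.n_merges else 1.0
    f["support_max"] = float(np.max(sup)) if sup.size else 0.0
    if int_weights:
        bidx = int(np.argmin(int_weights))
        bvec = vec(interior[bidx])
        f["bottleneck_weight"] = float(int_weights[bidx])
    else:
        bvec = vec((SOURCE, path[0]))
        f["bottleneck_weight"] = float(g.vertex_weights[path[0]])
    f["bottleneck_support_samples"] = float(np.sum(bvec > 0))
    f["bottleneck_support_total"] = float(np.sum(bvec))
    if jweights:
        f["junction_weight_min"] = float(np.min(jweights))
    f["guess_margin_min"] = float(t.guess_margin_min)
    f["n_guessed_merges"] = float(t.n_guessed_merges)
    f["exon_coverage_mean"] = float(np.mean([g.vertex_weights[v] for v in path]))
    nfrag = locus_fragments if locus_fragments is not None else sum(len(fr) for fr in cluster.member_fragments)
    f["locus_fragments_log"] = float(np.log1p(nfrag))
    total_src = sum(w for (u, _), w in g.edges.items() if u == SOURCE)
    f["abundance_fraction"] = float(t.abundance / total_src) if total_src > 0 else 0.0

    # graph structural group
    f["n_vertices_graph"] = float(len(g.vertices))
    f["n_junctions_graph"] = float(len(g.junction_edges()))
    f["n_vertices_combined"] = float(len(gm.vertices))
    f["n_junctions_combined"] = float(len(gm.junction_edges()))
    f["n_samples"] = float(n)
    f["n_exons"] = float(t.n_exons)
    f["transcript_length"] = float(sum(e - s for s, e in t.exons))
    f["n_paths_graph"] = float(n_graph_paths)
    f["assembled_in_both"] = 1.0 if counterpart_abundance is not None else 0.0
    f["counterpart_abundance"] = float(counterpart_abundance or 0.0)
    f["origin_is_combined"] = 1.0 if g.sample_id < 0 else 0.0
    if t.intron_chain:
        multi = 0
        for e in junction_edges:
            if np.sum(vec(e) > 0) >= 2:
                multi += 1
        f["junctions_multi_sample_frac"] = multi / len(junction_edges)

    # boundary group
    v0, vk = path[0], path[-1]
    w_start = g.edges.get((SOURCE, v0), 0.0)
    w_end = g.edges.get((vk, SINK), 0.0)
    svec, evec = vec((SOURCE, v0)), vec((vk, SINK))
    f["start_edge_weight"] = float(w_start)
    f["end_edge_weight"] = float(w_end)
    f["start_support_samples"] = float(np.sum(svec > 0))
    f["start_support_total"] = float(np.sum(svec))
    f["end_support_samples"] = float(np.sum(evec > 0))
    f["end_support_total"] = float(np.sum(evec))
    f["start_exon_length"] = float(t.exons[0][1] - t.exons[0][0])
    f["end_exon_length"] = float(t.exons[-1][1] - t.exons[-1][0])
    f["start_exon_coverage"] = float(g.vertex_weights[v0])
    f["end_exon_coverage"] = float(g.vertex_weights[vk])
    starts = [g.vertices[e[1]][0] for e in g.source_edges()]
    ends = [g.vertices[e[0]][1] for e in g.sink_edges()]
    f["start_is_leftmost"] = 1.0 if starts and g.vertices[v0][0] == min(starts) else 0.0
    f["end_is_rightmost"] = 1.0 if ends and g.vertices[vk][1] == max(ends) else 0.0
    f["start_weight_ratio"] = float(w_start / g.vertex_weights[v0]) if g.vertex_weights[v0] > 0 else 0.0
    f["end_weight_ratio"] = float(w_end / g.vertex_weights[vk]) if g.vertex_weights[vk] > 0 else 0.0

    # intron group: competitiveness of intron-spanning coverage.  A
    # retained intron shows as a transcript exon (run of adjacent
    # vertices) spanning a junction of the graph; its coverage competes
    # with the junction's spanning-read weight.
    jmap = g.junction_weight_map()
    runs: list[list[int]] = []
    for vid in path:
        if runs and g.vertices[runs[-1][-1]][1] == g.vertices[vid][0]:
            runs[-1].append(vid)
        else:
            runs.append([vid])
    ratios: list[float] = []
    n_ret = 0
    for run in runs:
        L, R = g.vertices[run[0]][0], g.vertices[run[-1]][1]
        contained = [(d, a) for (d, a) in jmap if L < d and a < R]
        if contained:
            n_ret += 1
            lens = np.array([g.vertices[v][1] - g.vertices[v][0] for v in run], dtype=float)
            wts = np.array([g.vertex_weights[v] for v in run], dtype=float)
            run_cov = float(np.sum(lens * wts) / np.sum(lens))
            for d, a in contained:
                w = jmap[(d, a)]
                if w > 0:
                    ratios.append(run_cov / w)
    if ratios:
        f["retention_ratio_max"] = float(np.max(ratios))
        f["retention_ratio_mean"] = float(np.mean(ratios))
    f["n_retention_vertices"] = float(n_ret)
    if t.intron_chain:
        ilens = [a - d for d, a in t.intron_chain]
        f["intron_length_mean"] = float(np.mean(ilens))
        f["intron_length_max"] = float(np.max(ilens))
        f["intron_length_min"] = float(np.min(ilens))
        jsup_counts = [float(np.sum(vec(e) > 0)) for e in junction_edges]
        if jsup_counts:
            f["junction_support_samples_mean"] = float(np.mean(jsup_counts))
            f["junction_support_samples_min"] = float(np.min(jsup_counts))
        gm_jmap = gm.junction_weight_map()
        gmw = [gm_jmap.get((d, a), 0.0) for d, a in t.intron_chain]
        f["junction_weight_combined_mean"] = float(np.mean(gmw))
        f["junction_weight_combined_min"] = float(np.min(gmw))

    row = np.array([f[name] for name in FEATURE_NAMES], dtype=float)
    assert np.all(np.isfinite(row))
    return row


def label_candidates(
    ts: Sequence[CandidateTranscript],
    annotation: Iterable[tuple[str, str, tuple[tuple[int, int], ...]]],
    features: Sequence[np.ndarray],
) -> list[tuple[np.ndarray, int]]:
    """Pair feature rows with 0/1 labels by exact intron-chain match.

    ``annotation`` yields (chrom, strand, intron_chain) keys of the
    reference transcripts.  Single-exon candidates are excluded —
    matching is intron-chain-based.
    """
    truth = set(annotation)
    rows: list[tuple[np.ndarray, int]] = []
    for t, x in zip(ts, features):
        if not t.intron_chain:
            continue
        label = 1 if (t.chrom, t.strand, t.intron_chain) in truth else 0
        rows.append((x, label))
    return rows
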