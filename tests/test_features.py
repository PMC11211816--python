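"""Feature schema, hand-computed values, and depth-scaling classes."""

import numpy as np
import pytest

from metassemble.alignment_io import AlignedRead, Fragment
from metassemble.clustering import Cluster, build_combined
from metassemble.bridging import bridge_all
from metassemble.decomposition import decompose_graph
from metassemble.edge_support import compute_supports
from metassemble.features import (
    FEATURE_CLASSES,
    FEATURE_NAMES,
    FEATURE_SCHEMA,
    compute_features,
    label_candidates,
    schema_hash,
)
from metassemble.splice_graph import augment_source_sink, build_graph


def test_schema_is_fifty_features_in_documented_groups():
    assert len(FEATURE_SCHEMA) == 50
    assert len(set(FEATURE_NAMES)) == 50
    # group sizes: abundance 14, structural 12, boundary 14, intron 10
    assert FEATURE_NAMES[0] == "abundance"
    assert FEATURE_NAMES[14] == "n_vertices_graph"
    assert FEATURE_NAMES[26] == "start_edge_weight"
    assert FEATURE_NAMES[40] == "retention_ratio_max"
    assert set(FEATURE_CLASSES.values()) <= {"count", "size", "ratio", "binary", "log"}
    assert len(schema_hash()) == 16


def _frag(name, blocks, junctions=None, sample=0):
    r1 = AlignedRead(sample_id=sample, query_name=name, chrom="chr1", strand="+",
                     blocks=blocks, junctions=junctions or [], is_first_mate=True)
    return Fragment(read1=r1)


def _two_sample_cluster(dup=1):
    """Two samples sharing one two-exon transcript; ``dup`` replicates
    every read (for the depth-scaling check)."""
    def reads(sample, n):
        out = []
        for i in range(n * dup):
            out.append(_frag(f"s{sample}r{i}", [(100, 150), (1150, 1200)], [(150, 1150)], sample=sample))
        return out

    f0, f1 = reads(0, 3), reads(1, 5)
    g0 = build_graph(f0, sample_id=0, chrom="chr1", strand="+")
    g1 = build_graph(f1, sample_id=1, chrom="chr1", strand="+")
    augment_source_sink(g0)
    augment_source_sink(g1)
    cluster = Cluster(members=[(0, g0), (1, g1)], member_fragments=[f0, f1])
    build_combined(cluster)
    bres = bridge_all(cluster)
    sup = compute_supports(cluster)
    return cluster, bres, sup


def test_hand_computed_features_on_shared_transcript():
    cluster, bres, sup = _two_sample_cluster()
    (sid0, g0) = cluster.members[0]
    ts = decompose_graph(g0, sup.members[0], bres.h_members[0])
    assert len(ts) == 1
    t = ts[0]
    x = compute_features(t, g0, cluster.combined, cluster, sup.members[0],
                         counterpart_abundance=8.0, locus_fragments=8, n_graph_paths=1)
    f = dict(zip(FEATURE_NAMES, x))
    # hand arithmetic: sample 0 has 3 spanning reads, sample 1 has 5
    assert f["abundance"] == 3.0
    assert f["support_samples"] == 2.0
    assert f["support_total"] == 8.0  # 3 (own) + 5 (other member)
    assert f["support_max"] == 5.0
    assert f["bottleneck_weight"] == 3.0
    assert f["junction_weight_min"] == 3.0
    assert f["exon_coverage_mean"] == 3.0
    assert f["abundance_fraction"] == 1.0
    assert f["n_vertices_graph"] == 2.0 and f["n_junctions_graph"] == 1.0
    assert f["n_vertices_combined"] == 2.0 and f["n_junctions_combined"] == 1.0
    assert f["n_samples"] == 2.0
    assert f["n_exons"] == 2.0
    assert f["transcript_length"] == 100.0
    assert f["assembled_in_both"] == 1.0 and f["counterpart_abundance"] == 8.0
    assert f["origin_is_combined"] == 0.0
    assert f["junctions_multi_sample_frac"] == 1.0
    assert f["start_edge_weight"] == 3.0 and f["end_edge_weight"] == 3.0
    assert f["start_support_samples"] == 2.0 and f["start_support_total"] == 8.0
    assert f["start_exon_length"] == 50.0 and f["end_exon_length"] == 50.0
    assert f["start_is_leftmost"] == 1.0 and f["end_is_rightmost"] == 1.0
    assert f["start_weight_ratio"] == 1.0 and f["end_weight_ratio"] == 1.0
    assert f["retention_ratio_max"] == 0.0 and f["n_retention_vertices"] == 0.0
    assert f["intron_length_mean"] == 1000.0
    assert f["junction_support_samples_min"] == 2.0
    assert f["junction_weight_combined_min"] == 8.0  # pooled 3+5
    assert f["phased_merge_frac"] == 0.0  # two boundary merges, unphaseable
    assert f["n_guessed_merges"] == 0.0
    assert np.all(np.isfinite(x))


def test_feature_classes_under_read_duplication():
    """Doubling every read doubles 'count' features and leaves 'size',
    'ratio' and 'binary' features unchanged."""
    rows = {}
    for dup in (1, 2):
        cluster, bres, sup = _two_sample_cluster(dup=dup)
        (sid0, g0) = cluster.members[0]
        ts = decompose_graph(g0, sup.members[0], bres.h_members[0])
        rows[dup] = compute_features(ts[0], g0, cluster.combined, cluster, sup.members[0],
                                     counterpart_abundance=None, locus_fragments=8 * dup,
                                     n_graph_paths=len(ts))
    for i, (name, cls) in enumerate(FEATURE_SCHEMA):
        a, b = rows[1][i], rows[2][i]
        if cls == "count":
            assert b == pytest.approx(2 * a), name
        elif cls in ("size", "ratio", "binary"):
            assert b == pytest.approx(a), name
        elif cls == "log":
            assert b >= a, name


def test_label_candidates_exact_chain_matching():
    cluster, bres, sup = _two_sample_cluster()
    (sid0, g0) = cluster.members[0]
    ts = decompose_graph(g0, sup.members[0], bres.h_members[0])
    feats = [np.zeros(50)] * len(ts)
    truth = [("chr1", "+", ((150, 1150),))]
    rows = label_candidates(ts, truth, feats)
    assert [l for _, l in rows] == [1]
    # off-by-one acceptor -> label 0
    rows0 = label_candidates(ts, [("chr1", "+", ((150, 1151),))], feats)
    assert [l for _, l in rows0] == [0]
    # single-exon candidates are excluded from training rows
    from metassemble.decomposition import CandidateTranscript

    single = CandidateTranscript(chrom="chr1", strand="+", exons=[(0, 500)],
                                 intron_chain=(), abundance=1.0,
                                 support=np.ones(1), origin=0, vertex_path=(0,))
    assert label_candidates([single], truth, [np.zeros(50)]) == []
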