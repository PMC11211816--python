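"""Fragment bridging, the bottleneck objective, and graph refinement."""

import numpy as np
import pytest

from metassemble.alignment_io import AlignedRead, Fragment
from metassemble.bridging import PhasingPath, bridge_all, bridge_fragment, refine_graph
from metassemble.clustering import Cluster, build_combined
from metassemble.pipeline import RunConfig, sample_loci
from metassemble.simulate import SimConfig, simulate_reads, simulate_transcriptome
from metassemble.splice_graph import augment_source_sink, build_graph
from conftest import make_graph


def _read(name, blocks, junctions=None, sample=0, first=True):
    return AlignedRead(sample_id=sample, query_name=name, chrom="chr1", strand="+",
                       blocks=blocks, junctions=junctions or [], is_first_mate=first)


def _pair(blocks1, blocks2, j1=None, j2=None, name="f"):
    return Fragment(
        read1=_read(name, blocks1, j1),
        read2=_read(name, blocks2, j2, first=False),
    )


def chain_graph():
    return make_graph(
        [(0, 100), (200, 300), (400, 500)],
        junctions=[(0, 1, 5), (1, 2, 5)],
    )


def test_bridge_unique_path():
    g = chain_graph()
    f = _pair([(10, 60)], [(420, 470)])
    p = bridge_fragment(f, g)
    assert p is not None and list(p.vertex_seq) == [0, 1, 2]


def test_bridge_failure_without_path():
    g = make_graph(
        [(0, 100), (200, 300), (400, 500)],
        junctions=[(0, 1, 5)],  # no route from vertex 1 to vertex 2
    )
    f = _pair([(10, 60)], [(420, 470)])
    assert bridge_fragment(f, g) is None


def test_bridge_failure_on_foreign_junction():
    g = chain_graph()
    f = _pair([(10, 60), (410, 460)], [(470, 490)], j1=[(60, 410)])
    assert bridge_fragment(f, g) is None  # read1's junction is absent from g


def test_bottleneck_objective_prefers_heavy_branch():
    """Diamond v1->{v2,v3}->v4 with w(v1,v2)=9 and w(v1,v3)=1: the
    connecting path must run through v2."""
    g = make_graph(
        [(0, 100), (200, 300), (400, 500), (600, 700)],
        junctions=[(0, 1, 9), (0, 2, 1), (1, 3, 5), (2, 3, 5)],
    )
    f = _pair([(10, 60)], [(620, 670)])
    p = bridge_fragment(f, g)
    assert list(p.vertex_seq) == [0, 1, 3]


def test_bridge_overlapping_mates_merge():
    g = chain_graph()
    f = _pair([(10, 100), (200, 240)], [(220, 300), (400, 440)],
              j1=[(100, 200)], j2=[(300, 400)])
    p = bridge_fragment(f, g)
    assert list(p.vertex_seq) == [0, 1, 2]


def test_bridge_respects_max_span():
    g = chain_graph()
    f = _pair([(10, 60)], [(420, 470)])
    assert bridge_fragment(f, g, max_span=100) is None


def test_refine_restores_missing_junction():
    """A graph lacking junction (150,1150) regains it, with weight equal to
    the rescued fragment count, when rescued combined-graph paths cross it."""
    frags = [Fragment(read1=_read("a", [(100, 150)]), read2=_read("a", [(1150, 1200)], first=False))
             for _ in range(2)]
    g = build_graph(frags, sample_id=0)
    augment_source_sink(g)
    assert (150, 1150) not in g.junction_weight_map()
    gm = make_graph([(100, 150), (1150, 1200)], junctions=[(0, 1, 4)], sample_id=-100)
    rescued = [bridge_fragment(f, gm) for f in frags]
    assert all(r is not None for r in rescued)
    g2, restored = refine_graph(g, rescued, gm, frags)
    assert restored == {(150, 1150): 2}
    assert g2.junction_weight_map()[(150, 1150)] == 2.0


def test_refine_empty_rescue_is_identity():
    g = chain_graph()
    gm = chain_graph()
    g2, restored = refine_graph(g, [], gm, [])
    assert g2 is g and restored == {}


def _two_sample_rescue_cluster():
    """Sample 0 lacks the middle junction that sample 1 covers; sample 0
    still has fragment pairs straddling it."""
    j = (150, 1150)
    s0 = [
        Fragment(read1=_read("a%d" % i, [(100, 150)], sample=0),
                 read2=_read("a%d" % i, [(1150, 1200)], sample=0, first=False))
        for i in range(3)
    ]
    s1 = [
        Fragment(read1=_read("b%d" % i, [(100, 150), (1150, 1200)], [j], sample=1))
        for i in range(4)
    ]
    g0 = build_graph(s0, sample_id=0)
    g1 = build_graph(s1, sample_id=1)
    augment_source_sink(g0)
    augment_source_sink(g1)
    cluster = Cluster(members=[(0, g0), (1, g1)], member_fragments=[s0, s1])
    build_combined(cluster)
    return cluster, j


def test_two_stage_rescue_reproduces_missing_junction_scenario():
    cluster, j = _two_sample_rescue_cluster()
    assert j not in cluster.members[0][1].junction_weight_map()
    assert j in cluster.combined.junction_weight_map()
    res = bridge_all(cluster)
    assert res.n_stage2 == 3
    refined0 = cluster.members[0][1]
    assert refined0.junction_weight_map()[j] == 3.0
    assert res.rescued_junctions[0] == {j: 3}
    # after refinement the fragments phase through the restored junction
    assert any(len(p.vertex_seq) >= 2 for p in res.h_members[0])


def test_stage1_priority_never_rebridges(rng):
    """Fragments bridgeable in their own graph are all accounted to stage 1."""
    cfg = SimConfig(n_loci=3, n_samples=2, sharing_fraction=1.0, depth=10.0, seed=9)
    ts, truth = simulate_transcriptome(cfg)
    samples = simulate_reads(cfg, ts, truth)
    graphs, frag_lists = [], []
    for s in samples:
        loci = sample_loci(s.fragments, RunConfig())
        big = max(loci, key=lambda l: sum(len(v) for v in l.fragments_by_sample.values()))
        frs = big.fragments_by_sample[s.sample_id]
        g = build_graph(frs, chrom=big.chrom, strand=big.strand, sample_id=s.sample_id)
        augment_source_sink(g)
        graphs.append((s.sample_id, g))
        frag_lists.append(frs)
    cluster = Cluster(members=graphs, member_fragments=frag_lists)
    build_combined(cluster)
    res = bridge_all(cluster)
    total = sum(len(f) for f in frag_lists)
    assert res.n_stage1 + res.n_stage2 + res.n_unbridged == total
    assert res.n_stage1 > 0


def test_phasing_paths_are_connected_and_consistent():
    cluster, _ = _two_sample_rescue_cluster()
    res = bridge_all(cluster)
    for k, (_, g) in enumerate(cluster.members):
        for p in res.h_members[k]:
            assert p.count >= 1
            for u, v in p.edge_seq():
                assert (u, v) in g.edges
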