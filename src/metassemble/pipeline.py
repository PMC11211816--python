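"""End-to-end orchestration: alignments -> scored meta-transcripts.

Stages: read loading -> per-sample locus bundling -> splice graphs ->
cross-sample clustering -> combined graphs -> two-stage bridging and
refinement -> edge supports -> phase-preserving decomposition of every
member graph and the combined graph -> feature extraction -> scoring ->
meta-transcript aggregation -> GTF emission.  Clusters are independent
of one another, so the loop over clusters is the natural
parallelization boundary; execution here is single-process and output
is post-sorted, keeping results byte-identical regardless of order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment_io import Fragment, Locus, bundle_loci, pair_fragments, parse_alignments, read_manifest
from .bridging import bridge_all
from .clustering import Cluster, build_combined, cluster_graphs
from .decomposition import CandidateTranscript, decompose_graph
from .edge_support import compute_supports
from .features import compute_features, label_candidates
from .gtf import read_gtf
from .scoring import (
    DEFAULT_THRESHOLD,
    MetaTranscript,
    ScoringModel,
    aggregate_meta,
    filter_and_emit,
    score_candidates,
    train_model,
)
from .splice_graph import SpliceGraph, augment_source_sink, build_graph

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bundle_gap: int = 50
    min_similarity: float = 0.1
    size_cap: Optional[int] = None  # default: number of input samples
    max_boundary_ext: int = 200
    max_bridge_span: int = 500_000
    min_junction_support: int = 1
    min_mapq: int = 0
    score_threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def validate(self) -> None:
        if self.bundle_gap < 1 or self.max_boundary_ext < 0 or self.max_bridge_span < 1:
            raise ValueError("invalid run configuration")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")


@dataclass
class AssemblyStats:
    n_graphs: int = 0
    n_clusters: int = 0
    n_stage1: int = 0
    n_stage2: int = 0
    n_unbridged: int = 0
    n_restored_junctions: int = 0
    n_candidates: int = 0
    n_metas: int = 0

    def log_summary(self) -> None:
        log.info(
            "graphs=%d clusters=%d bridged(stage1=%d stage2=%d unbridged=%d) "
            "restored_junctions=%d candidates=%d metas=%d",
            self.n_graphs, self.n_clusters, self.n_stage1, self.n_stage2,
            self.n_unbridged, self.n_restored_junctions, self.n_candidates, self.n_metas,
        )


def load_fragments(manifest_path: str, cfg: RunConfig) -> list[list[Fragment]]:
    """Parse each manifest entry into per-sample fragment lists."""
    out: list[list[Fragment]] = []
    for sid, (path, _label) in enumerate(read_manifest(manifest_path)):
        by_chrom: dict[str, list] = {}
        for r in parse_alignments(path, sid, min_mapq=cfg.min_mapq):
            by_chrom.setdefault(r.chrom, []).append(r)
        frags: list[Fragment] = []
        for chrom in sorted(by_chrom):
            frags.extend(pair_fragments(by_chrom[chrom]))
        out.append(frags)
    return out


def _overlap(span: tuple[int, int], loci: Sequence[Locus]) -> int:
    return sum(max(0, min(span[1], l.span[1]) - max(span[0], l.span[0])) for l in loci)


def sample_loci(fragments: Sequence[Fragment], cfg: RunConfig) -> list[Locus]:
    """Bundle one sample's fragments into loci per (chrom, strand).

    Unstranded fragments join the strand whose loci they overlap most;
    any left over form their own '.' loci."""
    loci: list[Locus] = []
    by_chrom: dict[str, list[Fragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom in sorted(by_chrom):
        frs = by_chrom[chrom]
        stranded = {s: sorted([f for f in frs if f.strand == s], key=lambda f: (f.start, f.end)) for s in "+-"}
        dots = sorted([f for f in frs if f.strand == "."], key=lambda f: (f.start, f.end))
        pre = {s: bundle_loci(stranded[s], gap=cfg.bundle_gap) for s in "+-"}
        leftover: list[Fragment] = []
        extra: dict[str, list[Fragment]] = {"+": [], "-": []}
        for f in dots:
            op = _overlap((f.start, f.end), pre["+"])
            om = _overlap((f.start, f.end), pre["-"])
            if op == om == 0:
                leftover.append(f)
            elif op >= om:
                extra["+"].append(f)
            else:
                extra["-"].append(f)
        for s in "+-":
            merged = sorted(stranded[s] + extra[s], key=lambda f: (f.start, f.end))
            for locus in bundle_loci(merged, gap=cfg.bundle_gap):
                locus.strand = s
                loci.append(locus)
        for locus in bundle_loci(leftover, gap=cfg.bundle_gap):
            locus.strand = "."
            loci.append(locus)
    return loci


def _super_groups(all_loci: list[tuple[int, Locus]]) -> list[list[tuple[int, Locus]]]:
    """Merge genomically overlapping loci across samples per (chrom, strand)."""
    groups: list[list[tuple[int, Locus]]] = []
    by_key: dict[tuple[str, str], list[tuple[int, Locus]]] = {}
    for sid, locus in all_loci:
        by_key.setdefault((locus.chrom, locus.strand), []).append((sid, locus))
    for key in sorted(by_key):
        items = sorted(by_key[key], key=lambda x: (x[1].span, x[0]))
        cur: list[tuple[int, Locus]] = []
        cur_end = -1
        for sid, locus in items:
            if cur and locus.span[0] >= cur_end:
                groups.append(cur)
                cur = []
                cur_end = -1
            cur.append((sid, locus))
            cur_end = max(cur_end, locus.span[1])
        if cur:
            groups.append(cur)
    return groups


def assemble_candidates(
    fragments_by_sample: Sequence[Sequence[Fragment]],
    cfg: Optional[RunConfig] = None,
) -> tuple[list[CandidateTranscript], list[np.ndarray], AssemblyStats]:
    """Run every stage up to (but excluding) scoring.

    Returns candidates from every member graph and every combined
    graph, their 50-feature rows, and per-stage counters.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    n_samples = len(fragments_by_sample)
    size_cap = cfg.size_cap or max(1, n_samples)

    all_loci: list[tuple[int, Locus]] = []
    for sid, frags in enumerate(fragments_by_sample):
        for locus in sample_loci(frags, cfg):
            all_loci.append((sid, locus))

    stats = AssemblyStats()
    candidates: list[CandidateTranscript] = []
    feature_rows: list[np.ndarray] = []

    for group in _super_groups(all_loci):
        graphs: list[tuple[int, SpliceGraph]] = []
        frag_lists: list[list[Fragment]] = []
        for sid, locus in group:
            frs = locus.fragments_by_sample.get(sid, [])
            g = build_graph(
                frs,
                min_junction_support=cfg.min_junction_support,
                bundle_gap=cfg.bundle_gap,
                chrom=locus.chrom,
                strand=locus.strand,
                sample_id=sid,
            )
            if not g.vertices:
                continue
            augment_source_sink(g)
            graphs.append((sid, g))
            frag_lists.append(list(frs))
        if not graphs:
            continue
        stats.n_graphs += len(graphs)
        clusters = cluster_graphs(graphs, size_cap=size_cap, min_similarity=cfg.min_similarity, fragments=frag_lists)
        for cluster in clusters:
            stats.n_clusters += 1
            _process_cluster(cluster, cfg, stats, candidates, feature_rows)

    stats.n_candidates = len(candidates)
    return candidates, feature_rows, stats


def _process_cluster(
    cluster: Cluster,
    cfg: RunConfig,
    stats: AssemblyStats,
    candidates: list[CandidateTranscript],
    feature_rows: list[np.ndarray],
) -> None:
    gm = build_combined(cluster, min_junction_support=cfg.min_junction_support, bundle_gap=cfg.bundle_gap)
    bres = bridge_all(
        cluster,
        max_span=cfg.max_bridge_span,
        min_junction_support=cfg.min_junction_support,
        bundle_gap=cfg.bundle_gap,
    )
    stats.n_stage1 += bres.n_stage1
    stats.n_stage2 += bres.n_stage2
    stats.n_unbridged += bres.n_unbridged
    stats.n_restored_junctions += sum(len(r) for r in bres.rescued_junctions)

    supports = compute_supports(cluster, max_ext=cfg.max_boundary_ext)
    member_cands: list[list[CandidateTranscript]] = []
    for k, (sid, g) in enumerate(cluster.members):
        member_cands.append(decompose_graph(g, supports.members[k], bres.h_members[k]))
    gm_cands = decompose_graph(gm, supports.combined, bres.h_combined)

    ind_best: dict[tuple, float] = {}
    for cands in member_cands:
        for t in cands:
            if t.intron_chain:
                key = (t.chrom, t.strand, t.intron_chain)
                ind_best[key] = max(ind_best.get(key, 0.0), t.abundance)
    gm_best: dict[tuple, float] = {}
    for t in gm_cands:
        if t.intron_chain:
            key = (t.chrom, t.strand, t.intron_chain)
            gm_best[key] = max(gm_best.get(key, 0.0), t.abundance)

    nfrag = sum(len(fr) for fr in cluster.member_fragments)
    for k, (sid, g) in enumerate(cluster.members):
        for t in member_cands[k]:
            cp = gm_best.get((t.chrom, t.strand, t.intron_chain)) if t.intron_chain else None
            feature_rows.append(
                compute_features(t, g, gm, cluster, supports.members[k], counterpart_abundance=cp,
                                 locus_fragments=nfrag, n_graph_paths=len(member_cands[k]))
            )
            candidates.append(t)
    for t in gm_cands:
        cp = ind_best.get((t.chrom, t.strand, t.intron_chain)) if t.intron_chain else None
        feature_rows.append(
            compute_features(t, gm, gm, cluster, supports.combined, counterpart_abundance=cp,
                             locus_fragments=nfrag, n_graph_paths=len(gm_cands))
        )
        candidates.append(t)


def assemble(
    fragments_by_sample: Sequence[Sequence[Fragment]],
    model: ScoringModel,
    cfg: Optional[RunConfig] = None,
    out_gtf: Optional[str] = None,
    threshold: Optional[float] = None,
) -> tuple[list[MetaTranscript], AssemblyStats]:
    """Full assembly: candidates -> scores -> meta-transcripts -> GTF."""
    cfg = cfg or RunConfig()
    ts, feats, stats = assemble_candidates(fragments_by_sample, cfg)
    scored = score_candidates(ts, feats, model)
    metas = aggregate_meta(scored)
    kept = filter_and_emit(metas, path=out_gtf, threshold=threshold if threshold is not None else cfg.score_threshold)
    stats.n_metas = len(kept)
    stats.log_summary()
    return kept, stats


def synthetic_training_rows(
    seed: int = 0,
    n_fixtures: int = 12,
    n_loci: int = 60,
    cfg: Optional[RunConfig] = None,
) -> list[tuple[np.ndarray, int]]:
    """Labeled feature rows from a bank of simulated fixtures.

    Fixtures alternate between sharing fractions 0.5 and 0.9 — samples
    with half-shared transcript sets produce the harder, more divergent
    loci a scorer must learn to reject, while highly shared sets cover
    the clean regime.  Every fixture seed derives from ``seed``.
    """
    from .simulate import SimConfig, simulate_reads, simulate_transcriptome

    cfg = cfg or RunConfig()
    rows: list[tuple[np.ndarray, int]] = []
    for i in range(n_fixtures):
        p = 0.5 if i % 2 == 0 else 0.9
        scfg = SimConfig(
            n_loci=n_loci, transcripts_per_locus=4, n_samples=5,
            sharing_fraction=p, depth=20.0, seed=(seed * 101 + 11 + 2 * i) % (2**31),
        )
        ts, truth = simulate_transcriptome(scfg)
        samples = simulate_reads(scfg, ts, truth)
        cands, feats, _ = assemble_candidates([s.fragments for s in samples], cfg)
        rows.extend(label_candidates(cands, [t.key for t in ts], feats))
    return rows


def train_reference_model(seed: int = 0, n_fixtures: int = 12, n_loci: int = 60) -> ScoringModel:
    """The model the package ships its benchmarks with: trained on the
    synthetic fixture bank, seeded end to end."""
    rows = synthetic_training_rows(seed=seed, n_fixtures=n_fixtures, n_loci=n_loci)
    return train_model(rows, seed=seed)


def train(
    fragments_by_sample: Sequence[Sequence[Fragment]],
    annotation_gtf: str,
    cfg: Optional[RunConfig] = None,
    seed: int = 0,
) -> ScoringModel:
    """Assemble candidates, label them against an annotation by exact
    intron-chain match, and fit the random-forest scorer."""
    cfg = cfg or RunConfig()
    ts, feats, _stats = assemble_candidates(fragments_by_sample, cfg)
    truth = [t.key for t in read_gtf(annotation_gtf)]
    rows = label_candidates(ts, truth, feats)
    if not rows:
        raise ValueError("no multi-exon candidates to train on")
    return train_model(rows, seed=seed)
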