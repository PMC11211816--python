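"""Ground-truthed multi-sample RNA-seq simulation.

Generates random multi-exon gene models, per-sample ground truths where
each sample expresses a fraction ``p`` of the transcript set, and
paired-end reads emitted as perfect spliced alignments (SAM written
directly; the assembler under test starts from alignments, so no
sequence-level error model is applied).  Junction dropout removes every
read of a sample that spans a designated junction, manufacturing the
missing-junction scenarios that stage-2 bridging must rescue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .alignment_io import AlignedRead, Fragment
from .gtf import write_gtf


@dataclass
class SimTranscript:
    tid: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1))

    @property
    def key(self):
        return (self.chrom, self.strand, self.intron_chain)


@dataclass
class SimConfig:
    n_loci: int = 30
    transcripts_per_locus: int = 4
    n_samples: int = 5
    sharing_fraction: float = 0.9  # p: fraction of the set each sample expresses
    read_length: int = 100
    frag_mean: float = 300.0
    frag_sd: float = 50.0
    depth: float = 20.0  # mean per-transcript coverage
    expr_mu: float = 1.0  # log-normal expression parameters
    expr_sigma: float = 1.0
    junction_dropout_rate: float = 0.0
    seed: int = 0
    chrom: str = "chr1"
    locus_gap: int = 10_000
    exon_range: tuple[int, int] = (80, 600)
    intron_range: tuple[int, int] = (200, 5000)
    exons_per_gene: tuple[int, int] = (3, 12)

    def __post_init__(self) -> None:
        if not 0.0 < self.sharing_fraction <= 1.0:
            raise ValueError("sharing_fraction must be in (0, 1]")
        if not 0.0 <= self.junction_dropout_rate <= 1.0:
            raise ValueError("junction_dropout_rate must be in [0, 1]")


def simulate_transcriptome(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> tuple[list[SimTranscript], list[set[str]]]:
    """Random gene models plus per-sample expressed subsets.

    Each gene has an exon skeleton; transcripts are ordered subsets of
    the skeleton (first and last exon always kept, internal exons kept
    with probability 0.7), deduplicated by intron chain, so isoforms of
    a gene share junctions the way alternatively spliced isoforms do.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    transcripts: list[SimTranscript] = []
    pos = 1000
    for li in range(cfg.n_loci):
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons: list[tuple[int, int]] = []
        cur = pos
        for _ in range(n_ex):
            elen = int(rng.integers(cfg.exon_range[0], cfg.exon_range[1] + 1))
            exons.append((cur, cur + elen))
            cur += elen + int(rng.integers(cfg.intron_range[0], cfg.intron_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{li:04d}"
        seen_chains = set()
        k = 0
        for _ in range(cfg.transcripts_per_locus):
            keep = [0] + [i for i in range(1, n_ex - 1) if rng.random() < 0.7] + [n_ex - 1]
            chain = tuple(keep)
            if chain in seen_chains:
                continue
            seen_chains.add(chain)
            transcripts.append(
                SimTranscript(
                    tid=f"{gene_id}.T{k}",
                    gene_id=gene_id,
                    chrom=cfg.chrom,
                    strand=strand,
                    exons=[exons[i] for i in keep],
                )
            )
            k += 1
        pos = exons[-1][1] + cfg.locus_gap
    truth_per_sample = []
    for _ in range(cfg.n_samples):
        truth_per_sample.append({t.tid for t in transcripts if rng.random() < cfg.sharing_fraction})
    return transcripts, truth_per_sample


def _genomic_blocks(t: SimTranscript, tstart: int, tend: int) -> list[tuple[int, int]]:
    """Map transcript-coordinate interval [tstart, tend) to genome blocks."""
    blocks = []
    off = 0
    for s, e in t.exons:
        elen = e - s
        lo, hi = max(tstart - off, 0), min(tend - off, elen)
        if lo < hi:
            blocks.append((s + lo, s + hi))
        off += elen
    return blocks


def _junctions_of(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]


@dataclass
class SimulatedSample:
    sample_id: int
    fragments: list[Fragment] = field(default_factory=list)
    dropped_junctions: set[tuple[int, int]] = field(default_factory=set)


def simulate_reads(
    cfg: SimConfig,
    transcripts: Sequence[SimTranscript],
    truth_per_sample: Sequence[set[str]],
    rng: Optional[np.random.Generator] = None,
) -> list[SimulatedSample]:
    """Paired-end fragments per sample with exact spliced coordinates.

    Per-sample, per-transcript expression is log-normal; the fragment
    count targets ``depth`` x (expression / mean expression) coverage.
    Junction dropout removes read pairs in which either mate spans a
    dropped junction; pairs whose insert gap merely straddles it are
    kept, which is exactly the material stage-2 bridging rescues.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    by_tid = {t.tid: t for t in transcripts}
    mean_expr = float(np.exp(cfg.expr_mu + cfg.expr_sigma**2 / 2))
    samples = []
    for sid, truth in enumerate(truth_per_sample):
        sample = SimulatedSample(sample_id=sid)
        if cfg.junction_dropout_rate > 0:
            juncs = sorted({j for tid in truth for j in by_tid[tid].intron_chain})
            for j in juncs:
                if rng.random() < cfg.junction_dropout_rate:
                    sample.dropped_junctions.add(j)
        ri = 0
        expr_by_tid = {tid: float(rng.lognormal(cfg.expr_mu, cfg.expr_sigma)) for tid in sorted(truth)}
        for tid in sorted(truth):
            t = by_tid[tid]
            if t.length < cfg.read_length + 1:
                continue
            expr = expr_by_tid[tid]
            cov = cfg.depth * expr / mean_expr
            n_frags = max(1, int(round(cov * t.length / (2 * cfg.read_length))))
            for _ in range(n_frags):
                flen = int(round(rng.normal(cfg.frag_mean, cfg.frag_sd)))
                flen = int(np.clip(flen, cfg.read_length, t.length))
                start = int(rng.integers(0, t.length - flen + 1))
                b1 = _genomic_blocks(t, start, start + cfg.read_length)
                b2 = _genomic_blocks(t, start + flen - cfg.read_length, start + flen)
                j1, j2 = _junctions_of(b1), _junctions_of(b2)
                if sample.dropped_junctions and (
                    set(j1) & sample.dropped_junctions or set(j2) & sample.dropped_junctions
                ):
                    continue
                qname = f"s{sid}r{ri}"
                ri += 1
                r1 = AlignedRead(sample_id=sid, query_name=qname, chrom=t.chrom, strand=t.strand,
                                 blocks=b1, junctions=j1, is_first_mate=True)
                r2 = AlignedRead(sample_id=sid, query_name=qname, chrom=t.chrom, strand=t.strand,
                                 blocks=b2, junctions=j2, is_first_mate=False)
                sample.fragments.append(Fragment(read1=r1, read2=r2))
        sample.fragments.sort(key=lambda f: (f.start, f.end))
        samples.append(sample)
    return samples


def _cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def write_sam(sample: SimulatedSample, path: str, chrom_sizes: dict[str, int]) -> None:
    """Write a sample's fragments as a coordinate-sorted SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chrom_sizes.items())],
    }
    recs = []
    for f in sample.fragments:
        for r, mate in ((f.read1, f.read2), (f.read2, f.read1)):
            if r is None:
                continue
            recs.append((r, mate))
    recs.sort(key=lambda rm: (rm[0].chrom, rm[0].start))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r, mate in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.query_name
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = _cigar(r.blocks)
            a.query_sequence = "A" * sum(e - s for s, e in r.blocks)
            flag = 0x1 | 0x2
            flag |= 0x40 if r.is_first_mate else 0x80
            if mate is not None:
                a.next_reference_name = mate.chrom
                a.next_reference_start = mate.start
                if r.start <= mate.start:
                    a.template_length = mate.end - r.start
                else:
                    a.template_length = -(r.end - mate.start)
                flag |= 0x20 if r.strand == "-" else 0  # mate orientation is synthetic
            a.flag = flag
            a.set_tag("XS", r.strand)
            out.write(a)


def end_to_end_fixture(cfg: SimConfig, outdir: str) -> dict[str, object]:
    """Write a complete bundle: SAM per sample, truth.gtf, manifest.txt,
    sample_truth.tsv and expected_rescues.tsv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    transcripts, truth = simulate_transcriptome(cfg)
    samples = simulate_reads(cfg, transcripts, truth)
    span = max(t.exons[-1][1] for t in transcripts) + 1000
    chrom_sizes = {cfg.chrom: span}
    sam_paths = []
    for s in samples:
        p = out / f"sample_{s.sample_id}.sam"
        write_sam(s, str(p), chrom_sizes)
        sam_paths.append(str(p))
    write_gtf(
        [(t.chrom, t.strand, t.gene_id, t.tid, t.exons, {}) for t in transcripts],
        str(out / "truth.gtf"),
    )
    with open(out / "manifest.txt", "w") as fh:
        for i, p in enumerate(sam_paths):
            fh.write(f"{p}\tsample_{i}\n")
    with open(out / "sample_truth.tsv", "w") as fh:
        fh.write("sample_id\ttranscript_id\n")
        for sid, tids in enumerate(truth):
            for tid in sorted(tids):
                fh.write(f"{sid}\t{tid}\n")
    with open(out / "expected_rescues.tsv", "w") as fh:
        fh.write("sample_id\tdonor\tacceptor\n")
        for s in samples:
            for d, a in sorted(s.dropped_junctions):
                fh.write(f"{s.sample_id}\t{d}\t{a}\n")
    return {
        "transcripts": transcripts,
        "truth_per_sample": truth,
        "samples": samples,
        "sam_paths": sam_paths,
        "truth_gtf": str(out / "truth.gtf"),
        "manifest": str(out / "manifest.txt"),
    }
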