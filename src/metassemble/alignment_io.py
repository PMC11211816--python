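"""Alignment input: reads, mate pairing, and gene-locus bundling.

Coordinates are 0-based half-open throughout the package; a junction is
the pair ``(donor, acceptor)`` where ``donor`` is the half-open end of
the left flanking block and ``acceptor`` the start of the right one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import pysam

log = logging.getLogger(__name__)

# CIGAR operation codes that consume the reference.
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_SKIP = 3  # N


@dataclass
class AlignedRead:
    """One primary alignment reduced to its genomic footprint."""

    sample_id: int
    query_name: str
    chrom: str
    strand: str  # '+', '-' or '.'
    blocks: list[tuple[int, int]]
    junctions: list[tuple[int, int]]
    is_first_mate: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class Fragment:
    """A sequenced fragment: one read or a mate pair (read1 left of read2)."""

    read1: AlignedRead
    read2: Optional[AlignedRead] = None
    bridged_path: object = None  # PhasingPath once bridged

    @property
    def start(self) -> int:
        return self.read1.start

    @property
    def end(self) -> int:
        return self.read2.end if self.read2 is not None else self.read1.end

    @property
    def chrom(self) -> str:
        return self.read1.chrom

    @property
    def strand(self) -> str:
        s = self.read1.strand
        if s == "." and self.read2 is not None:
            return self.read2.strand
        return s

    def reads(self) -> list[AlignedRead]:
        return [self.read1] if self.read2 is None else [self.read1, self.read2]

    def junctions(self) -> list[tuple[int, int]]:
        out = list(self.read1.junctions)
        if self.read2 is not None:
            out.extend(self.read2.junctions)
        return out


@dataclass
class Locus:
    """All fragments of one gene locus on one (chrom, strand)."""

    chrom: str
    strand: str
    span: tuple[int, int]
    fragments_by_sample: dict[int, list[Fragment]] = field(default_factory=dict)

    def all_fragments(self) -> list[Fragment]:
        out: list[Fragment] = []
        for sid in sorted(self.fragments_by_sample):
            out.extend(self.fragments_by_sample[sid])
        return out


def blocks_from_cigar(pos: int, cigartuples: Sequence[tuple[int, int]]) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split an alignment into reference blocks and N-gap junctions."""
    blocks: list[tuple[int, int]] = []
    junctions: list[tuple[int, int]] = []
    cur = pos
    block_start = pos
    open_block = False
    for op, length in cigartuples:
        if op in _REF_CONSUMING:
            if not open_block:
                block_start = cur
                open_block = True
            cur += length
        elif op == _SKIP:
            if open_block:
                blocks.append((block_start, cur))
                open_block = False
            junctions.append((cur, cur + length))
            cur += length
        # insertions and clips consume no reference
    if open_block:
        blocks.append((block_start, cur))
    return blocks, junctions


def parse_alignments(
    path: str,
    sample_id: int,
    min_mapq: int = 0,
    chrom: Optional[str] = None,
) -> Iterator[AlignedRead]:
    """Stream primary alignments of one sample as :class:`AlignedRead`.

    Secondary, supplementary and unmapped records are skipped; records
    below ``min_mapq`` are skipped.  Strand comes from the ``XS`` tag
    when present, else '.'.  Malformed (reference-free) CIGARs are
    counted and skipped rather than raised.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    skipped = 0
    with pysam.AlignmentFile(str(path), mode) as af:
        for rec in af.fetch(contig=chrom, until_eof=True) if chrom is None else af.fetch(chrom):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if not rec.cigartuples:
                skipped += 1
                continue
            blocks, junctions = blocks_from_cigar(rec.reference_start, rec.cigartuples)
            if not blocks:
                skipped += 1
                continue
            strand = "."
            if rec.has_tag("XS"):
                strand = rec.get_tag("XS")
            yield AlignedRead(
                sample_id=sample_id,
                query_name=rec.query_name,
                chrom=rec.reference_name,
                strand=strand,
                blocks=blocks,
                junctions=junctions,
                is_first_mate=not rec.is_read2,
            )
    if skipped:
        log.warning("%s: skipped %d records with unusable CIGAR", path, skipped)


def pair_fragments(reads: Iterator[AlignedRead] | Sequence[AlignedRead]) -> list[Fragment]:
    """Match mates by query name; unmatched reads become single-read fragments.

    If more than two primary records share a name, the two leftmost are
    kept as the pair and the rest dropped with a warning.
    """
    by_name: dict[str, list[AlignedRead]] = {}
    order: list[str] = []
    for r in reads:
        if r.query_name not in by_name:
            order.append(r.query_name)
        by_name.setdefault(r.query_name, []).append(r)
    frags: list[Fragment] = []
    for name in order:
        group = sorted(by_name[name], key=lambda r: (r.start, r.end))
        if len(group) > 2:
            log.warning("query %s has %d primary records; keeping leftmost pair", name, len(group))
            group = group[:2]
        if len(group) == 2:
            frags.append(Fragment(read1=group[0], read2=group[1]))
        else:
            frags.append(Fragment(read1=group[0]))
    frags.sort(key=lambda f: (f.start, f.end))
    return frags


def bundle_loci(fragments: Sequence[Fragment], gap: int = 50) -> list[Locus]:
    """Partition fragments into loci separated by >= ``gap`` uncovered bases.

    Fragments must arrive sorted by leftmost coordinate and belong to a
    single (chrom, strand) group; the footprint used for bundling is the
    full fragment span (mate gap included), so a pair never straddles
    two loci.
    """
    loci: list[Locus] = []
    cur: list[Fragment] = []
    cur_end = None
    for f in fragments:
        if cur_end is not None and f.start >= cur_end + gap:
            loci.append(_make_locus(cur))
            cur = []
            cur_end = None
        cur.append(f)
        cur_end = f.end if cur_end is None else max(cur_end, f.end)
    if cur:
        loci.append(_make_locus(cur))
    return loci


def _make_locus(fragments: list[Fragment]) -> Locus:
    chrom = fragments[0].chrom
    strand = fragments[0].strand
    span = (min(f.start for f in fragments), max(f.end for f in fragments))
    by_sample: dict[int, list[Fragment]] = {}
    for f in fragments:
        by_sample.setdefault(f.read1.sample_id, []).append(f)
    return Locus(chrom=chrom, strand=strand, span=span, fragments_by_sample=by_sample)


def read_manifest(path: str) -> list[tuple[str, str]]:
    """Read a plain-text manifest: one alignment path per line, optional
    tab-separated sample label."""
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            label = parts[1] if len(parts) > 1 else parts[0]
            entries.append((parts[0], label))
    return entries
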