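"""Minimal GTF input/output.

Internal coordinates are 0-based half-open; GTF is written and read as
1-based inclusive (single conversion point, here).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


@dataclass
class GtfTranscript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted
    attributes: dict[str, str]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1))

    @property
    def key(self) -> tuple[str, str, tuple[tuple[int, int], ...]]:
        return (self.chrom, self.strand, self.intron_chain)


def read_gtf(path: str) -> list[GtfTranscript]:
    """Collect transcripts from the exon records of a GTF file."""
    by_tid: dict[str, GtfTranscript] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            tid = attrs.get("transcript_id", "")
            start = int(parts[3]) - 1
            end = int(parts[4])
            if tid not in by_tid:
                by_tid[tid] = GtfTranscript(
                    transcript_id=tid,
                    gene_id=attrs.get("gene_id", tid),
                    chrom=parts[0],
                    strand=parts[6],
                    exons=[],
                    attributes=attrs,
                )
                order.append(tid)
            by_tid[tid].exons.append((start, end))
    out = []
    for tid in order:
        t = by_tid[tid]
        t.exons.sort()
        out.append(t)
    return out


def write_gtf(
    records: Iterable[tuple[str, str, str, str, Sequence[tuple[int, int]], dict]],
    path: str,
    source: str = "metassemble",
) -> None:
    """Write (chrom, strand, gene_id, transcript_id, exons, attrs) records."""
    with open(path, "w") as fh:
        for chrom, strand, gid, tid, exons, attrs in records:
            attr_str = f'gene_id "{gid}"; transcript_id "{tid}";'
            for k, v in attrs.items():
                attr_str += f' {k} "{v}";'
            start, end = exons[0][0] + 1, exons[-1][1]
            fh.write(f"{chrom}\t{source}\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t{attr_str}\n")
            for s, e in exons:
                fh.write(f"{chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr_str}\n")
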