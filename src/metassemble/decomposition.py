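"""Phase-preserving decomposition of splice graphs into transcripts.

The graph is reduced vertex by vertex until only parallel source-sink
edges remain; each surviving edge, with the interior vertices recorded
on it, is one candidate transcript.  Two principles govern every vertex
decomposition:

1. *Phase preservation* — a phasing path is never broken: whenever a
   path threads in-edge, vertex, out-edge, that in/out pair is realized
   as a new edge, so every phasing path survives contiguously in at
   least one output transcript.
2. *Support guidance* — in/out edges of a complex vertex that no
   phasing path touches (isolated in the bipartite pairing graph) are
   paired with the counterpart maximizing the summed composed support
   across samples.

Weights reallocate proportionally: each in-edge's weight is split over
its paired out-edges in proportion to their weights, which conserves
the total weight leaving the source exactly, so the final edge weights
are the inferred transcript abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bridging import PhasingPath
from .edge_support import compose_support
from .splice_graph import SOURCE, SINK, SpliceGraph

log = logging.getLogger(__name__)


@dataclass
class CandidateTranscript:
    """An s-t path extracted from a decomposed graph."""

    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    intron_chain: tuple[tuple[int, int], ...]
    abundance: float
    support: np.ndarray
    origin: int  # sample_id or COMBINED
    vertex_path: tuple[int, ...]
    score: Optional[float] = None
    n_merges: int = 0
    n_phased_merges: int = 0
    n_guessed_merges: int = 0
    guess_margin_min: float = 1.0

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class _Path:
    """A phasing path during decomposition: a definite edge sequence
    plus optional disjunctive ends.

    When a vertex at one end of the path is decomposed, the path's
    terminal edge is absorbed into several merged edges; the fragment
    only witnessed the terminal edge itself, so the path then asserts
    *one of* those merged edges (``trail``/``lead`` candidate sets, a
    disjunction pending at the neighbouring vertex), not a specific
    continuation.  Treating the end conjunctively would fabricate
    phasing evidence and assemble chimeric transcripts.
    """

    seq: list[int]
    count: int = 1
    lead: Optional[set[int]] = None  # candidates preceding seq[0]
    trail: Optional[set[int]] = None  # candidates following seq[-1]

    # When both ends have been absorbed (seq empty) the path degenerates
    # to a *join*: some lead candidate must pair with some trail
    # candidate at their shared vertex; once such a pair is realized the
    # path's content lies inside one surviving edge and it is done.

    def exhausted(self) -> bool:
        return len(self.seq) == 1 and self.lead is None and self.trail is None


@dataclass
class _Edge:
    u: int
    v: int
    weight: float
    support: np.ndarray
    inner: tuple[int, ...] = ()
    merges: int = 0  # vertex decompositions recorded on this edge
    phased: int = 0  # how many of those were forced by a phasing path
    guessed: int = 0  # unphased pairings at non-trivial vertices
    guess_margin: float = 1.0  # least decisive guess absorbed so far


@dataclass
class BipartiteResolver:
    """Pairing state at one non-trivial vertex: in-edge ids, out-edge
    ids, and the (ei, eo) links contributed by phasing or supports."""

    in_side: list[int]
    out_side: list[int]
    links: set[tuple[int, int]] = field(default_factory=set)
    margins: dict[tuple[int, int], float] = field(default_factory=dict)

    def isolated_in(self) -> list[int]:
        linked = {a for a, _ in self.links}
        return [e for e in self.in_side if e not in linked]

    def isolated_out(self) -> list[int]:
        linked = {b for _, b in self.links}
        return [e for e in self.out_side if e not in linked]


def _argmax_margin(totals: list[float]) -> tuple[int, float]:
    """Index of the largest total plus the relative gap to the runner-up
    (1.0 when unopposed; 0.0 on an exact tie or all-zero support)."""
    k = int(np.argmax(totals))
    if len(totals) == 1:
        return k, 1.0
    best = totals[k]
    second = max(t for i, t in enumerate(totals) if i != k)
    return k, (best - second) / best if best > 0 else 0.0


def resolve_isolated(b: BipartiteResolver, supports: dict[int, np.ndarray]) -> BipartiteResolver:
    """Link every isolated in-edge, then every isolated out-edge, to the
    counterpart with the largest summed composed support (ties: first
    counterpart in edge order).  The relative margin of each argmax is
    recorded per link: it quantifies how decisive the guess was."""
    for ei in b.isolated_in():
        if not b.out_side:
            log.warning("isolated in-edge %d has no counterpart; dropped", ei)
            continue
        totals = [float(np.sum(compose_support(supports[ei], supports[eo]))) for eo in b.out_side]
        k, margin = _argmax_margin(totals)
        b.links.add((ei, b.out_side[k]))
        b.margins[(ei, b.out_side[k])] = margin
    for eo in b.isolated_out():
        if not b.in_side:
            log.warning("isolated out-edge %d has no counterpart; dropped", eo)
            continue
        totals = [float(np.sum(compose_support(supports[ei], supports[eo]))) for ei in b.in_side]
        k, margin = _argmax_margin(totals)
        b.links.add((b.in_side[k], eo))
        b.margins[(b.in_side[k], eo)] = margin
    return b


class _Decomposer:
    def __init__(
        self,
        g: SpliceGraph,
        supports: Optional[dict[tuple[int, int], np.ndarray]],
        phasing: Sequence[PhasingPath],
    ):
        self.g = g
        self.edges: dict[int, _Edge] = {}
        self.in_map: dict[int, list[int]] = {}
        self.out_map: dict[int, list[int]] = {}
        self.next_id = 0
        self.dropped_paths = 0
        by_pair: dict[tuple[int, int], int] = {}
        for (u, v) in sorted(g.edges, key=lambda e: (e[0] if e[0] >= 0 else -10, e[1] if e[1] >= 0 else 10**12)):
            w = g.edges[(u, v)]
            if supports is not None and (u, v) in supports:
                vec = np.asarray(supports[(u, v)], dtype=float)
            else:
                vec = np.array([w], dtype=float) if supports is None else np.zeros(_veclen(supports))
            eid = self._add_edge(_Edge(u=u, v=v, weight=float(w), support=vec))
            by_pair[(u, v)] = eid
        # phasing paths as edge-id sequences with counts; single-edge
        # paths impose nothing (every edge survives into a transcript)
        self.paths: list[_Path] = []
        for p in phasing:
            seq = list(zip(p.vertex_seq, p.vertex_seq[1:]))
            if len(seq) < 2:
                continue
            try:
                eids = [by_pair[e] for e in seq]
            except KeyError:
                self.dropped_paths += 1
                continue
            self.paths.append(_Path(seq=eids, count=p.count))

    def _add_edge(self, e: _Edge) -> int:
        eid = self.next_id
        self.next_id += 1
        self.edges[eid] = e
        self.in_map.setdefault(e.v, []).append(eid)
        self.out_map.setdefault(e.u, []).append(eid)
        return eid

    def _remove_edge(self, eid: int) -> None:
        e = self.edges.pop(eid)
        self.in_map[e.v].remove(eid)
        self.out_map[e.u].remove(eid)

    # ------------------------------------------------------------------ steps
    def interior_vertices(self) -> list[int]:
        nodes = set()
        for e in self.edges.values():
            if e.u >= 0:
                nodes.add(e.u)
            if e.v >= 0:
                nodes.add(e.v)
        return sorted(nodes)

    def pick_vertex(self) -> Optional[int]:
        interior = self.interior_vertices()
        if not interior:
            return None
        trivial = [v for v in interior if len(self.in_map.get(v, [])) == 1 or len(self.out_map.get(v, [])) == 1]
        if trivial:
            return trivial[0]
        return min(interior, key=lambda v: (len(self.in_map[v]) * len(self.out_map[v]), v))

    def decompose_vertex(self, v: int) -> None:
        I = list(self.in_map.get(v, []))
        O = list(self.out_map.get(v, []))
        if not I or not O:
            # unreachable after augmentation; drop defensively
            for eid in I + O:
                self._remove_edge(eid)
            return
        trivial = len(I) == 1 or len(O) == 1
        in_set, out_set = set(I), set(O)
        # conjunctive links: a path genuinely threads in-edge, v, out-edge
        phased_pairs: set[tuple[int, int]] = set()
        for path in self.paths:
            for a, bb in zip(path.seq, path.seq[1:]):
                if self.edges[a].v == v:
                    phased_pairs.add((a, bb))
        # disjunctive ends pending at v: link only if no conjunctive link
        # already satisfies them; the choice among candidates is
        # support-guided, mirroring isolated-vertex resolution
        sup = {eid: self.edges[eid].support for eid in I + O}
        links = set(phased_pairs)
        margins: dict[tuple[int, int], float] = {}
        for path in self.paths:
            if not path.seq:
                # join constraint pending here?
                if not path.lead or self.edges[next(iter(path.lead))].v != v:
                    continue
                L = sorted(x for x in path.lead if x in in_set)
                T = sorted(y for y in (path.trail or ()) if y in out_set)
                if L and T and not any((x, y) in links for x in L for y in T):
                    combos = [(x, y) for x in L for y in T]
                    totals = [float(np.sum(compose_support(sup[x], sup[y]))) for x, y in combos]
                    k, margin = _argmax_margin(totals)
                    links.add(combos[k])
                    margins[combos[k]] = margin
                continue
            if path.trail is not None and self.edges[path.seq[-1]].v == v:
                p = path.seq[-1]
                cand = sorted(x for x in path.trail if x in out_set)
                if cand and not any((p, x) in links for x in cand):
                    totals = [float(np.sum(compose_support(sup[p], sup[x]))) for x in cand]
                    k, margin = _argmax_margin(totals)
                    links.add((p, cand[k]))
                    margins[(p, cand[k])] = margin
            if path.lead is not None and self.edges[path.seq[0]].u == v:
                q = path.seq[0]
                cand = sorted(x for x in path.lead if x in in_set)
                if cand and not any((x, q) in links for x in cand):
                    totals = [float(np.sum(compose_support(sup[x], sup[q]))) for x in cand]
                    k, margin = _argmax_margin(totals)
                    links.add((cand[k], q))
                    margins[(cand[k], q)] = margin
        if trivial:
            pairs = [(ei, eo) for ei in I for eo in O]
        else:
            b = BipartiteResolver(in_side=I, out_side=O, links=links, margins=margins)
            resolve_isolated(b, sup)
            pairs = sorted(b.links)
            margins = b.margins

        # proportional weight reallocation (conserves source-side totals)
        new_ids: dict[tuple[int, int], int] = {}
        outs_of: dict[int, list[int]] = {}
        for ei, eo in pairs:
            outs_of.setdefault(ei, []).append(eo)
        for ei, eo in pairs:
            wi = self.edges[ei].weight
            partners = outs_of[ei]
            denom = sum(self.edges[x].weight for x in partners)
            share = wi * self.edges[eo].weight / denom if denom > 0 else wi / len(partners)
            e = _Edge(
                u=self.edges[ei].u,
                v=self.edges[eo].v,
                weight=share,
                support=compose_support(self.edges[ei].support, self.edges[eo].support),
                inner=self.edges[ei].inner + (v,) + self.edges[eo].inner,
                merges=self.edges[ei].merges + self.edges[eo].merges + 1,
                phased=self.edges[ei].phased + self.edges[eo].phased + (1 if (ei, eo) in phased_pairs else 0),
                guessed=self.edges[ei].guessed + self.edges[eo].guessed
                + (1 if (not trivial and (ei, eo) not in phased_pairs) else 0),
                guess_margin=min(
                    self.edges[ei].guess_margin,
                    self.edges[eo].guess_margin,
                    margins.get((ei, eo), 1.0) if not trivial else 1.0,
                ),
            )
            new_ids[(ei, eo)] = self._add_edge(e)

        # rewrite phasing paths onto the new edges
        survivors: list[_Path] = []
        for path in self.paths:
            # disjunction candidates absorbed by this decomposition expand
            # to the merged edges that now contain them
            if path.trail is not None:
                dead = path.trail & in_set
                if dead:
                    path.trail = (path.trail - dead) | {
                        new_ids[pr] for pr in pairs if pr[0] in dead
                    }
            if path.lead is not None:
                dead = path.lead & out_set
                if dead:
                    path.lead = (path.lead - dead) | {
                        new_ids[pr] for pr in pairs if pr[1] in dead
                    }
            seq = path.seq
            if not seq:
                # join path: resolved (and finished) when its vertex falls
                if path.lead and self.edges[next(iter(path.lead))].v == v:
                    realized = [
                        (x, y) for x in path.lead for y in (path.trail or ()) if (x, y) in new_ids
                    ]
                    if not realized:
                        self.dropped_paths += 1
                    continue  # satisfied: content lives inside a merged edge
                survivors.append(path)
                continue
            if path.trail is not None and self.edges[seq[-1]].v == v:
                # pending disjunction resolves here: take a realized pair
                p = seq[-1]
                cand = [(p, x) for x in sorted(path.trail) if (p, x) in new_ids]
                if not cand:
                    self.dropped_paths += 1
                    continue
                best = max(cand, key=lambda pr: (self.edges[new_ids[pr]].weight, -new_ids[pr]))
                path.seq = seq[:-1] + [new_ids[best]]
                path.trail = None
            elif path.lead is not None and self.edges[seq[0]].u == v:
                q = seq[0]
                cand = [(x, q) for x in sorted(path.lead) if (x, q) in new_ids]
                if not cand:
                    self.dropped_paths += 1
                    continue
                best = max(cand, key=lambda pr: (self.edges[new_ids[pr]].weight, -new_ids[pr]))
                path.seq = [new_ids[best]] + seq[1:]
                path.lead = None
            else:
                hit = None
                for idx, (a, bb) in enumerate(zip(seq, seq[1:])):
                    if a in in_set and bb in out_set:
                        hit = idx
                        break
                if hit is not None:
                    path.seq = seq[:hit] + [new_ids[(seq[hit], seq[hit + 1])]] + seq[hit + 2:]
                elif seq[-1] in in_set:
                    ei = seq[-1]
                    derived = {new_ids[pr] for pr in pairs if pr[0] == ei}
                    if len(seq) == 1:
                        if path.lead is None:
                            continue  # content sits inside every derived edge
                        path.trail = derived  # becomes a join constraint
                        path.seq = []
                        survivors.append(path)
                        continue
                    path.trail = derived
                    path.seq = seq[:-1]
                elif seq[0] in out_set:
                    eo = seq[0]
                    derived = {new_ids[pr] for pr in pairs if pr[1] == eo}
                    if len(seq) == 1:
                        if path.trail is None:
                            continue
                        path.lead = derived
                        path.seq = []
                        survivors.append(path)
                        continue
                    path.lead = derived
                    path.seq = seq[1:]
            if not path.exhausted():
                survivors.append(path)
        self.paths = survivors

        for eid in I + O:
            self._remove_edge(eid)
        self.in_map.pop(v, None)
        self.out_map.pop(v, None)

    def run(self) -> list[CandidateTranscript]:
        while True:
            v = self.pick_vertex()
            if v is None:
                break
            self.decompose_vertex(v)
        out: list[CandidateTranscript] = []
        for eid in sorted(self.edges):
            e = self.edges[eid]
            if e.u != SOURCE or e.v != SINK or not e.inner:
                continue
            exons = _merge_exons(self.g, e.inner)
            introns = tuple(
                (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
            )
            out.append(
                CandidateTranscript(
                    chrom=self.g.chrom,
                    strand=self.g.strand,
                    exons=exons,
                    intron_chain=introns,
                    abundance=e.weight,
                    support=e.support,
                    origin=self.g.sample_id,
                    vertex_path=e.inner,
                    n_merges=e.merges,
                    n_phased_merges=e.phased,
                    n_guessed_merges=e.guessed,
                    guess_margin_min=e.guess_margin,
                )
            )
        return out


def _veclen(supports: dict) -> int:
    for v in supports.values():
        return len(v)
    return 1


def _merge_exons(g: SpliceGraph, path: tuple[int, ...]) -> list[tuple[int, int]]:
    exons: list[tuple[int, int]] = []
    for vid in path:
        s, e = g.vertices[vid]
        if exons and exons[-1][1] == s:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    return exons


def decompose_graph(
    g: SpliceGraph,
    supports: Optional[dict[tuple[int, int], np.ndarray]] = None,
    phasing: Sequence[PhasingPath] = (),
) -> list[CandidateTranscript]:
    """Decompose an augmented splice graph into candidate transcripts.

    ``supports`` maps each edge of ``g`` to its cross-sample support
    vector; when omitted, each edge supports itself with its own weight
    (single-sample use).  ``phasing`` is the compressed phasing-path
    set expressed in ``g``'s vertex indices.
    """
    if not g.augmented:
        raise ValueError("graph must be source/sink augmented before decomposition")
    if not g.vertices:
        return []
    return _Decomposer(g, supports, phasing).run()
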