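"""Random-forest transcript scoring and meta-transcript aggregation.

A binary random forest (100 trees, depth 20) maps each candidate's
50-feature vector to a probability that its intron chain is correct.
Candidates sharing an intron chain — assembled from different samples
or from an individual and the combined graph — merge into one
meta-transcript whose score is the arithmetic mean of member scores.
A score threshold (default 0.5; 0.2 is the recommended floor below
which output should be discarded) gates emission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .decomposition import CandidateTranscript
from .features import FEATURE_NAMES, schema_hash
from .gtf import write_gtf

N_ESTIMATORS = 100
MAX_DEPTH = 20
RECOMMENDED_FLOOR = 0.2
DEFAULT_THRESHOLD = 0.5


@dataclass
class ScoringModel:
    forest: RandomForestClassifier
    schema: str
    seed: int
    training_digest: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.forest.predict_proba(X)
        one = list(self.forest.classes_).index(1)
        return proba[:, one]

    def save(self, path: str) -> None:
        joblib.dump(self.forest, path)
        sidecar = {
            "schema": self.schema,
            "seed": self.seed,
            "training_digest": self.training_digest,
            "features": FEATURE_NAMES,
            "n_estimators": N_ESTIMATORS,
            "max_depth": MAX_DEPTH,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str) -> "ScoringModel":
        forest = joblib.load(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(forest=forest, schema=meta["schema"], seed=meta["seed"], training_digest=meta.get("training_digest", ""))


def train_model(rows: Sequence[tuple[np.ndarray, int]], seed: int = 0) -> ScoringModel:
    """Fit the scorer on labeled feature rows.

    Raises ``ValueError`` when only one class is present — a scorer
    cannot be trained without both correct and incorrect candidates.
    """
    if not rows:
        raise ValueError("no training rows")
    X = np.vstack([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    if len(set(y.tolist())) < 2:
        raise ValueError(
            f"training set contains a single class ({y[0]}); "
            "need both matched and unmatched candidates"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training rows")
    # balanced class weights: synthetic training sets skew heavily toward
    # correct candidates, which would inflate every probability estimate
    forest = RandomForestClassifier(
        n_estimators=N_ESTIMATORS, max_depth=MAX_DEPTH, random_state=seed,
        n_jobs=1, class_weight="balanced",
    )
    forest.fit(X, y)
    digest = f"{len(y)}:{int(y.sum())}:{float(X.sum()):.6g}"
    return ScoringModel(forest=forest, schema=schema_hash(), seed=seed, training_digest=digest)


def score_candidates(
    ts: Sequence[CandidateTranscript],
    features: Sequence[np.ndarray],
    model: ScoringModel,
) -> list[CandidateTranscript]:
    """Attach a probability score to each candidate (in place)."""
    if model.schema != schema_hash():
        raise ValueError("model feature schema does not match this extractor")
    if not ts:
        return []
    X = np.vstack(list(features))
    scores = model.predict(X)
    for t, s in zip(ts, scores):
        t.score = float(s)
    return list(ts)


@dataclass
class MetaTranscript:
    chrom: str
    strand: str
    intron_chain: tuple[tuple[int, int], ...]
    exons: list[tuple[int, int]]  # representative: member with highest abundance
    members: list[tuple[int, float, float]] = field(default_factory=list)  # (origin, score, abundance)
    score: float = 0.0

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def abundance(self) -> float:
        return max((a for _, _, a in self.members), default=0.0)


def aggregate_meta(scored: Sequence[CandidateTranscript]) -> list[MetaTranscript]:
    """Group candidates by identical intron chain into meta-transcripts.

    Multi-exon candidates group on (chrom, strand, intron chain);
    single-exon candidates have no chain and group on their exact span.
    The representative exon chain comes from the member with the
    highest abundance; the meta score is the mean member score.
    """
    groups: dict[tuple, list[CandidateTranscript]] = {}
    order: list[tuple] = []
    for t in scored:
        key = (t.chrom, t.strand, t.intron_chain) if t.intron_chain else (t.chrom, t.strand, (), t.start, t.end)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(t)
    metas = []
    for key in order:
        members = groups[key]
        rep = max(members, key=lambda t: t.abundance)
        metas.append(
            MetaTranscript(
                chrom=rep.chrom,
                strand=rep.strand,
                intron_chain=rep.intron_chain,
                exons=list(rep.exons),
                members=[(t.origin, t.score if t.score is not None else 0.0, t.abundance) for t in members],
                score=float(np.mean([t.score if t.score is not None else 0.0 for t in members])),
            )
        )
    metas.sort(key=lambda m: (m.chrom, m.exons[0][0], m.exons[-1][1]))
    return metas


def filter_and_emit(
    metas: Sequence[MetaTranscript],
    path: Optional[str] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MetaTranscript]:
    """Keep meta-transcripts with score >= threshold; optionally write GTF."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept = [m for m in metas if m.score >= threshold]
    kept.sort(key=lambda m: (m.chrom, m.exons[0][0], m.exons[-1][1]))
    if path is not None:
        records = []
        for i, m in enumerate(kept, 1):
            attrs = {
                "score": f"{m.score:.4f}",
                "samples": str(m.n_members),
                "abundance": f"{m.abundance:.3f}",
            }
            records.append((m.chrom, m.strand, f"MSG.{i}", f"MST.{i}", m.exons, attrs))
        write_gtf(records, path)
    return kept
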