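"""Self-supervised triplet mining from bibliography distances.

A training triplet pairs a query paper's title (anchor) with its own
abstract (positive) and the abstract of a dissimilar paper (negative).
Dissimilarity is decided without labels: a candidate is an acceptable
negative when the cosine distance between the two papers' latent
bibliography vectors reaches the threshold (default 1.0 — at or beyond
orthogonality, i.e. no shared citation structure).  The comparison is
inclusive (≥) because exactly-orthogonal bibliographies are the common
case for sparse disjoint reference lists.

A second harvest, the *teacher* set, is mined from the full retrieval
system's own ranked output: the top 3 documents of each ranked list act as
positives, the bottom 15 as negatives, paired sequentially five-per-positive
walking backward from the last rank.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .bibliography import BibliographyEmbeddingSpace
from .corpus import Document, RankedList

__all__ = [
    "Triplet",
    "MinerConfig",
    "eligible_query_docs",
    "mine_triplets",
    "build_teacher_set",
    "read_triplets",
    "write_triplets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Triplet:
    """(anchor title, positive abstract, negative abstract) instance."""

    query_doc_id: str
    negative_doc_id: str
    anchor_text: str
    positive_text: str
    negative_text: str

    def __post_init__(self) -> None:
        if self.query_doc_id == self.negative_doc_id:
            raise ValueError(
                f"triplet pairs document {self.query_doc_id!r} with itself"
            )
        if not (self.anchor_text and self.positive_text and self.negative_text):
            raise ValueError(
                f"triplet ({self.query_doc_id}, {self.negative_doc_id}) "
                "has an empty text field"
            )


@dataclass(frozen=True)
class MinerConfig:
    """Negative-selection parameters.

    ``negatives_per_query`` (default 3) triplets are emitted per eligible
    query paper; ``distance_threshold`` (default 1.0) is the minimum
    bibliography cosine distance a negative must have to the query.
    """

    negatives_per_query: int = 3
    distance_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.negatives_per_query < 1:
            raise ValueError("negatives_per_query must be >= 1")
        if not 0.0 <= self.distance_threshold <= 2.0:
            raise ValueError("distance_threshold must be in [0, 2]")


def eligible_query_docs(
    corpus: Iterable[Document],
    space: BibliographyEmbeddingSpace | None = None,
) -> set[str]:
    """Documents usable as triplet queries: non-empty title and abstract,
    full body available (≥ 1 paragraph), and present in the bibliography
    space when one is given."""
    out = set()
    for doc in corpus:
        if not (doc.title and doc.abstract and doc.paragraphs):
            continue
        if space is not None and doc.doc_id not in space:
            continue
        out.add(doc.doc_id)
    return out


def mine_triplets(
    corpus: Sequence[Document],
    space: BibliographyEmbeddingSpace,
    config: MinerConfig = MinerConfig(),
) -> list[Triplet]:
    """Create the self-supervised training set.

    For each eligible query paper, ``negatives_per_query`` negatives are
    sampled uniformly without replacement (seeded) from the papers whose
    bibliography vector lies at cosine distance ≥ threshold; queries with
    fewer eligible negatives contribute as many as exist (logged).
    Returns triplets sorted by (query, negative) id for reproducibility.
    """
    docs_by_id = {d.doc_id: d for d in corpus}
    queries = sorted(eligible_query_docs(corpus, space))
    # negative pool: any paper in the space whose abstract is usable
    pool = sorted(
        d.doc_id for d in corpus if d.abstract and d.doc_id in space
    )
    if queries and len(pool) < 2:
        raise ValueError(
            "no candidate negatives: fewer than two documents with an "
            "abstract are present in the bibliography space"
        )
    rng = np.random.default_rng(config.seed)
    triplets: list[Triplet] = []
    short = 0
    for q in queries:
        candidates = [
            n
            for n in pool
            if n != q and space.distance(q, n) >= config.distance_threshold
        ]
        if not candidates:
            short += 1
            continue
        take = min(config.negatives_per_query, len(candidates))
        if take < config.negatives_per_query:
            short += 1
        chosen = rng.choice(len(candidates), size=take, replace=False)
        qdoc = docs_by_id[q]
        for idx in sorted(chosen):
            n = candidates[idx]
            triplets.append(
                Triplet(
                    query_doc_id=q,
                    negative_doc_id=n,
                    anchor_text=qdoc.title,
                    positive_text=qdoc.abstract,
                    negative_text=docs_by_id[n].abstract,
                )
            )
    if short:
        logger.warning(
            "%d query documents had fewer than %d eligible negatives",
            short,
            config.negatives_per_query,
        )
    return triplets


def build_teacher_set(
    ranked_lists: Sequence[RankedList], corpus: Sequence[Document]
) -> list[Triplet]:
    """Harvest triplets from the retrieval system's own ranked output.

    Per topic: positives are ranks 1–3; negatives are the last 15 ranks.
    Each positive is paired with five negatives sequentially walking
    backward from the end of the list — positive 1 with ranks n…n−4,
    positive 2 with n−5…n−9, positive 3 with n−10…n−14 — giving 15
    triplets per topic (anchor = positive's title, positive = its
    abstract, negative = the negative's abstract).
    """
    docs_by_id = {d.doc_id: d for d in corpus}
    triplets: list[Triplet] = []
    for ranked in ranked_lists:
        if len(ranked) < 18:
            raise ValueError(
                f"topic {ranked.topic_id}: ranked list has {len(ranked)} "
                "entries; need at least 18 (3 positives + 15 negatives)"
            )
        ids = ranked.doc_ids()
        positives = ids[:3]
        negatives_backward = ids[::-1][:15]  # d_n, d_{n-1}, ..., d_{n-14}
        for p_idx, pos_id in enumerate(positives):
            pos = docs_by_id[pos_id]
            for neg_id in negatives_backward[5 * p_idx : 5 * (p_idx + 1)]:
                neg = docs_by_id[neg_id]
                triplets.append(
                    Triplet(
                        query_doc_id=pos_id,
                        negative_doc_id=neg_id,
                        anchor_text=pos.title,
                        positive_text=pos.abstract,
                        negative_text=neg.abstract,
                    )
                )
    return triplets


def write_triplets(triplets: Iterable[Triplet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triplets:
            fh.write(
                json.dumps(
                    {
                        "query_doc_id": t.query_doc_id,
                        "negative_doc_id": t.negative_doc_id,
                        "anchor_text": t.anchor_text,
                        "positive_text": t.positive_text,
                        "negative_text": t.negative_text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_triplets(path: str | Path) -> list[Triplet]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(Triplet(**json.loads(line)))
    return out
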