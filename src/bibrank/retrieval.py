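"""Hybrid retrieval: dense cosine scoring fused with BM25, plus a
paragraph-level reranker.

Retrieval scores every document twice — a neural score s_n (cosine between
the query embedding and the document's title+abstract embedding) and a
keyword score s_b (BM25 Okapi) — and mixes them linearly:

    s = α · s_n + (1 − α) · s_b'

where s_b' is the per-query min–max normalization of s_b to [0, 1].  The
normalization is a deliberate choice: cosine is bounded by 1 while raw BM25
is unbounded, so mixing them raw would make α meaningless.  α = 0.815 is
the tuned default.

The reranker then revisits the top ``pool`` documents (default 10) with
full-text evidence: each document's passage set is its paragraphs plus its
title and abstract; the rerank score s_r is the best passage cosine against
the query, and the final score is

    s_f = β · s + (1 − β) · s_r        (β = 0.77 default).

Only the pool is re-ordered; it stays ahead of the tail, whose internal
order is unchanged (s_f is defined only for pool members, so comparing it
against tail retrieval scores would mix scales).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Document, RankedList
from .lexical import BM25Index, tokenize

__all__ = [
    "NeuralIndex",
    "FusionConfig",
    "cosine_similarity",
    "build_neural_index",
    "retrieve",
    "rerank",
    "search",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Standard cosine; errors on zero vectors or mismatched dims."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class NeuralIndex:
    """doc_id -> dense embedding of the document's title + abstract."""

    doc_ids: list[str]
    vectors: np.ndarray  # (D, dim)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self.doc_ids) != self.vectors.shape[0]:
            raise ValueError("doc_ids and vectors disagree in length")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def scores(self, query_embedding: np.ndarray) -> np.ndarray:
        """Cosine of the query against every document, in doc_ids order.

        Documents whose embedding is the zero vector (no usable text)
        score 0 rather than erroring — they can never be ranked above a
        scored document by cosine alone.
        """
        q = np.asarray(query_embedding, dtype=float)
        if q.shape != (self.dim,):
            raise ValueError(f"query dim {q.shape} != index dim {self.dim}")
        qn = np.linalg.norm(q)
        if qn == 0.0:
            raise ValueError("query embedding is the zero vector")
        norms = np.linalg.norm(self.vectors, axis=1)
        safe = np.where(norms == 0.0, 1.0, norms)
        sims = (self.vectors @ q) / (safe * qn)
        return np.where(norms == 0.0, 0.0, sims)

    def save(self, path_prefix: str | Path) -> None:
        prefix = Path(path_prefix)
        np.savez(prefix.with_suffix(".npz"), vectors=self.vectors)
        prefix.with_suffix(".docs.txt").write_text(
            "\n".join(self.doc_ids) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path_prefix: str | Path) -> "NeuralIndex":
        prefix = Path(path_prefix)
        data = np.load(prefix.with_suffix(".npz"))
        doc_ids = prefix.with_suffix(".docs.txt").read_text(
            encoding="utf-8"
        ).splitlines()
        return cls(doc_ids=doc_ids, vectors=data["vectors"])


def build_neural_index(corpus: Iterable[Document], embedder) -> NeuralIndex:
    """Embed each document's title + abstract text."""
    docs = list(corpus)
    if not docs:
        raise ValueError("cannot index an empty corpus")
    vectors = np.stack([embedder.encode(d.text) for d in docs])
    return NeuralIndex(doc_ids=[d.doc_id for d in docs], vectors=vectors)


@dataclass(frozen=True)
class FusionConfig:
    """Score-fusion and reranker knobs.

    alpha weighs neural vs BM25 at retrieval; beta weighs the retrieval
    score vs the passage rerank score; pool is how many top documents the
    reranker revisits; cutoff caps the ranked-list length.
    """

    alpha: float = 0.815
    beta: float = 0.77
    pool: int = 10
    cutoff: int = 1000
    bm25_normalization: str = "minmax"  # "minmax" | "zscore" | "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.pool < 1:
            raise ValueError("pool must be >= 1")
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        if self.bm25_normalization not in ("minmax", "zscore", "none"):
            raise ValueError(
                f"unknown bm25_normalization {self.bm25_normalization!r}"
            )


def _normalize_bm25(scores: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return scores
    if mode == "zscore":
        sd = scores.std()
        return (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def _sorted_ranking(
    doc_ids: Sequence[str], scores: np.ndarray
) -> list[tuple[str, float]]:
    """Sort by score descending, ties broken by doc_id ascending."""
    order = sorted(range(len(doc_ids)), key=lambda i: (-scores[i], doc_ids[i]))
    return [(doc_ids[i], float(scores[i])) for i in order]


def retrieve(
    query_text: str,
    embedder,
    nindex: NeuralIndex,
    bm25: BM25Index,
    config: FusionConfig = FusionConfig(),
    topic_id: str = "0",
) -> RankedList:
    """Score the whole corpus with s = α·s_n + (1−α)·s_b' and rank it.

    The two indices must cover the same documents in the same order.
    Deterministic: ties break by doc_id ascending; the list is truncated
    to ``config.cutoff``.
    """
    if nindex.doc_ids != bm25.doc_ids:
        raise ValueError("neural and BM25 indices cover different documents")
    if not nindex.doc_ids:
        raise ValueError("empty corpus")
    q = embedder.encode(query_text)
    s_n = nindex.scores(q)
    s_b = _normalize_bm25(
        bm25.scores(tokenize(query_text)), config.bm25_normalization
    )
    s = config.alpha * s_n + (1.0 - config.alpha) * s_b
    entries = _sorted_ranking(nindex.doc_ids, s)[: config.cutoff]
    return RankedList(topic_id=topic_id, entries=entries)


def rerank(
    ranked: RankedList,
    query_embedding: np.ndarray,
    corpus: Sequence[Document],
    embedder,
    config: FusionConfig = FusionConfig(),
) -> RankedList:
    """Re-order the top ``pool`` documents by full-text passage evidence.

    Each pool document's passages are its paragraphs plus its title and
    abstract (so even a paper without full text has at least two
    entries); s_r is the maximum passage cosine against the query, and
    pool members are re-sorted by s_f = β·s + (1−β)·s_r.  The pool stays
    ahead of the tail; the tail's internal order is unchanged, and its
    scores are shifted down by a constant when needed so the output list
    remains non-increasing (order-preserving; pool scores are the literal
    s_f values).
    """
    if len(ranked) == 0:
        raise ValueError("cannot rerank an empty list")
    docs_by_id = {d.doc_id: d for d in corpus}
    q = np.asarray(query_embedding, dtype=float)
    p = min(config.pool, len(ranked))

    pool_entries = ranked.entries[:p]
    tail_entries = ranked.entries[p:]

    rescored: list[tuple[str, float]] = []
    for doc_id, s in pool_entries:
        doc = docs_by_id[doc_id]
        passages = [t for t in (*doc.paragraphs, doc.title, doc.abstract) if t]
        s_r = 0.0
        scored_any = False
        for passage in passages:
            v = embedder.encode(passage)
            if np.linalg.norm(v) == 0.0:
                continue
            sim = cosine_similarity(v, q)
            s_r = sim if not scored_any else max(s_r, sim)
            scored_any = True
        s_f = config.beta * s + (1.0 - config.beta) * s_r
        rescored.append((doc_id, s_f))

    rescored.sort(key=lambda e: (-e[1], e[0]))
    if tail_entries and rescored:
        pool_min = rescored[-1][1]
        tail_max = tail_entries[0][1]
        if tail_max > pool_min:
            shift = tail_max - pool_min + 1e-9
            tail_entries = [(d, s - shift) for d, s in tail_entries]
    return RankedList(topic_id=ranked.topic_id, entries=rescored + tail_entries)


def search(
    query_text: str,
    embedder,
    nindex: NeuralIndex,
    bm25: BM25Index,
    corpus: Sequence[Document],
    config: FusionConfig = FusionConfig(),
    topic_id: str = "0",
) -> RankedList:
    """Full pipeline for one query: retrieve, then rerank the pool."""
    ranked = retrieve(query_text, embedder, nindex, bm25, config, topic_id)
    return rerank(ranked, embedder.encode(query_text), corpus, embedder, config)
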