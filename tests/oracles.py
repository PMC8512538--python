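"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the defining formulas in the most naive
style possible (explicit loops, no shared code with the package) so that
agreement with the package is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# BM25 Okapi: naive double-loop evaluation of the idf and scoring formulas


def bm25_bruteforce(
    doc_tokens: list[list[str]],
    query_tokens: list[str],
    doc_index: int,
    k: float = 1.25,
    b: float = 0.75,
) -> float:
    n_docs = len(doc_tokens)
    avgdl = sum(len(toks) for toks in doc_tokens) / n_docs
    d = doc_tokens[doc_index]
    score = 0.0
    for q in query_tokens:  # sum over query token occurrences
        n_w = sum(1 for toks in doc_tokens if q in toks)
        idf = math.log((n_docs - n_w + 0.5) / (n_w + 0.5) + 1.0)
        f = sum(1 for t in d if t == q)
        denom = f + k * (1.0 - b + b * len(d) / avgdl)
        score += idf * f * (k + 1.0) / denom
    return score


# ---------------------------------------------------------------------------
# TREC metrics, trec_eval conventions, written over plain dicts/lists.
# ``ranking`` is a list of doc_ids in rank order; ``judged`` maps doc_id to
# its grade for the topic.


def p_at_n(ranking: list[str], judged: dict[str, int], n: int) -> float:
    hits = 0
    for doc in ranking[:n]:
        if judged.get(doc, 0) >= 1:
            hits += 1
    return hits / n


def ndcg_at_n(ranking: list[str], judged: dict[str, int], n: int) -> float:
    def dcg(grades):
        total = 0.0
        for i, g in enumerate(grades):
            rank = i + 1
            total += g if rank == 1 else g / math.log2(rank)
        return total

    got = dcg([judged.get(doc, 0) for doc in ranking[:n]])
    best = dcg(sorted(judged.values(), reverse=True)[:n])
    return got / best if best > 0 else 0.0


def avg_prec(ranking: list[str], judged: dict[str, int]) -> float:
    n_rel = sum(1 for g in judged.values() if g >= 1)
    if n_rel == 0:
        return 0.0
    found, acc = 0, 0.0
    for i, doc in enumerate(ranking):
        if judged.get(doc, 0) >= 1:
            found += 1
            acc += found / (i + 1)
    return acc / n_rel


def bpref_trec(ranking: list[str], judged: dict[str, int]) -> float:
    n_rel = sum(1 for g in judged.values() if g >= 1)
    n_nonrel = sum(1 for g in judged.values() if g == 0)
    if n_rel == 0:
        return 0.0
    bound = min(n_rel, n_nonrel)
    nonrel_seen, acc = 0, 0.0
    for doc in ranking:
        if doc not in judged:
            continue
        if judged[doc] >= 1:
            if nonrel_seen == 0 or bound == 0:
                acc += 1.0
            else:
                acc += 1.0 - min(nonrel_seen, bound) / bound
        else:
            nonrel_seen += 1
    return acc / n_rel


# ---------------------------------------------------------------------------
# Dense full-SVD truncation oracle for the bibliography space


def truncated_gram(dense_matrix: np.ndarray, k: int) -> np.ndarray:
    """Rank-k truncation of M·Mᵀ via a full dense SVD."""
    u, s, _ = np.linalg.svd(dense_matrix, full_matrices=False)
    uk = u[:, :k]
    sk = s[:k]
    return uk @ np.diag(sk**2) @ uk.T
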