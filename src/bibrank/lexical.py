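"""BM25 Okapi keyword scoring over title + abstract text.

The index stores, per word w, the document frequency n(w); per document d,
the term-frequency table f(w, d) and the token length |d|; plus the corpus
size N and average document length avgdl.  Scores use the Okapi formulation

    idf(w)       = ln( (N - n(w) + 0.5) / (n(w) + 0.5) + 1 )
    score(q, d)  = sum_i idf(q_i) * f(q_i, d) * (K + 1)
                   / ( f(q_i, d) + K * (1 - b + b * |d| / avgdl) )

summed over query token *occurrences* (a repeated query word counts
multiply).  Defaults K = 1.25, b = 0.75.  Tokenization is a plain lower-cased
English word tokenizer: no stemming, no stopword removal.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Document

__all__ = ["tokenize", "BM25Index", "build_index"]

_WORD_RE = re.compile(r"\w+(?:[-']\w+)*")

DEFAULT_K = 1.25
DEFAULT_B = 0.75


def tokenize(text: str) -> list[str]:
    """Lower-cased word tokens; punctuation-only tokens are dropped.

    Internal hyphens and apostrophes are kept ("COVID-19" -> "covid-19"),
    so tokenization is idempotent on its own space-joined output.
    """
    return _WORD_RE.findall(text.lower())


@dataclass
class BM25Index:
    """Okapi BM25 index over a fixed document collection."""

    doc_ids: list[str]
    doc_freq: dict[str, int]            # n(w): documents containing w
    term_freq: list[Counter]            # f(w, d) per document
    doc_len: np.ndarray                 # |d| in tokens
    k: float = DEFAULT_K
    b: float = DEFAULT_B
    _id_to_idx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.doc_len = np.asarray(self.doc_len, dtype=float)
        self._id_to_idx = {d: i for i, d in enumerate(self.doc_ids)}

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def avgdl(self) -> float:
        return float(self.doc_len.mean())

    def idf(self, word: str) -> float:
        """Inverse document frequency; unseen words use n(w) = 0.

        The +1 inside the log keeps idf strictly positive for all n(w) <= N.
        """
        n = self.doc_freq.get(word, 0)
        return math.log((self.n_docs - n + 0.5) / (n + 0.5) + 1.0)

    def score(self, query_tokens: Sequence[str], doc_id: str) -> float:
        """BM25 score of one document against a tokenized query."""
        try:
            idx = self._id_to_idx[doc_id]
        except KeyError:
            raise KeyError(f"doc_id {doc_id!r} not in index") from None
        return self._score_idx(query_tokens, idx)

    def _score_idx(self, query_tokens: Sequence[str], idx: int) -> float:
        tf = self.term_freq[idx]
        norm = self.k * (1.0 - self.b + self.b * self.doc_len[idx] / self.avgdl)
        total = 0.0
        for token in query_tokens:
            f = tf.get(token, 0)
            if f == 0:
                continue
            total += self.idf(token) * f * (self.k + 1.0) / (f + norm)
        return total

    def scores(self, query_tokens: Sequence[str]) -> np.ndarray:
        """Score every indexed document; order follows ``doc_ids``."""
        out = np.zeros(self.n_docs)
        norms = self.k * (1.0 - self.b + self.b * self.doc_len / self.avgdl)
        counts = Counter(query_tokens)
        for token, q_count in counts.items():
            idf_w = self.idf(token)
            for idx, tf in enumerate(self.term_freq):
                f = tf.get(token, 0)
                if f:
                    out[idx] += (
                        q_count * idf_w * f * (self.k + 1.0) / (f + norms[idx])
                    )
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "doc_ids": self.doc_ids,
            "doc_freq": self.doc_freq,
            "term_freq": [dict(tf) for tf in self.term_freq],
            "doc_len": self.doc_len.tolist(),
            "k": self.k,
            "b": self.b,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "BM25Index":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            doc_ids=payload["doc_ids"],
            doc_freq=payload["doc_freq"],
            term_freq=[Counter(tf) for tf in payload["term_freq"]],
            doc_len=np.asarray(payload["doc_len"], dtype=float),
            k=payload["k"],
            b=payload["b"],
        )


def build_index(
    corpus: Iterable[Document], k: float = DEFAULT_K, b: float = DEFAULT_B
) -> BM25Index:
    """Index every document's title + abstract text."""
    docs = list(corpus)
    if not docs:
        raise ValueError("cannot build a BM25 index over an empty corpus")
    doc_ids: list[str] = []
    term_freq: list[Counter] = []
    doc_len: list[int] = []
    doc_freq: Counter = Counter()
    for doc in docs:
        tokens = tokenize(doc.text)
        tf = Counter(tokens)
        doc_ids.append(doc.doc_id)
        term_freq.append(tf)
        doc_len.append(len(tokens))
        doc_freq.update(tf.keys())
    return BM25Index(
        doc_ids=doc_ids,
        doc_freq=dict(doc_freq),
        term_freq=term_freq,
        doc_len=np.asarray(doc_len, dtype=float),
        k=k,
        b=b,
    )
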