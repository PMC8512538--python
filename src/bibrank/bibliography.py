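"""Citation incidence matrix and the SVD latent bibliography space.

Each document's bibliography is a sparse binary row over the universe of
cited works.  After filtering (cited works referenced by fewer than two
documents are dropped, then documents left with no retained citations are
dropped, iterated to a fixed point), a truncated SVD of the incidence matrix
M ≈ U_k Σ_k V_kᵀ yields a k-dimensional real vector per document
(the row of U_k Σ_k).  Cosine distance between these vectors proxies
semantic relatedness: papers citing overlapping or co-cited literature land
close together even without a single shared reference (the latent space
surfaces higher-order citation structure, exactly as LSA does for words).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.sparse.linalg import svds

from .corpus import Document

__all__ = [
    "CitationMatrix",
    "BibliographyEmbeddingSpace",
    "build_citation_matrix",
    "embed_bibliographies",
    "random_pairs",
    "relevance_pairs",
]

# below this size a dense LAPACK SVD is exact, deterministic and fast;
# above it ARPACK iterates on the sparse matrix
_DENSE_SVD_MAX_DIM = 1500


@dataclass
class CitationMatrix:
    """Filtered binary documents × cited-works incidence matrix.

    Invariants: every column has ≥ 2 nonzeros, every row ≥ 1, cells ∈ {0,1}.
    """

    matrix: sp.csr_matrix
    doc_ids: list[str]
    citation_keys: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.doc_ids), len(self.citation_keys)):
            raise ValueError("index lengths do not match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row(self, doc_id: str) -> np.ndarray:
        idx = self.doc_ids.index(doc_id)
        return np.asarray(self.matrix[idx].todense()).ravel()

    def save(self, path_prefix: str | Path) -> None:
        """Persist as Matrix Market plus two plain-text index files."""
        prefix = Path(path_prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.matrix)
        prefix.with_suffix(".rows.txt").write_text(
            "\n".join(self.doc_ids) + "\n", encoding="utf-8"
        )
        prefix.with_suffix(".cols.txt").write_text(
            "\n".join(self.citation_keys) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path_prefix: str | Path) -> "CitationMatrix":
        prefix = Path(path_prefix)
        matrix = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
        doc_ids = prefix.with_suffix(".rows.txt").read_text(
            encoding="utf-8"
        ).splitlines()
        keys = prefix.with_suffix(".cols.txt").read_text(
            encoding="utf-8"
        ).splitlines()
        return cls(matrix=matrix, doc_ids=doc_ids, citation_keys=keys)


def build_citation_matrix(corpus: Iterable[Document]) -> CitationMatrix:
    """Build the filtered incidence matrix from document bibliographies.

    Filtering drops cited works referenced by fewer than two corpus
    documents (column support < 2), then documents whose bibliography is
    emptied by that (row support 0), and iterates column-then-row pruning
    until stable — one pass can leave rows violating the invariant after
    columns disappear.
    """
    docs = list(corpus)
    if not docs:
        raise ValueError("corpus is empty")

    key_index: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    doc_ids = [d.doc_id for d in docs]
    for i, doc in enumerate(docs):
        for key in doc.references:
            j = key_index.setdefault(key, len(key_index))
            rows.append(i)
            cols.append(j)
    if not key_index:
        raise ValueError("no document in the corpus has any citation")

    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(docs), len(key_index)),
    )
    keys = list(key_index)

    row_keep = np.arange(matrix.shape[0])
    col_keep = np.arange(matrix.shape[1])
    while True:
        col_support = np.asarray(matrix.sum(axis=0)).ravel()
        cols_ok = col_support >= 2
        if not cols_ok.all():
            matrix = matrix[:, cols_ok]
            col_keep = col_keep[cols_ok]
        row_support = np.asarray(matrix.sum(axis=1)).ravel()
        rows_ok = row_support >= 1
        if not rows_ok.all():
            matrix = matrix[rows_ok, :]
            row_keep = row_keep[rows_ok]
        if cols_ok.all() and rows_ok.all():
            break
    if matrix.nnz == 0:
        raise ValueError("filtering removed every citation")

    return CitationMatrix(
        matrix=matrix.tocsr(),
        doc_ids=[doc_ids[i] for i in row_keep],
        citation_keys=[keys[j] for j in col_keep],
    )


@dataclass
class BibliographyEmbeddingSpace:
    """Per-document k-dimensional latent vectors (rows of U_k Σ_k)."""

    k: int
    doc_ids: list[str]
    vectors: np.ndarray          # shape (D, k)
    singular_values: np.ndarray  # length k, non-increasing
    _id_to_idx: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.vectors.shape != (len(self.doc_ids), self.k):
            raise ValueError("vectors shape inconsistent with doc_ids and k")
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be non-increasing")
        self._id_to_idx = {d: i for i, d in enumerate(self.doc_ids)}

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._id_to_idx

    def vector(self, doc_id: str) -> np.ndarray:
        try:
            return self.vectors[self._id_to_idx[doc_id]]
        except KeyError:
            raise KeyError(f"doc_id {doc_id!r} not in embedding space") from None

    def distance(self, doc_i: str, doc_j: str) -> float:
        """Cosine distance 1 − cos(v_i, v_j), in [0, 2]."""
        v_i, v_j = self.vector(doc_i), self.vector(doc_j)
        n_i, n_j = np.linalg.norm(v_i), np.linalg.norm(v_j)
        if n_i == 0.0 or n_j == 0.0:
            raise ValueError(
                f"cosine distance undefined for zero vector "
                f"({doc_i!r} or {doc_j!r})"
            )
        return float(1.0 - np.dot(v_i, v_j) / (n_i * n_j))

    def pair_distance_summary(
        self, pairs: Sequence[tuple[str, str]]
    ) -> float:
        """Arithmetic mean cosine distance over document pairs."""
        if not pairs:
            raise ValueError("pair list is empty")
        return float(np.mean([self.distance(i, j) for i, j in pairs]))

    def save(self, path_prefix: str | Path) -> None:
        prefix = Path(path_prefix)
        np.savez(
            prefix.with_suffix(".npz"),
            vectors=self.vectors,
            singular_values=self.singular_values,
        )
        prefix.with_suffix(".docs.txt").write_text(
            "\n".join(self.doc_ids) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path_prefix: str | Path) -> "BibliographyEmbeddingSpace":
        prefix = Path(path_prefix)
        data = np.load(prefix.with_suffix(".npz"))
        doc_ids = prefix.with_suffix(".docs.txt").read_text(
            encoding="utf-8"
        ).splitlines()
        return cls(
            k=data["vectors"].shape[1],
            doc_ids=doc_ids,
            vectors=data["vectors"],
            singular_values=data["singular_values"],
        )


def _fix_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|coefficient| entry of each left vector positive."""
    for j in range(u.shape[1]):
        pivot = np.argmax(np.abs(u[:, j]))
        if u[pivot, j] < 0:
            u[:, j] = -u[:, j]
            vt[j, :] = -vt[j, :]
    return u, vt


def embed_bibliographies(
    cmatrix: CitationMatrix, k: int, method: str = "auto"
) -> BibliographyEmbeddingSpace:
    """Rank-k truncated SVD of the incidence matrix; vectors are U_k Σ_k.

    Scaling U by Σ preserves the relative weight of latent factors
    (standard LSA practice) and makes cosine over the embeddings equal
    cosine between the rank-k projections of the raw bibliography rows.
    Signs are fixed (largest-magnitude coefficient of each left singular
    vector positive) so results are machine-independent.

    ``method``: "dense" (exact LAPACK SVD), "sparse" (ARPACK), or "auto"
    (dense below a size threshold).
    """
    D, C = cmatrix.shape
    max_k = min(D, C) - 1
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}], got {k}")
    if method not in ("auto", "dense", "sparse"):
        raise ValueError(f"unknown SVD method {method!r}")
    if method == "auto":
        method = "dense" if min(D, C) <= _DENSE_SVD_MAX_DIM else "sparse"

    if method == "dense":
        u, s, vt = np.linalg.svd(
            cmatrix.matrix.toarray().astype(float), full_matrices=False
        )
        u, s, vt = u[:, :k], s[:k], vt[:k, :]
    else:
        # fixed start vector keeps ARPACK deterministic
        u, s, vt = svds(
            cmatrix.matrix.astype(float),
            k=k,
            v0=np.ones(min(D, C)),
        )
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order, :]
    u, vt = _fix_signs(u, vt)

    return BibliographyEmbeddingSpace(
        k=k,
        doc_ids=list(cmatrix.doc_ids),
        vectors=u * s,
        singular_values=s,
    )


# ---------------------------------------------------------------------------
# Pair-sampling helpers for the pair-distance evaluation protocol


def random_pairs(
    doc_ids: Sequence[str], n_pairs: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Sample distinct random document pairs (the baseline pool)."""
    ids = list(doc_ids)
    if len(ids) < 2:
        raise ValueError("need at least two documents to form pairs")
    pairs = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(ids), size=2, replace=False)
        pairs.append((ids[i], ids[j]))
    return pairs


def relevance_pairs(
    qrels,
    grade: int,
    doc_ids: Sequence[str],
    n_pairs: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Sample pairs of documents sharing the given relevance grade for the
    same topic (restricted to docs present in ``doc_ids``)."""
    available = set(doc_ids)
    pools: list[list[str]] = []
    for topic_id in qrels.topic_ids():
        pool = [
            d
            for d, g in sorted(qrels.judged_docs(topic_id).items())
            if g == grade and d in available
        ]
        if len(pool) >= 2:
            pools.append(pool)
    if not pools:
        raise ValueError(f"no topic has two judged docs with grade {grade}")
    pairs = []
    for _ in range(n_pairs):
        pool = pools[rng.integers(len(pools))]
        i, j = rng.choice(len(pool), size=2, replace=False)
        pairs.append((pool[i], pool[j]))
    return pairs
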