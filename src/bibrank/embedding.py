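"""Sentence embedders, triplet margin loss, and the metric-learning loop.

The training objective is the triplet margin loss

    L = max(d(e_qt, e_qa) − d(e_qt, e_na) + m, 0)

where e_qt / e_qa are the embeddings of a query paper's title and abstract
(the positive pair — two views of the same paper) and e_na is the abstract
embedding of a negative paper; d is the Euclidean distance and m the margin.
Minimizing L pulls a paper's title toward its own abstract and pushes it at
least m past the negative's abstract, so a short query string lands near the
documents it describes.

Any model satisfying the :class:`SentenceEmbedder` contract can be trained.
The reference implementation here is :class:`BagOfWordsEmbedder`: token
counts followed by a trainable linear projection and length normalization.
It is deterministic, CPU-fast, and differentiable in closed form, which
makes every training property checkable at desk scale; a transformer
encoder with mean pooling over its 512 token vectors drops in behind the
same contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .lexical import tokenize
from .mining import Triplet

__all__ = [
    "SentenceEmbedder",
    "TrainConfig",
    "BagOfWordsEmbedder",
    "mean_pool",
    "triplet_loss",
    "train",
]

logger = logging.getLogger(__name__)


@runtime_checkable
class SentenceEmbedder(Protocol):
    """Contract: deterministic text -> fixed-length real vector."""

    dim: int
    trainable: bool

    def encode(self, text: str) -> np.ndarray:
        ...


@dataclass
class TrainConfig:
    """Hyperparameters of the triplet training loop.

    Defaults follow the transformer fine-tuning recipe (lr 5e-6, batch
    size 1, 512-token truncation, 3 epochs); the bag-of-words embedder
    needs a larger step (lr around 0.05) because its parameter count is
    tiny.  ``margin`` is the required separation m between positive and
    negative distances; unit margin is the standard choice for Euclidean
    triplet losses.
    """

    margin: float = 1.0
    epochs: int = 3
    learning_rate: float = 5e-6
    batch_size: int = 1
    max_tokens: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_tokens < 1:
            raise ValueError("learning_rate, batch_size, max_tokens must be positive")


def mean_pool(token_vectors: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Element-wise arithmetic mean of a non-empty stack of token vectors.

    This is how a per-token encoder's output matrix is collapsed into one
    sentence embedding.  Pool only over real (non-padding) positions.
    """
    arr = np.asarray(token_vectors, dtype=float)
    if arr.size == 0 or arr.ndim != 2:
        raise ValueError("mean_pool needs a non-empty 2-D stack of vectors")
    return arr.mean(axis=0)


def triplet_loss(
    e_qt: np.ndarray, e_qa: np.ndarray, e_na: np.ndarray, m: float
) -> float:
    """max(‖e_qt − e_qa‖₂ − ‖e_qt − e_na‖₂ + m, 0)."""
    e_qt, e_qa, e_na = (np.asarray(v, dtype=float) for v in (e_qt, e_qa, e_na))
    if not (e_qt.shape == e_qa.shape == e_na.shape):
        raise ValueError("embedding dimensions differ")
    dp = float(np.linalg.norm(e_qt - e_qa))
    dn = float(np.linalg.norm(e_qt - e_na))
    return max(dp - dn + m, 0.0)


class BagOfWordsEmbedder:
    """Token counts → trainable linear projection → unit-norm vector.

    encode(text) = normalize(W c) where c is the vocabulary count vector of
    the (truncated) token sequence and W is a dim × |V| matrix initialized
    as a seeded Gaussian random projection.  Word order never matters;
    out-of-vocabulary tokens are ignored; a text with no in-vocabulary
    tokens embeds to the zero vector (callers treat that as unscorable).
    """

    def __init__(
        self,
        vocabulary: Sequence[str],
        dim: int,
        seed: int = 0,
        trainable: bool = True,
    ):
        if not vocabulary:
            raise ValueError("vocabulary must be non-empty")
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.vocab_index = {w: i for i, w in enumerate(vocabulary)}
        if len(self.vocab_index) != len(vocabulary):
            raise ValueError("vocabulary contains duplicates")
        self.dim = int(dim)
        self.trainable = bool(trainable)
        rng = np.random.default_rng(seed)
        # 1/sqrt(dim) scaling: random-projection rows are near-orthonormal
        self.weights = rng.standard_normal((dim, len(vocabulary))) / np.sqrt(dim)

    def counts(self, text: str, max_tokens: int | None = None) -> np.ndarray:
        tokens = tokenize(text)
        if max_tokens is not None:
            tokens = tokens[:max_tokens]
        c = np.zeros(len(self.vocab_index))
        for t in tokens:
            idx = self.vocab_index.get(t)
            if idx is not None:
                c[idx] += 1.0
        return c

    def encode(self, text: str, max_tokens: int | None = None) -> np.ndarray:
        c = self.counts(text, max_tokens)
        x = self.weights @ c
        norm = np.linalg.norm(x)
        return x / norm if norm > 0 else x

    # -- gradient of the triplet loss w.r.t. the projection matrix ---------

    def loss_and_grad(
        self, triplet: Triplet, margin: float, max_tokens: int
    ) -> tuple[float, np.ndarray]:
        """Triplet loss and dL/dW for one (anchor, positive, negative)."""
        texts = (triplet.anchor_text, triplet.positive_text, triplet.negative_text)
        cs = [self.counts(t, max_tokens) for t in texts]
        xs = [self.weights @ c for c in cs]
        norms = [np.linalg.norm(x) for x in xs]
        es = [x / n if n > 0 else x for x, n in zip(xs, norms)]
        e_a, e_p, e_n = es

        dp = float(np.linalg.norm(e_a - e_p))
        dn = float(np.linalg.norm(e_a - e_n))
        loss = dp - dn + margin
        grad = np.zeros_like(self.weights)
        if loss <= 0:
            return 0.0, grad

        # dL/de for each of the three embeddings (subgradient 0 at d = 0)
        g_a = np.zeros(self.dim)
        g_p = np.zeros(self.dim)
        g_n = np.zeros(self.dim)
        if dp > 0:
            u = (e_a - e_p) / dp
            g_a += u
            g_p -= u
        if dn > 0:
            u = (e_a - e_n) / dn
            g_a -= u
            g_n += u

        # back through e = x/‖x‖ then x = W c (shared W across the three)
        for g_e, x, n, c in zip((g_a, g_p, g_n), xs, norms, cs):
            if n == 0:
                continue
            e = x / n
            g_x = (g_e - np.dot(g_e, e) * e) / n
            grad += np.outer(g_x, c)
        return loss, grad

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        vocab = sorted(self.vocab_index, key=self.vocab_index.get)
        np.savez(
            path,
            weights=self.weights,
            vocabulary=np.array(vocab, dtype=object),
            trainable=self.trainable,
        )

    @classmethod
    def load(cls, path: str | Path) -> "BagOfWordsEmbedder":
        data = np.load(path, allow_pickle=True)
        vocab = [str(w) for w in data["vocabulary"]]
        emb = cls(vocab, dim=data["weights"].shape[0], trainable=bool(data["trainable"]))
        emb.weights = data["weights"]
        return emb


class _Adam:
    """Minimal Adam optimizer for a single parameter array."""

    def __init__(self, shape, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        return self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    embedder: BagOfWordsEmbedder,
    triplets: Sequence[Triplet],
    config: TrainConfig,
) -> list[float]:
    """Fine-tune a trainable embedder on mined triplets; returns per-epoch
    mean losses.

    Each epoch shuffles the triplets (seeded) and applies Adam updates on
    mini-batch-averaged gradients of the triplet loss; texts are truncated
    to ``max_tokens`` tokens before encoding.  The embedder is updated in
    place; zero epochs leave the parameters untouched.
    """
    if not getattr(embedder, "trainable", False):
        raise ValueError("embedder is not trainable")
    if not triplets:
        raise ValueError("no triplets to train on")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(embedder.weights.shape, config.learning_rate)
    epoch_losses: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(triplets))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grad = np.zeros_like(embedder.weights)
            for idx in batch:
                loss, g = embedder.loss_and_grad(
                    triplets[idx], config.margin, config.max_tokens
                )
                losses.append(loss)
                grad += g
            embedder.weights -= opt.step(grad / len(batch))
        epoch_losses.append(float(np.mean(losses)))
        logger.info("epoch %d: mean triplet loss %.4f", epoch + 1, epoch_losses[-1])
    return epoch_losses
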