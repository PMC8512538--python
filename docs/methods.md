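# Methods

## The model

`bibrank` treats a paper's bibliography as a bag of citation keys and the
corpus as a binary incidence matrix M ∈ {0,1}^(D×C) over D documents and C
cited works. The analogy with latent semantic analysis is exact:
bibliographies play the role of texts, citation keys the role of words. A
rank-k truncated SVD, M ≈ U_k Σ_k V_kᵀ, yields per-document latent vectors
U_k Σ_k whose cosine distances expose both first-order relations (shared
references) and higher-order relations (references that are themselves
co-cited). These distances supervise everything downstream, so the system
needs no human labels.

Negative selection for the triplet set uses the rule: a paper n is an
admissible negative for query q iff cos-dist(v_q, v_n) ≥ 1, i.e. the two
latent vectors are orthogonal or anti-correlated — no detectable shared
citation structure. The comparison is inclusive because exact
orthogonality is the typical case for sparse disjoint bibliographies;
an exclusive threshold would discard most intended negatives. Negatives
are drawn uniformly at random without replacement among admissible
candidates under a recorded seed, three per query by default.

The triplet margin loss L = max(d_p − d_n + m, 0) with Euclidean d acts on
(title, own abstract, negative abstract). The margin m defaults to 1.0 —
the standard unit margin for Euclidean triplet losses; the loss is scale-
bounded anyway because all embeddings are unit-normalized.

Retrieval fuses two scores per query over the whole corpus:
s = α·s_n + (1−α)·s_b′ with α = 0.815, where s_n is the cosine between
query and document (title+abstract) embeddings and s_b′ is BM25 Okapi
(K = 1.25, b = 0.75) min–max normalized to [0,1] per query. The
normalization is the single most consequential design choice that the
fusion formula itself leaves open: cosine is bounded by 1 while raw BM25
is unbounded, so without normalization α would effectively be corpus- and
query-dependent. Min–max is the default; z-score and raw are available via
`FusionConfig(bm25_normalization=...)`.

The reranker revisits the top p = 10 documents with full-text evidence.
Each document's passage set is its paragraphs plus its title and abstract
(guaranteeing ≥ 2 passages even without full text); s_r is the maximum
passage cosine against the query, and pool members are re-sorted by
s_f = β·s + (1−β)·s_r with β = 0.77. Two deliberate conventions:

* The pool stays ahead of the tail and the tail's internal order is
  untouched — s_f is only defined for pool members, and comparing it with
  tail retrieval scores would mix scales.
* Because s_f can still drop below the tail's raw s, tail scores are
  shifted down by a constant when needed so the output list remains
  non-increasing. The shift preserves order and score differences; pool
  scores are the literal s_f values. Evaluation uses list order, so the
  shift never affects metrics.

Ties anywhere are broken by doc_id ascending, making every ranking and
every written run file byte-reproducible.

The teacher loop closes the self-supervision cycle: the full system ranks
each topic, the top 3 documents become positives and the last 15 negatives,
paired sequentially five-per-positive walking backward from the final rank
(positive 1 ↔ ranks n…n−4, positive 2 ↔ n−5…n−9, positive 3 ↔ n−10…n−14),
giving 15 triplets per topic. The embedder is then fine-tuned for two more
epochs. Teacher retrieval runs over the full corpus by default.

## Evaluation conventions

P@N and MAP binarize relevance at grade ≥ 1; P@N divides by N even when
fewer documents are retrieved; MAP is discrete average precision with the
number of judged relevant documents in the denominator, and topics without
relevant documents count as zero. DCG uses linear gain with the classic
discount (rank 1 undiscounted, rank i ≥ 2 divided by log2 i), normalized
by the ideal DCG over the topic's judged grades. Bpref follows the
trec_eval convention: the count of judged non-relevant documents above
each relevant retrieved document is capped at and divided by min(R, N)
(R judged relevant, N judged non-relevant); unjudged documents are
invisible. The textbook variant that divides by R without capping can go
negative when judged non-relevant outnumber relevant; it is provided
behind `bpref(..., literal=True)` and exercised in a test that documents
where the two differ. Rankings are evaluated in list order, not re-sorted
by score.

## Numerical choices

* SVD: a dense LAPACK path is used when min(D, C) ≤ 1500 (exact,
  deterministic); larger matrices use ARPACK `svds` with a fixed start
  vector. Both paths fix singular-vector signs by making the
  largest-magnitude coefficient of each left singular vector positive, so
  embeddings are machine-independent; the two paths are cross-checked in a
  test. k must satisfy k ≤ min(D, C) − 1; the default for real corpora is
  1024, while synthetic runs use min(D, C)/4.
* Column-then-row pruning of the citation matrix iterates to a fixed
  point: removing low-support columns can empty rows, whose removal can
  push more columns below support 2.
* The bag-of-words embedder initializes its dim × |V| projection as a
  seeded Gaussian scaled by 1/√dim and L2-normalizes outputs. Texts with
  no in-vocabulary tokens embed to the zero vector; retrieval scores such
  documents 0 rather than erroring, and the reranker skips zero-norm
  passages. Gradients of the triplet loss through the normalization are
  analytic (verified against finite differences); the optimizer is a
  minimal Adam. The loss is piecewise smooth; at d_p = 0 or d_n = 0 the
  subgradient 0 is used.
* Tokenization: lower-cased `\w+` runs with internal hyphens/apostrophes
  kept ("COVID-19" stays one token), punctuation-only tokens dropped, no
  stemming or stopword removal. Query tokens repeated in the query
  contribute once per occurrence to BM25, per the summation over query
  positions.
* Training truncates each text to 512 tokens before counting, mirroring
  fixed-length encoder inputs. A transformer encoder would mean-pool only
  non-padding token vectors; `mean_pool` therefore takes the actual token
  stack rather than a padded matrix.

## The synthetic study corpus

The generator emulates the statistical structure the method exploits:
topical clusters (default 4 × 50 documents) with cluster-specific token
vocabularies (120 words each, plus 60 shared filler words, mixed 70/30),
per-cluster citation pools (40 keys) sampled within-cluster with
probability 0.9, 8 distinct citations per document, titles of 8 tokens,
abstracts of 40, three 30-token paragraphs, one topic per cluster, and
graded judgments: same-cluster documents are grade 2 (core) with
probability 0.5, otherwise grade 1; other clusters grade 0.

Core documents draw their within-cluster citations from the first half of
the cluster pool while peripheral documents use the whole pool. This makes
grade-2 pairs citation-tighter than grade-1 pairs, which in turn are far
tighter than cross-cluster pairs — the graded structure the pair-distance
evaluation (random > grade-1 > grade-2 mean distances) measures. The
pair-distance study uses a 6-cluster, 300-document variant with 60-key
pools so ranks up to k = 256 are well-defined.

Desk-scale training conditions, fixed once: embedding dim 32, learning
rate 0.05 (the tiny linear model needs a far larger step than a
transformer's 5e−6, which remains the `TrainConfig` default), 3 epochs for
initial training, 2 for the teacher step, batch size 1, margin 1.0.

What the generator does *not* emulate: natural language (tokens are
categorical draws, so nothing tests linguistic generalization, subword
tokenization, or encoder capacity), realistic citation-count skew,
metadata such as authors or dates, and partially judged pools (every
document is judged for every topic, so metrics here do not probe Bpref's
robustness advantage on incomplete judgments). Passing tests therefore
demonstrate the correctness and the qualitative behaviour of the
machinery — not the absolute retrieval quality achievable on a real
corpus with a transformer encoder.

## Known limitations

* The shipped embedder is intentionally small; state-of-the-art quality on
  real corpora requires plugging a pre-trained scientific-text transformer
  into the `SentenceEmbedder` contract and training it with the same loop
  (learning rate 5e−6, batch size 1, 3 epochs is the reference recipe).
* Scoring is exhaustive over the corpus (no approximate nearest-neighbor
  index); fine for 10⁵ documents, not for 10⁸.
* Whether to normalize BM25 before fusion — and how — is an open modelling
  question; results at α near the default are not very sensitive to it on
  the synthetic corpora, but real-corpus tuning of α should re-examine it.
* Queries are served from one chosen topic field (default the question);
  abstract-less documents are indexed with title-only text rather than
  dropped.
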