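import numpy as np
import pytest

from bibrank import (
    BagOfWordsEmbedder,
    Document,
    FusionConfig,
    NeuralIndex,
    build_index,
    build_neural_index,
    cosine_similarity,
    rerank,
    retrieve,
    search,
    tokenize,
    write_run,
)


class TestCosine:
    def test_identity_orthogonal_antipodal(self):
        a = np.array([1.0, 2.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity(a, -a) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([1.0], [1.0, 0.0])


class TestNeuralIndex:
    def test_query_equal_to_doc_scores_one(self):
        index = NeuralIndex(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        scores = index.scores(np.array([1.0, 0.0]))
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(0.0)

    def test_scores_match_bruteforce_cosine_loop(self):
        rng = np.random.default_rng(0)
        vectors = rng.standard_normal((12, 6))
        index = NeuralIndex([f"d{i}" for i in range(12)], vectors)
        q = rng.standard_normal(6)
        scores = index.scores(q)
        for i in range(12):
            assert scores[i] == pytest.approx(cosine_similarity(vectors[i], q))

    def test_zero_document_vector_scores_zero(self):
        index = NeuralIndex(["a", "b"], np.array([[0.0, 0.0], [0.0, 1.0]]))
        scores = index.scores(np.array([1.0, 1.0]))
        assert scores[0] == 0.0

    def test_dim_mismatch_and_zero_query_rejected(self):
        index = NeuralIndex(["a"], np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError):
            index.scores(np.zeros(3))
        with pytest.raises(ValueError):
            index.scores(np.zeros(2))

    def test_persistence_round_trip(self, tmp_path):
        index = NeuralIndex(["a", "b"], np.array([[1.0, 2.0], [3.0, 4.0]]))
        index.save(tmp_path / "nindex")
        back = NeuralIndex.load(tmp_path / "nindex")
        assert back.doc_ids == index.doc_ids
        np.testing.assert_array_equal(back.vectors, index.vectors)


VOCAB = [f"w{i}" for i in range(30)]


def _corpus():
    return [
        Document("a", title="w0 w1", abstract="w2 w3 w0",
                 paragraphs=("w0 w1 w2", "w4 w5")),
        Document("b", title="w10 w11", abstract="w12 w13",
                 paragraphs=("w10 w11 w12",)),
        Document("c", title="w20 w21", abstract="w22 w23",
                 paragraphs=("w20 w23",)),
    ]


@pytest.fixture()
def toy_setup():
    corpus = _corpus()
    embedder = BagOfWordsEmbedder(VOCAB, dim=16, seed=0)
    nindex = build_neural_index(corpus, embedder)
    bm25 = build_index(corpus)
    return corpus, embedder, nindex, bm25


class TestRetrieve:
    def test_alpha_one_reproduces_pure_neural_ordering(self, toy_setup):
        corpus, embedder, nindex, bm25 = toy_setup
        query = "w0 w1 w2"
        ranked = retrieve(query, embedder, nindex, bm25, FusionConfig(alpha=1.0))
        s_n = nindex.scores(embedder.encode(query))
        expected = [
            d for d, _ in sorted(
                zip(nindex.doc_ids, s_n), key=lambda e: (-e[1], e[0])
            )
        ]
        assert ranked.doc_ids() == expected

    def test_alpha_zero_reproduces_pure_bm25_ordering(self, toy_setup):
        corpus, embedder, nindex, bm25 = toy_setup
        query = "w0 w12"
        ranked = retrieve(query, embedder, nindex, bm25, FusionConfig(alpha=0.0))
        s_b = bm25.scores(tokenize(query))
        expected = [
            d for d, _ in sorted(
                zip(bm25.doc_ids, s_b), key=lambda e: (-e[1], e[0])
            )
        ]
        assert ranked.doc_ids() == expected

    def test_fused_score_arithmetic(self, toy_setup):
        corpus, embedder, nindex, bm25 = toy_setup
        # query embedding == doc a's embedding -> s_n(a) = 1; query shares
        # no token with a -> s_b(a) = 0 = min over docs -> normalized 0
        query = "w12 w22"
        q_emb = nindex.vectors[0]

        class FixedEmbedder:
            dim = 16
            trainable = False

            def encode(self, text):
                return q_emb

        ranked = retrieve(query, FixedEmbedder(), nindex, bm25,
                          FusionConfig(alpha=0.815))
        score_a = dict(ranked.entries)["a"]
        assert score_a == pytest.approx(0.815)

    def test_cutoff_truncates(self, toy_setup):
        corpus, embedder, nindex, bm25 = toy_setup
        ranked = retrieve("w0", embedder, nindex, bm25,
                          FusionConfig(cutoff=2))
        assert len(ranked) == 2

    def test_mismatched_indices_rejected(self, toy_setup):
        corpus, embedder, nindex, bm25 = toy_setup
        other = build_index(corpus[:2])
        with pytest.raises(ValueError):
            retrieve("w0", embedder, nindex, other, FusionConfig())

    def test_run_files_are_byte_identical_across_repeats(
        self, toy_setup, tmp_path
    ):
        corpus, embedder, nindex, bm25 = toy_setup
        payloads = []
        for rep in range(2):
            ranked = retrieve("w0 w10", embedder, nindex, bm25, FusionConfig())
            path = tmp_path / f"run{rep}.txt"
            write_run([ranked], "tag", path)
            payloads.append(path.read_bytes())
        assert payloads[0] == payloads[1]


class TestRerank:
    def test_beta_one_preserves_input_order(self, toy_setup):
        corpus, embedder, nindex, bm25 = toy_setup
        ranked = retrieve("w0 w10", embedder, nindex, bm25, FusionConfig())
        out = rerank(ranked, embedder.encode("w0 w10"), corpus, embedder,
                     FusionConfig(beta=1.0, pool=2))
        assert out.doc_ids() == ranked.doc_ids()

    def test_pool_set_is_invariant_and_tail_untouched(self, default_corpus):
        embedder = BagOfWordsEmbedder(
            sorted({t for d in default_corpus for t in tokenize(d.text)}),
            dim=32, seed=1,
        )
        nindex = build_neural_index(default_corpus, embedder)
        bm25 = build_index(default_corpus)
        query = default_corpus[0].title
        ranked = retrieve(query, embedder, nindex, bm25, FusionConfig())
        out = rerank(ranked, embedder.encode(query), default_corpus, embedder,
                     FusionConfig(pool=10, beta=0.3))
        assert set(out.doc_ids()[:10]) == set(ranked.doc_ids()[:10])
        assert out.doc_ids()[10:] == ranked.doc_ids()[10:]

    def test_matching_abstract_passage_reaches_similarity_one(self):
        corpus = _corpus()
        embedder = BagOfWordsEmbedder(VOCAB, dim=16, seed=0)
        q_emb = embedder.encode(corpus[1].abstract)
        from bibrank.corpus import RankedList

        ranked = RankedList("0", [("a", 3.0), ("b", 2.0), ("c", 1.0)])
        out = rerank(ranked, q_emb, corpus, embedder,
                     FusionConfig(beta=0.0, pool=3))
        assert out.doc_ids()[0] == "b"
        assert dict(out.entries)["b"] == pytest.approx(1.0)

    def test_hand_computed_fusion_with_pool_two(self):
        corpus = _corpus()
        embedder = BagOfWordsEmbedder(VOCAB, dim=16, seed=0)
        from bibrank.corpus import RankedList

        ranked = RankedList("0", [("a", 0.9), ("b", 0.4), ("c", 0.1)])
        q_emb = embedder.encode("w0 w10 w12")
        config = FusionConfig(beta=0.77, pool=2)
        out = rerank(ranked, q_emb, corpus, embedder, config)

        def best_passage(doc):
            passages = list(doc.paragraphs) + [doc.title, doc.abstract]
            return max(
                cosine_similarity(embedder.encode(p), q_emb) for p in passages
            )

        expected = {
            "a": 0.77 * 0.9 + 0.23 * best_passage(corpus[0]),
            "b": 0.77 * 0.4 + 0.23 * best_passage(corpus[1]),
        }
        got = dict(out.entries)
        assert got["a"] == pytest.approx(expected["a"], abs=1e-12)
        assert got["b"] == pytest.approx(expected["b"], abs=1e-12)
        # tail doc c keeps its position at the end
        assert out.doc_ids()[2] == "c"

    def test_tail_scores_shift_keeps_list_monotone(self):
        corpus = _corpus()
        embedder = BagOfWordsEmbedder(VOCAB, dim=16, seed=0)
        from bibrank.corpus import RankedList

        # huge retrieval scores so beta*s ~ s, but pool s_f can dip below tail
        ranked = RankedList("0", [("a", 1.0), ("b", 0.99), ("c", 0.98)])
        out = rerank(ranked, embedder.encode("w20 w21"), corpus, embedder,
                     FusionConfig(beta=0.1, pool=2))
        scores = [s for _, s in out.entries]
        assert all(x >= y for x, y in zip(scores, scores[1:]))

    def test_empty_list_rejected(self):
        from bibrank.corpus import RankedList

        embedder = BagOfWordsEmbedder(VOCAB, dim=16, seed=0)
        with pytest.raises(ValueError):
            rerank(RankedList("0", []), np.ones(16), [], embedder,
                   FusionConfig())


def test_search_pipeline_smoke(default_corpus, default_topics):
    vocab = sorted({t for d in default_corpus for t in tokenize(d.text)})
    embedder = BagOfWordsEmbedder(vocab, dim=32, seed=0)
    nindex = build_neural_index(default_corpus, embedder)
    bm25 = build_index(default_corpus)
    topic = default_topics[0]
    ranked = search(topic.query_text(), embedder, nindex, bm25,
                    default_corpus, FusionConfig(), topic_id=topic.topic_id)
    assert ranked.topic_id == topic.topic_id
    assert len(ranked) == len(default_corpus)
    scores = [s for _, s in ranked.entries]
    assert all(x >= y for x, y in zip(scores, scores[1:]))


def test_fusion_config_validation():
    with pytest.raises(ValueError):
        FusionConfig(alpha=1.5)
    with pytest.raises(ValueError):
        FusionConfig(beta=-0.1)
    with pytest.raises(ValueError):
        FusionConfig(pool=0)
    with pytest.raises(ValueError):
        FusionConfig(bm25_normalization="bogus")
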