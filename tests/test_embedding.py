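import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bibrank import (
    BagOfWordsEmbedder,
    TrainConfig,
    Triplet,
    mean_pool,
    train,
    triplet_loss,
)


class TestMeanPool:
    def test_identical_vectors_pool_to_themselves(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(mean_pool([v, v]), v)

    def test_simple_arithmetic(self):
        np.testing.assert_allclose(
            mean_pool([[1.0, 0.0], [0.0, 1.0]]), [0.5, 0.5]
        )

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        mat = rng.standard_normal((512, 8))
        naive = np.array(
            [sum(mat[i][j] for i in range(512)) / 512 for j in range(8)]
        )
        np.testing.assert_allclose(mean_pool(mat), naive, atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mean_pool(np.empty((0, 4)))


class TestTripletLoss:
    def test_equal_positive_and_negative_gives_margin(self):
        e = np.array([1.0, 0.0])
        other = np.array([0.0, 1.0])
        assert triplet_loss(e, other, other, m=0.4) == pytest.approx(0.4)

    def test_satisfied_margin_gives_zero(self):
        a = np.zeros(3)
        p = np.zeros(3)  # dp = 0
        n = np.array([2.0, 0.0, 0.0])  # dn = 2 >= m
        assert triplet_loss(a, p, n, m=1.0) == 0.0

    def test_direct_arithmetic(self):
        # dp = 0.2, dn = 0.9, m = 1 -> 0.3
        a = np.array([0.0])
        p = np.array([0.2])
        n = np.array([0.9])
        assert triplet_loss(a, p, n, m=1.0) == pytest.approx(0.3)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss(np.zeros(2), np.zeros(3), np.zeros(3), m=1.0)

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.floats(0, 3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nonnegative_and_zero_iff_margin_met(self, a, p, n, m):
        a, p, n = np.array(a), np.array(p), np.array(n)
        loss = triplet_loss(a, p, n, m)
        dp = np.linalg.norm(a - p)
        dn = np.linalg.norm(a - n)
        assert loss >= 0.0
        assert loss == pytest.approx(max(dp - dn + m, 0.0), abs=1e-12)
        assert (loss == 0.0) == (dp - dn + m <= 0)

    def test_swapping_closer_positive_for_negative_increases_loss(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, p, n = rng.standard_normal((3, 6))
            dp = np.linalg.norm(a - p)
            dn = np.linalg.norm(a - n)
            if dp < dn:
                assert triplet_loss(a, n, p, 1.0) >= triplet_loss(a, p, n, 1.0)


VOCAB = [f"w{i}" for i in range(40)]


class TestBagOfWordsEmbedder:
    def test_deterministic_and_unit_norm(self):
        emb = BagOfWordsEmbedder(VOCAB, dim=16, seed=3)
        v1 = emb.encode("w1 w2 w3")
        v2 = emb.encode("w1 w2 w3")
        np.testing.assert_array_equal(v1, v2)
        assert np.linalg.norm(v1) == pytest.approx(1.0)

    def test_word_order_is_irrelevant(self):
        emb = BagOfWordsEmbedder(VOCAB, dim=16, seed=3)
        np.testing.assert_allclose(
            emb.encode("w1 w2 w3"), emb.encode("w3 w1 w2")
        )

    def test_same_seed_same_weights(self):
        a = BagOfWordsEmbedder(VOCAB, dim=8, seed=5)
        b = BagOfWordsEmbedder(VOCAB, dim=8, seed=5)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_disjoint_vocabulary_texts_are_near_orthogonal(self):
        # random-projection concentration: |cos| stays small for most seeds
        sims = []
        for seed in range(40):
            emb = BagOfWordsEmbedder(VOCAB, dim=64, seed=seed)
            sims.append(
                abs(float(np.dot(emb.encode("w0 w1 w2 w3"), emb.encode("w20 w21 w22 w23"))))
            )
        assert np.mean(sims) < 0.2
        assert np.max(sims) < 0.6

    def test_out_of_vocabulary_text_embeds_to_zero(self):
        emb = BagOfWordsEmbedder(VOCAB, dim=8, seed=0)
        assert np.linalg.norm(emb.encode("unknown tokens only")) == 0.0

    def test_truncation_limits_counted_tokens(self):
        emb = BagOfWordsEmbedder(VOCAB, dim=8, seed=0)
        text = "w0 " * 600 + "w1"
        counts = emb.counts(text, max_tokens=512)
        assert counts[emb.vocab_index["w0"]] == 512
        assert counts[emb.vocab_index["w1"]] == 0

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            BagOfWordsEmbedder([], dim=8)
        with pytest.raises(ValueError):
            BagOfWordsEmbedder(VOCAB, dim=1)
        with pytest.raises(ValueError):
            BagOfWordsEmbedder(["a", "a"], dim=4)

    def test_save_load_round_trip(self, tmp_path):
        emb = BagOfWordsEmbedder(VOCAB, dim=8, seed=2)
        path = tmp_path / "model.npz"
        emb.save(path)
        back = BagOfWordsEmbedder.load(path)
        np.testing.assert_array_equal(back.weights, emb.weights)
        np.testing.assert_allclose(back.encode("w1 w2"), emb.encode("w1 w2"))


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        emb = BagOfWordsEmbedder(VOCAB[:10], dim=4, seed=1)
        triplet = Triplet("q", "n", "w0 w1", "w1 w2 w0", "w7 w8 w9")
        loss, grad = emb.loss_and_grad(triplet, margin=1.0, max_tokens=512)
        assert loss > 0  # otherwise the gradient is trivially zero
        eps = 1e-6
        num = np.zeros_like(grad)
        for i in range(emb.weights.shape[0]):
            for j in range(emb.weights.shape[1]):
                emb.weights[i, j] += eps
                lp, _ = emb.loss_and_grad(triplet, 1.0, 512)
                emb.weights[i, j] -= 2 * eps
                lm, _ = emb.loss_and_grad(triplet, 1.0, 512)
                emb.weights[i, j] += eps
                num[i, j] = (lp - lm) / (2 * eps)
        np.testing.assert_allclose(grad, num, atol=1e-5)


def _toy_triplets(rng, n=60):
    """Anchor/positive share a vocabulary half; negative uses the other."""
    left, right = VOCAB[:20], VOCAB[20:]
    triplets = []
    for i in range(n):
        src, other = (left, right) if i % 2 == 0 else (right, left)
        words = lambda pool, k: " ".join(rng.choice(pool, size=k))
        triplets.append(
            Triplet(f"q{i}", f"n{i}", words(src, 4), words(src, 10), words(other, 10))
        )
    return triplets


class TestTrain:
    def test_zero_epochs_leave_parameters_unchanged(self):
        emb = BagOfWordsEmbedder(VOCAB, dim=8, seed=0)
        before = emb.weights.copy()
        losses = train(emb, _toy_triplets(np.random.default_rng(0)),
                       TrainConfig(epochs=0))
        assert losses == []
        np.testing.assert_array_equal(emb.weights, before)

    def test_loss_trajectory_decreases_on_separable_triplets(self):
        emb = BagOfWordsEmbedder(VOCAB, dim=16, seed=0)
        triplets = _toy_triplets(np.random.default_rng(1))
        losses = train(
            emb, triplets,
            TrainConfig(epochs=3, learning_rate=0.05, seed=0),
        )
        assert losses[-1] < losses[0]

    def test_training_raises_margin_satisfaction_fraction(self):
        def satisfied_fraction(embedder, triplets):
            good = 0
            for t in triplets:
                a = embedder.encode(t.anchor_text)
                p = embedder.encode(t.positive_text)
                n = embedder.encode(t.negative_text)
                if np.linalg.norm(a - p) < np.linalg.norm(a - n):
                    good += 1
            return good / len(triplets)

        triplets = _toy_triplets(np.random.default_rng(2))
        emb = BagOfWordsEmbedder(VOCAB, dim=16, seed=3)
        before = satisfied_fraction(emb, triplets)
        train(emb, triplets, TrainConfig(epochs=3, learning_rate=0.05, seed=0))
        after = satisfied_fraction(emb, triplets)
        assert after > before

    def test_training_is_deterministic_under_seed(self):
        triplets = _toy_triplets(np.random.default_rng(3))
        results = []
        for _ in range(2):
            emb = BagOfWordsEmbedder(VOCAB, dim=8, seed=1)
            train(emb, triplets, TrainConfig(epochs=2, learning_rate=0.05, seed=9))
            results.append(emb.weights.copy())
        np.testing.assert_array_equal(results[0], results[1])

    def test_untrainable_embedder_rejected(self):
        emb = BagOfWordsEmbedder(VOCAB, dim=8, seed=0, trainable=False)
        with pytest.raises(ValueError):
            train(emb, _toy_triplets(np.random.default_rng(0)), TrainConfig())

    def test_empty_triplets_rejected(self):
        emb = BagOfWordsEmbedder(VOCAB, dim=8, seed=0)
        with pytest.raises(ValueError):
            train(emb, [], TrainConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(margin=-0.1)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
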