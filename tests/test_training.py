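"""Loss, input noise, Adadelta, max-norm, and the training loop.

The analytic gradients for every parameter group are checked against
central finite differences on a tiny model.
"""

import numpy as np
import pytest

from relexcnn.embeddings import MultichannelEmbedding, PAD_INDEX, build_vocab
from relexcnn.network import backward_batch, forward_batch, init_params, pad_batch
from relexcnn.preprocess import Instance
from relexcnn.training import (
    AdadeltaState,
    TrainConfig,
    add_input_noise,
    adadelta_step,
    apply_maxnorm,
    nll_loss,
    predict_batches,
    train,
)


class TestNllLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert nll_loss(probs, np.array([0, 1, 2])) == 0.0

    def test_uniform_single_instance_equals_ln_O(self):
        for O in (2, 5, 9):
            probs = np.full((1, O), 1.0 / O)
            assert np.isclose(nll_loss(probs, np.array([0])), np.log(O))

    def test_matches_per_instance_sum(self, rng):
        probs = rng.dirichlet(np.ones(5), size=16)
        gold = rng.integers(0, 5, size=16)
        want = sum(-np.log(probs[i, gold[i]]) for i in range(16))
        assert np.isclose(nll_loss(probs, gold), want)

    def test_zero_probability_clamped_with_warning(self):
        probs = np.array([[1.0, 0.0]])
        with pytest.warns(UserWarning, match="clamped"):
            loss = nll_loss(probs, np.array([1]))
        assert np.isclose(loss, -np.log(1e-12))


class TestInputNoise:
    def test_zero_noise_is_identity(self, rng):
        V = rng.normal(size=(2, 3, 4, 5))
        assert np.array_equal(add_input_noise(V, 0.0, 0.0, rng), V)

    def test_monte_carlo_mean(self):
        rng = np.random.default_rng(0)
        V = np.zeros((1, 1, 10, 100_000))
        noisy = add_input_noise(V, 0.001, 0.001, rng)
        diff = noisy - V
        se = 0.001 / np.sqrt(diff.size)
        assert abs(diff.mean() - 0.001) < 3 * se

    def test_padding_positions_untouched(self, rng):
        V = rng.normal(size=(2, 1, 6, 3))  # (B, c, N, d)
        lengths = np.array([4, 2])
        noisy = add_input_noise(V, 0.5, 0.1, rng, lengths=lengths)
        assert np.array_equal(noisy[0, :, 4:], V[0, :, 4:])
        assert np.array_equal(noisy[1, :, 2:], V[1, :, 2:])
        assert not np.array_equal(noisy[0, :, :4], V[0, :, :4])


class TestAdadelta:
    def _scalar_params(self, value=1.0):
        from relexcnn.network import ModelParams

        # minimal one-parameter-group stand-in via a real ModelParams
        emb = MultichannelEmbedding(D=np.zeros((1, 2, 1)))
        params = init_params(emb, (1,), 1, ["a", "b"], np.random.default_rng(0))
        params.W2[:] = value
        return params

    def test_zero_gradient_leaves_everything_unchanged(self, rng):
        emb = MultichannelEmbedding(D=rng.normal(size=(2, 10, 4)))
        emb.D[:, PAD_INDEX, :] = 0.0
        params = init_params(emb, (2, 3), 2, ["a", "b"], rng)
        state = AdadeltaState.for_params(params)
        before = {k: v.copy() for k, v in params.flat_groups().items()}
        grads = {k: np.zeros_like(v) for k, v in params.flat_groups().items()}
        adadelta_step(params, grads, state)
        for k, v in params.flat_groups().items():
            assert np.array_equal(v, before[k])
            assert np.all(state.sq_grad[k] == 0.0)

    def test_single_step_matches_hand_recurrence(self):
        rho, eps = 0.95, 1e-6
        theta0, g = 2.0, 0.3
        # hand-rolled recurrence
        Eg = (1 - rho) * g * g
        delta = -np.sqrt(0.0 + eps) / np.sqrt(Eg + eps) * g
        expected = theta0 + delta

        params = self._scalar_params(theta0)
        state = AdadeltaState.for_params(params)
        grads = {k: np.zeros_like(v) for k, v in params.flat_groups().items()}
        grads["W2"] = np.full_like(params.W2, g)
        adadelta_step(params, grads, state, rho, eps)
        assert np.allclose(params.W2, expected, atol=1e-12)
        assert np.allclose(state.sq_update["W2"], rho * 0 + (1 - rho) * delta**2)

    def test_non_finite_gradient_aborts(self):
        params = self._scalar_params()
        state = AdadeltaState.for_params(params)
        grads = {k: np.zeros_like(v) for k, v in params.flat_groups().items()}
        grads["W2"] = np.full_like(params.W2, np.nan)
        with pytest.raises(FloatingPointError, match="W2"):
            adadelta_step(params, grads, state)


class TestMaxNorm:
    def test_overlong_row_rescaled_to_exactly_maxnorm(self):
        W2 = np.array([[10.0, 0.0], [3.0, 0.0], [0.0, 0.0]])
        out = apply_maxnorm(W2, 5.0)
        norms = np.linalg.norm(out, axis=1)
        assert np.isclose(norms[0], 5.0)
        assert np.isclose(norms[1], 3.0)  # within the ball: untouched
        assert np.all(out[2] == 0.0)  # zero row: untouched

    def test_direction_preserved(self, rng):
        W2 = rng.normal(size=(4, 6)) * 10
        out = apply_maxnorm(W2, 5.0)
        for before, after in zip(W2, out):
            cos = before @ after / (np.linalg.norm(before) * np.linalg.norm(after))
            assert np.isclose(cos, 1.0)


def _toy_instances(n, n_classes, rng, vocab_words):
    labels = [f"class{i}" for i in range(n_classes)]
    out = []
    for i in range(n):
        lab = labels[i % n_classes]
        mid = [f"cue_{lab}"] + list(
            rng.choice(vocab_words, size=int(rng.integers(1, 4)))
        )
        tokens = ["Entity1"] + mid + ["Entity2"]
        out.append(
            Instance(
                sentence_id=f"s{i}", e1_id="e0", e2_id="e1",
                tokens=tuple(tokens), label=lab,
            )
        )
    return out, labels


class TestGradients:
    def test_analytic_matches_central_finite_differences(self, rng):
        """Backprop for every group of θ=(D, W, W2, b) against central
        finite differences on a tiny model; relative error <= 1e-4."""
        emb = MultichannelEmbedding(D=rng.normal(size=(2, 20, 6)) * 0.5)
        emb.D[:, PAD_INDEX, :] = 0.0
        params = init_params(emb, (2, 3), 3, [f"c{i}" for i in range(4)], rng)
        seqs = [rng.integers(1, 20, size=int(n)) for n in (4, 6, 5)]
        gold = np.array([0, 2, 3])
        idx, lengths = pad_batch(seqs, max(params.windows))

        def loss_fn():
            cache = forward_batch(idx, lengths, params)
            p = cache.probabilities[np.arange(len(gold)), gold]
            return float(-np.log(p).sum())

        cache = forward_batch(idx, lengths, params)
        grads = backward_batch(cache, gold, params)

        eps = 1e-6
        worst = 0.0
        for name, arr in params.flat_groups().items():
            flat = arr.reshape(-1)
            n_checked = min(flat.size, 60)
            check = rng.choice(flat.size, size=n_checked, replace=False)
            for j in check:
                if name == "D" and j // arr.shape[-1] % arr.shape[1] == PAD_INDEX:
                    continue
                orig = flat[j]
                flat[j] = orig + eps
                lp = loss_fn()
                flat[j] = orig - eps
                lm = loss_fn()
                flat[j] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name].reshape(-1)[j]
                denom = max(abs(numeric), abs(analytic), 1e-8)
                worst = max(worst, abs(numeric - analytic) / denom)
        assert worst <= 1e-4

    def test_pad_row_gradient_zero(self, rng):
        emb = MultichannelEmbedding(D=rng.normal(size=(1, 10, 4)))
        params = init_params(emb, (2,), 2, ["a", "b"], rng)
        seqs = [np.array([1, 2]), np.array([3, 4, 5, 6])]  # first gets padded
        idx, lengths = pad_batch(seqs, 2)
        cache = forward_batch(idx, lengths, params)
        grads = backward_batch(cache, np.array([0, 1]), params)
        assert np.all(grads["D"][:, PAD_INDEX, :] == 0.0)


class TestTrainLoop:
    def test_loss_decreases_on_separable_data(self, rng):
        insts, labels = _toy_instances(200, 2, rng, [f"w{i}" for i in range(10)])
        vocab = build_vocab(i.tokens for i in insts)
        emb = MultichannelEmbedding(
            D=np.random.default_rng(0).uniform(-0.25, 0.25, (1, len(vocab), 8))
        )
        emb.D[:, PAD_INDEX, :] = 0.0
        config = TrainConfig(
            n_filters=8, windows=(2, 3), batch_size=20, epochs=5,
            noise_mean=0.0, noise_std=0.0, seed=5,
        )
        _, losses = train(insts, emb, vocab, config, class_labels=labels)
        assert all(a > b for a, b in zip(losses[:5], losses[1:5]))

    def test_zero_epochs_returns_initialization(self, rng):
        insts, labels = _toy_instances(10, 2, rng, ["w0", "w1"])
        vocab = build_vocab(i.tokens for i in insts)
        emb = MultichannelEmbedding(
            D=np.random.default_rng(0).normal(size=(1, len(vocab), 4))
        )
        config = TrainConfig(n_filters=2, windows=(2,), epochs=0, seed=1)
        params, losses = train(insts, emb, vocab, config, class_labels=labels)
        assert losses == []
        # initialization is deterministic given the seed
        params2, _ = train(insts, emb, vocab, config, class_labels=labels)
        assert np.array_equal(params.W2, params2.W2)

    def test_empty_training_set_rejected(self, rng):
        emb = MultichannelEmbedding(D=np.zeros((1, 5, 2)))
        vocab = build_vocab([])
        with pytest.raises(ValueError, match="empty"):
            train([], emb, vocab, TrainConfig(windows=(2,)))

    def test_maxnorm_invariant_holds_after_every_step(self, rng):
        insts, labels = _toy_instances(60, 3, rng, [f"w{i}" for i in range(5)])
        vocab = build_vocab(i.tokens for i in insts)
        emb = MultichannelEmbedding(
            D=np.random.default_rng(1).normal(size=(1, len(vocab), 6))
        )
        maxnorm = 0.05  # tight constraint so rescaling actually bites
        seen: list[float] = []

        config = TrainConfig(
            n_filters=4, windows=(2, 3), batch_size=10, epochs=3,
            maxnorm=maxnorm, seed=2,
        )
        orig = apply_maxnorm

        def spy(W2, mn):
            out = orig(W2, mn)
            seen.append(float(np.linalg.norm(out, axis=1).max()))
            return out

        import relexcnn.training as tr

        old = tr.apply_maxnorm
        tr.apply_maxnorm = spy
        try:
            train(insts, emb, vocab, config, class_labels=labels)
        finally:
            tr.apply_maxnorm = old
        assert seen and all(n <= maxnorm + 1e-9 for n in seen)

    def test_bit_reproducible_with_fixed_seed(self, rng):
        insts, labels = _toy_instances(50, 2, rng, [f"w{i}" for i in range(6)])
        vocab = build_vocab(i.tokens for i in insts)
        emb = MultichannelEmbedding(
            D=np.random.default_rng(3).normal(size=(2, len(vocab), 5))
        )
        emb.D[:, PAD_INDEX, :] = 0.0
        config = TrainConfig(
            n_filters=3, windows=(2, 3), batch_size=10, epochs=3, seed=9
        )
        pa, la = train(insts, emb, vocab, config, class_labels=labels)
        pb, lb = train(insts, emb, vocab, config, class_labels=labels)
        assert la == lb
        for k, v in pa.flat_groups().items():
            assert np.array_equal(v, pb.flat_groups()[k])

    def test_predict_uses_no_noise_and_is_deterministic(self, rng):
        insts, labels = _toy_instances(40, 2, rng, ["w0", "w1", "w2"])
        vocab = build_vocab(i.tokens for i in insts)
        emb = MultichannelEmbedding(
            D=np.random.default_rng(4).normal(size=(1, len(vocab), 5))
        )
        emb.D[:, PAD_INDEX, :] = 0.0
        config = TrainConfig(n_filters=3, windows=(2,), epochs=2, seed=0)
        params, _ = train(insts, emb, vocab, config, class_labels=labels)
        l1, p1 = predict_batches(insts, params, vocab)
        l2, p2 = predict_batches(insts, params, vocab, batch_size=7)
        assert l1 == l2
        assert np.allclose(p1, p2, atol=1e-12)
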