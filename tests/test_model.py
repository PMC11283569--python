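"""Encoder forward/backward pass, masking scheme, ECE, checkpoints."""

import numpy as np
import pytest

from emit.model import (
    DegenerateSequenceError,
    EMITConfig,
    ShapeError,
    compute_ece,
    feed_forward,
    forward,
    init_model_state,
    load_checkpoint,
    mask_sequence,
    masked_lm_loss_and_grads,
    save_checkpoint,
    scaled_dot_product_attention,
    softmax,
)
from emit.motifs import InvalidParameterError, MotifCountProfile
from emit.sequences import rank_and_tokenize


def _hand_attention_3x2():
    """Independent scalar computation of softmax(QK^T/sqrt(2)) for fixed 3x2
    inputs, written out row by row with math.exp, frozen as the oracle."""
    import math

    Q = [[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]
    K = [[1.0, 1.0], [0.0, 2.0], [1.0, 0.0]]
    A = []
    for qi in Q:
        scores = [
            (qi[0] * kj[0] + qi[1] * kj[1]) / math.sqrt(2.0) for kj in K
        ]
        mx = max(scores)
        es = [math.exp(s - mx) for s in scores]
        Z = sum(es)
        A.append([e / Z for e in es])
    return np.array(Q), np.array(K), np.array(A)


class TestScaledDotProductAttention:
    def test_zero_queries_give_uniform_rows(self):
        n = 5
        Q = np.zeros((n, 3))
        K = np.random.default_rng(0).normal(size=(n, 3))
        V = np.eye(n, 3)
        _, A = scaled_dot_product_attention(Q, K, V)
        assert np.allclose(A, 1.0 / n)

    def test_single_position(self):
        out, A = scaled_dot_product_attention([[1.0, 2.0]], [[3.0, 4.0]], [[5.0, 6.0]])
        assert np.allclose(A, [[1.0]])
        assert np.allclose(out, [[5.0, 6.0]])

    def test_matches_hand_computed_3x2_oracle(self):
        Q, K, A_expected = _hand_attention_3x2()
        V = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        out, A = scaled_dot_product_attention(Q, K, V)
        assert np.allclose(A, A_expected, atol=1e-12)
        assert np.allclose(out, A_expected @ V, atol=1e-12)

    def test_rows_sum_to_one_with_and_without_mask(self, rng):
        Q = rng.normal(size=(2, 4, 6, 3))
        K = rng.normal(size=(2, 4, 6, 3))
        V = rng.normal(size=(2, 4, 6, 3))
        mask = np.array([[True] * 4 + [False] * 2, [True] * 6])[:, None, :]
        _, A = scaled_dot_product_attention(Q, K, V, mask=mask)
        assert np.allclose(A.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(A >= 0)
        # no attention leaks onto masked keys
        assert np.allclose(A[0, :, :, 4:], 0.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ShapeError):
            scaled_dot_product_attention(np.zeros((3, 2)), np.zeros((3, 3)), np.zeros((3, 2)))


class TestFeedForward:
    def test_zero_input_zero_biases_gives_zero(self, tiny_model):
        tiny_model.params["l0.b1"][:] = 0
        tiny_model.params["l0.b2"][:] = 0
        x = np.zeros((3, tiny_model.config.hidden_size))
        assert np.allclose(feed_forward(x, tiny_model), 0.0)

    def test_relu_saturation_returns_b2(self, dict_k2):
        cfg = EMITConfig(hidden_size=8, num_heads=2, vocab_size=20, max_positions=10)
        state = init_model_state(cfg, seed=0)
        state.params["l0.b1"][:] = -1e6
        state.params["l0.b2"][:] = 3.5
        out = feed_forward(np.random.default_rng(0).normal(size=(4, 8)), state)
        assert np.allclose(out, 3.5)

    def test_linearity_on_positive_cone(self):
        cfg = EMITConfig(hidden_size=4, num_heads=2, vocab_size=20, max_positions=10, ffn_dim=4)
        state = init_model_state(cfg, seed=0)
        state.params["l0.W1"] = np.eye(4)
        state.params["l0.W2"] = 2.0 * np.eye(4)
        state.params["l0.b1"][:] = 0
        state.params["l0.b2"][:] = 1.0
        x = np.abs(np.random.default_rng(0).normal(size=(3, 4)))
        assert np.allclose(feed_forward(x, state), 2.0 * x + 1.0)

    def test_width_mismatch_raises(self, tiny_model):
        with pytest.raises(ShapeError):
            feed_forward(np.zeros((2, 5)), tiny_model)


class TestForward:
    def _seq_ids(self, dict_k2, counts, t=8):
        seq = rank_and_tokenize(MotifCountProfile("s", counts), t, dict_k2)
        return seq.token_ids(dict_k2), seq.attention_mask

    def test_representation_shape_matches_embedded_input(self, tiny_model, dict_k2):
        ids, mask = self._seq_ids(dict_k2, {"AA": 3, "CC": 1})
        Z, logits, _ = forward(ids, tiny_model, attention_mask=mask)
        assert Z.shape == (10, tiny_model.config.hidden_size)
        assert logits.shape == (10, tiny_model.config.vocab_size)

    def test_eval_mode_deterministic(self, tiny_model, dict_k2):
        ids, mask = self._seq_ids(dict_k2, {"AA": 3, "GT": 2})
        _, l1, _ = forward(ids, tiny_model, attention_mask=mask, train=False)
        _, l2, _ = forward(ids, tiny_model, attention_mask=mask, train=False)
        assert np.array_equal(l1, l2)

    def test_softmax_of_logits_normalized(self, tiny_model, dict_k2):
        ids, mask = self._seq_ids(dict_k2, {"AA": 3})
        _, logits, _ = forward(ids, tiny_model, attention_mask=mask)
        assert np.allclose(softmax(logits).sum(axis=-1), 1.0)

    def test_attention_rows_sum_to_one(self, tiny_model, dict_k2):
        ids, mask = self._seq_ids(dict_k2, {"AA": 5, "CC": 4, "TG": 1})
        _, _, atts = forward(ids, tiny_model, attention_mask=mask)
        for A in atts:
            assert np.allclose(A.sum(axis=-1), 1.0, atol=1e-6)

    def test_pad_tail_invariance(self, tiny_model, dict_k2):
        """Appending PAD positions must not change logits at real positions."""
        short = rank_and_tokenize(MotifCountProfile("s", {"AA": 3, "CC": 1}), 4, dict_k2)
        long = rank_and_tokenize(MotifCountProfile("s", {"AA": 3, "CC": 1}), 10, dict_k2)
        ids_s, mask_s = short.token_ids(dict_k2), short.attention_mask
        ids_l, mask_l = long.token_ids(dict_k2), long.attention_mask
        _, logit_s, _ = forward(ids_s, tiny_model, attention_mask=mask_s)
        _, logit_l, _ = forward(ids_l, tiny_model, attention_mask=mask_l)
        n_real = int(mask_s.sum())
        assert np.allclose(logit_s[:n_real], logit_l[:n_real], atol=1e-10)

    def test_out_of_vocab_id_rejected(self, tiny_model):
        with pytest.raises(InvalidParameterError):
            forward(np.array([0, 99]), tiny_model)

    def test_too_long_sequence_rejected(self, tiny_model):
        with pytest.raises(InvalidParameterError):
            forward(np.zeros(50, dtype=int), tiny_model)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of the masked-LM loss agree with central
        finite differences on a tiny two-layer model."""
        cfg = EMITConfig(hidden_size=8, num_heads=2, num_layers=2, vocab_size=8,
                         max_positions=10, dropout_rate=0.0, ffn_dim=12)
        state = init_model_state(cfg, seed=3)
        ids = np.array([[4, 1, 0, 2, 5, 7], [4, 3, 2, 5, 7, 7]])
        attn = ids != 7
        targets = np.full_like(ids, -1)
        targets[0, 1], targets[0, 3], targets[1, 2] = 1, 2, 0

        def loss_only():
            l, _ = masked_lm_loss_and_grads(state, ids, targets,
                                            attention_mask=attn, train=False)
            return l

        _, grads = masked_lm_loss_and_grads(state, ids, targets,
                                            attention_mask=attn, train=False)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, P in state.params.items():
            flat = P.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_only()
                flat[i] = orig - eps
                lm = loss_only()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert abs(num - ana) <= 1e-6 + 1e-4 * max(abs(num), abs(ana)), name


class TestMaskSequence:
    def _batch_ids(self, dict_k4, rng, n_seq=1000, t=128):
        ids = np.empty((n_seq, t + 2), dtype=np.int64)
        for i in range(n_seq):
            motifs = rng.choice(256, size=t, replace=False)
            ids[i] = np.concatenate(([dict_k4.cls_id], motifs, [dict_k4.sep_id]))
        return ids

    def test_corruption_rate_near_15_percent(self, dict_k4, rng):
        ids = self._batch_ids(dict_k4, rng)
        _, _, selected = mask_sequence(ids, dict_k4, seed=42)
        frac = selected.sum() / (ids.shape[0] * 128)
        assert frac == pytest.approx(0.15, abs=0.005)

    def test_mask_random_keep_shares(self, dict_k4, rng):
        ids = self._batch_ids(dict_k4, rng)
        corrupted, _, selected = mask_sequence(ids, dict_k4, seed=42)
        sel_orig = ids[selected]
        sel_new = corrupted[selected]
        mask_share = (sel_new == dict_k4.mask_id).mean()
        kept_share = (sel_new == sel_orig).mean()
        rand_share = 1.0 - mask_share - kept_share
        assert mask_share == pytest.approx(0.80, abs=0.01)
        # a "random motif" draw can coincide with the original (1/256), so the
        # observed random/kept split shifts by ~0.04 pp; tolerance absorbs it
        assert rand_share == pytest.approx(0.10, abs=0.01)
        assert kept_share == pytest.approx(0.10, abs=0.01)

    def test_special_tokens_never_corrupted(self, dict_k4, rng):
        ids = self._batch_ids(dict_k4, rng, n_seq=50)
        corrupted, targets, selected = mask_sequence(ids, dict_k4, seed=0)
        assert not selected[:, 0].any() and not selected[:, -1].any()
        assert np.array_equal(corrupted[:, 0], ids[:, 0])
        assert np.array_equal(corrupted[:, -1], ids[:, -1])

    def test_at_least_one_position_always_selected(self, dict_k2):
        # a single motif position: Bernoulli(0.15) usually selects nothing,
        # so the forced-selection fallback must kick in every time
        ids = np.array([dict_k2.cls_id, 3, dict_k2.sep_id])
        for seed in range(25):
            _, targets, selected = mask_sequence(ids, dict_k2, seed=seed)
            assert selected.sum() >= 1
            assert (targets[selected] == 3).all()

    def test_same_seed_identical_corruption(self, dict_k4, rng):
        ids = self._batch_ids(dict_k4, rng, n_seq=20)
        a = mask_sequence(ids, dict_k4, seed=9)
        b = mask_sequence(ids, dict_k4, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_no_motif_tokens_raises(self, dict_k4):
        ids = np.array([dict_k4.cls_id, dict_k4.sep_id, dict_k4.pad_id])
        with pytest.raises(DegenerateSequenceError):
            mask_sequence(ids, dict_k4, seed=0)


class TestECE:
    def test_uniform_predictor_equals_vocab_size(self):
        logits = np.zeros((40, 260))
        targets = np.arange(40) % 260
        assert compute_ece(logits, targets) == pytest.approx(260.0, rel=1e-9)

    def test_perfect_predictor_equals_one(self):
        targets = np.array([3, 7, 1])
        logits = np.full((3, 10), -1e6)
        logits[np.arange(3), targets] = 0.0
        assert compute_ece(logits, targets) == pytest.approx(1.0, abs=1e-9)

    def test_half_probability_gives_two(self):
        # two-way tie between the target and one other token -> p(target)=0.5
        logits = np.full((1, 10), -1e6)
        logits[0, [2, 5]] = 0.0
        assert compute_ece(logits, np.array([2])) == pytest.approx(2.0, rel=1e-9)

    def test_never_below_one(self, rng):
        logits = rng.normal(size=(100, 20))
        targets = rng.integers(0, 20, size=100)
        assert compute_ece(logits, targets) >= 1.0

    def test_zero_targets_rejected(self):
        with pytest.raises(DegenerateSequenceError):
            compute_ece(np.zeros((0, 5)), np.array([], dtype=int))


class TestCheckpoint:
    def test_bit_stable_reload(self, tiny_model, dict_k2, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        back = load_checkpoint(path)
        assert back.config == tiny_model.config
        ids = np.array([dict_k2.cls_id, 1, 5, dict_k2.sep_id])
        _, l1, _ = forward(ids, tiny_model)
        _, l2, _ = forward(ids, back)
        assert np.array_equal(l1, l2)
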