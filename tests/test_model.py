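"""Attention LSTM: oracle equivalence, masking, gradients, invariants."""

import math

import numpy as np
import pytest
from attention_oracles import loop_multi_head, loop_single_head

from attnspeech.model import (
    AttentionLSTMClassifier,
    LSTMOutputs,
    ModelConfig,
    SequenceBatch,
    classify,
    lstm_forward,
    multi_head_time_attention,
    pad_sequences,
    project_heads,
    single_head_time_attention,
)
from attnspeech.nn import lstm_layer_forward


def random_outputs(rng, b=2, t=4, z=6):
    o_all = rng.normal(size=(b, t, z))
    lengths = rng.integers(1, t + 1, size=b)
    lengths[0] = t  # keep at least one full-length sequence
    for i in range(b):
        o_all[i, lengths[i]:] = 0.0
    o_last = o_all[np.arange(b), lengths - 1][:, None, :]
    return LSTMOutputs(o_all, o_last), lengths


# ---------------------------------------------------------------------------
# LSTM backbone


class TestLSTM:
    def test_matches_scalar_recurrence(self):
        """Hand-set weights, hidden size 2, 3 steps vs. a step-by-step unroll."""
        h_dim = 2
        params = {
            "wx": np.array([[0.5, -0.2, 0.1, 0.3, -0.4, 0.2, 0.6, -0.1]]),
            "wh": np.arange(16).reshape(2, 8) * 0.05 - 0.2,
            "b": np.linspace(-0.3, 0.4, 8),
        }
        x = np.array([[[1.0], [-0.5], [0.25]]])
        mask = np.ones((1, 3))
        hs, _ = lstm_layer_forward(x, mask, params)

        def sig(v):
            return 1.0 / (1.0 + math.exp(-v))

        h = np.zeros(2)
        c = np.zeros(2)
        for t in range(3):
            z = x[0, t, 0] * params["wx"][0] + h @ params["wh"] + params["b"]
            i = np.array([sig(z[0]), sig(z[1])])
            f = np.array([sig(z[2]), sig(z[3])])
            g = np.tanh(z[4:6])
            o = np.array([sig(z[6]), sig(z[7])])
            c = f * c + i * g
            h = o * np.tanh(c)
            np.testing.assert_allclose(hs[0, t], h, atol=1e-12)

    def test_output_bounded_by_tanh(self, rng):
        cfg = ModelConfig(input_size=4, lstm_hidden=(6, 6), heads=2, seed=0)
        model = AttentionLSTMClassifier(cfg)
        batch = pad_sequences([rng.normal(size=(5, 4))])
        o = lstm_forward(batch, model.params)
        assert np.all(np.abs(o.o_all) < 1.0)

    def test_o_last_invariant_to_padding_amount(self, rng):
        cfg = ModelConfig(input_size=3, lstm_hidden=(4, 4), heads=2, seed=1)
        model = AttentionLSTMClassifier(cfg)
        seq = rng.normal(size=(4, 3))
        short = pad_sequences([seq, rng.normal(size=(2, 3))])
        long = pad_sequences([seq, rng.normal(size=(9, 3))])
        o_short = lstm_forward(short, model.params)
        o_long = lstm_forward(long, model.params)
        np.testing.assert_allclose(o_short.o_last[0], o_long.o_last[0], atol=1e-12)


# ---------------------------------------------------------------------------
# attention operations


class TestSingleHeadAttention:
    def test_constant_o_all_gives_uniform_scores(self):
        t_len = 5
        o_all = np.tile(np.array([1.0, -2.0, 0.5]), (1, t_len, 1))
        o = LSTMOutputs(o_all, o_all[:, -1:, :])
        res = single_head_time_attention(o, np.eye(3), np.array([t_len]))
        np.testing.assert_allclose(res.scores[0, 0, 0], 1.0 / t_len)

    def test_singleton_time_axis(self, rng):
        o_all = rng.normal(size=(1, 1, 4))
        o = LSTMOutputs(o_all, o_all[:, -1:, :])
        res = single_head_time_attention(o, rng.normal(size=(4, 4)), np.array([1]))
        assert res.scores[0, 0, 0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(res.context, o_all)

    def test_matches_loop_oracle(self, rng):
        o, lengths = random_outputs(rng)
        w_t = rng.normal(size=(6, 6))
        res = single_head_time_attention(o, w_t, lengths)
        scores, ctx = loop_single_head(o.o_all, o.o_last, w_t, lengths)
        np.testing.assert_allclose(res.scores[0, :, 0, :], scores, atol=1e-6)
        np.testing.assert_allclose(res.context[:, 0, :], ctx, atol=1e-6)

    def test_shape_mismatch_named(self, rng):
        o, lengths = random_outputs(rng)
        with pytest.raises(ValueError, match=r"\(6, 6\)"):
            single_head_time_attention(o, np.eye(4), lengths)


class TestProjectHeads:
    def test_zero_weights_yield_bias_rows(self, rng):
        o, _ = random_outputs(rng, z=6)
        proj = [{"wk": np.zeros((6, 3)), "bk": np.array([1.0, 2.0, 3.0]),
                 "wv": np.zeros((6, 3)), "bv": np.zeros(3),
                 "wq": np.zeros((6, 3)), "bq": np.zeros(3)} for _ in range(2)]
        kvq = project_heads(o, proj)
        np.testing.assert_allclose(kvq[0][0], np.broadcast_to([1.0, 2.0, 3.0], kvq[0][0].shape))

    def test_identity_single_head_returns_o_all(self, rng):
        o, _ = random_outputs(rng, z=6)
        proj = [{"wk": np.eye(6), "bk": np.zeros(6), "wv": np.eye(6),
                 "bv": np.zeros(6), "wq": np.eye(6), "bq": np.zeros(6)}]
        k, v, q = project_heads(o, proj)[0]
        np.testing.assert_array_equal(k, o.o_all)
        np.testing.assert_array_equal(v, o.o_all)
        np.testing.assert_array_equal(q, o.o_last[:, 0, :])


class TestMultiHeadAttention:
    def test_matches_hand_computed_two_heads(self):
        """B=1, T=3, Z=4, n=2 with small integer weights."""
        o_all = np.array([[[1.0, 0.0, 2.0, -1.0],
                           [0.0, 1.0, 1.0, 0.0],
                           [2.0, -1.0, 0.0, 1.0]]])
        o_last = o_all[:, -1:, :]
        o = LSTMOutputs(o_all, o_last)
        heads = [
            {"wk": np.array([[1.0, 0], [0, 1], [0, 0], [0, 0]]), "bk": np.zeros(2),
             "wv": np.array([[0.0, 0], [0, 0], [1, 0], [0, 1]]), "bv": np.zeros(2),
             "wq": np.array([[1.0, 0], [0, 1], [0, 0], [0, 0]]), "bq": np.zeros(2)},
            {"wk": np.array([[0.0, 0], [0, 0], [1, 0], [0, 1]]), "bk": np.zeros(2),
             "wv": np.array([[1.0, 0], [0, 1], [0, 0], [0, 0]]), "bv": np.zeros(2),
             "wq": np.array([[0.0, 0], [0, 0], [1, 0], [0, 1]]), "bq": np.zeros(2)},
        ]
        lengths = np.array([3])
        res = multi_head_time_attention(project_heads(o, heads), lengths)
        exp_scores, exp_cv = loop_multi_head(o_all, o_last, heads, lengths)
        np.testing.assert_allclose(res.scores[:, :, 0, :], exp_scores, atol=1e-12)
        np.testing.assert_allclose(res.context[:, 0, :], exp_cv, atol=1e-12)
        # spot-check head 0 by explicit arithmetic: Q=(2,-1), K rows (1,0),(0,1),(2,-1)
        logits = np.array([2.0, -1.0, 5.0])
        s = np.exp(logits - 5.0) / np.exp(logits - 5.0).sum()
        np.testing.assert_allclose(res.scores[0, 0, 0], s, atol=1e-12)

    def test_identical_heads_tile_context(self, rng):
        o, lengths = random_outputs(rng, z=6)
        hp = {"wk": rng.normal(size=(6, 3)), "bk": rng.normal(size=3),
              "wv": rng.normal(size=(6, 3)), "bv": rng.normal(size=3),
              "wq": rng.normal(size=(6, 3)), "bq": rng.normal(size=3)}
        res = multi_head_time_attention(project_heads(o, [hp, hp]), lengths)
        np.testing.assert_allclose(res.context[:, 0, :3], res.context[:, 0, 3:], atol=1e-12)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-12)

    def test_single_head_reduction_to_eq12(self, rng):
        """n=1 with identity projections equals single-head attention, W_t = I."""
        o, lengths = random_outputs(rng, z=6)
        eye_head = [{"wk": np.eye(6), "bk": np.zeros(6), "wv": np.eye(6),
                     "bv": np.zeros(6), "wq": np.eye(6), "bq": np.zeros(6)}]
        multi = multi_head_time_attention(project_heads(o, eye_head), lengths)
        single = single_head_time_attention(o, np.eye(6), lengths)
        np.testing.assert_allclose(multi.scores[0], single.scores[0], atol=1e-6)
        np.testing.assert_allclose(multi.context, single.context, atol=1e-6)

    def test_scores_sum_to_one_and_zero_on_padding(self, rng):
        for _ in range(10):
            o, lengths = random_outputs(rng, b=3, t=5, z=8)
            heads = [{"wk": rng.normal(size=(8, 4)), "bk": rng.normal(size=4),
                      "wv": rng.normal(size=(8, 4)), "bv": rng.normal(size=4),
                      "wq": rng.normal(size=(8, 4)), "bq": rng.normal(size=4)}
                     for _ in range(2)]
            res = multi_head_time_attention(project_heads(o, heads), lengths)
            assert np.all(res.scores >= 0)
            sums = res.scores[:, :, 0, :].sum(axis=-1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            for b, ln in enumerate(lengths):
                assert np.all(res.scores[:, b, 0, ln:] == 0)


class TestClassifier:
    def test_zero_weights_give_uniform_probabilities(self):
        params = {"fc0/w": np.zeros((6, 4)), "fc0/b": np.zeros(4),
                  "fc1/w": np.zeros((4, 3)), "fc1/b": np.zeros(3),
                  "out/w": np.zeros((3, 2)), "out/b": np.zeros(2)}
        probs = classify(np.ones((5, 1, 6)), params)
        np.testing.assert_allclose(probs, 0.5)

    def test_rows_sum_to_one(self, rng):
        cfg = ModelConfig(input_size=4, lstm_hidden=(4, 4), heads=2, seed=3)
        model = AttentionLSTMClassifier(cfg)
        probs = classify(rng.normal(size=(7, 1, 4)), model.params)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_shift_invariance_of_softmax_head(self, rng):
        cfg = ModelConfig(input_size=4, lstm_hidden=(4, 4), heads=2, seed=3)
        model = AttentionLSTMClassifier(cfg)
        cv = rng.normal(size=(5, 1, 4))
        base = classify(cv, model.params)
        shifted = dict(model.params)
        shifted["out/b"] = model.params["out/b"] + 10.0
        np.testing.assert_allclose(classify(cv, shifted), base, atol=1e-9)


class TestModelForward:
    def test_deterministic_under_fixed_seed(self, rng):
        cfg = ModelConfig(input_size=5, lstm_hidden=(6, 6), heads=3, seed=9)
        seqs = [rng.normal(size=(t, 5)) for t in (4, 6, 3)]
        batch = pad_sequences(seqs, [0, 1, 0])
        p1, _ = AttentionLSTMClassifier(cfg).forward(batch)
        p2, _ = AttentionLSTMClassifier(cfg).forward(batch)
        np.testing.assert_array_equal(p1, p2)

    def test_batch_permutation_permutes_outputs(self, rng):
        cfg = ModelConfig(input_size=5, lstm_hidden=(6, 6), heads=3, seed=9)
        model = AttentionLSTMClassifier(cfg)
        seqs = [rng.normal(size=(t, 5)) for t in (4, 6, 3)]
        probs, _ = model.forward(pad_sequences(seqs))
        probs_perm, _ = model.forward(pad_sequences([seqs[2], seqs[0], seqs[1]]))
        np.testing.assert_allclose(probs_perm, probs[[2, 0, 1]], atol=1e-12)

    def test_single_head_config_reproduces_single_head_path(self, rng):
        """A 1-head multi-head model with identity projections equals the
        dedicated single-head variant with W_t = I, end to end."""
        cfg_m = ModelConfig(input_size=4, lstm_hidden=(5, 5), heads=1,
                            attention="multi", seed=4)
        cfg_s = ModelConfig(input_size=4, lstm_hidden=(5, 5), heads=1,
                            attention="single", seed=4)
        m = AttentionLSTMClassifier(cfg_m)
        s = AttentionLSTMClassifier(cfg_s)
        # share LSTM + FC weights; set both attentions to the identity
        s.params = {k: v.copy() for k, v in m.params.items() if not k.startswith("head0")}
        s.params["att/wt"] = np.eye(5)
        for name in ("wk", "wv", "wq"):
            m.params[f"head0/{name}"] = np.eye(5)
        for name in ("bk", "bv", "bq"):
            m.params[f"head0/{name}"] = np.zeros(5)
        batch = pad_sequences([rng.normal(size=(t, 4)) for t in (6, 3)])
        pm, am = m.forward(batch)
        ps, as_ = s.forward(batch)
        np.testing.assert_allclose(pm, ps, atol=1e-9)
        np.testing.assert_allclose(am.scores[0], as_.scores[0], atol=1e-9)


class TestGradients:
    @pytest.mark.parametrize("attention,heads", [("multi", 2), ("single", 1), ("none", 1)])
    def test_analytic_gradients_match_finite_differences(self, attention, heads):
        rng = np.random.default_rng(7)
        cfg = ModelConfig(input_size=3, lstm_hidden=(4, 4), heads=heads,
                          fc_sizes=(5, 3), attention=attention, seed=1)
        model = AttentionLSTMClassifier(cfg)
        batch = pad_sequences([rng.normal(size=(t, 3)) for t in (5, 3, 4)], [0, 1, 0])
        _, grads = model.loss_and_grads(batch)
        for key, p in model.params.items():
            flat = p.ravel()
            g = grads[key].ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 1e-6
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = model.loss_and_grads(batch)
                flat[i] = orig - eps
                lm, _ = model.loss_and_grads(batch)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[i], abs=5e-6, rel=5e-3), key

    def test_no_dead_heads_at_init(self, rng):
        """Every head's projection weights receive nonzero gradient."""
        cfg = ModelConfig(input_size=4, lstm_hidden=(8, 8), heads=4, seed=2)
        model = AttentionLSTMClassifier(cfg)
        batch = pad_sequences([rng.normal(size=(t, 4)) for t in (6, 4, 5, 7)], [0, 1, 1, 0])
        _, grads = model.loss_and_grads(batch)
        for i in range(4):
            for name in ("wq", "wk", "wv"):
                assert np.abs(grads[f"head{i}/{name}"]).max() > 0


class TestSequenceBatch:
    def test_nonzero_padding_rejected(self, rng):
        feats = rng.normal(size=(2, 5, 3))
        with pytest.raises(ValueError, match="padded"):
            SequenceBatch(feats, np.array([5, 3]))

    def test_config_rejects_indivisible_heads(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_size=4, lstm_hidden=(8, 6), heads=4)
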