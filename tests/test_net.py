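"""Time2Vec, attention, encoder and classification head numerics."""

import numpy as np
import pytest

from ecgrhythm.net import (
    Adam,
    ModelConfig,
    RhythmTransformer,
    Time2VecParams,
    count_parameters,
    embed_window,
    encoder_layer,
    ffn,
    layer_norm,
    multi_head_attention,
    scaled_dot_attention,
    softmax,
    time2vec,
)


class TestTime2Vec:
    def test_linear_identity_term(self):
        p = Time2VecParams(omega=[1.0, 0.5, 0.5], phi=[0.0, 0.0, 0.0])
        out = time2vec(np.array([5.0]), p)
        assert out[0, 0] == pytest.approx(5.0)

    def test_periodic_row_is_sine(self):
        p = Time2VecParams(omega=[1.0, np.pi / 2, 1.0], phi=[0.0, 0.0, 0.0])
        out = time2vec(np.array([1.0]), p)
        assert out[1, 0] == pytest.approx(1.0)  # sin(pi/2)
        assert np.all(np.abs(out[1:]) <= 1.0)

    def test_output_shape_k2_window250(self):
        p = Time2VecParams(omega=np.ones(3), phi=np.zeros(3))
        assert time2vec(np.arange(250.0), p).shape == (3, 250)


class TestScaledDotAttention:
    def test_single_query_single_key_returns_value(self, rng):
        V = rng.standard_normal((1, 4))
        out = scaled_dot_attention(rng.standard_normal((1, 3)), rng.standard_normal((1, 3)), V)
        np.testing.assert_allclose(out, V, atol=1e-12)

    def test_orthogonal_query_identical_values(self):
        Q = np.array([[0.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[3.5], [3.5]])
        np.testing.assert_allclose(scaled_dot_attention(Q, K, V), [[3.5]], atol=1e-12)

    def test_two_position_hand_example(self):
        Q, K, V = np.array([[1.0, 0.0]]), np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[1.0], [0.0]])
        out, w = scaled_dot_attention(Q, K, V, d_k=2, return_weights=True)
        # direct arithmetic: scores (1/sqrt(2), 0)
        e = np.exp([1.0 / np.sqrt(2.0), 0.0])
        expect = e / e.sum()
        np.testing.assert_allclose(w[0], expect, atol=1e-12)
        assert out[0, 0] == pytest.approx(expect[0])

    def test_weight_rows_sum_to_one(self, rng):
        _, w = scaled_dot_attention(
            rng.standard_normal((7, 3)), rng.standard_normal((5, 3)),
            rng.standard_normal((5, 2)), return_weights=True,
        )
        np.testing.assert_allclose(w.sum(axis=-1), np.ones(7), atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 1)))


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce_to_attention(self, rng):
        d = 4
        X = rng.standard_normal((6, d))
        I = np.eye(d)
        w = {"Wq": I, "Wk": I, "Wv": I, "bq": np.zeros(d), "bk": np.zeros(d),
             "bv": np.zeros(d), "Wo": I, "bo": np.zeros(d)}
        cfg = ModelConfig(d_model=d, n_heads=1, key_dim=d, n_layers=1, ffn_dim=4,
                          head_hidden=2, window_len=6, dropout=0.0)
        np.testing.assert_allclose(
            multi_head_attention(X, cfg, w), scaled_dot_attention(X, X, X), atol=1e-10
        )

    def test_output_width_equals_d_model(self, rng):
        cfg = ModelConfig(d_model=256, n_heads=12, key_dim=21, n_layers=1)
        model = RhythmTransformer(cfg, seed=0)
        X = rng.standard_normal((10, 256))
        out = multi_head_attention(X, cfg, model._layer_weights(0))
        assert out.shape == (10, 256)

    def test_oracle_dense_evaluation_small_instances(self, rng):
        """Module attention output == direct per-head dense matrix arithmetic."""
        cfg = ModelConfig(d_model=4, n_heads=3, key_dim=2, n_layers=1, ffn_dim=4,
                          head_hidden=2, window_len=3, dropout=0.0, dtype="float64")
        model = RhythmTransformer(cfg, seed=9)
        w = model._layer_weights(0)
        for _ in range(5):
            X = rng.standard_normal((3, 4))
            heads = []
            for h in range(3):
                sl = slice(h * 2, (h + 1) * 2)
                Q = X @ w["Wq"][:, sl] + w["bq"][sl]
                K = X @ w["Wk"][:, sl] + w["bk"][sl]
                V = X @ w["Wv"][:, sl] + w["bv"][sl]
                S = Q @ K.T / np.sqrt(2.0)
                A = np.exp(S - S.max(axis=1, keepdims=True))
                A /= A.sum(axis=1, keepdims=True)
                heads.append(A @ V)
            expect = np.concatenate(heads, axis=1) @ w["Wo"] + w["bo"]
            got = multi_head_attention(X, cfg, w)
            np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_head_permutation_with_permuted_output_blocks_is_invariant(self, rng):
        cfg = ModelConfig(d_model=4, n_heads=3, key_dim=2, n_layers=1, ffn_dim=4,
                          head_hidden=2, window_len=3, dropout=0.0, dtype="float64")
        w = RhythmTransformer(cfg, seed=9)._layer_weights(0)
        X = rng.standard_normal((3, 4))
        base = multi_head_attention(X, cfg, w)
        perm = [2, 0, 1]
        w2 = dict(w)
        for nm in ("Wq", "Wk", "Wv"):
            w2[nm] = np.concatenate([w[nm][:, h * 2 : (h + 1) * 2] for h in perm], axis=1)
            bn = nm.replace("W", "b")
            w2[bn] = np.concatenate([w[bn][h * 2 : (h + 1) * 2] for h in perm])
        w2["Wo"] = np.concatenate([w["Wo"][h * 2 : (h + 1) * 2] for h in perm], axis=0)
        np.testing.assert_allclose(multi_head_attention(X, cfg, w2), base, atol=1e-10)


class TestFfn:
    def test_scalar_hand_example(self):
        out = ffn(np.array([[1.0]]), np.array([[2.0]]), np.array([-1.0]),
                  np.array([[3.0]]), np.array([0.0]))
        assert out[0, 0] == pytest.approx(3.0)

    def test_all_negative_preactivations_give_bias_only(self, rng):
        W1 = -np.eye(2)
        out = ffn(np.abs(rng.standard_normal((5, 2))), W1, np.zeros(2),
                  rng.standard_normal((2, 2)), np.array([0.7, -0.2]))
        np.testing.assert_allclose(out, np.tile([0.7, -0.2], (5, 1)), atol=1e-12)

    def test_position_independence(self, rng):
        W1, b1 = rng.standard_normal((3, 8)), rng.standard_normal(8)
        W2, b2 = rng.standard_normal((8, 3)), rng.standard_normal(3)
        x = rng.standard_normal(3)
        X = np.vstack([x, x, x])
        out = ffn(X, W1, b1, W2, b2)
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)
        np.testing.assert_allclose(out[0], out[2], atol=1e-12)


class TestEncoderLayer:
    def test_zero_weight_sublayers_pass_layernorm_of_input(self, rng):
        d = 4
        cfg = ModelConfig(d_model=d, n_heads=1, key_dim=2, n_layers=1, ffn_dim=4,
                          head_hidden=2, window_len=5, dropout=0.0, dtype="float64")
        w = RhythmTransformer(cfg, seed=1)._layer_weights(0)
        for k in ("Wo", "bo", "W2", "b2"):
            w[k] = np.zeros_like(w[k])  # both sublayer outputs become 0
        X = rng.standard_normal((5, d))
        got = encoder_layer(X, cfg, w)
        ln1, _ = layer_norm(X, w["ln1_g"], w["ln1_b"])
        expect, _ = layer_norm(ln1, w["ln2_g"], w["ln2_b"])
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_normalized_features_before_gain_bias(self, rng):
        x = rng.standard_normal((7, 16))
        y, _ = layer_norm(x, np.ones(16), np.zeros(16))
        np.testing.assert_allclose(y.mean(axis=-1), 0.0, atol=1e-7)
        np.testing.assert_allclose(y.var(axis=-1), 1.0, atol=1e-3)

    def test_n_layers_applied_n_times(self, monkeypatch, rng):
        import ecgrhythm.net as net

        cfg = ModelConfig(d_model=4, n_heads=1, key_dim=2, n_layers=3, ffn_dim=4,
                          head_hidden=2, window_len=5, dropout=0.0)
        model = RhythmTransformer(cfg, seed=0)
        calls = []
        orig = net._mha_forward
        monkeypatch.setattr(net, "_mha_forward", lambda *a, **k: calls.append(1) or orig(*a, **k))
        model.forward(rng.standard_normal((2, 5)))
        assert len(calls) == 3


class TestClassifyAndSoftmax:
    def test_uniform_probs_for_zero_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(5)), np.full(5, 0.2), atol=1e-12)

    def test_ln2_logit_example(self):
        probs = softmax(np.array([np.log(2.0), 0, 0, 0, 0]))
        np.testing.assert_allclose(probs, [2 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 6], atol=1e-12)

    def test_shift_invariance_and_simplex(self, rng):
        z = rng.standard_normal((20, 5)) * 10
        p1, p2 = softmax(z), softmax(z + 123.4)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        assert (p1 >= 0).all()
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    def test_classify_window_prediction_on_simplex(self, tiny_model, rng):
        wp = tiny_model.classify_window(rng.standard_normal(10))
        assert wp.probs.shape == (5,)
        assert wp.probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert wp.probs.argmax() == wp.logits.argmax()

    def test_embedding_shape_and_linearity(self, rng):
        cfg = ModelConfig()  # defaults: d_model 256, window 250
        model = RhythmTransformer(cfg, seed=0)
        w = rng.standard_normal(250)
        E = embed_window(w, model)
        assert E.shape == (250, 256)
        # doubling the samples doubles the signal-projection contribution
        E0 = embed_window(np.zeros(250), model)
        E2 = embed_window(2 * w, model)
        np.testing.assert_allclose(E2 - E0, 2 * (E - E0), rtol=1e-4, atol=1e-4)

    def test_inference_deterministic(self, tiny_model, rng):
        X = rng.standard_normal((3, 10))
        np.testing.assert_array_equal(tiny_model.predict_proba(X), tiny_model.predict_proba(X))


class TestParameterCount:
    def test_toy_config_hand_tally(self):
        cfg = ModelConfig(d_model=4, n_heads=1, key_dim=4, ffn_dim=8, n_layers=1,
                          t2v_k=2, head_hidden=4, n_classes=5, window_len=10, dropout=0.0)
        model = RhythmTransformer(cfg, seed=0)
        t2v = 2 * 3  # omega, phi
        emb = 4 + 3 * 4 + 4  # signal weights, Time2Vec projection, shared bias
        qkv = 3 * (4 * 4 + 4)
        wo = 4 * 4 + 4
        lns = 2 * (2 * 4)
        f = (4 * 8 + 8) + (8 * 4 + 4)
        head = (4 * 4 + 4) + (4 * 5 + 5)
        assert count_parameters(model) == t2v + emb + qkv + wo + lns + f + head

    def test_ffn_doubling_increment_closed_form(self):
        base = dict(d_model=8, n_heads=2, key_dim=4, n_layers=2, t2v_k=2,
                    head_hidden=4, window_len=10, dropout=0.0)
        n1 = RhythmTransformer(ModelConfig(ffn_dim=16, **base)).count_parameters()
        n2 = RhythmTransformer(ModelConfig(ffn_dim=32, **base)).count_parameters()
        # per layer: W1 grows d*f, b1 grows f, W2 grows f*d
        assert n2 - n1 == 2 * (2 * 8 * 16 + 16)

    def test_zero_layer_model_is_embedding_plus_head(self):
        cfg = ModelConfig(d_model=4, n_layers=0, n_heads=1, key_dim=2, ffn_dim=4,
                          t2v_k=2, head_hidden=4, window_len=10, dropout=0.0)
        n = RhythmTransformer(cfg).count_parameters()
        assert n == 2 * 3 + (4 + 12 + 4) + (4 * 4 + 4) + (4 * 5 + 5)


class TestGradientsAndTraining:
    def test_gradients_match_finite_differences(self, tiny_model, rng):
        m = tiny_model
        X = rng.standard_normal((4, 10))
        y = rng.integers(0, 5, 4)
        loss, g = m.loss_and_grads(X, y, train=False)
        eps = 1e-6
        for k in sorted(m.params):
            flat = m.params[k].ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp, _ = m.loss_and_grads(X, y, train=False)
                flat[idx] = old - eps
                lm, _ = m.loss_and_grads(X, y, train=False)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = g[k].ravel()[idx]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), k

    def test_one_adam_step_decreases_training_loss(self, rng):
        cfg = ModelConfig(d_model=8, n_layers=1, n_heads=2, key_dim=4, ffn_dim=16,
                          dropout=0.0, window_len=20, head_hidden=8, dtype="float64")
        model = RhythmTransformer(cfg, seed=5)
        X = rng.standard_normal((16, 20))
        y = rng.integers(0, 5, 16)
        opt = Adam(model.params, lr=1e-2)
        l0, g = model.loss_and_grads(X, y, train=False)
        opt.step(model.params, g)
        l1, _ = model.loss_and_grads(X, y, train=False)
        assert l1 < l0

    def test_checkpoint_round_trip(self, tiny_model, tmp_path, rng):
        X = rng.standard_normal((2, 10))
        tiny_model.save(str(tmp_path / "ckpt"))
        back = RhythmTransformer.load(str(tmp_path / "ckpt"))
        np.testing.assert_array_equal(back.predict_proba(X), tiny_model.predict_proba(X))
        assert back.count_parameters() == tiny_model.count_parameters()
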