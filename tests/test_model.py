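"""Graph-transformer components against brute-force oracles."""

import numpy as np
import pytest
from scipy.special import erf
from scipy.stats import norm

import r2snet._autodiff as ad
from r2snet import (ModelConfig, build_r2sn, forward, init_params,
                    topk_sparsify)
from r2snet._autodiff import Tensor
from r2snet.model import (feed_forward, forward_batch, gated_structure_fusion,
                          graph_attention, layer_masks, load_checkpoint,
                          save_checkpoint, transformer_layer)

from conftest import random_graph_arrays, random_table, tiny_model_config


def gelu_scalar(x):
    return x * norm.cdf(x)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

class TestInitParams:
    def test_deterministic_given_seed(self):
        cfg = tiny_model_config(seed=5)
        assert init_params(cfg).checksum() == init_params(cfg).checksum()

    def test_seed_changes_params(self):
        a = init_params(tiny_model_config(seed=5))
        b = init_params(tiny_model_config(seed=6))
        assert a.checksum() != b.checksum()

    def test_shapes_match_declaration(self):
        cfg = ModelConfig(seed=0)
        p = init_params(cfg)
        assert p["layers.0.Wq.0"].shape == (36, 24)
        assert p["layers.0.Wk.3"].shape == (36, 24)
        assert p["layers.0.Wv.1"].shape == (36, 32)
        assert p["layers.0.Wo"].shape == (4 * 32, 36)
        assert p["layers.0.Wg"].shape == (72, 36)
        assert p["layers.0.W1"].shape == (36, 144)
        assert p["layers.0.W2"].shape == (144, 36)
        assert p["head.0.W"].shape == (108, 128)
        assert p["head.1.W"].shape == (128, 64)
        assert p["head.2.W"].shape == (64, 3)


# ---------------------------------------------------------------------------
# TopK sparsification
# ---------------------------------------------------------------------------

class TestTopKSparsify:
    def test_saturation_keeps_everything(self, rng):
        _, W = random_graph_arrays(rng, n=8)
        mask = topk_sparsify(W[0], 7)
        assert mask.all()

    def test_oversized_k_warns_full_mask(self, rng):
        _, W = random_graph_arrays(rng, n=6)
        with pytest.warns(UserWarning, match="full mask"):
            mask = topk_sparsify(W[0], 6)
        assert mask.all()

    def test_star_graph_k1(self):
        n = 6
        W = np.full((n, n), 0.1)
        W[0, 1:] = W[1:, 0] = 0.9  # hub node 0
        np.fill_diagonal(W, 1.0)
        mask = topk_sparsify(W, 1)
        expect = np.eye(n, dtype=bool)
        expect[0, 1:] = expect[1:, 0] = True
        np.testing.assert_array_equal(mask, expect)

    def test_matches_sort_oracle_with_tie_break(self, rng):
        for _ in range(10):
            _, W = random_graph_arrays(rng, n=12)
            w = np.round(W[0], 1)  # coarse values force ties
            w = (w + w.T) / 2
            np.fill_diagonal(w, 1.0)
            k = 4
            mask = topk_sparsify(w, k)
            oracle = np.eye(12, dtype=bool)
            for i in range(12):
                cand = sorted((j for j in range(12) if j != i),
                              key=lambda j: (-w[i, j], j))
                for j in cand[:k]:
                    oracle[i, j] = oracle[j, i] = True
            np.testing.assert_array_equal(mask, oracle)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

class TestGraphAttention:
    def test_uniform_attention_when_scores_flat(self, rng):
        cfg = tiny_model_config(n_heads=1)
        params = init_params(cfg)
        params.tensors["layers.0.Wq.0"].data[:] = 0.0  # Q = 0 -> flat scores
        n, d = cfg.n_nodes, cfg.d_model
        X = Tensor(rng.normal(size=(1, n, d)))
        W = np.ones((n, n))
        out, alphas = graph_attention(X, W, None, params, 0, cfg)
        np.testing.assert_allclose(alphas[0][0], 1.0 / n, atol=1e-12)
        V = X.data[0] @ params["layers.0.Wv.0"].data
        expect = np.tile(V.mean(axis=0), (n, 1)) @ params["layers.0.Wo"].data
        np.testing.assert_allclose(out.data[0], expect, atol=1e-10)

    def test_identity_weights_annihilate_off_diagonal(self, rng):
        cfg = tiny_model_config(n_heads=1)
        params = init_params(cfg)
        n, d = cfg.n_nodes, cfg.d_model
        X = Tensor(rng.normal(size=(1, n, d)))
        W = np.eye(n)
        out, alphas = graph_attention(X, W, None, params, 0, cfg)
        V = X.data[0] @ params["layers.0.Wv.0"].data
        expect = (np.diag(alphas[0][0])[:, None] * V) @ params["layers.0.Wo"].data
        np.testing.assert_allclose(out.data[0], expect, atol=1e-12)

    def test_matches_dense_loop_oracle(self, rng):
        cfg = tiny_model_config()
        params = init_params(cfg)
        X_np, W_np = random_graph_arrays(rng, n=cfg.n_nodes, d=cfg.d_model)
        mask = topk_sparsify(W_np[0], cfg.topk_neighbors)
        out, alphas = graph_attention(Tensor(X_np), W_np, mask, params, 0, cfg)

        n, H = cfg.n_nodes, cfg.n_heads
        heads = []
        for h in range(H):
            Q = X_np[0] @ params[f"layers.0.Wq.{h}"].data
            K = X_np[0] @ params[f"layers.0.Wk.{h}"].data
            V = X_np[0] @ params[f"layers.0.Wv.{h}"].data
            ctx = np.zeros((n, cfg.d_v))
            for i in range(n):
                scores = np.array([
                    Q[i] @ K[j] / np.sqrt(cfg.d_k) if mask[i, j] else -np.inf
                    for j in range(n)])
                e = np.exp(scores - scores[np.isfinite(scores)].max())
                e[~np.isfinite(scores)] = 0.0
                a = e / e.sum()
                np.testing.assert_allclose(alphas[h][0][i], a, atol=1e-10)
                for j in range(n):
                    ctx[i] += a[j] * W_np[0][i, j] * V[j]
            heads.append(ctx)
        expect = np.concatenate(heads, axis=1) @ params["layers.0.Wo"].data
        np.testing.assert_allclose(out.data[0], expect, atol=1e-10)

    def test_pre_hadamard_rows_sum_to_one(self, rng):
        cfg = tiny_model_config()
        params = init_params(cfg)
        X_np, W_np = random_graph_arrays(rng, n=cfg.n_nodes, d=cfg.d_model)
        mask = topk_sparsify(W_np[0], 2)
        _, alphas = graph_attention(Tensor(X_np), W_np, mask, params, 0, cfg)
        for a in alphas:
            np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-6)

    def test_non_finite_inputs_rejected(self, rng):
        cfg = tiny_model_config()
        params = init_params(cfg)
        X_np, W_np = random_graph_arrays(rng, n=cfg.n_nodes, d=cfg.d_model)
        X_np[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            graph_attention(Tensor(X_np), W_np, None, params, 0, cfg)


# ---------------------------------------------------------------------------
# fusion, FFN, layer
# ---------------------------------------------------------------------------

class TestGatedFusion:
    def test_zero_gate_weights_average(self, rng):
        d = 5
        X = Tensor(rng.normal(size=(1, 4, d)))
        s = Tensor(rng.normal(size=(1, d)))
        Wg = Tensor(np.zeros((2 * d, d)))
        out = gated_structure_fusion(X, s, Wg)
        np.testing.assert_allclose(out.data, (X.data + s.data[0]) / 2,
                                   atol=1e-12)

    def test_token_equal_to_features_is_fixed_point(self, rng):
        d = 5
        s = rng.normal(size=d)
        X = Tensor(np.tile(s, (1, 4, 1)))
        Wg = Tensor(rng.normal(size=(2 * d, d)))
        out = gated_structure_fusion(X, Tensor(s[None]), Wg)
        np.testing.assert_allclose(out.data, X.data, atol=1e-12)

    def test_matches_per_element_oracle(self, rng):
        d = 5
        X = rng.normal(size=(1, 4, d))
        s = rng.normal(size=d)
        Wg = rng.normal(size=(2 * d, d))
        out = gated_structure_fusion(Tensor(X), Tensor(s[None]), Tensor(Wg))
        for i in range(4):
            g = 1 / (1 + np.exp(-(np.concatenate([X[0, i], s]) @ Wg)))
            expect = g * X[0, i] + (1 - g) * s
            np.testing.assert_allclose(out.data[0, i], expect, atol=1e-12)
            assert ((g > 0) & (g < 1)).all()


class TestFeedForward:
    def test_zero_input_returns_output_bias(self, rng):
        d, h = 4, 6
        W1, b1 = Tensor(rng.normal(size=(d, h))), Tensor(np.zeros(h))
        W2, b2 = Tensor(rng.normal(size=(h, d))), Tensor(rng.normal(size=d))
        out = feed_forward(Tensor(np.zeros((1, 3, d))), W1, b1, W2, b2)
        np.testing.assert_allclose(out.data, np.tile(b2.data, (1, 3, 1)),
                                   atol=1e-15)

    def test_large_preactivations_approach_linear(self, rng):
        d, h = 3, 4
        W1 = Tensor(np.eye(d, h) * 1.0)
        b1 = Tensor(np.full(h, 30.0))
        W2, b2 = Tensor(rng.normal(size=(h, d))), Tensor(rng.normal(size=d))
        x = rng.normal(size=(1, 2, d))
        out = feed_forward(Tensor(x), W1, b1, W2, b2)
        linear = (x @ W1.data + b1.data) @ W2.data + b2.data
        np.testing.assert_allclose(out.data, linear, rtol=1e-9)

    def test_matches_scalar_loop_oracle(self, rng):
        d, h = 4, 6
        W1, b1 = rng.normal(size=(d, h)), rng.normal(size=h)
        W2, b2 = rng.normal(size=(h, d)), rng.normal(size=d)
        x = rng.normal(size=(1, 3, d))
        out = feed_forward(Tensor(x), Tensor(W1), Tensor(b1), Tensor(W2),
                           Tensor(b2))
        for i in range(3):
            pre = np.array([sum(x[0, i, a] * W1[a, b] for a in range(d)) + b1[b]
                            for b in range(h)])
            act = np.array([gelu_scalar(v) for v in pre])
            expect = np.array([sum(act[b] * W2[b, c] for b in range(h)) + b2[c]
                               for c in range(d)])
            np.testing.assert_allclose(out.data[0, i], expect, atol=1e-10)


class TestTransformerLayer:
    def test_layernorm_rows_standardised(self, rng):
        cfg = tiny_model_config()
        params = init_params(cfg)
        # unit scale, zero offset -> output rows have mean 0, var ~ 1
        X_np, W_np = random_graph_arrays(rng, cfg.n_nodes, cfg.d_model)
        out, _ = transformer_layer(Tensor(X_np), W_np, None, params, 0, cfg)
        np.testing.assert_allclose(out.data.mean(axis=-1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.data.var(axis=-1), 1.0, atol=1e-3)

    def test_matches_step_by_step_oracle(self, rng):
        cfg = tiny_model_config(n_heads=1)
        params = init_params(cfg)
        X_np, W_np = random_graph_arrays(rng, cfg.n_nodes, cfg.d_model)
        mask = topk_sparsify(W_np[0], cfg.topk_neighbors)
        out, _ = transformer_layer(Tensor(X_np), W_np, mask, params, 0, cfg)

        p = {k: v.data for k, v in params.items()}
        s = p["layers.0.tokens"].mean(axis=0)
        Xf = np.zeros_like(X_np[0])
        for i in range(cfg.n_nodes):
            g = 1 / (1 + np.exp(-(np.concatenate([X_np[0, i], s])
                                  @ p["layers.0.Wg"])))
            Xf[i] = g * X_np[0, i] + (1 - g) * s
        Q = Xf @ p["layers.0.Wq.0"]
        K = Xf @ p["layers.0.Wk.0"]
        V = Xf @ p["layers.0.Wv.0"]
        scores = Q @ K.T / np.sqrt(cfg.d_k)
        scores[~mask] = -np.inf
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        e[~mask] = 0.0
        alpha = e / e.sum(axis=1, keepdims=True)
        att = ((alpha * W_np[0]) @ V) @ p["layers.0.Wo"]
        pre = Xf @ p["layers.0.W1"] + p["layers.0.b1"]
        ffn = (pre * 0.5 * (1 + erf(pre / np.sqrt(2)))) @ p["layers.0.W2"] \
            + p["layers.0.b2"]
        z = Xf + att + ffn
        mu = z.mean(axis=1, keepdims=True)
        var = z.var(axis=1, keepdims=True)
        expect = (z - mu) / np.sqrt(var + 1e-5)
        np.testing.assert_allclose(out.data[0], expect, atol=1e-8)


# ---------------------------------------------------------------------------
# full forward
# ---------------------------------------------------------------------------

class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        cfg = tiny_model_config()
        params = init_params(cfg)
        for _ in range(20):
            X_np, W_np = random_graph_arrays(rng, cfg.n_nodes, cfg.d_model)
            masks = layer_masks(W_np[0], cfg)
            out = forward_batch(params, cfg, X_np, W_np, masks)
            assert out["probs"].data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_h_concat_dimension_full_model(self, rng):
        cfg = ModelConfig(seed=0)
        params = init_params(cfg)
        g = build_r2sn(random_table(rng, 36))
        trace = forward(g, params, cfg)
        assert trace.h_concat.shape == (108,)
        assert len(trace.h_pool) == 3
        np.testing.assert_array_equal(
            trace.h_concat, np.concatenate(trace.h_pool))

    def test_prediction_invariant_to_node_permutation(self, rng):
        cfg = tiny_model_config(attention_masking="global")
        params = init_params(cfg)
        X_np, W_np = random_graph_arrays(rng, cfg.n_nodes, cfg.d_model)
        base = forward_batch(params, cfg, X_np, W_np,
                             [None] * cfg.n_layers)
        for _ in range(20):
            perm = rng.permutation(cfg.n_nodes)
            Xp = X_np[:, perm]
            Wp = W_np[:, perm][:, :, perm]
            out = forward_batch(params, cfg, Xp, Wp, [None] * cfg.n_layers)
            np.testing.assert_allclose(out["probs"].data, base["probs"].data,
                                       atol=1e-9)
            for hp, hb in zip(out["pools"], base["pools"]):
                np.testing.assert_allclose(hp.data, hb.data, atol=1e-9)

    def test_widened_ffn_with_zero_extra_weights_is_consistent(self, rng):
        cfg = tiny_model_config()
        params = init_params(cfg)
        big_cfg = tiny_model_config(d_ffn=2 * cfg.d_ffn)
        big = init_params(big_cfg)
        for k, t in params.items():
            big.tensors[k].data = t.data.copy() if "W1" not in k and \
                "b1" not in k and "W2" not in k else big.tensors[k].data
        for l in range(cfg.n_layers):
            big.tensors[f"layers.{l}.W1"].data[:] = 0.0
            big.tensors[f"layers.{l}.W1"].data[:, :cfg.d_ffn] = \
                params[f"layers.{l}.W1"].data
            big.tensors[f"layers.{l}.b1"].data[:] = 0.0
            big.tensors[f"layers.{l}.b1"].data[:cfg.d_ffn] = \
                params[f"layers.{l}.b1"].data
            big.tensors[f"layers.{l}.W2"].data[:] = 0.0
            big.tensors[f"layers.{l}.W2"].data[:cfg.d_ffn, :] = \
                params[f"layers.{l}.W2"].data
        X_np, W_np = random_graph_arrays(rng, cfg.n_nodes, cfg.d_model)
        masks = layer_masks(W_np[0], cfg)
        a = forward_batch(params, cfg, X_np, W_np, masks)
        b = forward_batch(big, big_cfg, X_np, W_np, masks)
        np.testing.assert_allclose(a["probs"].data, b["probs"].data,
                                   atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        cfg = tiny_model_config()
        params = init_params(cfg)
        X_np, W_np = random_graph_arrays(rng, cfg.n_nodes + 1, cfg.d_model)
        with pytest.raises(ValueError, match="does not match"):
            forward_batch(params, cfg, X_np, W_np, [None] * cfg.n_layers)

    def test_post_hadamard_rows_bounded(self, rng):
        cfg = tiny_model_config()
        params = init_params(cfg)
        X_np, W_np = random_graph_arrays(rng, cfg.n_nodes, cfg.d_model)
        _, alphas = graph_attention(Tensor(X_np), W_np, None, params, 0, cfg)
        for a in alphas:
            post = a * W_np
            sums = post.sum(axis=-1)
            assert (sums >= -1e-12).all() and (sums <= 1 + 1e-12).all()


class TestCheckpoint:
    def test_exact_round_trip(self, tmp_path):
        cfg = tiny_model_config(seed=3)
        params = init_params(cfg)
        save_checkpoint(tmp_path / "ck.npz", params, cfg, meta={"note": "x"})
        back, cfg2, meta = load_checkpoint(tmp_path / "ck.npz")
        assert back.checksum() == params.checksum()
        assert cfg2 == cfg
        assert meta == {"note": "x"}
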