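"""Network branches: CNN, graph attention, cross-attention, fusion head."""

import math
from dataclasses import replace

import numpy as np
import pytest

import nmfuse as nm
from nmfuse import _autodiff as ad
from nmfuse import model as M


def _gat_params(rng, heads, f_in, f_out, dtype=float):
    return {"w": ad.parameter(rng.normal(size=(heads, f_in, f_out)).astype(dtype)),
            "a_src": ad.parameter(rng.normal(size=(heads, f_out)).astype(dtype)),
            "a_dst": ad.parameter(rng.normal(size=(heads, f_out)).astype(dtype))}


def brute_force_gat(h, w, a_src, a_dst, adj, slope):
    """Loop-based evaluation of one multi-head GAT layer.

    e_ij = LeakyReLU(a^T [W h_i || W h_j]) on the neighborhood, softmax,
    attention-weighted sum, heads averaged, ELU.
    """
    heads, _, f_out = w.shape
    n = h.shape[0]
    out = np.zeros((n, f_out))
    for k in range(heads):
        wh = h @ w[k]
        for i in range(n):
            scores = {}
            for j in range(n):
                if adj[i, j]:
                    v = a_src[k] @ wh[i] + a_dst[k] @ wh[j]
                    scores[j] = v if v > 0 else slope * v
            mx = max(scores.values())
            z = {j: math.exp(v - mx) for j, v in scores.items()}
            total = sum(z.values())
            for j, v in z.items():
                out[i] += (v / total) * wh[j]
    out /= heads
    return np.where(out > 0, out, np.expm1(np.minimum(out, 0)))


class TestGATLayer:
    def test_single_node_self_loop(self, tiny_config, rng):
        params = _gat_params(rng, 2, 3, 4)
        h = rng.normal(size=(1, 3))
        out = M.gat_layer(h, [(0, 0)], params, tiny_config)
        wh_mean = np.mean([h[0] @ params["w"].data[k] for k in range(2)],
                          axis=0)
        want = np.where(wh_mean > 0, wh_mean, np.expm1(np.minimum(wh_mean, 0)))
        assert np.allclose(out[0], want, atol=1e-12)

    def test_identical_features_give_uniform_attention(self, tiny_config, rng):
        params = _gat_params(rng, 2, 3, 4)
        h = np.tile(rng.normal(size=(1, 3)), (2, 1))
        edges = [(0, 0), (1, 1), (0, 1)]
        _, attn = M.gat_layer(h, edges, params, tiny_config,
                              return_attention=True)
        assert np.allclose(attn[attn > 0], 0.5)

    def test_matches_brute_force_on_random_graphs(self, tiny_config, rng):
        for _ in range(20):
            n = 5
            h = rng.normal(size=(n, 3))
            adj = rng.random((n, n)) < 0.4
            adj |= adj.T
            np.fill_diagonal(adj, True)
            edges = [(i, j) for i in range(n) for j in range(i, n)
                     if adj[i, j]]
            params = _gat_params(rng, 2, 3, 4)
            got = M.gat_layer(h, edges, params, tiny_config)
            want = brute_force_gat(h, params["w"].data,
                                   params["a_src"].data,
                                   params["a_dst"].data, adj,
                                   tiny_config.leaky_slope)
            assert np.abs(got - want).max() < 1e-5

    def test_requires_self_loops(self, tiny_config, rng):
        params = _gat_params(rng, 2, 3, 4)
        with pytest.raises(ValueError, match="self-loop"):
            M.gat_layer(rng.normal(size=(2, 3)), [(0, 1)], params,
                        tiny_config)

    def test_attention_rows_sum_to_one(self, tiny_config, rng):
        n = 7
        adj = rng.random((n, n)) < 0.5
        adj |= adj.T
        np.fill_diagonal(adj, True)
        edges = [(i, j) for i in range(n) for j in range(i, n) if adj[i, j]]
        params = _gat_params(rng, 3, 4, 5)
        _, attn = M.gat_layer(rng.normal(size=(n, 4)), edges, params,
                              tiny_config, return_attention=True)
        assert np.abs(attn.sum(axis=-1) - 1.0).max() < 1e-6


class TestGATBranch:
    def test_path_graph_output_shape_finite(self, tiny_config):
        cfg = tiny_config
        params = nm.init_params(cfg, 10, seed=0, dtype=np.float64)
        x_str = np.zeros((10, 10))
        x_node = np.eye(10, 4)
        out = M.gat_branch(x_str, x_node, params, cfg)
        assert out.data.shape == (10 // cfg.pool_size, cfg.embed_dim)
        assert np.isfinite(out.data).all()

    def test_rejects_asymmetric_matrix(self, tiny_config):
        params = nm.init_params(tiny_config, 6, seed=0)
        x_str = np.zeros((6, 6))
        x_str[0, 4] = 1
        with pytest.raises(ValueError, match="symmetric"):
            M.gat_branch(x_str, np.eye(6, 4), params, tiny_config)

    def test_hairpin_pair_edge_receives_attention(self, tiny_config, rng):
        """Paired bases attend to their pair partner with positive weight."""
        params = _gat_params(rng, 2, 4, 4)
        n = 9
        edges = [(i, i) for i in range(n)]
        edges += [(i, i + 1) for i in range(n - 1)]
        edges += [(0, 8), (1, 7)]  # stem
        h = np.eye(n, 4)
        _, attn = M.gat_layer(h, edges, params, tiny_config,
                              return_attention=True)
        assert (attn[:, 0, 8] > 0).all() and (attn[:, 8, 0] > 0).all()

    def test_node_permutation_equivariance(self, tiny_config, rng):
        n = 6
        adj = rng.random((n, n)) < 0.5
        adj |= adj.T
        np.fill_diagonal(adj, True)
        edges = [(i, j) for i in range(n) for j in range(i, n) if adj[i, j]]
        params = _gat_params(rng, 2, 4, 5)
        h = rng.normal(size=(n, 4))
        out = M.gat_layer(h, edges, params, tiny_config)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        edges_p = [(inv[i], inv[j]) for i, j in edges]
        out_p = M.gat_layer(h[perm], edges_p, params, tiny_config)
        assert np.allclose(out_p, out[perm], atol=1e-10)


class TestCrossAttention:
    def _params(self, rng, dx, dy, dk, dv):
        return {"xatt_wq": ad.parameter(rng.normal(size=(dx, dk))),
                "xatt_wk": ad.parameter(rng.normal(size=(dy, dk))),
                "xatt_wv": ad.parameter(rng.normal(size=(dy, dv)))}

    def test_single_key_broadcasts_value(self, rng):
        params = self._params(rng, 4, 4, 3, 5)
        kv = rng.normal(size=(1, 4))
        out1 = M.cross_attention(rng.normal(size=(3, 4)), kv, params)
        out2 = M.cross_attention(rng.normal(size=(3, 4)), kv, params)
        want = kv @ params["xatt_wv"].data
        assert np.allclose(out1.data, np.tile(want, (3, 1)))
        assert np.allclose(out1.data, out2.data)  # independent of queries

    def test_identical_keys_give_uniform_attention(self, rng):
        params = self._params(rng, 4, 4, 3, 5)
        kv = np.tile(rng.normal(size=(1, 4)), (6, 1))
        _, attn = M.cross_attention(rng.normal(size=(2, 4)), kv, params,
                                    return_attention=True)
        assert np.allclose(attn.data, 1.0 / 6.0)

    def test_matches_hand_matrix_algebra(self, rng):
        params = self._params(rng, 4, 4, 4, 4)
        q_in, kv = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        out, attn = M.cross_attention(q_in, kv, params, return_attention=True)
        q = q_in @ params["xatt_wq"].data
        k = kv @ params["xatt_wk"].data
        v = kv @ params["xatt_wv"].data
        scores = q @ k.T / np.sqrt(4)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        assert np.abs(attn.data - a).max() < 1e-12
        assert np.abs(out.data - a @ v).max() < 1e-12
        assert np.abs(attn.data.sum(axis=-1) - 1).max() < 1e-6


class TestCNNBranch:
    def test_zero_input_yields_fc_bias(self, tiny_config):
        params = nm.init_params(tiny_config, 8, seed=0, dtype=np.float64)
        out = M.cnn_branch(np.zeros((8, 4)), params, tiny_config, "seq")
        assert np.allclose(out.data, params["seq_fc_b"].data)

    def test_impulse_localizes_in_pooled_map(self, rng):
        cfg = nm.ModelConfig(n_kernels=1, embed_dim=2, n_heads=1)
        x = np.zeros((1, 6, 4))
        x[0, 3, 0] = 1.0  # impulse at position 3, channel A
        w = np.zeros((3, 4, 1))
        w[1, 0, 0] = 1.0  # identity-like center tap
        conv = ad.conv1d_same(ad.tensor(x), ad.tensor(w),
                              ad.tensor(np.zeros(1)))
        pooled = ad.maxpool1d(ad.relu(conv), 2).data[0, :, 0]
        assert pooled.tolist() == [0.0, 1.0, 0.0]

    @pytest.mark.parametrize("length", [3, 8, 51])
    def test_output_is_embed_dim(self, tiny_config, length):
        params = nm.init_params(tiny_config, length, seed=0)
        out = M.cnn_branch(np.ones((length, 3), dtype=np.float32), params,
                           tiny_config, "chem")
        assert out.data.shape == (tiny_config.embed_dim,)


class TestForward:
    def test_eval_forward_is_deterministic(self, small_dataset, tiny_config):
        params = nm.init_params(tiny_config, 51, seed=0)
        sample = nm.EncodedSample(
            small_dataset.x_seq[0], small_dataset.x_chem[0],
            small_dataset.x_str[0], small_dataset.x_node[0],
            int(small_dataset.labels[0]))
        p1 = nm.forward(sample, params, tiny_config)
        p2 = nm.forward(sample, params, tiny_config)
        assert p1.prob == p2.prob
        assert 0.0 < p1.prob < 1.0
        assert p1.label_hat == int(p1.prob >= 0.5)

    def test_all_views_disabled_is_config_error(self):
        with pytest.raises(M.ConfigError):
            nm.ModelConfig(use_seq=False, use_chem=False, use_str=False)

    @pytest.mark.parametrize("disabled", ["seq", "chem", "str"])
    def test_disabled_view_does_not_affect_output(self, small_dataset,
                                                  tiny_config, rng, disabled):
        cfg = replace(tiny_config, **{f"use_{disabled}": False})
        params = nm.init_params(cfg, 51, seed=3)
        arrays = {
            "x_seq": small_dataset.x_seq[:4].copy(),
            "x_chem": small_dataset.x_chem[:4].copy(),
            "x_str": small_dataset.x_str[:4].copy(),
            "x_node": small_dataset.x_node[:4].copy(),
        }
        base = M._forward_batch(arrays["x_seq"], arrays["x_chem"],
                                arrays["x_str"], arrays["x_node"],
                                params, cfg).data
        key = {"seq": "x_seq", "chem": "x_chem", "str": "x_str"}[disabled]
        if disabled == "str":
            arrays[key] = np.zeros_like(arrays[key])  # different, symmetric
        else:
            arrays[key] = rng.random(arrays[key].shape).astype(np.float32)
        out = M._forward_batch(arrays["x_seq"], arrays["x_chem"],
                               arrays["x_str"], arrays["x_node"],
                               params, cfg).data
        assert np.array_equal(base, out)

    def test_seq_only_is_plain_cnn_classifier(self, small_dataset):
        cfg = nm.ModelConfig(n_kernels=8, embed_dim=8, n_heads=2,
                             fc_hidden=8, use_chem=False, use_str=False)
        params = nm.init_params(cfg, 51, seed=0)
        assert set(params) == {"seq_conv_w", "seq_conv_b", "seq_fc_w",
                               "seq_fc_b", "head_fc1_w", "head_fc1_b",
                               "head_fc2_w", "head_fc2_b"}
        probs = nm.predict_probs(small_dataset, params, cfg)
        assert ((probs > 0) & (probs < 1)).all()


class TestLossAndGradients:
    def test_bce_examples(self):
        assert M.bce_loss(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-5
        assert np.isclose(M.bce_loss(np.full(4, 0.5), np.array([0, 1, 0, 1])),
                          math.log(2))
        want = -0.5 * (math.log(0.9) + math.log(0.8))
        assert np.isclose(M.bce_loss(np.array([0.9, 0.2]), np.array([1, 0])),
                          want)
        with pytest.raises(ValueError):
            M.bce_loss(np.array([0.5]), np.array([1, 0]))

    def test_end_to_end_gradient_matches_finite_difference(self,
                                                           small_dataset,
                                                           rng):
        """Autodiff through the full fused model vs central differences."""
        cfg = nm.ModelConfig(n_kernels=4, embed_dim=4, n_heads=2, fc_hidden=4)
        params = nm.init_params(cfg, 51, seed=7, dtype=np.float64)
        sl = slice(0, 6)
        labels = small_dataset.labels[sl]

        def loss_value():
            probs = M._forward_batch(
                small_dataset.x_seq[sl].astype(float),
                small_dataset.x_chem[sl].astype(float),
                small_dataset.x_str[sl].astype(float),
                small_dataset.x_node[sl].astype(float), params, cfg)
            return M.bce_loss(probs, labels)

        loss = loss_value()
        loss.backward()
        checked = 0
        for name in sorted(params):
            p = params[name]
            flat_idx = rng.integers(0, p.data.size, size=2)
            for fi in flat_idx:
                idx = np.unravel_index(int(fi), p.data.shape)
                orig = p.data[idx]
                eps = 1e-6
                p.data[idx] = orig + eps
                lp = float(loss_value().data)
                p.data[idx] = orig - eps
                lm = float(loss_value().data)
                p.data[idx] = orig
                num = (lp - lm) / (2 * eps)
                got = p.grad[idx]
                assert abs(got - num) <= 1e-4 * max(1.0, abs(num)), name
                checked += 1
        assert checked >= 10


def test_checkpoint_roundtrip(tmp_path, tiny_config, small_dataset):
    params = nm.init_params(tiny_config, 51, seed=0)
    path = tmp_path / "model.npz"
    nm.save_checkpoint(path, params, tiny_config)
    params2, cfg2 = nm.load_checkpoint(path)
    assert cfg2 == tiny_config
    p1 = nm.predict_probs(small_dataset, params, tiny_config)
    p2 = nm.predict_probs(small_dataset, params2, cfg2)
    assert np.array_equal(p1, p2)
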