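"""Forward-pass exactness (hand computations), gradients and invariants."""

import numpy as np
import pytest

import schiclink.network as net
from schiclink.network import (
    Adam,
    ModelConfig,
    ablation_variant,
    attention_bias_forward,
    bce_loss,
    cell_encoder_forward,
    decoder_forward,
    init_params,
    load_checkpoint,
    loss_and_grads,
    model_forward,
    save_checkpoint,
    subgraph_encoder_forward,
)
from schiclink.sampling import EnclosingSubgraph, batch_subgraphs

LN_EPS = 1e-5


def tiny_config(**kw):
    defaults = dict(n_bins_total=20, d=8, d_c=4, p=3, n_layers=2, n_heads=2,
                    n_max=6, d_max=6, dec_hidden=5, cell_hidden=5, bias_hidden=4,
                    dropout=0.0)
    defaults.update(kw)
    return ModelConfig(**defaults)


def random_subgraph(rng, n, n_ids=20):
    a = (rng.random((n, n)) < 0.5).astype(np.uint8)
    a = np.triu(a, 1)
    a = a + a.T
    a[0, 1] = a[1, 0] = 0
    nodes = np.sort(rng.choice(n_ids, size=n, replace=False)).astype(np.int64)
    return EnclosingSubgraph(nodes, a, 0, 1)


def perturb_biases(params, rng, scale=0.1):
    """Move biases off their zero init so no ReLU sits exactly on its kink."""
    for k, v in params.items():
        if v.ndim == 1:
            params[k] = v + scale * rng.standard_normal(v.shape)
    return params


class TestCellEncoder:
    def test_hand_computed_two_layer_mlp(self):
        # C = W2 . max(0, W1 B + b1) + b2 with 2x2 weights, worked by hand
        params = {
            "W1c": np.array([[1.0, -2.0], [0.5, 1.0]]),
            "b1c": np.array([0.5, -1.0]),
            "W2c": np.array([[2.0, 0.0], [1.0, -1.0]]),
            "b2c": np.array([0.25, 0.75]),
        }
        b = np.array([[1.0, 2.0]])
        # pre = [1*1+2*0.5+0.5, 1*(-2)+2*1-1] = [2.5, -1.0]; hid = [2.5, 0]
        # C = [2.5*2+0*1+0.25, 2.5*0+0*(-1)+0.75] = [5.25, 0.75]
        c, _ = cell_encoder_forward(b, params)
        assert np.allclose(c, [[5.25, 0.75]], atol=1e-12)

    def test_zero_weights_constant_output(self):
        beta = np.array([3.0, -1.0])
        params = {"W1c": np.zeros((4, 3)), "b1c": np.zeros(3),
                  "W2c": np.zeros((3, 2)), "b2c": beta}
        c, _ = cell_encoder_forward(np.random.default_rng(0).standard_normal((5, 4)), params)
        assert np.allclose(c, beta)

    def test_rectifier_blocks_negative_preactivations(self):
        params = {"W1c": np.array([[1.0]]), "b1c": np.array([0.0]),
                  "W2c": np.array([[1.0]]), "b2c": np.array([0.0])}
        c, _ = cell_encoder_forward(np.array([[-5.0]]), params)
        assert c[0, 0] == 0.0


class TestAttentionBias:
    def test_zero_weights_zero_bias(self, rng):
        params = {"W1e": np.zeros((3, 2)), "b1e": np.zeros(2),
                  "W2e": np.zeros((2, 3)), "b2e": np.zeros(3)}
        d = rng.integers(0, 2, size=(4, 3, 3)).astype(float)
        e, _ = attention_bias_forward(d, params)
        assert np.all(e == 0.0)

    def test_tanh_bound(self, rng):
        params = {"W1e": rng.standard_normal((3, 5)), "b1e": rng.standard_normal(5),
                  "W2e": rng.standard_normal((5, 3)), "b2e": rng.standard_normal(3)}
        d = rng.integers(0, 2, size=(2, 3, 3)).astype(float)
        e, _ = attention_bias_forward(d, params)
        assert np.all(np.abs(e) < 1.0)

    def test_hand_computed_single_hidden_unit(self):
        # 3-node adjacency through a 1-unit hidden layer, worked by hand
        params = {"W1e": np.array([[1.0], [2.0], [-1.0]]), "b1e": np.array([0.5]),
                  "W2e": np.array([[1.0, -0.5, 2.0]]), "b2e": np.array([0.1, 0.2, -0.3])}
        d = np.array([[[0.0, 1.0, 1.0],
                       [1.0, 0.0, 0.0],
                       [1.0, 0.0, 0.0]]])
        # rows of D -> hidden: row0: 1*1+1*2-0*1+0.5 = wait: D row0=[0,1,1]:
        # h = relu(0*1 + 1*2 + 1*(-1) + 0.5) = relu(1.5) = 1.5
        # row1=[1,0,0]: relu(1 + 0.5) = 1.5 ; row2=[1,0,0]: 1.5
        # lin row_i = h_i * [1, -0.5, 2] + [0.1, 0.2, -0.3]
        lin = np.array([[1.6, -0.55, 2.7]] * 3)
        expected = np.tanh(lin)
        e, _ = attention_bias_forward(d, params)
        assert np.allclose(e[0], expected, atol=1e-12)


class TestDecoderAndLoss:
    def test_zero_decoder_weights_give_half(self, rng):
        cfg = tiny_config()
        params = init_params(cfg, seed=0)
        params["W1d"][:] = 0; params["b1d"][:] = 0
        params["W2d"][:] = 0; params["b2d"][:] = 0
        yhat, logit, _ = decoder_forward(rng.standard_normal((7, cfg.decoder_in)), params)
        assert np.allclose(yhat, 0.5, atol=0)
        y = rng.integers(0, 2, size=7).astype(float)
        assert np.isclose(bce_loss(yhat, y) / 7, np.log(2.0), atol=1e-12)

    def test_hand_computed_decoder(self):
        params = {"W1d": np.array([[1.0], [-1.0]]), "b1d": np.array([0.5]),
                  "W2d": np.array([[2.0]]), "b2d": np.array([-0.25])}
        x = np.array([[1.0, 0.25]])
        # hid = relu(1 - 0.25 + 0.5) = 1.25; logit = 2*1.25 - 0.25 = 2.25
        yhat, logit, _ = decoder_forward(x, params)
        assert np.isclose(logit[0], 2.25, atol=1e-12)
        assert np.isclose(yhat[0], 1 / (1 + np.exp(-2.25)), atol=1e-14)

    def test_sigmoid_monotone_in_output_bias(self):
        params = {"W1d": np.zeros((2, 1)), "b1d": np.array([1.0]),
                  "W2d": np.zeros((1, 1)), "b2d": np.array([0.0])}
        x = np.zeros((1, 2))
        vals = []
        for b in [0.0, 2.0, 8.0, 30.0]:
            params["b2d"] = np.array([b])
            yhat, _, _ = decoder_forward(x, params)
            vals.append(yhat[0])
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 1 - 1e-9

    def test_bce_matches_scalar_loop(self, rng):
        yhat = rng.uniform(0.01, 0.99, size=10)
        y = rng.integers(0, 2, size=10).astype(float)
        loop = -sum(yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for pi, yi in zip(yhat, y))
        assert np.isclose(bce_loss(yhat, y), loop, atol=1e-12)

    def test_bce_near_zero_when_exact(self):
        y = np.array([0.0, 1.0, 1.0])
        assert bce_loss(y, y) <= 3 * 2e-7

    def test_bce_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([1.0, 0.0]))


class TestSubgraphEncoder:
    def test_hand_computed_transformer_layer(self):
        """One layer, one head, d=2, 2-node subgraph vs an independent scalar
        re-derivation of the node-update equations."""
        cfg = ModelConfig(n_bins_total=4, d=2, d_c=2, p=2, n_layers=1, n_heads=1,
                          n_max=2, d_max=2, bias_hidden=1, dropout=0.0)
        rng = np.random.default_rng(5)
        params = init_params(cfg, seed=5)
        perturb_biases(params, rng)
        g = EnclosingSubgraph(np.array([1, 3]), np.zeros((2, 2), np.uint8), 0, 1)
        g.adj[0, 1] = g.adj[1, 0] = 1  # leave the edge in D to exercise the bias
        batch = batch_subgraphs([g], n_max=2)
        h_u, h_v, h, _ = subgraph_encoder_forward(batch, params, cfg, train=False)

        # --- independent scalar computation -------------------------------
        def ln(vec, gamma, beta):
            mu = vec.mean()
            var = ((vec - mu) ** 2).mean()
            return gamma * (vec - mu) / np.sqrt(var + LN_EPS) + beta

        deg = g.adj.sum(1)
        h0 = np.array([params["x"][1] + params["z"][deg[0]],
                       params["x"][3] + params["z"][deg[1]]])
        d_mat = g.adj.astype(float)
        e_rows = np.tanh(np.maximum(d_mat @ params["W1e"] + params["b1e"], 0)
                         @ params["W2e"] + params["b2e"])
        hn = np.array([ln(h0[i], params["ln1_g0"], params["ln1_b0"]) for i in range(2)])
        q = hn @ params["Wq0"] + params["bq0"]
        k = hn @ params["Wk0"] + params["bk0"]
        v = hn @ params["Wv0"] + params["bv0"]
        logits = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                logits[i, j] = q[i] @ k[j] / np.sqrt(2.0) + e_rows[i, j]
        attn = np.exp(logits - logits.max(1, keepdims=True))
        attn /= attn.sum(1, keepdims=True)
        ctx = attn @ v
        h_mid = h0 + ctx @ params["Wo0"] + params["bo0"]
        hn2 = np.array([ln(h_mid[i], params["ln2_g0"], params["ln2_b0"]) for i in range(2)])
        ffn = np.maximum(hn2 @ params["Wf10"] + params["bf10"], 0) @ params["Wf20"] + params["bf20"]
        h1 = h_mid + ffn

        assert np.allclose(h_u[0], h1[0], atol=1e-10)
        assert np.allclose(h_v[0], h1[1], atol=1e-10)

    def test_single_node_attention_is_identity_weight(self):
        cfg = tiny_config(n_layers=1)
        params = init_params(cfg, seed=1)
        g = EnclosingSubgraph(np.array([4]), np.zeros((1, 1), np.uint8), 0, 0)
        batch = batch_subgraphs([g], n_max=cfg.n_max)
        _, _, _, cache = subgraph_encoder_forward(batch, params, cfg, train=False)
        attn = cache["layers"][0]["attn"]
        assert np.allclose(attn[0, :, 0, 0], 1.0)

    def test_padded_keys_get_zero_attention(self, rng):
        cfg = tiny_config()
        params = init_params(cfg, seed=2)
        batch = batch_subgraphs([random_subgraph(rng, 3)], n_max=cfg.n_max)
        _, _, _, cache = subgraph_encoder_forward(batch, params, cfg, train=False)
        for layer in cache["layers"]:
            attn = layer["attn"]  # (S,H,N,N)
            assert np.all(attn[..., 3:] == 0.0)
            # rows over real keys sum to 1
            assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_permutation_equivariance_of_central_states(self, rng):
        # exact for the encoder without the adjacency bias: node identity then
        # enters only via x, z and D.  (The row-wise bias MLP is deliberately
        # position-aware — bins are sorted by genomic position — so the full
        # variant is not permutation-equivariant by construction.)
        cfg = ablation_variant(tiny_config(), "no_bias")
        params = init_params(cfg, seed=3)
        g = random_subgraph(rng, 6)
        perm = np.array([3, 0, 5, 2, 4, 1])  # where each old index lands
        inv = np.argsort(perm)
        g2 = EnclosingSubgraph(g.nodes[inv], g.adj[np.ix_(inv, inv)],
                               int(perm[g.u_idx]), int(perm[g.v_idx]))
        b1 = batch_subgraphs([g], n_max=cfg.n_max)
        b2 = batch_subgraphs([g2], n_max=cfg.n_max)
        hu1, hv1, _, _ = subgraph_encoder_forward(b1, params, cfg, train=False)
        hu2, hv2, _, _ = subgraph_encoder_forward(b2, params, cfg, train=False)
        assert np.allclose(hu1, hu2, atol=1e-5)
        assert np.allclose(hv1, hv2, atol=1e-5)

    def test_identical_features_identical_updates_without_bias(self):
        cfg = ablation_variant(tiny_config(), "no_bias")
        params = init_params(cfg, seed=4)
        nodes = np.array([7, 7, 7, 7])  # same bin embedding for every node
        g = EnclosingSubgraph(nodes, np.zeros((4, 4), np.uint8), 0, 1)  # same degree too
        batch = batch_subgraphs([g], n_max=cfg.n_max)
        _, _, h, _ = subgraph_encoder_forward(batch, params, cfg, train=False)
        for i in range(1, 4):
            assert np.allclose(h[0, i], h[0, 0], atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("variant", ["full", "no_bias", "sub_only", "cell_only"])
    def test_finite_difference_gradient_check(self, variant, rng):
        cfg = ablation_variant(tiny_config(), variant)
        params = perturb_biases(init_params(cfg, seed=1), rng)
        subs = [random_subgraph(rng, n) for n in (4, 6, 3)]
        batch = batch_subgraphs(subs, n_max=cfg.n_max)
        b_feats = rng.standard_normal((3, cfg.p))
        y = np.array([1.0, 0.0, 1.0])

        def loss_fn():
            _, logit, _ = model_forward(batch, b_feats, params, cfg, train=False)
            return float(np.mean(np.maximum(logit, 0) - logit * y
                                 + np.log1p(np.exp(-np.abs(logit)))))

        _, grads, _ = loss_and_grads(batch, b_feats, y, params, cfg, train=False)
        eps = 1e-6
        for key, p in params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss_fn()
                p[idx] = orig - eps
                lm = loss_fn()
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[key][idx]
                assert abs(fd - an) <= 1e-6 + 1e-4 * max(abs(fd), abs(an)), (
                    f"{key}{idx}: finite-diff {fd} vs analytic {an}"
                )


class TestVariants:
    def test_probabilities_in_unit_interval_all_variants(self, rng):
        for variant in ("full", "cell_only", "sub_only", "no_bias"):
            cfg = ablation_variant(tiny_config(), variant)
            params = init_params(cfg, seed=6)
            batch = batch_subgraphs([random_subgraph(rng, 5) for _ in range(4)],
                                    n_max=cfg.n_max)
            b_feats = rng.standard_normal((4, cfg.p))
            yhat, _, _ = model_forward(batch, b_feats, params, cfg)
            assert np.all((yhat > 0) & (yhat < 1))

    def test_cell_only_never_runs_subgraph_encoder(self, rng, monkeypatch):
        calls = {"n": 0}
        original = net.subgraph_encoder_forward

        def counting(*args, **kwargs):
            calls["n"] += 1
            return original(*args, **kwargs)

        monkeypatch.setattr(net, "subgraph_encoder_forward", counting)
        cfg = ablation_variant(tiny_config(), "cell_only")
        params = init_params(cfg, seed=7)
        batch = batch_subgraphs([random_subgraph(rng, 4)], n_max=cfg.n_max)
        model_forward(batch, rng.standard_normal((1, cfg.p)), params, cfg)
        assert calls["n"] == 0

    def test_no_bias_equals_full_with_zeroed_bias_mlp(self, rng):
        cfg = tiny_config()
        params = init_params(cfg, seed=8)
        for key in ("W1e", "b1e", "W2e", "b2e"):
            params[key][:] = 0.0
        batch = batch_subgraphs([random_subgraph(rng, 5)], n_max=cfg.n_max)
        b_feats = rng.standard_normal((1, cfg.p))
        y_full, _, _ = model_forward(batch, b_feats, params, cfg)
        y_nb, _, _ = model_forward(batch, b_feats, params,
                                   ablation_variant(cfg, "no_bias"))
        assert np.allclose(y_full, y_nb, atol=1e-14)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            ablation_variant(tiny_config(), "bogus")


class TestOptimizerAndCheckpoint:
    def test_adam_descends_on_quadratic(self):
        params = {"w": np.array([5.0])}
        opt = Adam(params, lr=0.1, weight_decay=0.0)
        for _ in range(200):
            opt.step(params, {"w": 2 * params["w"]})
        assert abs(params["w"][0]) < 1e-2

    def test_checkpoint_round_trip_identical_predictions(self, rng, tmp_path):
        cfg = tiny_config()
        params = init_params(cfg, seed=9)
        batch = batch_subgraphs([random_subgraph(rng, 5) for _ in range(3)],
                                n_max=cfg.n_max)
        b_feats = rng.standard_normal((3, cfg.p))
        y0, _, _ = model_forward(batch, b_feats, params, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, cfg, metadata={"note": "test"})
        params2, cfg2, meta = load_checkpoint(str(path) + ".npz"
                                              if not str(path).endswith(".npz") else path)
        assert cfg2 == cfg and meta["note"] == "test"
        y1, _, _ = model_forward(batch, b_feats, params2, cfg2)
        assert np.array_equal(y0, y1)
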