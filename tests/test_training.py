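"""Training loop, contrastive pretraining, imputation and reproducibility."""

import numpy as np
import pytest

import schiclink as sk
from schiclink.network import ModelConfig, init_params, loss_and_grads, Adam
from schiclink.sampling import batch_subgraphs
from schiclink.simulate import two_type_config, simulate_graphset
from schiclink.training import (
    TrainConfig,
    contrastive_loss_and_grads,
    edge_perturb,
    impute,
    make_batch,
    node_drop,
    pretrain_contrastive,
    subgraph_for_sample,
)
from conftest import make_graphset


def small_problem(seed=0, n_cells=6, n_bins=50, reads=500):
    cfg = two_type_config(n_cells=n_cells, n_bins=n_bins, reads_per_cell=reads,
                          domain_width=12, seed=seed)
    gs, truths = simulate_graphset(cfg)
    train_s, test_s, masked = sk.split_edges(gs, seed=seed)
    from schiclink.features import pca_cell_features

    b_all, _ = pca_cell_features(masked, n_cells - 1)
    mc = ModelConfig(n_bins_total=gs.bin_map.n_bins_total, p=b_all.shape[1],
                     d=16, n_heads=2, n_max=16, d_max=16, dropout=0.0)
    return gs, truths, train_s, test_s, masked, b_all, mc


class TestDescent:
    def test_single_adam_step_decreases_sample_loss(self, rng):
        gs, truths, train_s, _, masked, b_all, mc = small_problem()
        params = init_params(mc, seed=0)
        chunk = train_s[:8]
        batch, b_feats, y = make_batch(chunk, masked, b_all, mc, rng)
        loss0, grads, _ = loss_and_grads(batch, b_feats, y, params, mc, train=False)
        opt = Adam(params, lr=1e-3, weight_decay=0.0)
        opt.step(params, grads)
        loss1, _, _ = loss_and_grads(batch, b_feats, y, params, mc, train=False)
        assert loss1 < loss0


class TestAugmentations:
    def _subgraph(self, rng):
        gs, truths, train_s, _, masked, b_all, mc = small_problem(seed=3)
        sample = train_s[rng.integers(len(train_s))]
        return subgraph_for_sample(sample, masked, mc, rng)

    def test_node_drop_spares_central_nodes(self, rng):
        g = self._subgraph(rng)
        for trial in range(1000):
            out = node_drop(g, 0.5, rng)
            assert g.nodes[g.u_idx] in out.nodes
            assert g.nodes[g.v_idx] in out.nodes
            assert out.nodes[out.u_idx] == g.nodes[g.u_idx]
            assert out.nodes[out.v_idx] == g.nodes[g.v_idx]

    def test_node_drop_removes_expected_count(self, rng):
        g = self._subgraph(rng)
        out = node_drop(g, 0.5, rng)
        expected = g.n_nodes - int(0.5 * (g.n_nodes - 2))
        assert out.n_nodes == expected

    def test_edge_perturb_preserves_candidate_edge_absence(self, rng):
        g = self._subgraph(rng)
        for trial in range(1000):
            out = edge_perturb(g, 0.4, rng)
            assert out.adj[out.u_idx, out.v_idx] == 0
            assert np.array_equal(out.adj, out.adj.T)

    def test_edge_perturb_keeps_edge_count(self, rng):
        g = self._subgraph(rng)
        n_edges = int(np.triu(g.adj, 1).sum())
        out = edge_perturb(g, 0.3, rng)
        n_pert = int(0.3 * n_edges)
        # perturbation swaps edges: count changes only if non-edge pool ran out
        assert int(np.triu(out.adj, 1).sum()) <= n_edges
        assert int(np.triu(out.adj, 1).sum()) >= n_edges - n_pert


class TestContrastive:
    def test_identical_views_have_unit_positive_cosine(self, rng):
        gs, truths, train_s, _, masked, b_all, mc = small_problem(seed=4)
        subs = [subgraph_for_sample(s, masked, mc, rng) for s in train_s[:6]]
        batch = batch_subgraphs(subs, n_max=mc.n_max)
        params = init_params(mc, seed=1)
        loss, _, pos_cos = contrastive_loss_and_grads(batch, batch, params, mc, 0.5)
        assert np.allclose(pos_cos, 1.0, atol=1e-12)
        # loss equals its analytic value for perfectly aligned positives
        assert loss > 0

    def test_batch_of_one_rejected(self, rng):
        gs, truths, train_s, _, masked, b_all, mc = small_problem(seed=4)
        g = subgraph_for_sample(train_s[0], masked, mc, rng)
        batch = batch_subgraphs([g], n_max=mc.n_max)
        params = init_params(mc, seed=1)
        with pytest.raises(ValueError, match="batch size"):
            contrastive_loss_and_grads(batch, batch, params, mc, 0.5)

    def test_pretraining_reduces_contrastive_loss(self, rng):
        gs, truths, train_s, _, masked, b_all, mc = small_problem(seed=5)
        subs = [subgraph_for_sample(s, masked, mc, rng) for s in train_s[:160]]
        params = init_params(mc, seed=2)
        tc = TrainConfig(pretrain_epochs=5, pretrain_batch=32, aug_ratio=0.2, seed=0)
        history = pretrain_contrastive(subs, params, mc, tc)
        assert len(history) == 5
        assert history[-1] < history[0]

    def test_pretraining_requires_two_subgraphs(self):
        gs, truths, train_s, _, masked, b_all, mc = small_problem(seed=5)
        params = init_params(mc, seed=2)
        with pytest.raises(ValueError, match="at least 2"):
            pretrain_contrastive([], params, mc, TrainConfig())


class TestTrainLoop:
    def _fit(self, seed=0, epochs=3):
        cfg = two_type_config(n_cells=6, n_bins=50, reads_per_cell=500,
                              domain_width=12, seed=1)
        gs, _ = simulate_graphset(cfg)
        model = sk.ContactImputer(gs, d=16, n_heads=2, n_max=16, d_max=16,
                                  n_bins_total=gs.bin_map.n_bins_total,
                                  p=5)
        tc = TrainConfig(epochs=epochs, samples_per_epoch=600, batch_size=128,
                         max_val_samples=400, seed=seed)
        return model.fit(train_config=tc, seed=seed)

    def test_loss_curve_reproducible_under_seed(self):
        a = self._fit(seed=7)
        b = self._fit(seed=7)
        assert np.allclose(a.history["train_loss"], b.history["train_loss"], atol=1e-6)
        assert np.allclose(a.history["val_aupr"], b.history["val_aupr"], atol=1e-12)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])

    def test_history_and_summary(self):
        res = self._fit(seed=3, epochs=2)
        assert list(res.history.columns) == ["epoch", "train_loss", "val_aupr"]
        text = res.summary()
        assert "Held-out AUPR" in text and "Cells:" in text
        m = res.metrics()
        assert set(m) >= {"auc", "aupr", "test_prevalence"}

    def test_results_checkpoint_round_trip(self, tmp_path):
        res = self._fit(seed=5, epochs=2)
        path = tmp_path / "ck.npz"
        res.save(path)
        params, config, meta = res.load_params(path)
        assert meta["seed"] == 5
        scores = res.predict(res.test_samples[:32])
        from schiclink.training import score_samples

        scores2 = score_samples(res.test_samples[:32], res.masked_graphset,
                                res.b_all, params, config)
        assert np.array_equal(scores, scores2)


class TestImpute:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = two_type_config(n_cells=6, n_bins=40, reads_per_cell=500,
                              domain_width=10, seed=2)
        gs, truths = simulate_graphset(cfg)
        model = sk.ContactImputer(gs, d=16, n_heads=2, n_max=16, d_max=16,
                                  n_bins_total=gs.bin_map.n_bins_total, p=5)
        tc = TrainConfig(epochs=8, samples_per_epoch=1500, batch_size=128,
                         max_val_samples=300, seed=0)
        return gs, truths, model.fit(train_config=tc, seed=0)

    def test_keep_observed_flag_pins_probability_one(self, fitted):
        gs, truths, res = fitted
        maps = res.impute(band=10, keep_observed=True)
        masked = res.masked_graphset
        import scipy.sparse as sp

        tri = sp.triu(masked.cells[0].matrices["chr1"], k=1).tocoo()
        for u, v in zip(tri.row, tri.col):
            assert maps[0]["chr1"][u, v] == 1.0

    def test_output_symmetric_zero_diagonal(self, fitted):
        gs, truths, res = fitted
        maps = res.impute(band=8)
        m = maps[0]["chr1"]
        assert np.array_equal(m, m.T)
        assert np.all(np.diagonal(m) == 0)

    def test_scores_track_planted_truth(self, fitted):
        # mean predicted probability over the true top-decile pairs exceeds
        # the mean over the bottom decile
        gs, truths, res = fitted
        maps = res.impute()
        iu, ju = np.triu_indices(40, k=1)
        top_means, bot_means = [], []
        for ci in range(gs.n_cells):
            p = truths[ci]["chr1"][iu, ju]
            yhat = maps[ci]["chr1"][iu, ju]
            q90, q10 = np.quantile(p, [0.9, 0.1])
            top_means.append(yhat[p >= q90].mean())
            bot_means.append(yhat[p <= q10].mean())
        assert np.mean(top_means) > np.mean(bot_means)

    def test_pair_outside_bins_rejected(self, fitted):
        gs, truths, res = fitted
        with pytest.raises(ValueError, match="outside"):
            res.impute(targets=[(0, "chr1", 0, 99)])

    def test_attention_debug_export(self, fitted):
        gs, truths, res = fitted
        sample = res.test_samples[0]
        out = res.attention_maps(sample)
        n = len(out["nodes"])
        assert out["bias"].shape == (n, n)
        assert np.all(np.abs(out["bias"]) < 1.0)
        assert len(out["attention"]) == res.config.n_layers
        for attn in out["attention"]:
            assert attn.shape == (res.config.n_heads, n, n)
            assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
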