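"""Model facade: build from a graphset, fit, inspect results.

Follows the model/results convention of statistical modelling packages:
:class:`ContactImputer` holds the data and configuration, ``fit()`` runs the
(optional) contrastive pretraining and the supervised optimization, and
returns a :class:`ContactImputerResults` carrying the fitted parameters,
the training history, held-out metrics, cell embeddings, imputation and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from .evaluation import auc_aupr
from .features import pca_cell_features
from .io import GraphSet
from .network import (
    ModelConfig,
    ablation_variant,
    cell_encoder_forward,
    init_params,
    load_checkpoint,
    save_checkpoint,
)
from .sampling import EdgeSample, split_edges
from .training import (
    TrainConfig,
    impute,
    pretrain_contrastive,
    score_samples,
    subgraph_for_sample,
    train,
)

Split = tuple[list[EdgeSample], list[EdgeSample], GraphSet]


class ContactImputer:
    """Link-prediction imputation model over a single-cell Hi-C graphset.

    Parameters
    ----------
    graphset : GraphSet
        Binned single-cell contact maps sharing one bin map.
    config : ModelConfig, optional
        Network hyperparameters; built from defaults when omitted.  The PCA
        dimension is truncated to the number of cells minus one.
    """

    def __init__(self, graphset: GraphSet, config: ModelConfig | None = None, **overrides):
        if graphset.n_cells < 2:
            raise ValueError("need at least 2 cells")
        self.graphset = graphset
        if config is None:
            overrides.setdefault("n_bins_total", graphset.bin_map.n_bins_total)
            # a handful of leading components per expected population: taking
            # nearly m-1 components drowns the population axes in sampling
            # noise and starves the cell pathway during training
            overrides.setdefault("p", min(32, max(2, graphset.n_cells // 5)))
            config = ModelConfig(**overrides)
        if config.p > graphset.n_cells - 1:
            config = replace(config, p=graphset.n_cells - 1)
        self.config = config

    @classmethod
    def from_graphset(cls, graphset: GraphSet, **overrides) -> "ContactImputer":
        return cls(graphset, **overrides)

    def make_split(self, seed: int = 0, test_fraction: float = 0.10) -> Split:
        """Edge split reusable across variants for like-for-like comparison."""
        return split_edges(self.graphset, test_fraction=test_fraction, seed=seed)

    def fit(
        self,
        train_config: TrainConfig | None = None,
        seed: int = 0,
        variant: str | None = None,
        split: Split | None = None,
    ) -> "ContactImputerResults":
        """Split (unless given), optionally pretrain, train, evaluate held-out.

        One seed fans out to independent streams for the edge split, the
        parameter initialization, pretraining and training, so runs are fully
        reproducible.
        """
        config = ablation_variant(self.config, variant) if variant else self.config
        if train_config is None:
            train_config = TrainConfig(seed=seed)
        ss = np.random.SeedSequence(seed)
        seed_split, seed_init, seed_pre = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        )
        if split is None:
            split = split_edges(self.graphset, seed=seed_split)
        train_samples, test_samples, masked = split
        b_all, pca = pca_cell_features(masked, config.p)
        if b_all.shape[1] < config.p:
            config = replace(config, p=b_all.shape[1])
        params = init_params(config, seed=seed_init)

        pretrain_history: list[float] = []
        if train_config.pretrain and config.variant != "cell_only":
            rng = np.random.default_rng(seed_pre)
            n_sub = min(len(train_samples), train_config.max_pretrain_subgraphs)
            idx = rng.choice(len(train_samples), size=n_sub, replace=False)
            subgraphs = [
                subgraph_for_sample(train_samples[i], masked, config, rng) for i in idx
            ]
            pretrain_history = pretrain_contrastive(subgraphs, params, config, train_config)

        best_params, history = train(masked, train_samples, b_all, params, config, train_config)
        scores = score_samples(test_samples, masked, b_all, best_params, config)
        y_test = np.array([s.label for s in test_samples], dtype=float)
        test_auc, test_aupr = auc_aupr(scores, y_test)
        return ContactImputerResults(
            model=self,
            config=config,
            train_config=train_config,
            params=best_params,
            history=pd.DataFrame(history),
            pretrain_history=pretrain_history,
            split=split,
            b_all=b_all,
            pca=pca,
            test_scores=scores,
            test_auc=test_auc,
            test_aupr=test_aupr,
            seed=seed,
        )


class ContactImputerResults:
    """Fitted model: parameters, history, held-out metrics and downstream ops."""

    def __init__(self, model, config, train_config, params, history, pretrain_history,
                 split, b_all, pca, test_scores, test_auc, test_aupr, seed):
        self.model = model
        self.config = config
        self.train_config = train_config
        self.params = params
        self.history = history
        self.pretrain_history = pretrain_history
        self.train_samples, self.test_samples, self.masked_graphset = split
        self.b_all = b_all
        self.pca = pca
        self.test_scores = test_scores
        self.test_auc = test_auc
        self.test_aupr = test_aupr
        self.seed = seed

    # -- estimates ---------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    @property
    def test_prevalence(self) -> float:
        y = np.array([s.label for s in self.test_samples], dtype=float)
        return float(y.mean())

    def cell_embeddings(self) -> np.ndarray:
        """Learned cell embeddings C_i (one row per cell)."""
        c, _ = cell_encoder_forward(self.b_all, self.params)
        return c

    def predict(self, samples: list[EdgeSample] | None = None) -> np.ndarray:
        """Predicted contact probabilities for edge samples (default: test split)."""
        if samples is None:
            return self.test_scores.copy()
        return score_samples(samples, self.masked_graphset, self.b_all,
                             self.params, self.config)

    def impute(self, band: int | None = None, targets=None,
               keep_observed: bool = False) -> list[dict[str, np.ndarray]]:
        """Dense per-cell probability maps over a genomic-distance band."""
        return impute(self.masked_graphset, self.b_all, self.params, self.config,
                      band=band, targets=targets, keep_observed=keep_observed)

    def attention_maps(self, sample: EdgeSample) -> dict:
        """Debug export: per-layer/head attention and the adjacency bias for
        one candidate edge (interpretability of what the encoder attends to).

        Returns node ids, the bias matrix E and a list of (heads, n, n)
        attention arrays, cropped to the real (unpadded) nodes.
        """
        from .network import attention_bias_forward, subgraph_encoder_forward
        from .sampling import batch_subgraphs
        from .training import subgraph_for_sample

        if self.config.variant == "cell_only":
            raise ValueError("the cell-only variant has no subgraph encoder")
        sub = subgraph_for_sample(sample, self.masked_graphset, self.config,
                                  np.random.default_rng(self.seed))
        batch = batch_subgraphs([sub], n_max=self.config.n_max)
        _, _, _, cache = subgraph_encoder_forward(batch, self.params, self.config,
                                                  train=False)
        n = sub.n_nodes
        if self.config.variant == "no_bias":
            bias = np.zeros((n, n))
        else:
            e, _ = attention_bias_forward(batch.adj.astype(float), self.params)
            bias = e[0, :n, :n]
        layers = [layer["attn"][0, :, :n, :n].copy() for layer in cache["layers"]]
        return {"nodes": sub.nodes.copy(), "bias": bias, "attention": layers,
                "u_idx": sub.u_idx, "v_idx": sub.v_idx}

    # -- reporting ---------------------------------------------------------

    def metrics(self) -> dict:
        return {
            "auc": round(self.test_auc, 6),
            "aupr": round(self.test_aupr, 6),
            "test_prevalence": round(self.test_prevalence, 6),
            "best_val_aupr": round(float(self.history["val_aupr"].max()), 6),
            "final_train_loss": round(float(self.history["train_loss"].iloc[-1]), 6),
        }

    def summary(self) -> str:
        g = self.model.graphset
        lines = [
            "Single-cell Hi-C contact imputation (subgraph transformer)",
            "=" * 62,
            f"Cells: {g.n_cells:>6}    Genome bins: {g.bin_map.n_bins_total:>6}    "
            f"Resolution: {g.bin_map.resolution} bp",
            f"Variant: {self.config.variant:<10} k-hop: {self.config.k}   "
            f"d={self.config.d} heads={self.config.n_heads} layers={self.config.n_layers}",
            f"Parameters: {self.n_parameters}",
            "-" * 62,
            f"Train samples: {len(self.train_samples):>8}    "
            f"Test samples: {len(self.test_samples):>8}",
            f"Epochs run: {len(self.history):>5}    "
            f"Final train loss: {self.history['train_loss'].iloc[-1]:.4f}",
            f"Best validation AUPR: {self.history['val_aupr'].max():.4f}",
            "-" * 62,
            f"Held-out AUC:  {self.test_auc:.4f}",
            f"Held-out AUPR: {self.test_aupr:.4f}   "
            f"(positive prevalence {self.test_prevalence:.4f})",
            "=" * 62,
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training-loss and validation-AUPR curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train loss")
        ax2 = ax.twinx()
        ax2.plot(self.history["epoch"], self.history["val_aupr"], color="C1",
                 label="val AUPR")
        ax.set_xlabel("epoch")
        ax.set_ylabel("train loss")
        ax2.set_ylabel("validation AUPR")
        return ax

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: config + parameters + run metadata (history, metrics)."""
        save_checkpoint(path, self.params, self.config, metadata={
            "seed": self.seed,
            "metrics": self.metrics(),
            "history": self.history.to_dict(orient="list"),
            "train_config": asdict(self.train_config),
        })

    @staticmethod
    def load_params(path) -> tuple[dict, ModelConfig, dict]:
        return load_checkpoint(path)
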