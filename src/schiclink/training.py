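"""Training: contrastive pretraining, supervised optimization, imputation.

The subgraph encoder can first be pretrained with graph contrastive learning:
two augmented views of each enclosing subgraph (node dropping and edge
perturbation, both sparing the central pair u, v and the candidate edge) are
pushed together in embedding space by the normalized-temperature
cross-entropy (NT-Xent) loss.  Supervised training then minimizes binary
cross-entropy over the train edge samples with Adam
(beta1 = 0.9, beta2 = 0.999, lr = 1e-3, weight decay = 1e-5).

A small validation slice (default 5% of the train samples) is carved out for
early stopping on AUPR; the test split is never touched during fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import GraphSet
from .network import (
    Adam,
    ModelConfig,
    loss_and_grads,
    model_forward,
    subgraph_encoder_forward,
    subgraph_encoder_backward,
)
from .sampling import (
    EdgeSample,
    EnclosingSubgraph,
    SubgraphBatch,
    batch_subgraphs,
    extract_enclosing_subgraph,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings.

    Optimizer defaults follow the standard Adam recipe for this model family
    (beta1 = 0.9, beta2 = 0.999, lr = 1e-3, weight decay = 1e-5).
    ``samples_per_epoch`` caps how many train edge samples are visited per
    epoch (a fresh uniform subsample each epoch) so that desk-scale CPU runs
    stay fast; None visits all samples every epoch.
    """

    epochs: int = 30
    batch_size: int = 256
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-5
    pretrain: bool = False
    pretrain_epochs: int = 5
    pretrain_batch: int = 64
    max_pretrain_subgraphs: int = 50_000
    aug_ratio: float = 0.2
    temperature: float = 0.5
    val_fraction: float = 0.05
    max_val_samples: int = 3000
    patience: int | None = None
    samples_per_epoch: int | None = 6000
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= self.aug_ratio < 1:
            raise ValueError("aug_ratio must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


# ---------------------------------------------------------------------------
# sample -> batch plumbing
# ---------------------------------------------------------------------------

def subgraph_for_sample(
    sample: EdgeSample,
    masked_graphset: GraphSet,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> EnclosingSubgraph:
    adj = masked_graphset.cells[sample.cell_index].matrices[sample.chrom]
    offset = masked_graphset.bin_map.offsets[sample.chrom]
    return extract_enclosing_subgraph(
        adj, sample.u, sample.v, k=config.k, n_max=config.n_max, rng=rng, global_offset=offset
    )


def make_batch(
    samples: list[EdgeSample],
    masked_graphset: GraphSet,
    b_all: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SubgraphBatch, np.ndarray, np.ndarray]:
    """Extract subgraphs and per-sample cell features; returns (batch, B, y)."""
    subs = [subgraph_for_sample(s, masked_graphset, config, rng) for s in samples]
    batch = batch_subgraphs(subs, n_max=config.n_max)
    b_feats = b_all[[s.cell_index for s in samples]]
    y = np.array([s.label for s in samples], dtype=float)
    return batch, b_feats, y


def score_samples(
    samples: list[EdgeSample],
    masked_graphset: GraphSet,
    b_all: np.ndarray,
    params: dict,
    config: ModelConfig,
    batch_size: int = 512,
    cap_seed: int = 0,
) -> np.ndarray:
    """Evaluation-mode predicted probabilities for a list of edge samples."""
    rng = np.random.default_rng(cap_seed)
    out = np.empty(len(samples))
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo:lo + batch_size]
        batch, b_feats, _ = make_batch(chunk, masked_graphset, b_all, config, rng)
        yhat, _, _ = model_forward(batch, b_feats, params, config, train=False)
        out[lo:lo + len(chunk)] = yhat
    return out


# ---------------------------------------------------------------------------
# contrastive pretraining
# ---------------------------------------------------------------------------

def node_drop(g: EnclosingSubgraph, ratio: float, rng: np.random.Generator) -> EnclosingSubgraph:
    """Drop a fraction of non-central nodes; u and v are always preserved."""
    n = g.n_nodes
    others = [i for i in range(n) if i not in (g.u_idx, g.v_idx)]
    n_drop = int(ratio * len(others))
    if n_drop == 0:
        return EnclosingSubgraph(g.nodes.copy(), g.adj.copy(), g.u_idx, g.v_idx)
    dropped = set(rng.choice(others, size=n_drop, replace=False).tolist())
    keep = [i for i in range(n) if i not in dropped]
    adj = g.adj[np.ix_(keep, keep)].copy()
    pos = {old: new for new, old in enumerate(keep)}
    return EnclosingSubgraph(g.nodes[keep].copy(), adj, pos[g.u_idx], pos[g.v_idx])


def edge_perturb(g: EnclosingSubgraph, ratio: float, rng: np.random.Generator) -> EnclosingSubgraph:
    """Remove a fraction of edges and add as many non-edges; (u, v) is spared.

    The candidate edge (u, v) is already masked out of the adjacency and is
    excluded from the pool of addable non-edges, so the augmentation can
    neither remove nor introduce it.
    """
    n = g.n_nodes
    adj = g.adj.copy()
    iu, ju = np.triu_indices(n, k=1)
    present = adj[iu, ju] != 0
    central = ((iu == min(g.u_idx, g.v_idx)) & (ju == max(g.u_idx, g.v_idx)))
    edges = np.flatnonzero(present & ~central)
    non_edges = np.flatnonzero(~present & ~central)
    n_pert = int(ratio * len(edges))
    if n_pert == 0:
        return EnclosingSubgraph(g.nodes.copy(), adj, g.u_idx, g.v_idx)
    rm = rng.choice(edges, size=n_pert, replace=False)
    add = rng.choice(non_edges, size=min(n_pert, len(non_edges)), replace=False)
    for idx in rm:
        adj[iu[idx], ju[idx]] = adj[ju[idx], iu[idx]] = 0
    for idx in add:
        adj[iu[idx], ju[idx]] = adj[ju[idx], iu[idx]] = 1
    return EnclosingSubgraph(g.nodes.copy(), adj, g.u_idx, g.v_idx)


def _encoder_param_keys(params: dict, config: ModelConfig) -> list[str]:
    keys = ["x", "z", "Wp1", "bp1", "Wp2", "bp2"]
    if config.variant != "no_bias":
        keys += ["W1e", "b1e", "W2e", "b2e"]
    for layer in range(config.n_layers):
        keys += [f"{nm}{layer}" for nm in
                 ("ln1_g", "ln1_b", "Wq", "bq", "Wk", "bk", "Wv", "bv", "Wo", "bo",
                  "ln2_g", "ln2_b", "Wf1", "bf1", "Wf2", "bf2")]
    return keys


def _projection_forward(batch: SubgraphBatch, params: dict, config: ModelConfig):
    _, _, h, enc_cache = subgraph_encoder_forward(batch, params, config, train=False)
    maskf = batch.mask.astype(float)[..., None]
    n_real = batch.mask.sum(axis=1, keepdims=True).astype(float)
    g = (h * maskf).sum(axis=1) / n_real  # mean readout over real nodes
    pre = g @ params["Wp1"] + params["bp1"]
    hid = np.maximum(pre, 0.0)
    z = hid @ params["Wp2"] + params["bp2"]
    return z, (enc_cache, maskf, n_real, g, pre, hid)


def _projection_backward(dz, cache, params, config, grads):
    enc_cache, maskf, n_real, g, pre, hid = cache
    grads["Wp2"] += hid.T @ dz
    grads["bp2"] += dz.sum(axis=0)
    dhid = dz @ params["Wp2"].T
    dpre = dhid * (pre > 0)
    grads["Wp1"] += g.T @ dpre
    grads["bp1"] += dpre.sum(axis=0)
    dg = dpre @ params["Wp1"].T
    dh = (dg[:, None, :] / n_real[:, :, None]) * maskf
    subgraph_encoder_backward(dh, enc_cache, params, config, grads)


def contrastive_loss_and_grads(
    batch_a: SubgraphBatch,
    batch_b: SubgraphBatch,
    params: dict,
    config: ModelConfig,
    temperature: float,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """NT-Xent loss over two views; returns (loss, grads, positive cosines)."""
    s = batch_a.size
    if s < 2:
        raise ValueError("contrastive loss requires batch size >= 2")
    za, ca = _projection_forward(batch_a, params, config)
    zb, cb = _projection_forward(batch_b, params, config)
    z = np.vstack([za, zb])  # (2S, dp)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    zn = z / norms
    sim = zn @ zn.T / temperature
    np.fill_diagonal(sim, -1e30)
    targets = np.concatenate([np.arange(s, 2 * s), np.arange(s)])
    m = sim.max(axis=1, keepdims=True)
    e = np.exp(sim - m)
    p = e / e.sum(axis=1, keepdims=True)
    rows = np.arange(2 * s)
    loss = float(-np.log(np.maximum(p[rows, targets], 1e-300)).mean())
    pos_cos = (zn[:s] * zn[s:]).sum(axis=1)

    dsim = p.copy()
    dsim[rows, targets] -= 1.0
    dsim /= 2 * s
    np.fill_diagonal(dsim, 0.0)
    dzn = (dsim + dsim.T) @ zn / temperature
    dz = (dzn - zn * (dzn * zn).sum(axis=1, keepdims=True)) / norms
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    _projection_backward(dz[:s], ca, params, config, grads)
    _projection_backward(dz[s:], cb, params, config, grads)
    return loss, grads, pos_cos


def pretrain_contrastive(
    subgraphs: list[EnclosingSubgraph],
    params: dict,
    config: ModelConfig,
    train_config: TrainConfig,
) -> list[float]:
    """Contrastive pretraining of the subgraph encoder; returns per-epoch losses."""
    if len(subgraphs) < 2:
        raise ValueError("pretraining requires at least 2 subgraphs")
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 17]))
    keys = _encoder_param_keys(params, config)
    sub_params = {k: params[k] for k in keys}
    opt = Adam(sub_params, lr=train_config.lr, beta1=train_config.beta1,
               beta2=train_config.beta2, weight_decay=train_config.weight_decay)
    history = []
    for epoch in range(train_config.pretrain_epochs):
        order = rng.permutation(len(subgraphs))
        losses = []
        for lo in range(0, len(order), train_config.pretrain_batch):
            idx = order[lo:lo + train_config.pretrain_batch]
            if len(idx) < 2:
                continue
            views_a = [node_drop(subgraphs[i], train_config.aug_ratio, rng) for i in idx]
            views_b = [edge_perturb(subgraphs[i], train_config.aug_ratio, rng) for i in idx]
            ba = batch_subgraphs(views_a, n_max=config.n_max)
            bb = batch_subgraphs(views_b, n_max=config.n_max)
            loss, grads, _ = contrastive_loss_and_grads(
                ba, bb, params, config, train_config.temperature
            )
            opt.step(sub_params, {k: grads[k] for k in keys})
            losses.append(loss)
        history.append(float(np.mean(losses)))
        logger.info("pretrain epoch %d: contrastive loss %.4f", epoch, history[-1])
    return history


# ---------------------------------------------------------------------------
# supervised training
# ---------------------------------------------------------------------------

def train(
    masked_graphset: GraphSet,
    train_samples: list[EdgeSample],
    b_all: np.ndarray,
    params: dict,
    config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[dict, list[dict]]:
    """Minimize BCE over train edge samples; returns (best params, history).

    A fixed ``val_fraction`` of the train samples is held out for per-epoch
    AUPR monitoring; the parameters achieving the best validation AUPR are
    returned.  Fully deterministic under ``train_config.seed``.
    """
    from .evaluation import auc_aupr

    ss = np.random.SeedSequence([train_config.seed, 29])
    rng_split, rng_epoch, rng_cap, rng_drop = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]
    samples = list(train_samples)
    order = rng_split.permutation(len(samples))
    n_val = max(2, int(train_config.val_fraction * len(samples)))
    n_val = min(n_val, train_config.max_val_samples)
    val_idx = set(order[:n_val].tolist())
    val_samples = [samples[i] for i in sorted(val_idx)]
    pool = [samples[i] for i in order[n_val:]]

    opt = Adam(params, lr=train_config.lr, beta1=train_config.beta1,
               beta2=train_config.beta2, weight_decay=train_config.weight_decay)
    best = {k: v.copy() for k, v in params.items()}
    best_aupr, since_best = -np.inf, 0
    history: list[dict] = []
    y_val = np.array([s.label for s in val_samples], dtype=float)

    for epoch in range(train_config.epochs):
        if train_config.samples_per_epoch and train_config.samples_per_epoch < len(pool):
            idx = rng_epoch.choice(len(pool), size=train_config.samples_per_epoch, replace=False)
        else:
            idx = rng_epoch.permutation(len(pool))
        losses = []
        for lo in range(0, len(idx), train_config.batch_size):
            chunk = [pool[i] for i in idx[lo:lo + train_config.batch_size]]
            batch, b_feats, y = make_batch(chunk, masked_graphset, b_all, config, rng_cap)
            loss, grads, _ = loss_and_grads(batch, b_feats, y, params, config,
                                            train=True, rng=rng_drop)
            opt.step(params, grads)
            losses.append(loss)
        train_loss = float(np.mean(losses))
        scores = score_samples(val_samples, masked_graphset, b_all, params, config)
        _, val_aupr = auc_aupr(scores, y_val)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_aupr": val_aupr})
        logger.info("epoch %d: train loss %.4f  val AUPR %.4f", epoch, train_loss, val_aupr)
        if val_aupr > best_aupr:
            best_aupr, since_best = val_aupr, 0
            best = {k: v.copy() for k, v in params.items()}
        else:
            since_best += 1
            if train_config.patience is not None and since_best > train_config.patience:
                logger.info("early stop at epoch %d (patience %d)", epoch, train_config.patience)
                break
    return best, history


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute(
    masked_graphset: GraphSet,
    b_all: np.ndarray,
    params: dict,
    config: ModelConfig,
    band: int | None = None,
    targets: list[tuple[int, str, int, int]] | None = None,
    keep_observed: bool = False,
    batch_size: int = 512,
) -> list[dict[str, np.ndarray]]:
    """Score candidate pairs for every cell; returns per-cell dense maps.

    By default all off-diagonal pairs with genomic distance <= ``band`` bins
    are scored (band defaults to the whole chromosome); alternatively an
    explicit target list of (cell_index, chrom, u, v) can be given.  With
    ``keep_observed`` the observed contacts retain probability 1.0 instead of
    being re-scored.
    """
    bin_map = masked_graphset.bin_map
    if targets is None:
        targets = []
        for ci, cg in enumerate(masked_graphset.cells):
            for chrom in cg.matrices:
                n = bin_map.chrom_bins[chrom]
                bmax = band if band is not None else n - 1
                for dist in range(1, min(bmax, n - 1) + 1):
                    for u in range(n - dist):
                        targets.append((ci, chrom, u, u + dist))
    maps: list[dict[str, np.ndarray]] = []
    for ci, cg in enumerate(masked_graphset.cells):
        maps.append({
            chrom: np.zeros((bin_map.chrom_bins[chrom],) * 2)
            for chrom in cg.matrices
        })
    edge_samples = []
    for ci, chrom, u, v in targets:
        n = bin_map.chrom_bins[chrom]
        if not (0 <= u < n and 0 <= v < n and u != v):
            raise ValueError(f"pair ({u}, {v}) outside bins of {chrom}")
        if u > v:
            u, v = v, u
        edge_samples.append(EdgeSample(ci, chrom, u, v, 0, "test"))
    scores = score_samples(edge_samples, masked_graphset, b_all, params, config,
                           batch_size=batch_size)
    for s, score in zip(edge_samples, scores):
        maps[s.cell_index][s.chrom][s.u, s.v] = score
        maps[s.cell_index][s.chrom][s.v, s.u] = score
    if keep_observed:
        for ci, cg in enumerate(masked_graphset.cells):
            for chrom, m in cg.matrices.items():
                tri = sp.triu(m, k=1).tocoo()
                maps[ci][chrom][tri.row, tri.col] = 1.0
                maps[ci][chrom][tri.col, tri.row] = 1.0
    return maps
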