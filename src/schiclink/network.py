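"""The imputation network: cell encoder, subgraph transformer, decoder, loss.

Architecture
------------
Each candidate bin pair (u, v) in cell i is scored from two information
sources:

* a *cell embedding* ``C_i`` — the cell's flattened contact map is reduced by
  PCA to ``B_i`` and passed through a two-layer MLP,
  ``C_i = W2c . max(0, W1c B_i + b1c) + b2c``;
* a *subgraph embedding* — the k-hop enclosing subgraph around (u, v) is
  encoded by a transformer variant in which the subgraph adjacency ``D``
  produces an additive attention bias
  ``E = tanh(relu(D W1e + b1e) W2e + b2e)`` (row-wise MLP),
  added to every head's pre-softmax logits
  ``A_ij = (h_i Wq)(h_j Wk)^T / sqrt(d_h) + E_ij``.
  Node states start as ``h_i^0 = x_{bin(i)} + z_{deg(i)}`` (learned bin and
  degree-centrality embeddings) and are updated with pre-LayerNorm multi-head
  attention and FFN blocks, both with residual connections.  Attention is
  fully connected within the subgraph — message passing is not restricted to
  observed edges.

The decoder is a two-layer MLP with a sigmoid head on the concatenation
``(C_i | h_u^L | h_v^L)``; the loss is binary cross-entropy.

Implementation notes
--------------------
Forward and backward passes are written directly in NumPy (no autodiff
framework): every forward helper returns a cache and has a matching backward
that propagates exact analytic gradients, verified against central finite
differences in the test suite.  All math is float64 for bit-reproducibility
of training curves on CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .sampling import SubgraphBatch

VARIANTS = ("full", "cell_only", "sub_only", "no_bias")

_NEG_INF = -1e30
_LN_EPS = 1e-5
LOSS_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network.

    ``d`` is the node/model width, ``d_c`` the cell-embedding width, ``p`` the
    PCA dimension of the cell features, ``n_layers``/``n_heads`` the
    transformer depth/heads, ``n_max`` the subgraph size cap (also the input
    width of the bias MLP), ``d_max`` the degree-embedding clip, and ``k``
    the enclosing-subgraph hop count.
    """

    n_bins_total: int
    d: int = 32
    d_c: int = 32
    p: int = 100
    n_layers: int = 2
    n_heads: int = 4
    n_max: int = 32
    d_max: int = 32
    k: int = 1
    dropout: float = 0.1
    bias_hidden: int = 32
    cell_hidden: int = 64
    dec_hidden: int = 64
    ffn_mult: int = 4
    variant: str = "full"

    def __post_init__(self):
        if self.d % self.n_heads:
            raise ValueError("d must be divisible by n_heads")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        for name in ("n_bins_total", "d", "d_c", "p", "n_layers", "n_heads", "n_max", "d_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads

    @property
    def decoder_in(self) -> int:
        return 2 * self.d if self.variant == "sub_only" else self.d_c + 2 * self.d


def ablation_variant(config: ModelConfig, variant: str) -> ModelConfig:
    """Return a config for one of the ablation variants.

    ``cell_only`` replaces the subgraph embedding by the *initial* node
    embeddings of u and v (the transformer is never run); ``sub_only`` drops
    the cell embedding from the decoder input; ``no_bias`` forces E = 0.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return replace(config, variant=variant)


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Initialize all weights; bin (x) and centrality (z) embeddings are
    standard normal, dense layers use 1/sqrt(fan_in) scaling."""
    rng = np.random.default_rng(seed)

    def dense(n_in, n_out):
        return rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))

    d, dc = config.d, config.d_c
    params: dict[str, np.ndarray] = {
        "x": rng.standard_normal((config.n_bins_total, d)),
        "z": rng.standard_normal((config.d_max + 1, d)),
        "W1e": dense(config.n_max, config.bias_hidden),
        "b1e": np.zeros(config.bias_hidden),
        "W2e": dense(config.bias_hidden, config.n_max),
        "b2e": np.zeros(config.n_max),
        "W1c": dense(config.p, config.cell_hidden),
        "b1c": np.zeros(config.cell_hidden),
        "W2c": dense(config.cell_hidden, dc),
        "b2c": np.zeros(dc),
        "W1d": dense(config.decoder_in, config.dec_hidden),
        "b1d": np.zeros(config.dec_hidden),
        "W2d": dense(config.dec_hidden, 1),
        "b2d": np.zeros(1),
        "Wp1": dense(d, d),
        "bp1": np.zeros(d),
        "Wp2": dense(d, d // 2),
        "bp2": np.zeros(d // 2),
    }
    for layer in range(config.n_layers):
        f = config.ffn_mult * d
        params.update({
            f"ln1_g{layer}": np.ones(d), f"ln1_b{layer}": np.zeros(d),
            f"Wq{layer}": dense(d, d), f"bq{layer}": np.zeros(d),
            f"Wk{layer}": dense(d, d), f"bk{layer}": np.zeros(d),
            f"Wv{layer}": dense(d, d), f"bv{layer}": np.zeros(d),
            f"Wo{layer}": dense(d, d), f"bo{layer}": np.zeros(d),
            f"ln2_g{layer}": np.ones(d), f"ln2_b{layer}": np.zeros(d),
            f"Wf1{layer}": dense(d, f), f"bf1{layer}": np.zeros(f),
            f"Wf2{layer}": dense(f, d), f"bf2{layer}": np.zeros(d),
        })
    return params


# ---------------------------------------------------------------------------
# primitive layers (forward returns cache; backward consumes it)
# ---------------------------------------------------------------------------

def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m = xhat.shape[-1]
    dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
    return dx, dg, db


def _masked_softmax_fwd(logits, key_mask):
    # key_mask: True where the key is a real node; broadcastable to logits
    masked = np.where(key_mask, logits, _NEG_INF)
    m = masked.max(axis=-1, keepdims=True)
    e = np.exp(masked - m)
    p = e / e.sum(axis=-1, keepdims=True)
    return p


def _softmax_bwd(dp, p):
    return p * (dp - (dp * p).sum(axis=-1, keepdims=True))


def _dropout_fwd(x, rate, rng):
    if rate <= 0 or rng is None:
        return x, None
    keep = rng.random(x.shape) >= rate
    scale = 1.0 / (1.0 - rate)
    return x * keep * scale, (keep, scale)


def _dropout_bwd(dy, cache):
    if cache is None:
        return dy
    keep, scale = cache
    return dy * keep * scale


# ---------------------------------------------------------------------------
# attention bias (row-wise MLP on the padded adjacency)
# ---------------------------------------------------------------------------

def attention_bias_forward(adj_padded: np.ndarray, params: dict) -> tuple[np.ndarray, tuple]:
    """E = tanh(relu(D W1e + b1e) W2e + b2e), applied row-wise to D.

    Every entry of E lies in (-1, 1); padded key positions are masked later
    in the attention itself, so their bias values are irrelevant.
    """
    pre = adj_padded @ params["W1e"] + params["b1e"]
    hid = np.maximum(pre, 0.0)
    lin = hid @ params["W2e"] + params["b2e"]
    e = np.tanh(lin)
    return e, (adj_padded, pre, hid, e)


def attention_bias_backward(de, cache, params, grads):
    adj_padded, pre, hid, e = cache
    dlin = de * (1.0 - e ** 2)
    grads["W2e"] += np.tensordot(hid, dlin, axes=([0, 1], [0, 1]))
    grads["b2e"] += dlin.sum(axis=(0, 1))
    dhid = dlin @ params["W2e"].T
    dpre = dhid * (pre > 0)
    grads["W1e"] += np.tensordot(adj_padded, dpre, axes=([0, 1], [0, 1]))
    grads["b1e"] += dpre.sum(axis=(0, 1))


# ---------------------------------------------------------------------------
# subgraph encoder (transformer with adjacency-derived attention bias)
# ---------------------------------------------------------------------------

def subgraph_encoder_forward(
    batch: SubgraphBatch,
    params: dict,
    config: ModelConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Run the transformer over a padded batch; returns (h_u, h_v, H, cache).

    Initial states are bin embedding + degree-centrality embedding; padded
    rows are zeroed and padded keys receive -inf attention logits, so they
    can never influence real nodes.
    """
    s, n = batch.mask.shape
    d, nh, dh = config.d, config.n_heads, config.head_dim
    ids = batch.node_ids
    deg = np.minimum(batch.degrees, config.d_max)
    maskf = batch.mask.astype(float)[..., None]

    h = (params["x"][ids] + params["z"][deg]) * maskf
    h0 = h.copy()

    if config.variant == "no_bias":
        e_bias, bias_cache = np.zeros((s, n, n)), None
    else:
        e_bias, bias_cache = attention_bias_forward(batch.adj.astype(float), params)

    key_mask = batch.mask[:, None, None, :]  # (S,1,1,N)
    drop_rng = rng if train else None
    layers = []
    for layer in range(config.n_layers):
        hn, ln1c = _layernorm_fwd(h, params[f"ln1_g{layer}"], params[f"ln1_b{layer}"])
        q = hn @ params[f"Wq{layer}"] + params[f"bq{layer}"]
        kk = hn @ params[f"Wk{layer}"] + params[f"bk{layer}"]
        vv = hn @ params[f"Wv{layer}"] + params[f"bv{layer}"]
        qh = q.reshape(s, n, nh, dh).transpose(0, 2, 1, 3)
        kh = kk.reshape(s, n, nh, dh).transpose(0, 2, 1, 3)
        vh = vv.reshape(s, n, nh, dh).transpose(0, 2, 1, 3)
        logits = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + e_bias[:, None, :, :]
        attn = _masked_softmax_fwd(logits, key_mask)
        ctx = attn @ vh  # (S,H,N,dh)
        ctx_m = ctx.transpose(0, 2, 1, 3).reshape(s, n, d)
        proj = ctx_m @ params[f"Wo{layer}"] + params[f"bo{layer}"]
        proj_d, do1 = _dropout_fwd(proj, config.dropout, drop_rng)
        h_mid = h + proj_d

        hn2, ln2c = _layernorm_fwd(h_mid, params[f"ln2_g{layer}"], params[f"ln2_b{layer}"])
        fpre = hn2 @ params[f"Wf1{layer}"] + params[f"bf1{layer}"]
        fh = np.maximum(fpre, 0.0)
        fout = fh @ params[f"Wf2{layer}"] + params[f"bf2{layer}"]
        fout_d, do2 = _dropout_fwd(fout, config.dropout, drop_rng)
        h = h_mid + fout_d

        layers.append(dict(ln1c=ln1c, hn=hn, qh=qh, kh=kh, vh=vh, attn=attn,
                           ctx_m=ctx_m, do1=do1, ln2c=ln2c, hn2=hn2, fpre=fpre,
                           fh=fh, do2=do2))

    rows = np.arange(s)
    h_u = h[rows, batch.u_pos]
    h_v = h[rows, batch.v_pos]
    cache = dict(batch=batch, ids=ids, deg=deg, maskf=maskf, h0=h0,
                 bias_cache=bias_cache, layers=layers, h_final=h)
    return h_u, h_v, h, cache


def subgraph_encoder_backward(dh_final, cache, params, config, grads):
    """Backprop from a gradient on the full final node-state tensor."""
    batch = cache["batch"]
    s, n = batch.mask.shape
    d, nh, dh = config.d, config.n_heads, config.head_dim
    dh_ = dh_final
    de_total = np.zeros((s, n, n))
    for layer in reversed(range(config.n_layers)):
        c = cache["layers"][layer]
        # FFN block
        dfout = _dropout_bwd(dh_, c["do2"])
        grads[f"Wf2{layer}"] += np.tensordot(c["fh"], dfout, axes=([0, 1], [0, 1]))
        grads[f"bf2{layer}"] += dfout.sum(axis=(0, 1))
        dfh = dfout @ params[f"Wf2{layer}"].T
        dfpre = dfh * (c["fpre"] > 0)
        grads[f"Wf1{layer}"] += np.tensordot(c["hn2"], dfpre, axes=([0, 1], [0, 1]))
        grads[f"bf1{layer}"] += dfpre.sum(axis=(0, 1))
        dhn2 = dfpre @ params[f"Wf1{layer}"].T
        dx, dg, db = _layernorm_bwd(dhn2, c["ln2c"])
        grads[f"ln2_g{layer}"] += dg
        grads[f"ln2_b{layer}"] += db
        dh_mid = dh_ + dx  # residual

        # attention block
        dproj = _dropout_bwd(dh_mid, c["do1"])
        grads[f"Wo{layer}"] += np.tensordot(c["ctx_m"], dproj, axes=([0, 1], [0, 1]))
        grads[f"bo{layer}"] += dproj.sum(axis=(0, 1))
        dctx_m = dproj @ params[f"Wo{layer}"].T
        dctx = dctx_m.reshape(s, n, nh, dh).transpose(0, 2, 1, 3)
        dattn = dctx @ c["vh"].transpose(0, 1, 3, 2)
        dvh = c["attn"].transpose(0, 1, 3, 2) @ dctx
        dlogits = _softmax_bwd(dattn, c["attn"])
        de_total += dlogits.sum(axis=1)
        dqh = dlogits @ c["kh"] / np.sqrt(dh)
        dkh = dlogits.transpose(0, 1, 3, 2) @ c["qh"] / np.sqrt(dh)
        dq = dqh.transpose(0, 2, 1, 3).reshape(s, n, d)
        dk = dkh.transpose(0, 2, 1, 3).reshape(s, n, d)
        dv = dvh.transpose(0, 2, 1, 3).reshape(s, n, d)
        hn = c["hn"]
        grads[f"Wq{layer}"] += np.tensordot(hn, dq, axes=([0, 1], [0, 1]))
        grads[f"bq{layer}"] += dq.sum(axis=(0, 1))
        grads[f"Wk{layer}"] += np.tensordot(hn, dk, axes=([0, 1], [0, 1]))
        grads[f"bk{layer}"] += dk.sum(axis=(0, 1))
        grads[f"Wv{layer}"] += np.tensordot(hn, dv, axes=([0, 1], [0, 1]))
        grads[f"bv{layer}"] += dv.sum(axis=(0, 1))
        dhn = dq @ params[f"Wq{layer}"].T + dk @ params[f"Wk{layer}"].T + dv @ params[f"Wv{layer}"].T
        dx1, dg1, db1 = _layernorm_bwd(dhn, c["ln1c"])
        grads[f"ln1_g{layer}"] += dg1
        grads[f"ln1_b{layer}"] += db1
        dh_ = dh_mid + dx1  # residual

    if config.variant != "no_bias" and cache["bias_cache"] is not None:
        attention_bias_backward(de_total, cache["bias_cache"], params, grads)

    dh0 = dh_ * cache["maskf"]
    mask = cache["batch"].mask
    np.add.at(grads["x"], cache["ids"][mask], dh0[mask])
    np.add.at(grads["z"], cache["deg"][mask], dh0[mask])


# ---------------------------------------------------------------------------
# cell encoder / decoder / loss
# ---------------------------------------------------------------------------

def cell_encoder_forward(b_feats: np.ndarray, params: dict) -> tuple[np.ndarray, tuple]:
    """C = W2c . max(0, W1c B + b1c) + b2c  (rows of b_feats are cells)."""
    pre = b_feats @ params["W1c"] + params["b1c"]
    hid = np.maximum(pre, 0.0)
    c = hid @ params["W2c"] + params["b2c"]
    return c, (b_feats, pre, hid)


def cell_encoder_backward(dc, cache, params, grads):
    b_feats, pre, hid = cache
    grads["W2c"] += hid.T @ dc
    grads["b2c"] += dc.sum(axis=0)
    dhid = dc @ params["W2c"].T
    dpre = dhid * (pre > 0)
    grads["W1c"] += b_feats.T @ dpre
    grads["b1c"] += dpre.sum(axis=0)
    return dpre @ params["W1c"].T


def decoder_forward(dec_in: np.ndarray, params: dict) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Two-layer MLP with sigmoid head; returns (yhat, logit, cache)."""
    pre = dec_in @ params["W1d"] + params["b1d"]
    hid = np.maximum(pre, 0.0)
    logit = (hid @ params["W2d"] + params["b2d"]).ravel()
    yhat = 1.0 / (1.0 + np.exp(-logit))
    return yhat, logit, (dec_in, pre, hid)


def decoder_backward(dlogit, cache, params, grads):
    dec_in, pre, hid = cache
    grads["W2d"] += hid.T @ dlogit[:, None]
    grads["b2d"] += dlogit.sum(keepdims=True)
    dhid = dlogit[:, None] @ params["W2d"].T
    dpre = dhid * (pre > 0)
    grads["W1d"] += dec_in.T @ dpre
    grads["b1d"] += dpre.sum(axis=0)
    return dpre @ params["W1d"].T


def bce_loss(yhat: np.ndarray, y: np.ndarray, eps: float = LOSS_EPS) -> float:
    """Summed binary cross-entropy, -sum[y log yhat + (1-y) log(1-yhat)].

    Predictions are clamped to [eps, 1-eps] for log stability.
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("yhat and y must have equal length")
    yc = np.clip(yhat, eps, 1.0 - eps)
    return float(-(y * np.log(yc) + (1.0 - y) * np.log(1.0 - yc)).sum())


# ---------------------------------------------------------------------------
# full model forward / backward
# ---------------------------------------------------------------------------

def model_forward(
    batch: SubgraphBatch,
    b_feats: np.ndarray,
    params: dict,
    config: ModelConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Score a batch of edge samples; returns (yhat, logit, cache).

    ``b_feats`` holds the PCA cell feature of each sample's cell (one row per
    sample).  The ``cell_only`` variant bypasses the transformer entirely and
    uses the initial node embeddings of u and v; ``sub_only`` drops the cell
    embedding from the decoder input.
    """
    s = batch.size
    rows = np.arange(s)
    cache: dict = {"config": config}

    if config.variant == "cell_only":
        deg = np.minimum(batch.degrees, config.d_max)
        h0 = params["x"][batch.node_ids] + params["z"][deg]
        h_u = h0[rows, batch.u_pos]
        h_v = h0[rows, batch.v_pos]
        cache["cell_only"] = (batch, deg)
    else:
        h_u, h_v, _, enc_cache = subgraph_encoder_forward(batch, params, config, train, rng)
        cache["enc"] = enc_cache

    if config.variant == "sub_only":
        dec_in = np.concatenate([h_u, h_v], axis=1)
    else:
        c_emb, cell_cache = cell_encoder_forward(b_feats, params)
        cache["cell"] = cell_cache
        dec_in = np.concatenate([c_emb, h_u, h_v], axis=1)

    yhat, logit, dec_cache = decoder_forward(dec_in, params)
    cache["dec"] = dec_cache
    cache["batch"] = batch
    return yhat, logit, cache


def model_backward(dlogit: np.ndarray, cache: dict, params: dict) -> dict[str, np.ndarray]:
    """Propagate d loss/d logit back to every parameter; returns grads."""
    config: ModelConfig = cache["config"]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    ddec_in = decoder_backward(dlogit, cache["dec"], params, grads)

    d, dc = config.d, config.d_c
    if config.variant == "sub_only":
        dhu, dhv = ddec_in[:, :d], ddec_in[:, d:]
    else:
        dcell = ddec_in[:, :dc]
        dhu = ddec_in[:, dc:dc + d]
        dhv = ddec_in[:, dc + d:]
        cell_encoder_backward(dcell, cache["cell"], params, grads)

    batch: SubgraphBatch = cache["batch"]
    rows = np.arange(batch.size)
    if config.variant == "cell_only":
        _, deg = cache["cell_only"]
        dh0 = np.zeros((batch.size, batch.mask.shape[1], d))
        np.add.at(dh0, (rows, batch.u_pos), dhu)
        np.add.at(dh0, (rows, batch.v_pos), dhv)
        mask = batch.mask
        np.add.at(grads["x"], batch.node_ids[mask], dh0[mask])
        np.add.at(grads["z"], deg[mask], dh0[mask])
    else:
        dh_final = np.zeros_like(cache["enc"]["h_final"])
        np.add.at(dh_final, (rows, batch.u_pos), dhu)
        np.add.at(dh_final, (rows, batch.v_pos), dhv)
        subgraph_encoder_backward(dh_final, cache["enc"], params, config, grads)
    return grads


def loss_and_grads(
    batch: SubgraphBatch,
    b_feats: np.ndarray,
    y: np.ndarray,
    params: dict,
    config: ModelConfig,
    train: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Mean BCE over the batch and its exact gradients (logit formulation)."""
    yhat, logit, cache = model_forward(batch, b_feats, params, config, train, rng)
    y = np.asarray(y, dtype=float)
    # numerically stable BCE-with-logits, averaged over the batch
    loss = float(np.mean(np.maximum(logit, 0) - logit * y + np.log1p(np.exp(-np.abs(logit)))))
    if np.isnan(loss):
        raise FloatingPointError("NaN loss in forward pass")
    dlogit = (yhat - y) / len(y)
    grads = model_backward(dlogit, cache, params)
    return loss, grads, yhat


class Adam:
    """Adam with (torch-style) L2 weight decay added to the gradients."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=1e-5):
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k] + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def save_checkpoint(path: str | Path, params: dict, config: ModelConfig,
                    metadata: dict | None = None) -> None:
    """Serialize config + parameters (+ run metadata) to a single .npz."""
    header = json.dumps({"config": asdict(config), "metadata": metadata or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **params)


def load_checkpoint(path: str | Path) -> tuple[dict, ModelConfig, dict]:
    """Inverse of :func:`save_checkpoint`."""
    with np.load(path) as f:
        header = json.loads(bytes(f["__header__"]).decode())
        params = {k: f[k].copy() for k in f.files if k != "__header__"}
    return params, ModelConfig(**header["config"]), header["metadata"]
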