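"""Link-prediction sampling: edge splits, negatives and enclosing subgraphs.

Imputation is cast as link prediction: per cell, 10% of the observed contacts
are hidden and become test positives, negatives are drawn from never-observed
bin pairs (4x the test positives; 5x the train positives for training), and
every candidate pair is encoded through the k-hop enclosing subgraph around
its two endpoints, extracted from the masked graph so test edges never leak.

Negative pairs are restricted to the genomic-distance band actually covered
by the cell's observed contacts; without that restriction negatives are
trivially separable by distance alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io import GraphSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeSample:
    """One supervised unit: (cell, chromosome, bin pair, label, split)."""

    cell_index: int
    chrom: str
    u: int
    v: int
    label: int
    split: str  # "train" or "test"

    def __post_init__(self):
        if not self.u < self.v:
            raise ValueError("edge sample requires canonical u < v")


@dataclass
class EnclosingSubgraph:
    """The k-hop neighborhood of a candidate edge (u, v), induced and masked.

    ``nodes`` holds genome-wide bin ids (chromosome offset applied); ``adj``
    is the induced binary adjacency with the candidate edge itself removed —
    train positives would otherwise carry their own label.  ``degrees`` are
    within-subgraph degrees computed on the masked adjacency.
    """

    nodes: np.ndarray  # (n',) global bin ids
    adj: np.ndarray  # (n', n') uint8, symmetric, zero diagonal
    u_idx: int
    v_idx: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def degrees(self) -> np.ndarray:
        return self.adj.sum(axis=1).astype(np.int64)


@dataclass
class SubgraphBatch:
    """Zero-padded batch of enclosing subgraphs ready for the encoder."""

    adj: np.ndarray  # (S, N, N) float32
    node_ids: np.ndarray  # (S, N) int64, global bin ids, 0 at padding
    degrees: np.ndarray  # (S, N) int64, 0 at padding
    mask: np.ndarray  # (S, N) bool, True at real nodes
    u_pos: np.ndarray  # (S,) int64
    v_pos: np.ndarray  # (S,) int64

    @property
    def size(self) -> int:
        return self.adj.shape[0]


def _band_nonedges(adj: sp.csr_matrix, d_max: int) -> tuple[np.ndarray, np.ndarray]:
    """All non-edge pairs (u, v), u < v, with genomic distance 1..d_max."""
    n = adj.shape[0]
    us, vs = [], []
    for d in range(1, min(d_max, n - 1) + 1):
        u = np.arange(n - d)
        us.append(u)
        vs.append(u + d)
    u_all = np.concatenate(us) if us else np.zeros(0, dtype=int)
    v_all = np.concatenate(vs) if vs else np.zeros(0, dtype=int)
    present = np.asarray(adj[u_all, v_all]).ravel() != 0
    return u_all[~present], v_all[~present]


def split_edges(
    graphset: GraphSet,
    test_fraction: float = 0.10,
    test_neg_ratio: int = 4,
    train_neg_ratio: int = 5,
    seed: int = 0,
    min_edges: int = 10,
) -> tuple[list[EdgeSample], list[EdgeSample], GraphSet]:
    """Build train/test edge samples and the masked graphset.

    Per cell and chromosome: ``test_fraction`` of the observed (off-diagonal)
    edges are removed and labelled test positives; the remainder are train
    positives; negatives are uniform over distance-banded non-edges at
    ``test_neg_ratio`` x / ``train_neg_ratio`` x the respective positives.
    The returned graphset has the test positives deleted — it is the graph
    subgraph extraction must see.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    masked = graphset.copy()
    train: list[EdgeSample] = []
    test: list[EdgeSample] = []
    for ci, cg in enumerate(graphset.cells):
        for chrom, adj in cg.matrices.items():
            tri = sp.triu(adj, k=1).tocoo()
            n_edges = tri.nnz
            if n_edges < min_edges:
                logger.warning(
                    "cell %s %s: only %d edges (< %d) — chromosome skipped",
                    cg.cell_id, chrom, n_edges, min_edges,
                )
                continue
            order = rng.permutation(n_edges)
            eu, ev = tri.row[order], tri.col[order]
            n_test = int(test_fraction * n_edges)
            n_train = n_edges - n_test
            d_max = int(np.max(ev - eu))

            nu, nv = _band_nonedges(adj, d_max)
            k_test_neg = test_neg_ratio * n_test
            if len(nu) < k_test_neg:
                raise ValueError(
                    f"cell {cg.cell_id} {chrom}: {len(nu)} candidate non-edges "
                    f"cannot satisfy {k_test_neg} test negatives"
                )
            # test negatives take strict priority at the full ratio (the
            # evaluation protocol); in dense graphs the leftover pool may not
            # cover the full train-negative ratio, so cap with a warning.
            n_train_neg = min(train_neg_ratio * n_train, len(nu) - k_test_neg)
            if n_train_neg < train_neg_ratio * n_train:
                logger.warning(
                    "cell %s %s: non-edge pool supports only %d of %d train negatives",
                    cg.cell_id, chrom, n_train_neg, train_neg_ratio * n_train,
                )
            n_neg = k_test_neg + n_train_neg
            pick = rng.choice(len(nu), size=n_neg, replace=False)
            neg_u, neg_v = nu[pick], nv[pick]
            for j in range(n_test):
                test.append(EdgeSample(ci, chrom, int(eu[j]), int(ev[j]), 1, "test"))
            for j in range(n_test, n_edges):
                train.append(EdgeSample(ci, chrom, int(eu[j]), int(ev[j]), 1, "train"))
            for j in range(k_test_neg):
                test.append(EdgeSample(ci, chrom, int(neg_u[j]), int(neg_v[j]), 0, "test"))
            for j in range(k_test_neg, n_neg):
                train.append(EdgeSample(ci, chrom, int(neg_u[j]), int(neg_v[j]), 0, "train"))

            # delete test positives from the masked graph (both triangles)
            m = masked.cells[ci].matrices[chrom].tolil()
            for j in range(n_test):
                m[eu[j], ev[j]] = 0
                m[ev[j], eu[j]] = 0
            mm = m.tocsr()
            mm.eliminate_zeros()
            masked.cells[ci].matrices[chrom] = mm
    return train, test, masked


def extract_enclosing_subgraph(
    adj: sp.csr_matrix,
    u: int,
    v: int,
    k: int = 1,
    n_max: int = 64,
    rng: np.random.Generator | None = None,
    global_offset: int = 0,
) -> EnclosingSubgraph:
    """Extract the k-hop enclosing subgraph of candidate edge (u, v).

    The node set is every vertex within graph distance <= k of u or of v on
    the (masked) cell graph, always including u and v themselves even when
    isolated.  If the set exceeds ``n_max``, u and v are kept and the rest is
    down-sampled uniformly.  The induced adjacency is binarized and the
    candidate edge itself is removed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = adj.shape[0]
    if not (0 <= u < n and 0 <= v < n and u != v):
        raise ValueError("u, v must be distinct valid bins")
    indptr, indices = adj.indptr, adj.indices

    visited = {u, v}
    frontier = [u, v]
    for _ in range(k):
        nxt = []
        for node in frontier:
            for nb in indices[indptr[node]:indptr[node + 1]]:
                if nb not in visited:
                    visited.add(int(nb))
                    nxt.append(int(nb))
        frontier = nxt
        if not frontier:
            break

    others = sorted(visited - {u, v})
    if 2 + len(others) > n_max:
        if rng is None:
            rng = np.random.default_rng(0)
        others = sorted(rng.choice(others, size=n_max - 2, replace=False).tolist())
    nodes = np.array(sorted([u, v] + others), dtype=np.int64)
    sub = adj[np.ix_(nodes, nodes)].toarray()
    d = (sub != 0).astype(np.uint8)
    np.fill_diagonal(d, 0)
    u_idx = int(np.searchsorted(nodes, u))
    v_idx = int(np.searchsorted(nodes, v))
    d[u_idx, v_idx] = 0
    d[v_idx, u_idx] = 0
    return EnclosingSubgraph(nodes + global_offset, d, u_idx, v_idx)


def batch_subgraphs(subgraphs: list[EnclosingSubgraph], n_max: int = 64) -> SubgraphBatch:
    """Zero-pad subgraphs to a common size; unpadding recovers inputs exactly."""
    s = len(subgraphs)
    adj = np.zeros((s, n_max, n_max), dtype=np.float32)
    node_ids = np.zeros((s, n_max), dtype=np.int64)
    degrees = np.zeros((s, n_max), dtype=np.int64)
    mask = np.zeros((s, n_max), dtype=bool)
    u_pos = np.zeros(s, dtype=np.int64)
    v_pos = np.zeros(s, dtype=np.int64)
    for i, g in enumerate(subgraphs):
        np_ = g.n_nodes
        if np_ > n_max:
            raise RuntimeError(f"subgraph with {np_} nodes exceeds n_max={n_max}")
        adj[i, :np_, :np_] = g.adj
        node_ids[i, :np_] = g.nodes
        degrees[i, :np_] = g.degrees
        mask[i, :np_] = True
        u_pos[i], v_pos[i] = g.u_idx, g.v_idx
    return SubgraphBatch(adj, node_ids, degrees, mask, u_pos, v_pos)


def unbatch_subgraphs(batch: SubgraphBatch) -> list[EnclosingSubgraph]:
    """Invert :func:`batch_subgraphs` (round-trip identity on real nodes)."""
    out = []
    for i in range(batch.size):
        np_ = int(batch.mask[i].sum())
        out.append(
            EnclosingSubgraph(
                batch.node_ids[i, :np_].copy(),
                batch.adj[i, :np_, :np_].astype(np.uint8),
                int(batch.u_pos[i]),
                int(batch.v_pos[i]),
            )
        )
    return out


def export_split(
    train: list[EdgeSample],
    test: list[EdgeSample],
    graphset: GraphSet,
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Write the split as a TSV manifest plus a run-metadata JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\tchrom\tu\tv\tlabel\tsplit\n")
        for s in list(train) + list(test):
            cell_id = graphset.cells[s.cell_index].cell_id
            fh.write(f"{cell_id}\t{s.chrom}\t{s.u}\t{s.v}\t{s.label}\t{s.split}\n")
    meta = {"n_train": len(train), "n_test": len(test), "seed": seed}
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
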