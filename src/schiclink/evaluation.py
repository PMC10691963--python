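"""Evaluation metrics: imputation (AUC/AUPR) and clustering (ARI, circular ROC).

AUC is the ties-averaged rank statistic (Mann-Whitney); AUPR is the step-wise
precision-recall integral without linear interpolation — the conservative
convention, since interpolating between PR points is optimistic.  Clustering
of discrete cell types is scored by K-means + adjusted Rand index; continuous
cyclic states (e.g. cell-cycle phase) are scored by a circular ROC average.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, average_precision_score, roc_auc_score


def auc_aupr(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, AUPR) of binary labels under continuous scores.

    Raises on single-class input — both metrics are undefined there.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


def kmeans_ari(
    embeddings: np.ndarray,
    true_labels: list | np.ndarray,
    n_clusters: int | None = None,
    n_init: int = 20,
    seed: int = 0,
) -> float:
    """K-means on cell embeddings, scored against true labels by ARI.

    ``n_clusters`` defaults to the number of distinct true labels; the best
    of ``n_init`` seeded restarts (by inertia) is kept.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    true_labels = np.asarray(true_labels)
    k = n_clusters if n_clusters is not None else len(np.unique(true_labels))
    if embeddings.shape[0] < k:
        raise ValueError(f"{embeddings.shape[0]} cells cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    pred = km.fit_predict(embeddings)
    return float(adjusted_rand_score(true_labels, pred))


def acroc(
    embeddings: np.ndarray,
    phase_labels: list | np.ndarray,
    phase_order: list | None = None,
) -> float:
    """Average circular ROC for cyclic cell states.

    Cells are projected to 2D by PCA and assigned an angle around the
    centroid.  For each phase, a one-vs-rest AUC is computed with score equal
    to the negative circular distance from that phase's circular-mean angle;
    the metric is the mean over phases.  Because circular distances are
    invariant to rotating or reflecting all angles, the score does not depend
    on the orientation of the embedding.  Contiguous phase arcs in cycle
    order give 1.0; random labels give ~0.5.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    phase_labels = np.asarray(phase_labels)
    phases = list(phase_order) if phase_order is not None else list(np.unique(phase_labels))
    if len(phases) < 2:
        raise ValueError("at least 2 phases are required")
    coords = PCA(n_components=2, svd_solver="full").fit_transform(embeddings)
    coords = coords - coords.mean(axis=0)
    theta = np.arctan2(coords[:, 1], coords[:, 0])
    aucs = []
    for phase in phases:
        is_phase = phase_labels == phase
        if not is_phase.any():
            continue
        t = theta[is_phase]
        center = np.arctan2(np.sin(t).mean(), np.cos(t).mean())
        circ_dist = np.abs(np.angle(np.exp(1j * (theta - center))))
        aucs.append(roc_auc_score(is_phase.astype(int), -circ_dist))
    return float(np.mean(aucs))


def export_embeddings(
    embeddings: np.ndarray,
    cell_ids: list[str],
    path: str | Path,
    labels: list | None = None,
    projection_2d: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Write cell embeddings as a TSV (id, label, dim_0..dim_{d-1}[, x, y]).

    The optional 2D projection uses seeded PCA (deterministic across runs).
    """
    embeddings = np.asarray(embeddings, dtype=float)
    df = pd.DataFrame(embeddings, columns=[f"dim_{j}" for j in range(embeddings.shape[1])])
    df.insert(0, "cell_id", cell_ids)
    df.insert(1, "label", labels if labels is not None else [""] * len(cell_ids))
    if projection_2d:
        xy = PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(embeddings)
        df["x"] = xy[:, 0]
        df["y"] = xy[:, 1]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df
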