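"""Per-cell feature vectors: flattened contact maps reduced by PCA.

The cell encoder consumes a low-dimensional summary ``B_i`` of each cell's
contact map: the upper triangles of its per-chromosome matrices are flattened,
concatenated genome-wide, centered and projected onto the top principal
components.  The fitted projection is kept so unseen cells can be embedded
consistently.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .io import GraphSet

logger = logging.getLogger(__name__)


@dataclass
class CellFeatureProjection:
    """Fitted PCA plus a single global scale, reusable for unseen cells.

    One scalar rescales all components identically, so the relative variance
    structure (which carries the cell-type signal in the leading components)
    is preserved while the absolute scale is tamed for the encoder.
    """

    pca: PCA
    scale: float

    def transform(self, flat: np.ndarray) -> np.ndarray:
        return self.pca.transform(flat) / self.scale


def flatten_cells(graphset: GraphSet) -> np.ndarray:
    """Stack each cell's upper-triangle contact entries into one row vector."""
    chroms = list(graphset.bin_map.chrom_bins)
    rows = []
    for cg in graphset.cells:
        parts = []
        for chrom in chroms:
            n = graphset.bin_map.chrom_bins[chrom]
            iu, ju = np.triu_indices(n, k=0)
            m = cg.matrices.get(chrom)
            if m is None:
                parts.append(np.zeros(len(iu)))
            else:
                parts.append(np.asarray(m[iu, ju]).ravel().astype(float))
        rows.append(np.concatenate(parts))
    return np.vstack(rows)


def pca_cell_features(graphset: GraphSet, p: int = 100) -> tuple[np.ndarray, CellFeatureProjection]:
    """PCA-reduce the flattened contact vectors; returns (B, fitted projection).

    ``p`` is truncated to m - 1 (the maximum rank of centered data over m
    cells) with a warning.  Components are variance-ordered, so the projected
    per-component variance is non-increasing.  The scores are divided by one
    global factor (the leading component's standard deviation): raw contact
    counts give projections with scales of tens to hundreds that would
    saturate the downstream encoder, while per-component whitening would
    erase the variance ordering that separates cell populations.
    """
    m = graphset.n_cells
    if m < 2:
        raise ValueError("PCA cell features require at least 2 cells")
    flat = flatten_cells(graphset)
    p_eff = min(p, m - 1, flat.shape[1])
    if p_eff < p:
        logger.warning("pca_cell_features: p truncated from %d to %d", p, p_eff)
    pca = PCA(n_components=p_eff, svd_solver="full")
    scores = pca.fit_transform(flat)
    scale = float(scores[:, 0].std())
    if scale == 0:
        scale = 1.0
    proj = CellFeatureProjection(pca, scale)
    return scores / scale, proj
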