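"""3D-genome structure analyses: compartments and TAD-boundary insulation.

A/B compartments: single-cell maps are merged into a pseudo-bulk matrix M,
each entry is divided by the average contact level at its genomic distance
(the expected decay), and the Pearson correlation matrix of the normalized
map exposes the compartment checkerboard.

TAD boundaries: the insulation score at position x with window w is the ratio
of contacts crossing x (between the w bins on either side) to all contacts in
the (2w+1)-bin square centered on x.  Minima of the score mark boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GraphSet


@dataclass
class CompartmentMaps:
    """Pseudo-bulk matrix, its distance normalization, and the Pearson map."""

    pseudo_bulk: np.ndarray
    normalized: np.ndarray  # NaN where the expected decay is zero
    pearson: np.ndarray
    chromosome: str
    resolution: int


@dataclass
class InsulationProfile:
    """Per-bin insulation scores; NaN marks undefined positions (margins or
    empty windows)."""

    scores: np.ndarray
    window: int


def _cell_maps(source: GraphSet | list[dict[str, np.ndarray]]) -> list[dict[str, np.ndarray]]:
    if isinstance(source, GraphSet):
        return [
            {chrom: m.toarray().astype(float) for chrom, m in cg.matrices.items()}
            for cg in source.cells
        ]
    return source


def pseudo_bulk(source: GraphSet | list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Elementwise sum of single-cell maps per chromosome."""
    maps = _cell_maps(source)
    if not maps:
        raise ValueError("pseudo_bulk requires at least one cell")
    shapes = {chrom: m.shape for chrom, m in maps[0].items()}
    out = {chrom: np.zeros(shape) for chrom, shape in shapes.items()}
    for cell in maps:
        if {c: m.shape for c, m in cell.items()} != shapes:
            raise ValueError("cells do not share one bin map")
        for chrom, m in cell.items():
            out[chrom] += m
    return out


def expected_by_distance(matrices: dict[str, np.ndarray] | np.ndarray) -> np.ndarray:
    """Average contact level at each genomic distance, zeros included.

    With several chromosomes the per-distance means are pooled by entry count
    so every (i, j) with |i - j| = d contributes equally genome-wide.
    """
    if isinstance(matrices, np.ndarray):
        matrices = {"": matrices}
    d_max = max(m.shape[0] for m in matrices.values()) - 1
    sums = np.zeros(d_max + 1)
    counts = np.zeros(d_max + 1)
    for m in matrices.values():
        n = m.shape[0]
        for d in range(n):
            diag = np.diagonal(m, offset=d)
            sums[d] += diag.sum()
            counts[d] += len(diag)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def distance_normalize(m: np.ndarray, expected: np.ndarray | None = None) -> np.ndarray:
    """Divide each entry by the average contact level at its distance.

    Entries whose expected level is zero are undefined (NaN) and excluded
    from downstream correlation.  Invariant to global scaling of M.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("M must be square")
    if expected is None:
        expected = expected_by_distance(m)
    n = m.shape[0]
    i, j = np.indices((n, n))
    exp_mat = expected[np.abs(i - j)]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(exp_mat > 0, m / exp_mat, np.nan)
    return out


def pearson_map(m_star: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of the rows of M* (NaNs excluded pairwise).

    Each pair of rows is correlated over the columns where both are defined
    (pairwise-complete observations).  The diagonal is 1 by convention; pairs
    with fewer than 2 jointly defined entries or a constant row are set to 0.
    """
    m_star = np.asarray(m_star, dtype=float)
    n = m_star.shape[0]
    valid = ~np.isnan(m_star)
    if valid.all():
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.corrcoef(m_star)
        out = np.nan_to_num(out, nan=0.0)
        np.fill_diagonal(out, 1.0)
        return np.clip(out, -1.0, 1.0)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = valid[i] & valid[j]
            if common.sum() < 2:
                continue
            xi, xj = m_star[i, common], m_star[j, common]
            sx, sy = xi.std(), xj.std()
            if sx == 0 or sy == 0:
                continue
            out[i, j] = out[j, i] = ((xi - xi.mean()) * (xj - xj.mean())).mean() / (sx * sy)
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)


def compartment_maps(
    source: GraphSet | list[dict[str, np.ndarray]],
    chromosome: str,
    resolution: int | None = None,
) -> CompartmentMaps:
    """Pseudo-bulk -> distance normalization -> Pearson map for one chromosome."""
    bulk = pseudo_bulk(source)[chromosome]
    m_star = distance_normalize(bulk)
    c = pearson_map(m_star)
    if resolution is None:
        resolution = source.bin_map.resolution if isinstance(source, GraphSet) else 0
    return CompartmentMaps(bulk, m_star, c, chromosome, resolution)


def insulation_scores(m: np.ndarray, w: int) -> InsulationProfile:
    """Insulation score profile of a contact map.

    s(x) = sum of contacts between the w bins left of x and the w bins right
    of x, divided by all contacts in the (2w+1)-bin square centered at x
    (both triangles plus the diagonal).  Undefined (NaN) within w bins of the
    matrix edge or where the denominator is zero.  Low scores mean strong
    insulation, i.e. a likely domain boundary.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if w < 1:
        raise ValueError("window must be >= 1")
    if n <= 2 * w:
        raise ValueError(f"matrix of size {n} too small for window {w}")
    scores = np.full(n, np.nan)
    for x in range(w, n - w):
        num = m[x - w:x, x + 1:x + w + 1].sum()
        den = m[x - w:x + w + 1, x - w:x + w + 1].sum()
        if den > 0:
            scores[x] = num / den
    return InsulationProfile(scores, w)


def insulation_matrix(
    source: GraphSet | list[dict[str, np.ndarray]],
    chromosome: str,
    w: int,
) -> np.ndarray:
    """Per-cell insulation profiles stacked into a (cells x positions) matrix."""
    maps = _cell_maps(source)
    return np.vstack([insulation_scores(cell[chromosome], w).scores for cell in maps])


def call_boundaries(
    profile: InsulationProfile,
    quantile: float = 0.1,
    min_separation: int = 3,
) -> np.ndarray:
    """Boundary positions: local minima of the score below a quantile cutoff.

    Minima closer than ``min_separation`` bins keep only the deepest one.
    """
    s = profile.scores
    defined = ~np.isnan(s)
    cutoff = np.nanquantile(s, quantile)
    cands = []
    for x in range(1, len(s) - 1):
        if not (defined[x] and s[x] <= cutoff):
            continue
        left = s[x - 1] if defined[x - 1] else np.inf
        right = s[x + 1] if defined[x + 1] else np.inf
        if s[x] <= left and s[x] <= right:
            cands.append(x)
    cands.sort(key=lambda x: s[x])
    picked: list[int] = []
    for x in cands:
        if all(abs(x - y) >= min_separation for y in picked):
            picked.append(x)
    return np.array(sorted(picked), dtype=int)
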