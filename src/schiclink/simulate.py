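"""Synthetic single-cell Hi-C data with controllable planted structure.

Real scHi-C maps are extremely sparse multinomial samples from an underlying
per-cell contact-probability surface.  The generator here builds that surface
explicitly — a genomic-distance power-law decay modulated by planted
cell-type blocks, an A/B compartment checkerboard and TAD blocks — then draws
a fixed number of reads per cell with replacement.  Because the true surface
is returned alongside the sample, imputation accuracy can be scored against
ground truth, which is impossible with real data.

Also implemented: the conversion of multiplexed 3D genome-imaging data
(per-cell pairwise spatial-distance maps) into pseudo scHi-C contact maps by
sampling reads proportionally to inverse spatial distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import BinMap, CellGraph, GraphSet

Block = tuple[tuple[int, int], tuple[int, int]]  # ((row_lo, row_hi), (col_lo, col_hi)), half-open


@dataclass
class CellTypeSpec:
    """A discrete cell type: planted contact blocks enriched by `contrast`."""

    name: str
    blocks: list[Block]
    contrast: float = 8.0
    weight: float = 1.0


@dataclass
class CompartmentSpec:
    """Alternating A/B segments; same-compartment contacts enriched by `contrast`."""

    segment_length: int
    contrast: float = 3.0


@dataclass
class TADSpec:
    """Contiguous domains delimited by `boundaries`; within-domain contacts enriched."""

    boundaries: list[int]
    contrast: float = 4.0


@dataclass
class SimConfig:
    """Configuration of the synthetic graphset generator.

    Defaults describe a small but realistic single-chromosome population:
    40 cells, 150 bins at 1 Mb, 3000 reads per cell, distance-decay exponent
    alpha = 1 (the classic fractal-globule scaling of contact probability
    with genomic distance).
    """

    n_cells: int = 40
    n_bins: int = 150
    n_chromosomes: int = 1
    reads_per_cell: int = 3000
    resolution: int = 1_000_000
    alpha: float = 1.0
    cell_types: list[CellTypeSpec] | None = None
    cyclic: bool = False
    n_phases: int = 4
    compartments: CompartmentSpec | None = None
    tads: TADSpec | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cells", "n_bins", "n_chromosomes", "reads_per_cell", "resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for spec in self.cell_types or []:
            if spec.contrast < 1:
                raise ValueError("cell-type contrast must be >= 1")
        if self.compartments is not None and self.compartments.contrast < 1:
            raise ValueError("compartment contrast must be >= 1")
        if self.tads is not None and self.tads.contrast < 1:
            raise ValueError("TAD contrast must be >= 1")


def domain_blocks(n_bins: int, width: int, phase: int = 0) -> list[Block]:
    """Square on-diagonal domain blocks tiling [0, n_bins), offset by `phase`."""
    blocks = []
    b = -phase if phase else 0
    while b < n_bins:
        lo, hi = max(b, 0), min(b + width, n_bins)
        if hi - lo >= 2:
            blocks.append(((lo, hi), (lo, hi)))
        b += width
    return blocks


def two_type_config(domain_width: int = 25, contrast: float = 8.0, **overrides) -> SimConfig:
    """A ready-made two-cell-type benchmark configuration.

    Both types share the distance-decay background but carry contact domains
    (TAD-like on-diagonal blocks) shifted by half a domain width relative to
    each other — the kind of type-specific domain architecture seen between
    cell lines.  A pair at a given genomic distance can thus be enriched in
    one type and depleted in the other, so imputation genuinely needs the
    cell's identity and its local contact structure, not distance alone; the
    flattened maps also cluster cleanly by type.
    """
    overrides.setdefault("alpha", 1.5)
    cfg = SimConfig(**overrides)
    n = cfg.n_bins
    type_a = CellTypeSpec("typeA", domain_blocks(n, domain_width, 0), contrast)
    type_b = CellTypeSpec("typeB", domain_blocks(n, domain_width, domain_width // 2), contrast)
    cfg.cell_types = [type_a, type_b]
    return cfg


def _block_mask(n: int, blocks: list[Block]) -> np.ndarray:
    mask = np.zeros((n, n), dtype=bool)
    for (r0, r1), (c0, c1) in blocks:
        mask[r0:r1, c0:c1] = True
        mask[c0:c1, r0:r1] = True
    return mask


def _base_surface(config: SimConfig) -> np.ndarray:
    n = config.n_bins
    i, j = np.indices((n, n))
    p = (np.abs(i - j) + 1.0) ** (-config.alpha)
    np.fill_diagonal(p, 0.0)  # self-contacts are artifacts, never sampled
    if config.compartments is not None:
        seg = config.compartments.segment_length
        comp = (np.arange(n) // seg) % 2
        same = comp[:, None] == comp[None, :]
        p = p * np.where(same, config.compartments.contrast, 1.0)
    if config.tads is not None:
        bounds = [0] + sorted(config.tads.boundaries) + [n]
        domain = np.zeros(n, dtype=int)
        for d, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            domain[lo:hi] = d
        within = domain[:, None] == domain[None, :]
        p = p * np.where(within, config.tads.contrast, 1.0)
    np.fill_diagonal(p, 0.0)
    return p


def _sample_matrix(p_upper: np.ndarray, n_reads: int, rng: np.random.Generator) -> sp.csr_matrix:
    """Multinomial draw of n_reads contacts (with replacement) over the upper triangle."""
    n = p_upper.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    probs = p_upper[iu, ju]
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate configuration: zero total contact probability")
    counts = rng.multinomial(n_reads, probs / total)
    nz = counts > 0
    r, c, d = iu[nz], ju[nz], counts[nz]
    m = sp.coo_matrix(
        (np.concatenate([d, d]), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n),
    )
    return m.tocsr()


def simulate_graphset(config: SimConfig) -> tuple[GraphSet, list[dict[str, np.ndarray]]]:
    """Simulate a graphset; returns (graphset, per-cell true probability maps).

    Each cell's contact surface is the distance-decay background multiplied by
    its planted structure, normalized over the upper triangle; reads are drawn
    with replacement so counts accumulate.  The returned truth maps are the
    normalized symmetric probability matrices, the target an ideal imputation
    would recover.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_bins
    chroms = [f"chr{k + 1}" for k in range(config.n_chromosomes)]
    bin_map = BinMap(config.resolution, {c: n * config.resolution for c in chroms})
    base = _base_surface(config)

    types = config.cell_types or []
    if types:
        weights = np.array([t.weight for t in types], dtype=float)
        weights = weights / weights.sum()
        assignments = rng.choice(len(types), size=config.n_cells, p=weights)
    else:
        assignments = np.full(config.n_cells, -1)
    phases = rng.uniform(0, 2 * np.pi, size=config.n_cells) if config.cyclic else None

    type_masks = [_block_mask(n, t.blocks) for t in types]
    cells, truths = [], []
    for ci in range(config.n_cells):
        p = base.copy()
        if config.cyclic and types:
            # each type's blocks peak at a preferred phase around the cycle
            label_angle = phases[ci]
            for t_idx, t in enumerate(types):
                pref = 2 * np.pi * t_idx / len(types)
                w = (1 + np.cos(label_angle - pref)) / 2
                eff = 1 + (t.contrast - 1) * w
                p = p * np.where(type_masks[t_idx], eff, 1.0)
            phase_bin = int(label_angle / (2 * np.pi) * config.n_phases) % config.n_phases
            label = f"phase{phase_bin}"
        elif types:
            t_idx = assignments[ci]
            p = p * np.where(type_masks[t_idx], types[t_idx].contrast, 1.0)
            label = types[t_idx].name
        else:
            label = None
        np.fill_diagonal(p, 0.0)
        iu, ju = np.triu_indices(n, k=1)
        total = p[iu, ju].sum()
        if total <= 0:
            raise ValueError("degenerate configuration: zero total contact probability")
        p_norm = p / (2 * total)  # symmetric matrix summing to 1 over off-diagonal entries

        mats, truth = {}, {}
        total_reads = 0
        for chrom in chroms:
            m = _sample_matrix(p, config.reads_per_cell, rng)
            mats[chrom] = m
            truth[chrom] = p_norm
            total_reads += config.reads_per_cell
        cells.append(CellGraph(f"cell{ci}", mats, total_reads=total_reads, label=label))
        truths.append(truth)
    return GraphSet(bin_map, cells), truths


def phase_order(config: SimConfig) -> list[str]:
    """Cycle-ordered phase label names for a cyclic simulation."""
    return [f"phase{k}" for k in range(config.n_phases)]


def storm_to_schic(
    distance_maps: np.ndarray,
    reads_per_cell: int = 200,
    resolution: int = 30_000,
    chrom: str = "chr21",
    seed: int = 0,
) -> GraphSet:
    """Convert per-cell pairwise spatial-distance maps into pseudo scHi-C.

    The probability map of a cell is the elementwise reciprocal of its
    spatial-distance map (diagonal excluded; NaN distances treated as missing,
    i.e. zero probability), normalized over the upper triangle.  Each cell
    receives exactly ``reads_per_cell`` contacts drawn with replacement,
    proportionally to the probability-map entries.
    """
    distance_maps = np.asarray(distance_maps, dtype=float)
    if distance_maps.ndim != 3 or distance_maps.shape[1] != distance_maps.shape[2]:
        raise ValueError("distance_maps must have shape (n_cells, n, n)")
    m_cells, n, _ = distance_maps.shape
    iu, ju = np.triu_indices(n, k=1)
    offdiag = distance_maps[:, iu, ju]
    if np.any(offdiag[~np.isnan(offdiag)] <= 0):
        raise ValueError("off-diagonal spatial distances must be positive")
    rng = np.random.default_rng(seed)
    bin_map = BinMap(resolution, {chrom: n * resolution})
    cells = []
    for ci in range(m_cells):
        with np.errstate(divide="ignore", invalid="ignore"):
            prob = 1.0 / distance_maps[ci]
        prob[~np.isfinite(prob)] = 0.0
        np.fill_diagonal(prob, 0.0)
        mat = _sample_matrix(prob, reads_per_cell, rng)
        cells.append(CellGraph(f"cell{ci}", {chrom: mat}, total_reads=reads_per_cell))
    return GraphSet(bin_map, cells)


def downsample_edges(graphset: GraphSet, dropout_ratio: float, seed: int = 0) -> GraphSet:
    """Uniformly remove a fraction of each cell's nonzero entries (count mass too).

    Emulates additional technical sparsity ("dropout") for robustness studies.
    Exactly floor(ratio * n_entries) upper-triangle entries per cell and
    chromosome are removed.
    """
    if not 0 <= dropout_ratio < 1:
        raise ValueError("dropout_ratio must be in [0, 1)")
    if dropout_ratio == 0:
        return graphset.copy()
    rng = np.random.default_rng(seed)
    out_cells = []
    for cg in graphset.cells:
        mats = {}
        removed_mass = 0
        for chrom, m in cg.matrices.items():
            tri = sp.triu(m, k=0).tocoo()
            n_entries = tri.nnz
            n_drop = int(dropout_ratio * n_entries)
            keep = np.ones(n_entries, dtype=bool)
            if n_drop > 0:
                drop_idx = rng.choice(n_entries, size=n_drop, replace=False)
                keep[drop_idx] = False
                removed_mass += int(tri.data[~keep].sum())
            r, c, d = tri.row[keep], tri.col[keep], tri.data[keep]
            off = r != c
            rows = np.concatenate([r, c[off]])
            cols = np.concatenate([c, r[off]])
            vals = np.concatenate([d, d[off]])
            mats[chrom] = sp.coo_matrix((vals, (rows, cols)), shape=m.shape).tocsr()
        out_cells.append(
            CellGraph(cg.cell_id, mats, total_reads=cg.total_reads - removed_mass, label=cg.label)
        )
    return GraphSet(graphset.bin_map, out_cells)
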