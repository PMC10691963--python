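"""Reading, binning and serialising single-cell Hi-C contact data.

A single-cell Hi-C experiment yields, per cell, a sparse list of pairwise
genomic contacts.  At a chosen resolution (bin width in bp) each chromosome
becomes a symmetric contact matrix whose rows/columns are fixed-width bins;
the collection of per-cell matrices sharing one bin map is a :class:`GraphSet`,
the unit every downstream module operates on.

Conventions: bins are 0-based, half-open ``[i*res, (i+1)*res)``; bp positions
map to bins by floor division.  Inter-chromosomal (trans) contacts are not
stored in the matrices — the model is strictly per-chromosome — but they are
counted towards each cell's read total used for quality filtering.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


class GraphSetFormatError(ValueError):
    """Raised when a serialized graphset container cannot be interpreted."""


@dataclass(frozen=True)
class BinMap:
    """Genome binning at a fixed resolution.

    Parameters
    ----------
    resolution : int
        Bin width in base pairs.
    chrom_sizes : dict
        Chromosome name -> length in bp, in genome order.
    """

    resolution: int
    chrom_sizes: dict[str, int]

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chrom_bins(self) -> dict[str, int]:
        """Bin count per chromosome: ceil(length / resolution)."""
        return {c: -(-s // self.resolution) for c, s in self.chrom_sizes.items()}

    @property
    def offsets(self) -> dict[str, int]:
        """Global bin offset of each chromosome for genome-wide flattening."""
        out, acc = {}, 0
        for c, s in self.chrom_sizes.items():
            out[c] = acc
            acc += -(-s // self.resolution)
        return out

    @property
    def n_bins_total(self) -> int:
        return sum(self.chrom_bins.values())

    def bin_of(self, chrom: str, pos: int) -> int:
        nbins = self.chrom_bins[chrom]
        b = pos // self.resolution
        if b < 0 or b >= nbins:
            raise ValueError(f"position {pos} outside chromosome {chrom}")
        return b


@dataclass(frozen=True)
class ContactRecord:
    """One raw interaction pair, before binning."""

    cell_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    count: int = 1


@dataclass
class CellGraph:
    """Per-cell binned contact maps, one symmetric sparse matrix per chromosome.

    ``total_reads`` counts every input record (count-weighted, trans included)
    so that read-count quality filters see the same totals the assay produced.
    Diagonal (self-bin) entries are stored but are never prediction targets.
    """

    cell_id: str
    matrices: dict[str, sp.csr_matrix]
    total_reads: int = 0
    label: str | None = None

    def n_contacts(self, chrom: str | None = None) -> int:
        """Count-weighted cis contacts (upper triangle incl. diagonal)."""
        chroms = [chrom] if chrom is not None else list(self.matrices)
        total = 0
        for c in chroms:
            m = self.matrices[c]
            total += int(sp.triu(m, k=0).sum())
        return total

    def copy(self) -> "CellGraph":
        return CellGraph(
            self.cell_id,
            {c: m.copy() for c, m in self.matrices.items()},
            self.total_reads,
            self.label,
        )


@dataclass
class GraphSet:
    """An ordered collection of cell graphs sharing one :class:`BinMap`."""

    bin_map: BinMap
    cells: list[CellGraph] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def labels(self) -> list[str | None]:
        return [c.label for c in self.cells]

    def __iter__(self) -> Iterator[CellGraph]:
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def copy(self) -> "GraphSet":
        return GraphSet(self.bin_map, [c.copy() for c in self.cells])


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-dialect two-column chrom.sizes TSV (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {ln}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_pairs(path: str | Path, bin_map: BinMap) -> Iterator[ContactRecord]:
    """Stream contact records from a tab-separated pairs file.

    Columns: cell_id, chrom1, pos1, chrom2, pos2[, count].  Records naming a
    chromosome absent from ``bin_map`` are skipped (and counted); a summary
    of read/kept/skipped totals is logged when the stream is exhausted.
    """
    n_read = n_kept = n_skipped = 0
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: line {ln}: expected >=5 tab-separated columns")
            try:
                cell, ca, pa, cb, pb = parts[0], parts[1], int(parts[2]), parts[3], int(parts[4])
                count = int(parts[5]) if len(parts) > 5 and parts[5] != "" else 1
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: malformed record: {exc}") from exc
            n_read += 1
            if ca not in bin_map.chrom_sizes or cb not in bin_map.chrom_sizes:
                n_skipped += 1
                continue
            if count < 1:
                raise ValueError(f"{path}: line {ln}: count must be >= 1")
            n_kept += 1
            yield ContactRecord(cell, ca, pa, cb, pb, count)
    logger.info("read_pairs(%s): read=%d kept=%d skipped=%d", path, n_read, n_kept, n_skipped)


def write_pairs(records: Iterable[ContactRecord], path: str | Path) -> None:
    """Write contact records as the tab-separated pairs dialect read_pairs reads."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.cell_id}\t{r.chrom_a}\t{r.pos_a}\t{r.chrom_b}\t{r.pos_b}\t{r.count}\n")


def bin_and_aggregate(
    records: Iterable[ContactRecord],
    bin_map: BinMap,
    labels: dict[str, str] | None = None,
    keep_trans_in_totals: bool = True,
) -> GraphSet:
    """Bin contact records and aggregate them into a :class:`GraphSet`.

    Counts are summed per (cell, chromosome, bin_u, bin_v) with u <= v made
    canonical; matrices are stored symmetrically.  Trans (inter-chromosomal)
    records are dropped from the matrices but, by default, still counted in
    each cell's ``total_reads``.
    """
    # (cell -> chrom -> {(u, v): count}), insertion-ordered
    agg: dict[str, dict[str, dict[tuple[int, int], int]]] = {}
    totals: dict[str, int] = {}
    for r in records:
        totals[r.cell_id] = totals.get(r.cell_id, 0) + (
            r.count if (keep_trans_in_totals or r.chrom_a == r.chrom_b) else 0
        )
        agg.setdefault(r.cell_id, {})
        if r.chrom_a != r.chrom_b:
            continue
        u = bin_map.bin_of(r.chrom_a, r.pos_a)
        v = bin_map.bin_of(r.chrom_b, r.pos_b)
        if u > v:
            u, v = v, u
        d = agg[r.cell_id].setdefault(r.chrom_a, {})
        d[(u, v)] = d.get((u, v), 0) + r.count

    cells = []
    for cell_id, per_chrom in agg.items():
        mats: dict[str, sp.csr_matrix] = {}
        for chrom, entries in per_chrom.items():
            n = bin_map.chrom_bins[chrom]
            if entries:
                uu, vv = np.array(list(entries.keys()), dtype=np.int64).T
                cc = np.array(list(entries.values()), dtype=np.int64)
            else:
                uu = vv = np.zeros(0, dtype=np.int64)
                cc = np.zeros(0, dtype=np.int64)
            off = uu != vv
            rows = np.concatenate([uu, vv[off]])
            cols = np.concatenate([vv, uu[off]])
            data = np.concatenate([cc, cc[off]])
            mats[chrom] = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        cells.append(CellGraph(cell_id, mats, total_reads=totals[cell_id]))
    if labels:
        for c in cells:
            c.label = labels.get(c.cell_id)
    if not cells:
        logger.warning("bin_and_aggregate: no records — empty GraphSet")
    return GraphSet(bin_map, cells)


def filter_cells(graphset: GraphSet, min_reads: int, max_reads: float) -> GraphSet:
    """Retain cells whose total read count lies in [min_reads, max_reads].

    Standard quality control: cells with very few reads carry too little
    signal, cells with very many are suspected doublets/artifacts.
    """
    if min_reads > max_reads:
        raise ValueError("min_reads must be <= max_reads")
    kept = [c for c in graphset.cells if min_reads <= c.total_reads <= max_reads]
    if not kept:
        raise ValueError(
            f"filter_cells removed all {graphset.n_cells} cells "
            f"(thresholds {min_reads}-{max_reads}); relax the thresholds"
        )
    logger.info("filter_cells: kept %d / %d cells", len(kept), graphset.n_cells)
    return GraphSet(graphset.bin_map, kept)


def write_graphset(graphset: GraphSet, path: str | Path) -> None:
    """Serialize a graphset to an HDF5 container (lossless round trip).

    Layout: /bins holds the bin map; /cells/<idx>/<chrom> holds COO triplets
    of the upper triangle; labels and cell ids are stored as attributes.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        bins = f.create_group("bins")
        bins.attrs["resolution"] = graphset.bin_map.resolution
        names = list(graphset.bin_map.chrom_sizes)
        bins.create_dataset("chrom_names", data=np.array(names, dtype="S"))
        bins.create_dataset(
            "chrom_sizes",
            data=np.array([graphset.bin_map.chrom_sizes[c] for c in names], dtype=np.int64),
        )
        cells = f.create_group("cells")
        for i, cg in enumerate(graphset.cells):
            g = cells.create_group(str(i))
            g.attrs["cell_id"] = cg.cell_id
            g.attrs["total_reads"] = cg.total_reads
            g.attrs["label"] = cg.label if cg.label is not None else ""
            g.attrs["has_label"] = cg.label is not None
            for chrom, m in cg.matrices.items():
                tri = sp.triu(m, k=0).tocoo()
                cg_grp = g.create_group(chrom)
                cg_grp.create_dataset("row", data=tri.row.astype(np.int64))
                cg_grp.create_dataset("col", data=tri.col.astype(np.int64))
                cg_grp.create_dataset("count", data=tri.data.astype(np.int64))


def read_graphset(path: str | Path) -> GraphSet:
    """Read a graphset container written by :func:`write_graphset`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != _FORMAT_VERSION:
            raise GraphSetFormatError(
                f"{path}: container version {version!r}, expected {_FORMAT_VERSION}"
            )
        names = [n.decode() for n in f["bins/chrom_names"][()]]
        sizes = f["bins/chrom_sizes"][()]
        bin_map = BinMap(int(f["bins"].attrs["resolution"]), dict(zip(names, map(int, sizes))))
        cells = []
        for i in sorted(f["cells"], key=int):
            g = f["cells"][i]
            mats = {}
            for chrom in g:
                n = bin_map.chrom_bins[chrom]
                row = g[chrom]["row"][()]
                col = g[chrom]["col"][()]
                data = g[chrom]["count"][()]
                off = row != col
                rows = np.concatenate([row, col[off]])
                cols = np.concatenate([col, row[off]])
                vals = np.concatenate([data, data[off]])
                mats[chrom] = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
            label = str(g.attrs["label"]) if bool(g.attrs["has_label"]) else None
            cells.append(
                CellGraph(str(g.attrs["cell_id"]), mats, int(g.attrs["total_reads"]), label)
            )
    return GraphSet(bin_map, cells)


def export_matrix_market(graphset: GraphSet, directory: str | Path) -> Path:
    """Export one .mtx per cell per chromosome plus a manifest TSV.

    Returns the manifest path.  The manifest columns are
    (cell_id, chrom, path, label).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("cell_id\tchrom\tpath\tlabel\n")
        for i, cg in enumerate(graphset.cells):
            for chrom, m in cg.matrices.items():
                fname = f"cell{i}_{chrom}.mtx"
                mmwrite(directory / fname, m.tocoo())
                fh.write(f"{cg.cell_id}\t{chrom}\t{fname}\t{cg.label or ''}\n")
    return manifest


def read_matrix_market(manifest_path: str | Path, bin_map: BinMap) -> GraphSet:
    """Assemble a graphset from a manifest TSV of per-cell .mtx matrices."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    per_cell: dict[str, CellGraph] = {}
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {k: j for j, k in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            cell_id, chrom, rel = parts[idx["cell_id"]], parts[idx["chrom"]], parts[idx["path"]]
            label = parts[idx["label"]] or None if "label" in idx else None
            m = sp.csr_matrix(mmread(base / rel))
            if m.shape[0] != bin_map.chrom_bins[chrom]:
                raise ValueError(f"{rel}: shape {m.shape} != bin count for {chrom}")
            cg = per_cell.setdefault(cell_id, CellGraph(cell_id, {}, 0, label))
            cg.matrices[chrom] = m
            cg.total_reads += int(sp.triu(m, k=0).sum())
    return GraphSet(bin_map, list(per_cell.values()))
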