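import numpy as np
import pytest
import scipy.sparse as sp

from schiclink.io import BinMap, CellGraph, GraphSet
from schiclink.simulate import two_type_config, simulate_graphset


@pytest.fixture(scope="session")
def tiny_graphset():
    """Small two-type synthetic set shared by read-only tests."""
    cfg = two_type_config(n_cells=6, n_bins=40, reads_per_cell=400,
                          domain_width=10, seed=7)
    gs, truths = simulate_graphset(cfg)
    return gs, truths


def make_cell_graph(n_bins, edges, cell_id="c0", chrom="chr1", label=None):
    """Build a CellGraph from a list of (u, v, count) triplets."""
    rows, cols, data = [], [], []
    total = 0
    for u, v, c in edges:
        rows.append(u)
        cols.append(v)
        data.append(c)
        total += c
        if u != v:
            rows.append(v)
            cols.append(u)
            data.append(c)
    m = sp.coo_matrix((data, (rows, cols)), shape=(n_bins, n_bins)).tocsr()
    return CellGraph(cell_id, {chrom: m}, total_reads=total, label=label)


def make_graphset(n_bins, cells_edges, resolution=1_000_000, chrom="chr1"):
    bin_map = BinMap(resolution, {chrom: n_bins * resolution})
    cells = [
        make_cell_graph(n_bins, edges, cell_id=f"c{i}", chrom=chrom)
        for i, edges in enumerate(cells_edges)
    ]
    return GraphSet(bin_map, cells)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
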