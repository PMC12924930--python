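import numpy as np
import pandas as pd
import pytest

from tilgraph.synthetic import ProcessParams, simulate_core
from tilgraph.types import CellMap, TileGrid, Window


@pytest.fixture
def window():
    return Window(500.0, 500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def csr_core():
    """A ~300-cell CSR core reused by read-only tests."""
    return simulate_core(ProcessParams(intensity=0.0012, seed=7), Window(500.0, 500.0))


def make_cellmap(points_px, cell_types=None, tiles=((0.0, 0.0),), tile_size=2000,
                 core_id="c0", pixel_spacing=0.25):
    points_px = np.asarray(points_px, dtype=float).reshape(-1, 2)
    if cell_types is None:
        cell_types = ["lymphocyte"] * len(points_px)
    cells = pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(len(points_px))],
        "x_px": points_px[:, 0],
        "y_px": points_px[:, 1],
        "cell_type": cell_types,
    })
    grid = TileGrid(core_id=core_id, tiles=tuple(map(tuple, tiles)), tile_size=tile_size)
    return CellMap(core_id=core_id, cells=cells, tumor_tiles=grid,
                   pixel_spacing=pixel_spacing)
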