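"""Plain-text table formats shared by the CLI and the simulators.

Centroid table: ``cell_id,core_id,x_px,y_px,cell_type``
Tile list:      ``core_id,tile_x_px,tile_y_px,tile_size_px``
Clinical table: ``patient_id,pcr_label`` plus covariate columns.
"""

from __future__ import annotations

import pandas as pd

from .types import CELL_TYPES, CellMap, TileGrid

CENTROID_COLUMNS = ["cell_id", "core_id", "x_px", "y_px", "cell_type"]
TILE_COLUMNS = ["core_id", "tile_x_px", "tile_y_px", "tile_size_px"]


def write_centroids(cellmaps, path) -> None:
    frames = []
    for cm in cellmaps:
        df = cm.cells.copy()
        df["core_id"] = cm.core_id
        frames.append(df[CENTROID_COLUMNS])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=CENTROID_COLUMNS)
    out.to_csv(path, index=False)


def write_tiles(cellmaps, path) -> None:
    rows = []
    for cm in cellmaps:
        grid = cm.tumor_tiles
        for ox, oy in grid.tiles:
            rows.append((cm.core_id, ox, oy, grid.tile_size))
    pd.DataFrame(rows, columns=TILE_COLUMNS).to_csv(path, index=False)


def read_cellmaps(centroid_path, tile_path, pixel_spacing=0.25) -> list[CellMap]:
    """Join a centroid table with a tile list into per-core :class:`CellMap`s."""
    cells = pd.read_csv(centroid_path)
    tiles = pd.read_csv(tile_path)
    _require(cells, CENTROID_COLUMNS, "centroid table")
    _require(tiles, TILE_COLUMNS, "tile list")
    unknown = set(cells["cell_type"].unique()) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown cell types: {sorted(unknown)}")
    maps = []
    core_ids = sorted(set(cells["core_id"].astype(str)) | set(tiles["core_id"].astype(str)))
    for core_id in core_ids:
        sub = cells[cells["core_id"].astype(str) == core_id]
        tsub = tiles[tiles["core_id"].astype(str) == core_id]
        sizes = tsub["tile_size_px"].unique()
        if len(sizes) > 1:
            raise ValueError(f"core {core_id}: mixed tile sizes {sizes}")
        grid = TileGrid(
            core_id=core_id,
            tiles=tuple(zip(tsub["tile_x_px"].astype(float), tsub["tile_y_px"].astype(float))),
            tile_size=int(sizes[0]) if len(sizes) else 750,
        )
        maps.append(
            CellMap(
                core_id=core_id,
                cells=sub.drop(columns=["core_id"]).reset_index(drop=True),
                tumor_tiles=grid,
                pixel_spacing=pixel_spacing,
            )
        )
    return maps


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{what} missing columns: {sorted(missing)}")
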