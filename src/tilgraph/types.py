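"""Core domain types: analysis window, tumor-bed tile grid, cell map."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CELL_TYPES = ("lymphocyte", "epithelial", "macrophage", "neutrophil", "other")

#: Default scan resolution at 40x magnification, micrometers per pixel.
DEFAULT_PIXEL_SPACING = 0.25

#: Tile side used throughout the pipeline, pixels.
DEFAULT_TILE_SIZE = 750


@dataclass(frozen=True)
class Window:
    """Rectangular analysis window in micrometers.

    ``pixel_spacing`` converts between the internal micrometer frame and the
    pixel frame used by all file formats.
    """

    width: float
    height: float
    pixel_spacing: float = DEFAULT_PIXEL_SPACING

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("window dimensions must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def area(self) -> float:
        """Window area in square micrometers."""
        return self.width * self.height

    @property
    def width_px(self) -> float:
        return self.width / self.pixel_spacing

    @property
    def height_px(self) -> float:
        return self.height / self.pixel_spacing


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping axis-aligned tumor-bed tiles for one core.

    ``tiles`` holds tile origins ``(x_px, y_px)``; every tile has side
    ``tile_size`` pixels. Membership of a point in a tile is half-open:
    ``origin <= coord < origin + tile_size`` on both axes.
    """

    core_id: str
    tiles: tuple[tuple[float, float], ...]
    tile_size: int = DEFAULT_TILE_SIZE
    max_background: float = 0.10

    def __post_init__(self):
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if not 0 <= self.max_background <= 1:
            raise ValueError("max_background must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.tiles)

    def contains(self, x_px, y_px) -> np.ndarray:
        """Vectorized half-open point-in-any-tile test."""
        x = np.atleast_1d(np.asarray(x_px, dtype=float))
        y = np.atleast_1d(np.asarray(y_px, dtype=float))
        inside = np.zeros(x.shape, dtype=bool)
        s = self.tile_size
        for ox, oy in self.tiles:
            inside |= (x >= ox) & (x < ox + s) & (y >= oy) & (y < oy + s)
        return inside

    def bounding_box_px(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the tile union in pixels."""
        if not self.tiles:
            raise ValueError("empty tile grid has no bounding box")
        xs = np.array([t[0] for t in self.tiles])
        ys = np.array([t[1] for t in self.tiles])
        s = self.tile_size
        return float(xs.min()), float(ys.min()), float(xs.max() + s), float(ys.max() + s)

def tile_area_mm2(grid: TileGrid, pixel_spacing: float) -> float:
    """Total tumor-bed tile area in square millimeters."""
    side_um = grid.tile_size * pixel_spacing
    return len(grid.tiles) * (side_um * side_um) / 1e6


@dataclass(frozen=True)
class CellMap:
    """Cell centroids of one core together with its tumor-bed tile grid.

    ``cells`` is a DataFrame with columns ``cell_id, x_px, y_px, cell_type``
    (``core_id`` optional). Coordinates are pixels in the slide frame.
    """

    core_id: str
    cells: pd.DataFrame
    tumor_tiles: TileGrid
    pixel_spacing: float = DEFAULT_PIXEL_SPACING

    def __post_init__(self):
        required = {"cell_id", "x_px", "y_px", "cell_type"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns: {sorted(missing)}")
        if len(self.cells) and self.cells["cell_id"].duplicated().any():
            raise ValueError("cell ids must be unique within a core")
        if len(self.cells) and ((self.cells["x_px"] < 0).any() or (self.cells["y_px"] < 0).any()):
            raise ValueError("cell coordinates must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def lymphocytes(self) -> pd.DataFrame:
        return self.cells[self.cells["cell_type"] == "lymphocyte"]

    def points_um(self, cell_type: str | None = "lymphocyte") -> np.ndarray:
        """(n, 2) centroid coordinates in micrometers."""
        df = self.cells if cell_type is None else self.cells[self.cells["cell_type"] == cell_type]
        return df[["x_px", "y_px"]].to_numpy(dtype=float) * self.pixel_spacing

    def with_cells(self, cells: pd.DataFrame) -> "CellMap":
        return replace(self, cells=cells.reset_index(drop=True))


@dataclass
class PatientRecord:
    """One patient: clinical covariates, binary response label, cores."""

    patient_id: str
    clinical: dict
    label: int
    cores: list = field(default_factory=list)

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be binary (1 = complete response)")
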