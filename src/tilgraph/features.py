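"""Spatial graph features of lymphocyte point patterns.

All geometric computation happens in micrometers. Features that cannot be
computed for a degenerate input (too few points, collinear configurations,
no clusters) are emitted as NaN and later imputed inside the modeling stage,
keeping the 371-column contract stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPoint, box

from .clustering import clustering_features
from .registry import (
    ClusterConfig,
    DensityConfig,
    FeatureRegistry,
    default_registry,
)
from .stats import STAT_NAMES, SummaryStats, summary_stats
from .types import CellMap, tile_area_mm2

_NAN4 = (np.nan,) * 4


@dataclass(frozen=True)
class FeatureVector:
    """One core's named feature values (NaN = missing)."""

    core_id: str
    values: dict

    def to_array(self, registry: FeatureRegistry) -> np.ndarray:
        return np.array([self.values[n] for n in registry.names], dtype=float)


def _stats4(values) -> tuple[float, float, float, float]:
    return summary_stats(values).as_tuple()


# ---------------------------------------------------------------------------
# Delaunay
# ---------------------------------------------------------------------------

def delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Unique undirected Delaunay edges as an (m, 2) index array (i < j)."""
    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        a, b, c = sorted(int(v) for v in simplex)
        edges.update(((a, b), (a, c), (b, c)))
    return np.array(sorted(edges), dtype=int)


def delaunay_features(points: np.ndarray) -> dict:
    """SummaryStats of Delaunay edge lengths and triangle areas (8 values)."""
    points = np.asarray(points, dtype=float)
    names = [f"DE-{s}" for s in STAT_NAMES] + [f"DA-{s}" for s in STAT_NAMES]
    try:
        if len(points) < 3:
            raise QhullError("need >= 3 points")
        tri = Delaunay(points)
    except QhullError:
        return dict(zip(names, _NAN4 + _NAN4))
    edges = delaunay_edges(points)
    lengths = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)
    p = points[tri.simplices]
    u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    areas = 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    return dict(zip(names, _stats4(lengths) + _stats4(areas)))


# ---------------------------------------------------------------------------
# Voronoi
# ---------------------------------------------------------------------------

def voronoi_cells(points: np.ndarray, window_box: tuple) -> list:
    """Window-clipped Voronoi polygons, ordered like the input points.

    ``window_box`` is (xmin, ymin, xmax, ymax) in micrometers.
    """
    clip = box(*window_box)
    polys = shapely.voronoi_polygons(MultiPoint(points.tolist()),
                                     extend_to=clip, ordered=True)
    return [poly.intersection(clip) for poly in polys.geoms]


def _max_chord(poly) -> float:
    verts = np.asarray(poly.exterior.coords)[:-1]
    diff = verts[:, None, :] - verts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def voronoi_features(points: np.ndarray, window_box: tuple) -> dict:
    """SummaryStats of clipped-cell areas, perimeters, and max chords (12)."""
    points = np.asarray(points, dtype=float)
    names = [f"{q}-{s}" for q in ("VA", "VP", "VMD") for s in STAT_NAMES]
    if len(points) < 2:
        return dict(zip(names, _NAN4 * 3))
    try:
        cells = voronoi_cells(points, window_box)
    except shapely.errors.GEOSException:
        return dict(zip(names, _NAN4 * 3))
    cells = [c for c in cells if not c.is_empty and c.area > 0]
    if len(cells) < 2:
        return dict(zip(names, _NAN4 * 3))
    areas = [c.area for c in cells]
    perims = [c.length for c in cells]
    chords = [_max_chord(c) for c in cells]
    return dict(zip(names, _stats4(areas) + _stats4(perims) + _stats4(chords)))


# ---------------------------------------------------------------------------
# Minimum spanning tree
# ---------------------------------------------------------------------------

def mst_edge_lengths(points: np.ndarray) -> np.ndarray:
    """The n-1 Euclidean MST edge lengths. Uses the Delaunay graph when
    available (EMST is a subgraph), otherwise the dense pairwise graph."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    try:
        if n < 4:
            raise QhullError("small")
        edges = delaunay_edges(points)
        w = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)
        graph = csr_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    except QhullError:
        diff = points[:, None, :] - points[None, :, :]
        graph = csr_matrix(np.triu(np.sqrt((diff ** 2).sum(-1)), k=1))
    mst = minimum_spanning_tree(graph)
    return np.sort(mst.data)


def mst_features(points: np.ndarray) -> dict:
    names = [f"MST-{s}" for s in STAT_NAMES]
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return dict(zip(names, _NAN4))
    return dict(zip(names, _stats4(mst_edge_lengths(points))))


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------

def neighbor_counts(points: np.ndarray, radius: float) -> np.ndarray:
    """Per-point count of *other* points within ``radius`` (closed ball)."""
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r=radius, return_length=True)
    return np.asarray(counts) - 1


def knn_distances(points: np.ndarray, k_max: int) -> np.ndarray:
    """(n, k_max) distances to the 1st..k_max-th nearest other point."""
    tree = cKDTree(points)
    d, _ = tree.query(points, k=k_max + 1)
    return d[:, 1:]


def density_features(points: np.ndarray, config: DensityConfig | None = None) -> dict:
    """DND neighbor-count stats over 40 radii plus DDN k-NN-distance stats
    over 14 ranks (216 values)."""
    config = config or DensityConfig()
    points = np.asarray(points, dtype=float)
    out: dict[str, float] = {}
    n = len(points)
    if n < 2:
        for i in range(len(config.radii)):
            out.update({f"DND-{s}_{i}": np.nan for s in STAT_NAMES})
        for i in range(len(config.k_values)):
            out.update({f"DDN-{s}_{i}": np.nan for s in STAT_NAMES})
        return out

    for i, r in enumerate(config.radii):
        out.update(zip((f"DND-{s}_{i}" for s in STAT_NAMES),
                       _stats4(neighbor_counts(points, r))))
    k_max = int(config.k_values[-1])
    dists = knn_distances(points, min(k_max, n - 1))
    for i, k in enumerate(config.k_values):
        if k > n - 1:
            out.update({f"DDN-{s}_{i}": np.nan for s in STAT_NAMES})
        else:
            out.update(zip((f"DDN-{s}_{i}" for s in STAT_NAMES),
                           _stats4(dists[:, k - 1])))
    return out


# ---------------------------------------------------------------------------
# Frequency and full extraction
# ---------------------------------------------------------------------------

def til_frequency(cells: CellMap) -> float:
    """Lymphocyte count per mm^2 of tumor-bed tile area."""
    area = tile_area_mm2(cells.tumor_tiles, cells.pixel_spacing)
    if area <= 0:
        return np.nan
    return len(cells.lymphocytes()) / area


def extract_all(cells: CellMap, density: DensityConfig | None = None,
                cluster: ClusterConfig | None = None,
                registry: FeatureRegistry | None = None) -> FeatureVector:
    """Compute the full catalogue for one tumor-bed-filtered core."""
    density = density or DensityConfig()
    cluster = cluster or ClusterConfig()
    registry = registry or default_registry(density, cluster)

    pts = cells.points_um("lymphocyte")
    values: dict[str, float] = {}
    values.update(clustering_features(pts, cluster))
    if len(cells.tumor_tiles):
        bbox_px = cells.tumor_tiles.bounding_box_px()
        window_box = tuple(v * cells.pixel_spacing for v in bbox_px)
        values.update(voronoi_features(pts, window_box))
    else:
        values.update({f"{q}-{s}": np.nan for q in ("VA", "VP", "VMD") for s in STAT_NAMES})
    values.update(delaunay_features(pts))
    values.update(mst_features(pts))
    values.update(density_features(pts, density))
    values["TIL-FREQ"] = til_frequency(cells)

    missing = set(registry.names) - set(values)
    if missing:
        raise RuntimeError(f"extractor/registry mismatch: {sorted(missing)[:5]}")
    return FeatureVector(core_id=cells.core_id,
                         values={n: float(values[n]) for n in registry.names})
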