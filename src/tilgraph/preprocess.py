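"""Image front end: foreground detection, tiling, stain normalization, and
assignment of lymphocyte centroids to the tumor bed.

The tumor-bed segmentation network and the nuclei classifier are consumed as
inputs (tile lists, centroid tables); nothing here learns anything.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import CellMap, TileGrid


class DegenerateImageError(ValueError):
    """Raised when Otsu's criterion is undefined (constant image)."""


def _luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance after white-balance clipping at the 99th percentile."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        lum = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    else:
        lum = img
    hi = np.percentile(lum, 99)
    return np.minimum(lum, hi)


def otsu_foreground(image: np.ndarray):
    """Tissue/background mask by Otsu's criterion on luminance.

    Returns ``(mask, boundary)`` where ``mask`` is True on tissue (the darker
    class) and ``boundary`` is the contour of the largest foreground component
    as an (m, 2) array of (row, col) vertices, or None if no foreground.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import find_contours, label

    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    lum = _luminance(img)
    if np.ptp(lum) == 0:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    thr = threshold_otsu(lum)
    mask = lum <= thr

    boundary = None
    if mask.any():
        lab = label(mask)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        contours = find_contours((lab == largest).astype(float), 0.5)
        if contours:
            boundary = max(contours, key=len)
    return mask, boundary


def tile_image(mask: np.ndarray, tile_size: int = 750,
               max_background: float = 0.10, core_id: str = "core") -> TileGrid:
    """Non-overlapping grid over a tissue mask; keeps full tiles whose
    background fraction is at most ``max_background``. Partial border tiles
    are dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if tile_size > h or tile_size > w:
        warnings.warn("tile_size exceeds image extent; empty grid", stacklevel=2)
        return TileGrid(core_id=core_id, tiles=(), tile_size=tile_size,
                        max_background=max_background)
    tiles = []
    for oy in range(0, h - tile_size + 1, tile_size):
        for ox in range(0, w - tile_size + 1, tile_size):
            block = mask[oy:oy + tile_size, ox:ox + tile_size]
            background = 1.0 - block.mean()
            if background <= max_background:
                tiles.append((float(ox), float(oy)))
    return TileGrid(core_id=core_id, tiles=tuple(tiles), tile_size=tile_size,
                    max_background=max_background)


# ---------------------------------------------------------------------------
# Macenko stain normalization
# ---------------------------------------------------------------------------

_EPS = 1e-6


def _white_point(image: np.ndarray) -> np.ndarray:
    """Per-channel background intensity (99th percentile), the reference
    against which optical density is measured."""
    wp = np.percentile(image.reshape(-1, 3).astype(float), 99, axis=0)
    return np.maximum(wp, 1.0)


def _stain_decompose(image: np.ndarray, beta: float = 0.15, alpha: float = 1.0):
    """Macenko estimation: optical-density transform against the image's own
    white point, plane fit of the two dominant stain directions, percentile
    concentration scaling.

    Returns ``(stain_matrix (3, 2), concentrations (2, n), max_conc (2,))``
    or None when too few stained pixels exist.
    """
    io = _white_point(image)
    od = -np.log((image.reshape(-1, 3).astype(float) + 1.0) / (io + 1.0))
    od = np.maximum(od, 0.0)
    stained = od[(od > beta).any(axis=1)]
    if len(stained) < 50:
        return None
    cov = np.cov(stained.T)
    evals, evecs = np.linalg.eigh(cov)
    basis = evecs[:, 1:]  # two leading eigenvectors
    proj = stained @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, (alpha, 100 - alpha))
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    # hematoxylin first (larger first OD component), both pointing positive
    v1, v2 = (v1, v2) if v1[0] > v2[0] else (v2, v1)
    stains = np.column_stack([_positive(v1), _positive(v2)])
    conc, *_ = np.linalg.lstsq(stains, od.T, rcond=None)
    max_conc = np.percentile(conc, 99, axis=1)
    return stains, conc, np.maximum(max_conc, _EPS)


def _positive(v):
    v = v if v.sum() >= 0 else -v
    return v / np.linalg.norm(v)


def stain_normalize(tile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map ``tile``'s stain statistics onto ``reference``'s (Macenko).

    Optical density is measured against each image's own estimated white
    point and rebuilt against the reference's, so global illumination shifts
    are corrected alongside stain variation. Off-stain-plane OD content is
    carried through unchanged, making normalization the identity when the
    tile already matches the reference. Near-white tiles (no measurable
    stain) pass through with a warning.
    """
    tile = np.asarray(tile)
    reference = np.asarray(reference)
    ref_fit = _stain_decompose(reference)
    tile_fit = _stain_decompose(tile)
    if tile_fit is None or ref_fit is None:
        warnings.warn("insufficient stained pixels; passing tile through", stacklevel=2)
        return tile.copy()
    ref_stains, _, ref_max = ref_fit
    tile_stains, conc, tile_max = tile_fit
    conc_scaled = conc * (ref_max / tile_max)[:, None]
    io_tile = _white_point(tile)
    io_ref = _white_point(reference)
    od = -np.log((tile.reshape(-1, 3).astype(float) + 1.0) / (io_tile + 1.0))
    od = np.maximum(od, 0.0)
    residual = od.T - tile_stains @ conc  # off-stain-plane content is preserved
    od_new = ref_stains @ conc_scaled + residual
    out = (io_ref + 1.0)[:, None] * np.exp(-od_new) - 1.0
    return np.clip(out.T.reshape(tile.shape), 0, 255).astype(np.uint8)


def assign_tils_to_tumor_bed(cells: CellMap) -> CellMap:
    """Retain only lymphocytes whose centroid falls inside a tumor-bed tile.

    Tile membership is half-open ``[origin, origin + size)`` on both axes;
    idempotent by construction.
    """
    df = cells.lymphocytes()
    if len(df) == 0:
        return cells.with_cells(df)
    inside = cells.tumor_tiles.contains(df["x_px"].to_numpy(), df["y_px"].to_numpy())
    return cells.with_cells(df[inside])
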