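"""Synthetic point patterns, cores, cohorts, and H&E-like tiles.

Everything downstream of the (out-of-scope) segmentation networks consumes
centroid tables and tile lists; this module fabricates those inputs with
controlled spatial structure:

* ``CSR`` — homogeneous Poisson process (complete spatial randomness),
* ``THOMAS`` — Poisson parents with Gaussian-scattered offspring (clustering),
* ``HARDCORE`` — sequential inhibition with a minimum inter-point distance.

Coordinates are simulated in micrometers and converted to pixels on output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_TILE_SIZE,
    CellMap,
    PatientRecord,
    TileGrid,
    Window,
)


class Process(str, enum.Enum):
    CSR = "CSR"
    THOMAS = "THOMAS"
    HARDCORE = "HARDCORE"


@dataclass(frozen=True)
class ProcessParams:
    """Parameters of a planar point process.

    For ``THOMAS`` the expected intensity is
    ``parent_intensity * offspring_mean / area`` ... offspring are scattered
    isotropically N(0, offspring_sd^2) around each parent and points falling
    outside the window are discarded (bounded-core convention, no wrap).
    """

    process: Process = Process.CSR
    intensity: float = 0.001
    parent_intensity: float = 0.0
    offspring_mean: float = 0.0
    offspring_sd: float = 10.0
    inhibition_radius: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "process", Process(self.process))
        for name in ("intensity", "parent_intensity", "offspring_mean",
                     "offspring_sd", "inhibition_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_point_pattern(params: ProcessParams, window: Window,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one realization; returns an (n, 2) array of micrometer coordinates."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    w, h = window.width, window.height
    if params.process is Process.CSR:
        n = rng.poisson(params.intensity * w * h)
        return _uniform(rng, n, w, h)
    if params.process is Process.THOMAS:
        n_parents = rng.poisson(params.parent_intensity * w * h)
        parents = _uniform(rng, n_parents, w, h)
        pts = []
        for px, py in parents:
            k = rng.poisson(params.offspring_mean)
            off = rng.normal(0.0, params.offspring_sd, size=(k, 2)) + (px, py)
            pts.append(off)
        if not pts:
            return np.empty((0, 2))
        out = np.concatenate(pts)
        keep = (out[:, 0] >= 0) & (out[:, 0] < w) & (out[:, 1] >= 0) & (out[:, 1] < h)
        return out[keep]
    # HARDCORE: random sequential adsorption targeting a Poisson count
    target = rng.poisson(params.intensity * w * h)
    r2 = params.inhibition_radius ** 2
    accepted: list[tuple[float, float]] = []
    attempts = 0
    while len(accepted) < target and attempts < 50 * max(target, 1):
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        attempts += 1
        if all((x - ax) ** 2 + (y - ay) ** 2 >= r2 for ax, ay in accepted):
            accepted.append((x, y))
    return np.asarray(accepted, dtype=float).reshape(-1, 2)


def _uniform(rng, n, w, h):
    pts = np.empty((n, 2))
    pts[:, 0] = rng.uniform(0, w, size=n)
    pts[:, 1] = rng.uniform(0, h, size=n)
    return pts


def full_tile_grid(window: Window, tile_size: int = DEFAULT_TILE_SIZE,
                   core_id: str = "core") -> TileGrid:
    """Tile grid covering the whole window (ceil coverage, so every interior
    point falls in some tile)."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    nx = max(1, int(np.ceil(window.width_px / tile_size)))
    ny = max(1, int(np.ceil(window.height_px / tile_size)))
    tiles = tuple(
        (float(ix * tile_size), float(iy * tile_size))
        for iy in range(ny) for ix in range(nx)
    )
    return TileGrid(core_id=core_id, tiles=tiles, tile_size=tile_size)


def simulate_core(params: ProcessParams, window: Window,
                  tile_size: int = DEFAULT_TILE_SIZE, core_id: str = "core0",
                  rng: np.random.Generator | None = None) -> CellMap:
    """One core: lymphocyte centroids plus a tumor-bed tile list covering the window."""
    pts_um = simulate_point_pattern(params, window, rng=rng)
    px = pts_um / window.pixel_spacing
    cells = pd.DataFrame({
        "cell_id": [f"{core_id}_c{i:05d}" for i in range(len(px))],
        "x_px": px[:, 0],
        "y_px": px[:, 1],
        "cell_type": "lymphocyte",
    })
    grid = full_tile_grid(window, tile_size=tile_size, core_id=core_id)
    return CellMap(core_id=core_id, cells=cells, tumor_tiles=grid,
                   pixel_spacing=window.pixel_spacing)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Baseline (class-independent) clinical covariate generators, loosely shaped
#: like a breast-cancer NST cohort. Categorical entries give (levels, probs).
DEFAULT_CLINICAL = {
    "age": {"kind": "normal", "mean": 51.0, "sd": 11.0},
    "menopausal_status": {"kind": "categorical", "levels": ["pre", "post", "peri"],
                          "probs": [0.44, 0.47, 0.09]},
    "laterality": {"kind": "categorical", "levels": ["left", "right"], "probs": [0.48, 0.52]},
    "regimen": {"kind": "categorical", "levels": ["FEC-D", "AC-T"], "probs": [0.41, 0.59]},
    "anti_her2_therapy": {"kind": "categorical", "levels": ["no", "yes"], "probs": [0.61, 0.39]},
    "er_status": {"kind": "categorical", "levels": ["negative", "positive"], "probs": [0.36, 0.64]},
    "pr_status": {"kind": "categorical", "levels": ["negative", "positive"], "probs": [0.47, 0.53]},
    "her2_status": {"kind": "categorical", "levels": ["negative", "positive"], "probs": [0.61, 0.39]},
    "tumor_size_mm": {"kind": "normal", "mean": 45.0, "sd": 26.0},
    "clinical_t_stage": {"kind": "ordinal", "levels": [1, 2, 3, 4],
                         "probs": [0.10, 0.59, 0.29, 0.02]},
    "clinical_n_stage": {"kind": "ordinal", "levels": [0, 1, 2, 3],
                         "probs": [0.31, 0.57, 0.08, 0.04]},
    "node_status": {"kind": "categorical", "levels": ["negative", "positive"], "probs": [0.31, 0.69]},
    "inflammatory_status": {"kind": "categorical", "levels": ["no", "yes"], "probs": [0.92, 0.08]},
    "nottingham_grade": {"kind": "ordinal", "levels": [1, 2, 3], "probs": [0.05, 0.44, 0.51]},
    "histology": {"kind": "categorical", "levels": ["IDC", "ILC", "IMC"],
                  "probs": [0.93, 0.05, 0.02]},
    "brca_status": {"kind": "categorical", "levels": ["negative", "positive"], "probs": [0.94, 0.06]},
}


@dataclass(frozen=True)
class CohortSpec:
    """Two-class cohort description.

    ``class_effect`` maps a :class:`ProcessParams` field name to
    ``(responder_value, non_responder_value)``; fields not listed take the
    value in ``base_params``. ``clinical_effect`` maps a covariate name to a
    class-conditional override of its :data:`DEFAULT_CLINICAL` entry, as
    ``{"responder": {...}, "non_responder": {...}}``.
    """

    n_patients: int = 50
    cores_per_patient: int | tuple[int, int] = 1
    pcr_fraction: float = 0.3
    class_effect: dict = field(default_factory=dict)
    clinical_effect: dict = field(default_factory=dict)
    base_params: ProcessParams = field(default_factory=ProcessParams)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.pcr_fraction <= 1:
            raise ValueError("pcr_fraction must lie in [0, 1]")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        n_pos = int(round(self.n_patients * self.pcr_fraction))
        if n_pos == 0 or n_pos == self.n_patients:
            raise ValueError("pcr_fraction leaves one class empty")


def _draw_covariate(rng, spec: dict):
    if spec["kind"] == "normal":
        return float(rng.normal(spec["mean"], spec["sd"]))
    probs = np.asarray(spec["probs"], dtype=float)
    idx = rng.choice(len(spec["levels"]), p=probs / probs.sum())
    return spec["levels"][idx]


def simulate_cohort(spec: CohortSpec, window: Window,
                    tile_size: int = DEFAULT_TILE_SIZE) -> list[PatientRecord]:
    """Generate a labeled cohort with class-conditional spatial and clinical structure."""
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_patients * spec.pcr_fraction))
    labels = np.array([1] * n_pos + [0] * (spec.n_patients - n_pos))
    rng.shuffle(labels)

    patients = []
    for i, label in enumerate(labels):
        pid = f"p{i:04d}"
        cls = "responder" if label == 1 else "non_responder"
        overrides = {k: (v[0] if label == 1 else v[1]) for k, v in spec.class_effect.items()}
        params = replace(spec.base_params, **overrides)

        clinical = {}
        for name, base in DEFAULT_CLINICAL.items():
            eff = spec.clinical_effect.get(name, {})
            clinical[name] = _draw_covariate(rng, {**base, **eff.get(cls, {})})

        if isinstance(spec.cores_per_patient, tuple):
            lo, hi = spec.cores_per_patient
            n_cores = int(rng.integers(lo, hi + 1))
        else:
            n_cores = int(spec.cores_per_patient)
        cores = [
            simulate_core(params, window, tile_size=tile_size,
                          core_id=f"{pid}_core{j}", rng=rng)
            for j in range(max(1, n_cores))
        ]
        patients.append(PatientRecord(patient_id=pid, clinical=clinical,
                                      label=int(label), cores=cores))
    return patients


def cohort_clinical_table(patients: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        rows.append({"patient_id": p.patient_id, "pcr_label": p.label, **p.clinical})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# H&E-like tiles
# ---------------------------------------------------------------------------

_BACKGROUND = np.array([232, 226, 236], dtype=float)   # pale eosin-tinted glass
_NUCLEUS = np.array([84, 48, 122], dtype=float)        # hematoxylin purple


def simulate_he_tile(window: Window, nuclei_um: np.ndarray,
                     stain_shift: tuple[float, float, float] = (0.0, 0.0, 0.0),
                     nucleus_radius_um: float = 3.0, seed: int = 0,
                     return_mask: bool = False):
    """Render dark elliptical nuclei on a pale background.

    ``stain_shift`` is added per channel (then clipped) to emulate staining
    variation; ``return_mask`` additionally returns the boolean nucleus mask.
    """
    from skimage.draw import ellipse

    rng = np.random.default_rng(seed)
    h = int(round(window.height_px))
    w = int(round(window.width_px))
    img = np.tile(_BACKGROUND, (h, w, 1))
    img += rng.normal(0, 2.0, size=img.shape)
    mask = np.zeros((h, w), dtype=bool)

    nuclei_um = np.asarray(nuclei_um, dtype=float).reshape(-1, 2)
    r_px = nucleus_radius_um / window.pixel_spacing
    for x_um, y_um in nuclei_um:
        if not (0 <= x_um <= window.width and 0 <= y_um <= window.height):
            raise ValueError("nucleus outside window")
        cy = y_um / window.pixel_spacing
        cx = x_um / window.pixel_spacing
        ry = r_px * rng.uniform(0.8, 1.2)
        rx = r_px * rng.uniform(0.8, 1.2)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = True
        jitter = rng.normal(0, 6.0, size=3)
        img[rr, cc] = _NUCLEUS + jitter

    img += np.asarray(stain_shift, dtype=float)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return (img, mask) if return_mask else img


def clark_evans_index(points_um: np.ndarray, window: Window) -> float:
    """Clark-Evans aggregation index: observed mean nearest-neighbor distance
    over the CSR expectation 1/(2*sqrt(intensity)). < 1 indicates clustering."""
    from scipy.spatial import cKDTree

    pts = np.asarray(points_um, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    d, _ = cKDTree(pts).query(pts, k=2)
    lam = len(pts) / window.area
    return float(d[:, 1].mean() * 2.0 * np.sqrt(lam))
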