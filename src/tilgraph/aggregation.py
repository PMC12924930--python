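"""Reduce per-core feature rows to per-patient feature sets.

Seven schemes: per-core (one row per core, label inherited), max, min, mean,
weighted-mean, median, and mean-min-max (three columns per feature). The
weighted mean weights cores by lymphocyte count unless another per-core
weight column is supplied. Reductions ignore missing values column-wise; a
column missing in every core stays missing.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd


class Scheme(str, enum.Enum):
    PER_CORE = "per-core"
    MAX = "max"
    MIN = "min"
    MEAN = "mean"
    WEIGHTED_MEAN = "wmean"
    MEDIAN = "median"
    MEAN_MIN_MAX = "mmm"


ID_COLUMNS = ("patient_id", "core_id")


def aggregate_patient(core_rows: pd.DataFrame, scheme: Scheme,
                      weights: np.ndarray | None = None) -> pd.DataFrame:
    """Aggregate one patient's core feature rows.

    ``core_rows`` holds one row per core with feature columns only (plus
    optional ``core_id``). Returns a one-row frame (or one row per core for
    PER_CORE, sorted by core id; or a 3x-wide row for MEAN_MIN_MAX).
    """
    if len(core_rows) == 0:
        raise ValueError("patient has no cores")
    scheme = Scheme(scheme)
    feat = core_rows.drop(columns=[c for c in ID_COLUMNS if c in core_rows], errors="ignore")

    if scheme is Scheme.PER_CORE:
        if "core_id" in core_rows:
            return core_rows.sort_values("core_id").reset_index(drop=True)
        return core_rows.reset_index(drop=True)
    if scheme is Scheme.MAX:
        return feat.max(skipna=True).to_frame().T
    if scheme is Scheme.MIN:
        return feat.min(skipna=True).to_frame().T
    if scheme is Scheme.MEAN:
        return feat.mean(skipna=True).to_frame().T
    if scheme is Scheme.MEDIAN:
        return feat.median(skipna=True).to_frame().T
    if scheme is Scheme.WEIGHTED_MEAN:
        if weights is None:
            raise ValueError("weighted mean needs per-core weights")
        w = np.asarray(weights, dtype=float)
        if len(w) != len(feat) or w.sum() <= 0:
            raise ValueError("weights must match cores and have positive sum")
        x = feat.to_numpy(dtype=float)
        mask = ~np.isnan(x)
        wmat = np.where(mask, w[:, None], 0.0)
        with np.errstate(invalid="ignore"):
            out = np.nansum(x * wmat, axis=0) / wmat.sum(axis=0)
        return pd.DataFrame([out], columns=feat.columns)
    # MEAN_MIN_MAX
    parts = {}
    for suffix, reduced in (("mean", feat.mean(skipna=True)),
                            ("min", feat.min(skipna=True)),
                            ("max", feat.max(skipna=True))):
        for col, val in reduced.items():
            parts[f"{col}_{suffix}"] = val
    return pd.DataFrame([parts])


def aggregate_cohort(features: pd.DataFrame, scheme: Scheme,
                     weight_column: str | None = None) -> pd.DataFrame:
    """Aggregate a cohort feature matrix (one row per core, ``patient_id``
    and ``core_id`` keys) into one row per patient (or per core for
    PER_CORE). The weight column defaults to ``TIL-FREQ``-independent raw
    lymphocyte counts if present as ``n_tils``."""
    scheme = Scheme(scheme)
    if "patient_id" not in features:
        raise ValueError("feature matrix needs a patient_id column")
    if weight_column is None:
        weight_column = "n_tils" if "n_tils" in features else None
    drop = [c for c in (weight_column,) if c]

    out = []
    for pid, group in features.groupby("patient_id", sort=True):
        weights = group[weight_column].to_numpy() if (
            scheme is Scheme.WEIGHTED_MEAN and weight_column) else None
        if scheme is Scheme.WEIGHTED_MEAN and weights is None:
            raise ValueError("weighted mean needs a weight column (e.g. n_tils)")
        rows = aggregate_patient(group.drop(columns=drop), scheme, weights=weights)
        rows = rows.drop(columns=[c for c in ID_COLUMNS if c in rows], errors="ignore")
        rows.insert(0, "patient_id", pid)
        if scheme is Scheme.PER_CORE:
            rows.insert(1, "core_id", sorted(group["core_id"]))
        out.append(rows)
    return pd.concat(out, ignore_index=True)
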