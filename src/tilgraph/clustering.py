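"""Density-based cluster morphometrics (the 130-feature CLUSTER family)."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .hdbscan_ import hdbscan
from .registry import CLUSTER_STATISTICS, ClusterConfig
from .stats import summary_stats


def _davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import davies_bouldin_score

    mask = labels >= 0
    if len(np.unique(labels[mask])) < 2:
        return np.nan
    return float(davies_bouldin_score(points[mask], labels[mask]))


def _intra_cluster_distance(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean pairwise distance pooled over all within-cluster pairs."""
    total, count = 0.0, 0
    for lab in np.unique(labels[labels >= 0]):
        d = pdist(points[labels == lab])
        total += d.sum()
        count += len(d)
    return total / count if count else np.nan


def cluster_statistics(points: np.ndarray, labels: np.ndarray,
                       persistence: np.ndarray) -> dict:
    """The 13 per-parameterization statistics from one clustering run."""
    n = len(labels)
    clustered = labels >= 0
    uniq, sizes = np.unique(labels[clustered], return_counts=True)
    ccf = clustered.sum() / n if n else 0.0
    out = {"NC": float(len(uniq)), "CCF": ccf, "OF": 1.0 - ccf}
    if len(uniq) == 0:
        for key in CLUSTER_STATISTICS[3:]:
            out[key] = np.nan
        return out
    s = summary_stats(sizes)
    out.update({"CS-MEAN": s.mean, "MCS": float(np.median(sizes)),
                "CS-STD": s.std, "CS-MMR": s.mmr, "CS-DIS": s.disorder})
    p = summary_stats(persistence)
    out.update({"CP-MEAN": p.mean, "MCP": float(np.median(persistence)),
                "STD-CP": p.std})
    out["DBS"] = _davies_bouldin(points, labels)
    out["ICD"] = _intra_cluster_distance(points, labels)
    return out


def clustering_features(points: np.ndarray, config: ClusterConfig | None = None) -> dict:
    """Run the clusterer at each min_cluster_size and emit 10 x 13 features,
    each name suffixed by its min_cluster_size."""
    config = config or ClusterConfig()
    points = np.asarray(points, dtype=float)
    out: dict[str, float] = {}
    for m in config.min_cluster_sizes:
        if len(points) == 0:
            stats = {k: np.nan for k in CLUSTER_STATISTICS}
        else:
            result = hdbscan(points, min_cluster_size=int(m), allow_single_cluster=True)
            stats = cluster_statistics(points, result.labels, result.persistence)
        out.update({f"{k}_{m}": stats[k] for k in CLUSTER_STATISTICS})
    return out
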