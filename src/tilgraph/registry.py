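"""Catalogue of the 371 spatial features.

Family cardinalities: CLUSTER 130, VORONOI 12, DELAUNAY 8, MST 4,
DENSITY 216, FREQUENCY 1. Naming follows the published abbreviations:
``CCF`` clustered cell fraction, ``OF`` outlier fraction, ``MCS`` median
cluster size, ``MCP`` median cluster persistence, ``STD-CP`` persistence
standard deviation, ``DBS`` Davies-Bouldin score, ``DND`` density neighbors
in distance, ``DDN`` density distance for neighbors, ``VMD`` Voronoi max
distance, ``MMR`` min-max ratio, ``DIS`` disorder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .stats import STAT_NAMES

FAMILIES = ("CLUSTER", "VORONOI", "DELAUNAY", "MST", "DENSITY", "FREQUENCY")

#: 13 per-min-cluster-size statistics, in emission order.
CLUSTER_STATISTICS = (
    "NC",        # number of clusters
    "CCF",       # clustered cell fraction
    "OF",        # outlier fraction (1 - CCF)
    "CS-MEAN",   # cluster size mean
    "MCS",       # cluster size median
    "CS-STD",    # cluster size std
    "CS-MMR",    # cluster size min-max ratio
    "CS-DIS",    # cluster size disorder
    "CP-MEAN",   # cluster persistence mean
    "MCP",       # cluster persistence median
    "STD-CP",    # cluster persistence std
    "DBS",       # Davies-Bouldin score
    "ICD",       # mean intra-cluster pairwise distance
)

#: 3 Voronoi cell quantities, each reduced by the 4 summary statistics.
VORONOI_QUANTITIES = ("VA", "VP", "VMD")  # area, perimeter, max chord


@dataclass(frozen=True)
class DensityConfig:
    """Radius grid for neighbor counts (DND) and rank grid for k-NN
    distances (DDN). Subscripts in feature names are grid *indices*."""

    radii: tuple = field(default_factory=lambda: tuple(5.0 * (i + 1) for i in range(40)))
    k_values: tuple = field(default_factory=lambda: tuple(range(1, 15)))

    def __post_init__(self):
        if len(self.radii) != 40 or np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be 40 strictly increasing lengths")
        ks = np.asarray(self.k_values)
        if len(ks) != 14 or np.any(np.diff(ks) <= 0) or ks[0] < 1 or ks.dtype.kind not in "iu":
            raise ValueError("k_values must be 14 strictly increasing positive integers")


@dataclass(frozen=True)
class ClusterConfig:
    min_cluster_sizes: tuple = field(default_factory=lambda: tuple(range(10, 101, 10)))

    def __post_init__(self):
        if len(self.min_cluster_sizes) != 10:
            raise ValueError("expected 10 min_cluster_size values")


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    family: str
    parameter: object   # radius, rank, min_cluster_size, quantity, ...
    statistic: str
    units: str = ""


class FeatureRegistry:
    """Ordered, named catalogue of every emitted feature."""

    def __init__(self, entries: list[RegistryEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("registry names must be unique")
        self.entries = tuple(entries)
        self._index = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def family_counts(self) -> dict[str, int]:
        counts = {f: 0 for f in FAMILIES}
        for e in self.entries:
            counts[e.family] += 1
        return counts

    def to_json(self, path=None) -> str:
        payload = [
            {"name": e.name, "family": e.family, "parameter": e.parameter,
             "statistic": e.statistic, "units": e.units}
            for e in self.entries
        ]
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def default_registry(density: DensityConfig | None = None,
                     cluster: ClusterConfig | None = None) -> FeatureRegistry:
    """Build the standard 371-entry catalogue."""
    density = density or DensityConfig()
    cluster = cluster or ClusterConfig()
    entries: list[RegistryEntry] = []

    for m in cluster.min_cluster_sizes:
        for stat in CLUSTER_STATISTICS:
            entries.append(RegistryEntry(f"{stat}_{m}", "CLUSTER", m, stat,
                                         "um" if stat == "ICD" else ""))
    for q in VORONOI_QUANTITIES:
        for stat in STAT_NAMES:
            unit = {"VA": "um^2", "VP": "um", "VMD": "um"}[q] if stat in ("MEAN", "STD") else ""
            entries.append(RegistryEntry(f"{q}-{stat}", "VORONOI", q, stat, unit))
    for q, tag in (("edge", "DE"), ("area", "DA")):
        for stat in STAT_NAMES:
            unit = ("um" if q == "edge" else "um^2") if stat in ("MEAN", "STD") else ""
            entries.append(RegistryEntry(f"{tag}-{stat}", "DELAUNAY", q, stat, unit))
    for stat in STAT_NAMES:
        entries.append(RegistryEntry(f"MST-{stat}", "MST", "edge", stat,
                                     "um" if stat in ("MEAN", "STD") else ""))
    for i, r in enumerate(density.radii):
        for stat in STAT_NAMES:
            entries.append(RegistryEntry(f"DND-{stat}_{i}", "DENSITY", r, stat, ""))
    for i, k in enumerate(density.k_values):
        for stat in STAT_NAMES:
            entries.append(RegistryEntry(f"DDN-{stat}_{i}", "DENSITY", int(k), stat,
                                         "um" if stat in ("MEAN", "STD") else ""))
    entries.append(RegistryEntry("TIL-FREQ", "FREQUENCY", None, "COUNT_PER_MM2", "1/mm^2"))
    return FeatureRegistry(entries)
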