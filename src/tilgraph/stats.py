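"""Summary statistics shared by every spatial feature family.

Each family reduces a per-object quantity (edge length, cell area, neighbor
count, ...) to four scalars: mean, population standard deviation, min-max
ratio, and disorder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STAT_NAMES = ("MEAN", "STD", "MMR", "DIS")


class DegenerateInputError(ValueError):
    """Raised when a quantity cannot be computed from the given input."""


@dataclass(frozen=True)
class SummaryStats:
    """Four-number summary of a non-negative sample.

    Attributes
    ----------
    mean : float
        Arithmetic mean.
    std : float
        Population standard deviation (ddof=0).
    mmr : float
        Min-max ratio ``min/max``; defined as 0 when ``max == 0``.
    disorder : float
        ``std / (mean + std)``; defined as 0 when both are 0. Lies in [0, 1).
    """

    mean: float
    std: float
    mmr: float
    disorder: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mean, self.std, self.mmr, self.disorder)


def summary_stats(values) -> SummaryStats:
    """Reduce a non-empty sequence of non-negative reals to :class:`SummaryStats`.

    Raises
    ------
    DegenerateInputError
        If ``values`` is empty.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("summary_stats requires a non-empty sample")
    mean = float(arr.mean())
    std = float(arr.std(ddof=0))
    mx = float(arr.max())
    mmr = float(arr.min()) / mx if mx > 0 else 0.0
    denom = mean + std
    disorder = std / denom if denom > 0 else 0.0
    return SummaryStats(mean=mean, std=std, mmr=mmr, disorder=disorder)
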