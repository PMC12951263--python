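"""Empirical extreme-centile cut-off derivation.

Centiles of each marker are split into twenty 5-point bins; within each
bin the percentage frequency among abnormal-karyotype cases is divided by
the percentage frequency among normal-karyotype cases.  The bin with the
highest defined ratio names the marker's cut-off: an extreme low bin gives
a "below" threshold at its upper edge, an extreme high bin an
"at-or-above" threshold at its lower edge.

Bins are half-open ``[lo, hi)`` with a closed final bin ``[95, 100]``.
Bins where the normal group has zero mass are excluded from the maximum
search (the ratio is undefined there, and an infinite ratio driven by a
single case would be unstable); ties break toward the lower bin index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .biometry import Marker

__all__ = ["CentileHistogram", "CutoffSpec", "bin_centiles", "frequency_ratio", "derive_cutoff"]

BIN_EDGES = tuple(range(0, 105, 5))  # 0, 5, ..., 100 -> 20 bins
N_BINS = len(BIN_EDGES) - 1


@dataclass(frozen=True)
class CentileHistogram:
    marker: Marker
    counts_normal: tuple[int, ...]
    counts_abnormal: tuple[int, ...]
    bin_edges: tuple[int, ...] = BIN_EDGES

    @property
    def n_normal(self) -> int:
        return int(sum(self.counts_normal))

    @property
    def n_abnormal(self) -> int:
        return int(sum(self.counts_abnormal))


@dataclass(frozen=True)
class CutoffSpec:
    """A derived or preselected extreme-centile threshold.

    ``direction="below"`` flags centiles strictly less than ``threshold``;
    ``direction="at_or_above"`` flags centiles greater than or equal to it.
    """

    marker: Marker
    threshold: float
    direction: str  # "below" | "at_or_above"
    ratio: float = math.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", Marker(self.marker))
        if self.direction not in ("below", "at_or_above"):
            raise ValueError(f"direction must be 'below' or 'at_or_above', got {self.direction!r}")

    def is_extreme(self, centile: float) -> bool:
        if self.direction == "below":
            return centile < self.threshold
        return centile >= self.threshold


def _bin_index(centile: float) -> int:
    if not 0.0 <= centile <= 100.0:
        raise ValueError(f"centile {centile} outside [0, 100]")
    return min(int(centile // 5), N_BINS - 1)


def bin_centiles(
    marker: Marker, centiles_normal: Sequence[float], centiles_abnormal: Sequence[float]
) -> CentileHistogram:
    """Histogram both karyotype groups' centiles into the 5-point bins."""
    if len(centiles_normal) == 0 or len(centiles_abnormal) == 0:
        raise ValueError("both karyotype groups must be non-empty")

    def count(vals):
        counts = np.zeros(N_BINS, dtype=int)
        for v in vals:
            counts[_bin_index(float(v))] += 1
        return tuple(int(c) for c in counts)

    return CentileHistogram(
        marker=Marker(marker),
        counts_normal=count(centiles_normal),
        counts_abnormal=count(centiles_abnormal),
    )


def frequency_ratio(hist: CentileHistogram, bin_index: int) -> float:
    """Abnormal-group percentage frequency over normal-group percentage
    frequency in one bin; NaN where the normal-group frequency is zero."""
    if hist.counts_normal[bin_index] == 0:
        return math.nan
    p_abn = hist.counts_abnormal[bin_index] / hist.n_abnormal
    p_norm = hist.counts_normal[bin_index] / hist.n_normal
    return p_abn / p_norm


def derive_cutoff(hist: CentileHistogram) -> CutoffSpec:
    """Select the maximum-ratio bin and translate it into a cut-off.

    The winning ``[0, 5)`` bin yields ``(5, below)``, the winning
    ``[95, 100]`` bin yields ``(95, at_or_above)``; an interior winner
    below the median bin yields ``below`` at its upper edge, otherwise
    ``at_or_above`` at its lower edge.  Undefined ratios are skipped and
    ties resolve to the lower bin index.
    """
    ratios = [frequency_ratio(hist, i) for i in range(N_BINS)]
    best, best_ratio = None, -math.inf
    for i, r in enumerate(ratios):
        if not math.isnan(r) and r > best_ratio:
            best, best_ratio = i, r
    if best is None:
        raise ValueError("no bin has a defined frequency ratio; cannot derive a cut-off")
    lo, hi = hist.bin_edges[best], hist.bin_edges[best + 1]
    if best < N_BINS / 2:
        return CutoffSpec(hist.marker, float(hi), "below", best_ratio)
    return CutoffSpec(hist.marker, float(lo), "at_or_above", best_ratio)
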