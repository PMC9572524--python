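"""The pRRx family on a quantized threshold grid.

pRRx is the percentage of adjacent RR-interval pairs whose absolute
difference is at least x ms (pNN50 is the sinus-rhythm special case at
x = 50 ms).  Because R-wave locations are quantized to ECG samples, every
measurable RR difference is a multiple of the sampling period
Δ = 1000/fs ms, so only thresholds x_k = k·Δ are distinguishable; the
grid enumerates k = 1..k_max.  At the 128 Hz of long-term Holter
recordings this gives x from 7.8125 to 195.3125 ms in 7.8125 ms steps.

Threshold comparison is performed in integer sample units (|ΔRR|/Δ ≥ k),
never in floating-point milliseconds, so exact-multiple boundary cases
cannot flip with rounding error.  Parameter names use the integer part of
x (``pRR7`` for 7.8125 ms).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Segment

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdGrid",
    "UndefinedFeatureError",
    "build_grid",
    "compute_prrx",
    "feature_matrix",
    "META_COLUMNS",
]

#: Non-feature columns of a pRRx feature table.
META_COLUMNS = ("record_id", "start_time_ms", "label")


class UndefinedFeatureError(ValueError):
    """Raised when a segment has no valid adjacent pair to difference."""


@dataclass(frozen=True)
class ThresholdGrid:
    """Quantized pRRx thresholds x_k = k·Δ, Δ = 1000/fs ms, k = 1..k_max."""

    fs: float
    k_max: int

    @property
    def delta_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def k_values(self) -> np.ndarray:
        return np.arange(1, self.k_max + 1)

    @property
    def x_ms(self) -> np.ndarray:
        return self.k_values * self.delta_ms

    @property
    def names(self) -> list[str]:
        """Column names using the integer part of x, e.g. ``pRR7``."""
        return [f"pRR{math.floor(x)}" for x in self.x_ms]

    def __len__(self) -> int:
        return self.k_max

    def name_of(self, x_ms: float) -> str:
        """Name of the grid threshold matching *x_ms* exactly."""
        k = self.k_of(x_ms)
        return f"pRR{math.floor(k * self.delta_ms)}"

    def k_of(self, x_ms: float) -> int:
        """Grid index k of an exact threshold value."""
        k = round(x_ms / self.delta_ms)
        if not (1 <= k <= self.k_max) or abs(k * self.delta_ms - x_ms) > 1e-9:
            raise ValueError(f"{x_ms} ms is not on the grid (fs={self.fs})")
        return int(k)

    def equivalent_x(self, x_ms: float) -> float:
        """Grid threshold classifying identically to an off-grid *x_ms*.

        Measured differences are multiples of Δ, so every threshold in
        (kΔ − Δ, kΔ] selects the same pairs as kΔ: the equivalent is
        ⌈x/Δ⌉·Δ (e.g. 50 ms -> 54.6875 ms at 128 Hz).
        """
        k = int(np.ceil(round(x_ms / self.delta_ms, 9)))
        if not 1 <= k <= self.k_max:
            raise ValueError(f"{x_ms} ms has no equivalent on the grid")
        return float(k * self.delta_ms)

    def nearest_x(self, x_ms: float) -> float:
        """Nearest representable grid threshold; exact midpoints resolve
        toward the smaller x."""
        k = int(np.clip(np.floor(x_ms / self.delta_ms + 0.5), 1, self.k_max))
        lower = int(np.clip(np.floor(x_ms / self.delta_ms), 1, self.k_max))
        if abs(x_ms - lower * self.delta_ms) == abs(x_ms - k * self.delta_ms):
            k = lower
        return float(k * self.delta_ms)


def build_grid(fs: float, k_max: int) -> ThresholdGrid:
    """Build the quantized threshold grid for sampling rate *fs*."""
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    return ThresholdGrid(fs=float(fs), k_max=int(k_max))


def _diffs_in_samples(segment: Segment) -> np.ndarray:
    """Absolute successive differences in sample units, valid (gap-free)
    pairs only.

    Annotation-derived RR values are exact multiples of Δ, so these are
    integers up to float rounding; the caller compares them against
    ``k - eps`` so an exact k-sample difference always counts.
    """
    delta = 1000.0 / segment.fs
    d = np.abs(np.diff(segment.rr_ms)) / delta
    valid = ~segment.gap_after[:-1]
    return d[valid]


def compute_prrx(segment: Segment, grid: ThresholdGrid) -> pd.Series:
    """pRRx of one segment at every grid threshold, in percent.

    A pair of intervals is valid only when no beat between them was
    removed (``gap_after`` false).  pRRx = 100 · #{valid pairs with
    |ΔRR| ≥ x} / #valid pairs, with the comparison done in sample units.
    """
    if abs(segment.fs - grid.fs) > 1e-9:
        raise ValueError(
            f"segment fs {segment.fs} does not match grid fs {grid.fs}"
        )
    d = _diffs_in_samples(segment)
    n = len(d)
    if n == 0:
        raise UndefinedFeatureError(
            f"segment {segment.record_id}@{segment.start_time_ms:g} has no "
            "valid adjacent pair"
        )
    d_sorted = np.sort(d)
    # fraction of diffs >= k, via one searchsorted per grid threshold;
    # the eps guard keeps exact k-sample differences inclusive
    counts = n - np.searchsorted(d_sorted, grid.k_values - 1e-9, side="left")
    values = 100.0 * counts / n
    return pd.Series(values, index=grid.names, dtype=float)


def feature_matrix(segments: list[Segment], grid: ThresholdGrid) -> pd.DataFrame:
    """One pRRx row per accepted segment.

    Segments without a valid pair are dropped (count logged).  Columns:
    ``record_id``, ``start_time_ms``, ``label``, then one column per grid
    threshold.
    """
    rows = []
    meta = []
    dropped = 0
    for seg in segments:
        try:
            rows.append(compute_prrx(seg, grid))
        except UndefinedFeatureError:
            dropped += 1
            continue
        meta.append((seg.record_id, seg.start_time_ms, seg.label))
    if dropped:
        logger.info("feature_matrix: dropped %d segment(s) with no valid pair",
                    dropped)
    if not rows:
        return pd.DataFrame(columns=list(META_COLUMNS) + grid.names)
    out = pd.DataFrame(meta, columns=list(META_COLUMNS))
    out = pd.concat([out, pd.DataFrame(rows).reset_index(drop=True)], axis=1)
    return out
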