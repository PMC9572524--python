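"""Cutting RR series into rhythm-pure 60-s segments and filtering them.

The preprocessing chain mirrors standard tachogram hygiene for AF/SR
discrimination studies:

1. keep only uninterrupted runs of a single rhythm (SR or AF) lasting at
   least 60 s;
2. cut each run into consecutive, non-overlapping 60-s windows (a trailing
   remainder shorter than the window is dropped);
3. within each window remove implausible intervals (< 240 ms or > 3000 ms),
   technical artifacts, ventricular-premature intervals (both rhythms) and
   supraventricular-premature intervals (SR only);
4. discard the window entirely when the removed intervals total more than
   6 s.

Removal sites are marked with ``gap_after`` flags so that downstream
successive-difference statistics never pair two intervals that were not
adjacent in the recording.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .io import RRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "Rejection",
    "SegmentationConfig",
    "extract_pure_fragments",
    "segment_fragment",
    "apply_filters",
    "segment_series",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Windowing and filter settings.

    ``max_excluded_ms`` is a strict budget: a segment is rejected only when
    the removed intervals *exceed* it.  ``strict_purity`` switches to the
    conservative reading in which any ectopic beat (non-sinus in SR, or
    ventricular in AF) rejects the whole segment outright.
    """

    window_s: float = 60.0
    min_duration_s: float = 60.0
    min_rr_ms: float = 240.0
    max_rr_ms: float = 3000.0
    max_excluded_ms: float = 6000.0
    strict_purity: bool = False


@dataclass
class Segment:
    """One rhythm-pure window of retained RR intervals.

    ``gap_after[i]`` is True when the interval retained after ``i`` was not
    its neighbour in the original series (an interval in between was
    removed), so the pair (i, i+1) must not contribute a successive
    difference.
    """

    record_id: str
    start_time_ms: float
    label: str  # "AF" or "SR"
    fs: float
    rr_ms: np.ndarray
    gap_after: np.ndarray = None
    excluded_ms: float = 0.0
    n_removed: int = 0
    beat_type: np.ndarray = None  # pre-filter candidates carry beat codes

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.gap_after is None:
            self.gap_after = np.zeros(len(self.rr_ms), dtype=bool)
        else:
            self.gap_after = np.asarray(self.gap_after, dtype=bool)
        if self.beat_type is not None:
            self.beat_type = np.asarray(self.beat_type, dtype="U1")
        if self.label not in ("AF", "SR"):
            raise ValueError(f"label must be 'AF' or 'SR', got {self.label!r}")
        if len(self.gap_after) != len(self.rr_ms):
            raise ValueError("gap_after must match rr_ms in length")

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def n_valid_pairs(self) -> int:
        """Number of adjacent interval pairs not broken by a gap."""
        if len(self.rr_ms) < 2:
            return 0
        return int((~self.gap_after[:-1]).sum())


@dataclass(frozen=True)
class Rejection:
    """Returned instead of a Segment when a candidate fails the filters."""

    record_id: str
    start_time_ms: float
    label: str
    reason: str  # excess_exclusion | empty_after_filtering | impure


def extract_pure_fragments(
    series: RRSeries, min_duration_s: float = 60.0
) -> list[tuple[int, int]]:
    """Find maximal constant-rhythm runs of at least *min_duration_s*.

    Returns half-open index ranges ``(start, end)`` into ``series.rr_ms``.
    Runs whose rhythm is neither SR nor AF are dropped, as are runs whose
    summed RR duration falls short of the minimum.
    """
    n = len(series)
    if n == 0:
        return []
    rhythm = series.rhythm
    # run boundaries where the rhythm annotation changes
    change = np.flatnonzero(rhythm[1:] != rhythm[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    min_ms = min_duration_s * 1000.0
    out = []
    for s, e in zip(starts, ends):
        if rhythm[s] in ("SR", "AF") and series.rr_ms[s:e].sum() >= min_ms:
            out.append((int(s), int(e)))
    return out


def segment_fragment(
    series: RRSeries,
    fragment: tuple[int, int],
    window_s: float = 60.0,
) -> list[Segment]:
    """Cut a rhythm-pure fragment into consecutive *window_s* windows.

    Window boundaries run on cumulative RR time from the fragment start.
    An interval belongs to the window containing its terminating beat
    (an interval ending exactly on a boundary closes the earlier window).
    A trailing remainder shorter than the window is dropped.
    """
    s, e = fragment
    rr = series.rr_ms[s:e]
    if len(rr) == 0:
        return []
    label = str(series.rhythm[s])
    w_ms = window_s * 1000.0
    t_end = np.cumsum(rr)  # terminating-beat time of each interval
    total = t_end[-1]
    n_windows = int(total // w_ms)
    # window of each interval: ceil(t/w) - 1, i.e. (w*(k), w*(k+1)] -> k
    widx = np.ceil(t_end / w_ms).astype(int) - 1
    start_offset = series.rr_ms[:s].sum()
    out = []
    for w in range(n_windows):
        mask = widx == w
        if not mask.any():
            continue
        sel = np.flatnonzero(mask)
        out.append(
            Segment(
                record_id=series.record_id,
                start_time_ms=float(start_offset + w * w_ms),
                label=label,
                fs=series.fs,
                rr_ms=rr[sel],
                beat_type=series.beat_type[s:e][sel],
            )
        )
    return out


def apply_filters(
    candidate: Segment, config: SegmentationConfig = SegmentationConfig()
) -> Segment | Rejection:
    """Apply interval-level exclusions; reject over-edited segments.

    Removes intervals outside ``[min_rr_ms, max_rr_ms]``, artifact
    intervals, ventricular-premature intervals (both labels) and
    supraventricular-premature intervals (SR only).  Each removal site sets
    ``gap_after`` on the preceding retained interval.  The candidate is
    rejected when the removed intervals total more than
    ``max_excluded_ms``, or when nothing usable remains.
    """
    rr = candidate.rr_ms
    bt = (
        candidate.beat_type
        if candidate.beat_type is not None
        else np.full(len(rr), "N", dtype="U1")
    )
    if config.strict_purity:
        impure = (bt == "V") if candidate.label == "AF" else (bt != "N")
        if impure.any():
            return Rejection(
                candidate.record_id, candidate.start_time_ms,
                candidate.label, "impure",
            )

    remove = (rr < config.min_rr_ms) | (rr > config.max_rr_ms) | (bt == "A") | (bt == "V")
    if candidate.label == "SR":
        remove |= bt == "S"

    excluded_ms = float(rr[remove].sum())
    n_removed = int(remove.sum())
    if excluded_ms > config.max_excluded_ms:
        return Rejection(
            candidate.record_id, candidate.start_time_ms,
            candidate.label, "excess_exclusion",
        )
    keep = np.flatnonzero(~remove)
    if len(keep) < 2:
        return Rejection(
            candidate.record_id, candidate.start_time_ms,
            candidate.label, "empty_after_filtering",
        )
    # a gap opens wherever the next retained interval is not the original
    # neighbour
    gap_after = np.zeros(len(keep), dtype=bool)
    gap_after[:-1] = np.diff(keep) != 1
    return replace(
        candidate,
        rr_ms=rr[keep],
        gap_after=gap_after,
        excluded_ms=excluded_ms,
        n_removed=n_removed,
        beat_type=bt[keep],
    )


def segment_series(
    series_list: RRSeries | list[RRSeries],
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[list[Segment], Counter]:
    """Full chain: fragments -> windows -> filters, over one or many series.

    Returns the accepted segments plus a tally of rejection reasons
    (including ``short_remainder`` counts implicitly dropped by windowing).
    """
    if isinstance(series_list, RRSeries):
        series_list = [series_list]
    accepted: list[Segment] = []
    tally: Counter = Counter()
    for series in series_list:
        for frag in extract_pure_fragments(series, config.min_duration_s):
            for cand in segment_fragment(series, frag, config.window_s):
                result = apply_filters(cand, config)
                if isinstance(result, Rejection):
                    tally[result.reason] += 1
                else:
                    accepted.append(result)
                    tally["accepted"] += 1
    logger.info(
        "segmentation: %d accepted, rejections: %s",
        len(accepted),
        {k: v for k, v in tally.items() if k != "accepted"} or "none",
    )
    return accepted, tally
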