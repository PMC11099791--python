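"""Heart-rate, pause, and corrected-RMSSD variables.

These are the screening numbers a cardiologist reads off a 24-hour
Holter report: average and minimum heart rate, time spent under
50 bpm, sinus-pause counts above 2/3/4 s, the longest pause, and a
single rate-corrected short-term variability index (cRMSSD).  They are
computed over the whole recording and, separately, over an
automatically selected "stable/sleep" window between 22:00 and 07:00.

Pause statistics assume escape beats were already merged away
(:func:`exitblock.core.merge_nonsinus`), so every interval is a true
sinus-to-sinus duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time as dtime
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .core import RRSeries

__all__ = [
    "HRMetrics",
    "SleepWindow",
    "basic_metrics",
    "crmssd",
    "select_sleep_window",
    "slice_by_clock",
]

#: Default pause thresholds, seconds.
PAUSE_THRESHOLDS_S = (2.0, 3.0, 4.0)

#: Sleep search span: 22:00 to 07:00 (wraps midnight).
SLEEP_SPAN = (22, 7)


@dataclass
class HRMetrics:
    """One row of Holter heart-rate summary statistics."""

    avg_hr: float  # bpm
    avg_rr: float  # ms
    min_hr: float  # bpm, lowest 60-s rolling mean
    time_below_50: float  # minutes with per-minute mean HR < 50 bpm
    n_pauses_gt2: int
    n_pauses_gt3: int
    n_pauses_gt4: int
    longest_pause: float  # s
    crmssd: float  # dimensionless (RMSSD / mean RR)

    def to_row(self) -> dict:
        """Column names matching the standard Holter report layout."""
        return {
            "Average HR (bpm)": self.avg_hr,
            "Average RR interval (ms)": self.avg_rr,
            "Minimum HR (bpm)": self.min_hr,
            "Time <50 bpm (min)": self.time_below_50,
            "Number of pauses >2 s": self.n_pauses_gt2,
            "Number of pauses >3 s": self.n_pauses_gt3,
            "Number of pauses >4 s": self.n_pauses_gt4,
            "Longest pause (s)": self.longest_pause,
            "cRMSSD (ms)": self.crmssd,
        }


@dataclass
class SleepWindow:
    """A contiguous whole-hour window inside the 22:00-07:00 span."""

    start_clock: dtime
    end_clock: dtime
    duration_h: int

    def __post_init__(self) -> None:
        if not 1 <= self.duration_h <= 6:
            raise ValueError("sleep window duration must be 1-6 hours")


def crmssd(series: RRSeries) -> float:
    """Heart-rate-corrected RMSSD.

    RMSSD = sqrt(mean((RR_{i+1} - RR_i)^2)) over successive sinus
    intervals, divided by the mean RR interval.  The division removes
    the strong dependence of raw RMSSD on prevailing cycle length, so
    slow-rhythm recordings are comparable with fast ones.
    """
    rr = series.intervals
    if rr.size < 2:
        raise ValueError("crmssd requires at least 2 intervals")
    diffs = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    return rmssd / float(np.mean(rr))


def _rolling_min_hr(rr: np.ndarray, window_ms: float = 60_000.0) -> float:
    """Minimum heart rate = 60000 / (max mean RR over a sliding 60 s
    window of interval ends).  Two-pointer sweep, O(n)."""
    ends = np.cumsum(rr)
    csum = np.concatenate([[0.0], ends])
    max_mean = 0.0
    lo = 0
    for hi in range(rr.size):
        while ends[hi] - ends[lo] > window_ms:
            lo += 1
        mean = (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)
        if mean > max_mean:
            max_mean = mean
    return 60000.0 / max_mean


def _time_below_50(rr: np.ndarray, threshold_bpm: float = 50.0) -> float:
    """Minutes whose per-minute mean heart rate is below threshold.

    The recording is cut into consecutive 60 s bins of elapsed time and
    each bin's mean instantaneous rate (time-weighted 60000/RR) is
    compared with the threshold; long pauses spanning whole minutes
    count those minutes as slow.
    """
    total_ms = float(rr.sum())
    n_bins = int(np.ceil(total_ms / 60_000.0))
    if n_bins == 0:
        return 0.0
    rate_sum = np.zeros(n_bins)  # integral of instantaneous rate, per bin
    occupied = np.zeros(n_bins)
    starts = np.concatenate([[0.0], np.cumsum(rr)[:-1]])
    for start, dur in zip(starts, rr):
        rate = 60000.0 / dur
        end = start + dur
        b0 = int(start // 60_000.0)
        b1 = int(np.ceil(end / 60_000.0))
        for b in range(b0, b1):
            lo = max(start, b * 60_000.0)
            hi = min(end, (b + 1) * 60_000.0)
            overlap = hi - lo
            rate_sum[b] += rate * overlap
            occupied[b] += overlap
    mask = occupied > 0
    mean_rate = np.full(n_bins, np.nan)
    mean_rate[mask] = rate_sum[mask] / occupied[mask]
    return float(np.sum(mean_rate[mask] < threshold_bpm))


def basic_metrics(
    series: RRSeries, pause_thresholds_s: Sequence[float] = PAUSE_THRESHOLDS_S
) -> HRMetrics:
    """Compute the full heart-rate summary for one recording.

    Pauses are intervals *strictly* exceeding each threshold; the
    longest pause is simply the longest interval.  Average HR follows
    the beats-per-elapsed-time convention (60000·n / ΣRR), which equals
    60000 / mean RR.
    """
    rr = series.intervals
    if rr.size == 0:
        raise ValueError("basic_metrics requires a non-empty series")
    avg_rr = float(np.mean(rr))
    counts = [int(np.sum(rr > th * 1000.0)) for th in pause_thresholds_s]
    return HRMetrics(
        avg_hr=60000.0 / avg_rr,
        avg_rr=avg_rr,
        min_hr=_rolling_min_hr(rr),
        time_below_50=_time_below_50(rr),
        n_pauses_gt2=counts[0],
        n_pauses_gt3=counts[1],
        n_pauses_gt4=counts[2],
        longest_pause=float(np.max(rr)) / 1000.0,
        crmssd=crmssd(series) if rr.size >= 2 else 0.0,
    )


def _span_hours(span: Tuple[int, int]) -> list[int]:
    """Clock hours covered by the span, in span order (wraps midnight)."""
    start, end = span
    hours = []
    h = start
    while h != end:
        hours.append(h)
        h = (h + 1) % 24
    return hours


def select_sleep_window(
    series: RRSeries,
    span: Tuple[int, int] = SLEEP_SPAN,
    max_hours: int = 6,
    cv_threshold: float = 0.5,
    pause_threshold_s: float = 2.0,
) -> SleepWindow:
    """Pick the stable/sleep window inside 22:00-07:00.

    Candidate windows are every contiguous run of 1 to ``max_hours``
    whole clock hours inside the span that the recording covers.  Each
    is scored by ``rank(low mean HR) + rank(high pause count)`` minus a
    disqualifying penalty when the hour-to-hour coefficient of
    variation of mean RR exceeds ``cv_threshold`` (a proxy for the
    visual "pattern stability" check).  Ties break to the earlier start
    and then the longer duration, so a featureless recording yields the
    full window starting at 22:00.
    """
    if series.start_clock is None:
        raise ValueError("sleep window selection requires a clock anchor")
    hours_in_span = _span_hours(span)
    clock_s = series.clock_seconds()
    hour_of_day = (clock_s // 3600.0).astype(int)

    # Per-clock-hour aggregates over the whole recording.
    hour_stats: dict[int, tuple[float, int, float]] = {}  # hour -> (mean RR, pauses, coverage ms)
    for h in hours_in_span:
        m = hour_of_day == h
        if not np.any(m):
            continue
        rr_h = series.intervals[m]
        hour_stats[h] = (
            float(np.mean(rr_h)),
            int(np.sum(rr_h > pause_threshold_s * 1000.0)),
            float(np.sum(rr_h)),
        )

    # An hour counts as covered if at least half of it was recorded.
    covered = [h for h in hours_in_span if h in hour_stats and hour_stats[h][2] >= 1.8e6]
    if not covered:
        raise ValueError("recording does not cover at least 1 hour of the sleep span")

    offsets = {h: i for i, h in enumerate(hours_in_span)}
    cov_offsets = sorted(offsets[h] for h in covered)

    candidates = []  # (start_offset, duration, mean_hr, pauses, cv)
    for i, start_off in enumerate(cov_offsets):
        for dur in range(1, max_hours + 1):
            wanted = [start_off + k for k in range(dur)]
            if not all(o in cov_offsets for o in wanted):
                break
            hrs = [hours_in_span[o] for o in wanted]
            means = np.array([hour_stats[h][0] for h in hrs])
            weights = np.array([hour_stats[h][2] / hour_stats[h][0] for h in hrs])  # beat counts
            mean_rr = float(np.average(means, weights=weights))
            pauses = sum(hour_stats[h][1] for h in hrs)
            cv = float(np.std(means) / np.mean(means)) if dur > 1 else 0.0
            candidates.append((start_off, dur, 60000.0 / mean_rr, pauses, cv))

    hr_rank = rankdata([-c[2] for c in candidates])  # lowest HR -> highest rank
    pause_rank = rankdata([c[3] for c in candidates])  # most pauses -> highest rank
    penalty = (len(candidates) + 1.0) * np.array([c[4] > cv_threshold for c in candidates])
    scores = hr_rank + pause_rank - penalty

    # Deterministic tie-break: earlier start, then longer duration.
    order = sorted(
        range(len(candidates)), key=lambda i: (-scores[i], candidates[i][0], -candidates[i][1])
    )
    best = candidates[order[0]]
    start_h = hours_in_span[best[0]]
    end_h = (start_h + best[1]) % 24
    return SleepWindow(start_clock=dtime(start_h, 0), end_clock=dtime(end_h, 0), duration_h=best[1])


def slice_by_clock(series: RRSeries, window: SleepWindow) -> RRSeries:
    """Sub-series of intervals whose ends fall inside the window
    (handles midnight wrap)."""
    clock_s = series.clock_seconds()
    start = window.start_clock.hour * 3600 + window.start_clock.minute * 60
    end = window.end_clock.hour * 3600 + window.end_clock.minute * 60
    if start < end:
        m = (clock_s >= start) & (clock_s < end)
    else:
        m = (clock_s >= start) | (clock_s < end)
    return RRSeries(
        intervals=series.intervals[m],
        start_clock=window.start_clock,
        label=series.label,
    )
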