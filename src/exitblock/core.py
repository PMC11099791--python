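"""Core domain types and RR-interval file handling.

Everything downstream works on :class:`RRSeries` — an ordered run of
sinus beat-to-beat intervals in milliseconds, optionally anchored to a
time of day and labeled with one of the three rhythm diagnoses.  The RR
interval stands in for the sinus PP interval, so escape (non-sinus)
beats must be merged away before pause statistics mean anything; see
:func:`merge_nonsinus`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import time as dtime
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Diagnosis",
    "CLASS_ORDER",
    "RRSeries",
    "IntervalTriple",
    "read_rr_file",
    "write_rr_file",
    "merge_nonsinus",
    "extract_triples",
    "to_bpm",
    "nearest_multiple",
]


class Diagnosis(Enum):
    """The three rhythm classes, in the fixed order used everywhere.

    BALANCED — balanced autonomic modulation (normal).
    HPLSM — high-parasympathetic / low-sympathetic modulation, a
    physiologic slow rhythm that mimics disease.
    SND — sinus node dysfunction with the interval-clustering pattern of
    sinoatrial exit block.
    """

    BALANCED = 0
    HPLSM = 1
    SND = 2

    @property
    def short(self) -> str:
        return self.name.lower()


#: Fixed class ordering shared by confusion matrices and tie-breaks.
CLASS_ORDER = (Diagnosis.BALANCED, Diagnosis.HPLSM, Diagnosis.SND)

_NAME_TO_DIAGNOSIS = {d.name.lower(): d for d in Diagnosis}
_NAME_TO_DIAGNOSIS.update({"hp/lsm": Diagnosis.HPLSM, "normal": Diagnosis.BALANCED})


def parse_diagnosis(name: Union[str, Diagnosis]) -> Diagnosis:
    """Map a label string (``balanced``/``hplsm``/``snd``, case-insensitive)
    to a :class:`Diagnosis`."""
    if isinstance(name, Diagnosis):
        return name
    try:
        return _NAME_TO_DIAGNOSIS[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown diagnosis label: {name!r}") from None


class IntervalTriple(NamedTuple):
    """Three consecutive RR intervals — the classification unit."""

    rr1: float
    rr2: float
    rr3: float


@dataclass
class RRSeries:
    """Ordered sinus beat-to-beat intervals in milliseconds.

    Parameters
    ----------
    intervals
        Positive, finite interval durations in ms, in recording order.
    start_clock
        Optional time of day at which the recording (first interval)
        starts.  Cumulative interval sums give elapsed time, so clock
        times wrap past midnight.
    beat_flags
        Optional per-interval booleans; ``True`` marks an interval that
        is *terminated* by a non-sinus (escape) beat.  The recording's
        very first beat is assumed sinus.
    label
        Optional recording-level diagnosis.
    """

    intervals: np.ndarray
    start_clock: Optional[dtime] = None
    beat_flags: Optional[np.ndarray] = None
    label: Optional[Diagnosis] = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and (
            not np.all(np.isfinite(self.intervals)) or np.any(self.intervals <= 0)
        ):
            raise ValueError("all intervals must be positive and finite")
        if self.beat_flags is not None:
            self.beat_flags = np.asarray(self.beat_flags, dtype=bool)
            if self.beat_flags.shape != self.intervals.shape:
                raise ValueError("beat_flags must match intervals in length")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_ms(self) -> float:
        """Total elapsed recording time (sum of intervals)."""
        return float(self.intervals.sum())

    def elapsed_ms(self) -> np.ndarray:
        """End-of-interval timestamps relative to the recording start."""
        return np.cumsum(self.intervals)

    def clock_seconds(self) -> np.ndarray:
        """Seconds-of-day of each interval end, wrapping at midnight.

        Requires ``start_clock``.
        """
        if self.start_clock is None:
            raise ValueError("series has no clock anchor")
        t0 = (
            self.start_clock.hour * 3600
            + self.start_clock.minute * 60
            + self.start_clock.second
            + self.start_clock.microsecond / 1e6
        )
        return (t0 + self.elapsed_ms() / 1000.0) % 86400.0

    def replace(self, **kwargs) -> "RRSeries":
        return replace(self, **kwargs)


def _parse_clock(token: str, lineno: int) -> dtime:
    token = token.strip()
    parts = token.split(":")
    try:
        if len(parts) != 3:
            raise ValueError
        h, m = int(parts[0]), int(parts[1])
        sec = float(parts[2])
        s = int(sec)
        us = int(round((sec - s) * 1e6))
        return dtime(h, m, s, us)
    except ValueError:
        raise ValueError(f"line {lineno}: cannot parse clock time {token!r}") from None


def _format_clock(seconds_of_day: float) -> str:
    seconds_of_day = seconds_of_day % 86400.0
    h = int(seconds_of_day // 3600)
    m = int((seconds_of_day % 3600) // 60)
    s = seconds_of_day % 60
    return f"{h:02d}:{m:02d}:{s:06.3f}"


def _parse_ms(token: str, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"line {lineno}: non-numeric interval {token!r}") from None
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"line {lineno}: interval must be > 0, got {token!r}")
    return value


def read_rr_file(
    source: Union[str, Path], dialect: str = "plain", label: Optional[Diagnosis] = None
) -> RRSeries:
    """Read an RR-interval export.

    ``plain`` dialect: one interval (ms) per line; a trailing ``*``
    marks the beat ending that interval as non-sinus.  ``csv`` dialect:
    ``clock-time,interval-ms`` rows (``HH:MM:SS.mmm`` 24-hour clock),
    optional ``time,interval_ms`` header.  Blank lines are skipped.

    ``source`` may be a filesystem path or the file content itself (a
    string containing a newline is always treated as content).
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = str(source)

    if dialect not in ("plain", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")

    intervals: list[float] = []
    flags: list[bool] = []
    start_clock: Optional[dtime] = None
    prev_clock: Optional[float] = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if dialect == "plain":
            flagged = line.endswith("*")
            if flagged:
                line = line[:-1].strip()
            intervals.append(_parse_ms(line, lineno))
            flags.append(flagged)
        else:
            fields = [f.strip() for f in line.split(",")]
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected clock,interval columns")
            if lineno == 1 and not _looks_numeric(fields[1]):
                continue  # header row
            clock = _parse_clock(fields[0], lineno)
            value = _parse_ms(fields[1], lineno)
            clock_s = (
                clock.hour * 3600 + clock.minute * 60 + clock.second + clock.microsecond / 1e6
            )
            if start_clock is None:
                start_clock = clock
            intervals.append(value)
            flags.append(len(fields) > 2 and fields[2] == "*")
            prev_clock = clock_s

    beat_flags = np.array(flags, dtype=bool) if any(flags) else None
    return RRSeries(
        intervals=np.array(intervals, dtype=float),
        start_clock=start_clock,
        beat_flags=beat_flags,
        label=label,
    )


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _format_ms(value: float) -> str:
    # Holter exports are integer ms; the simulator is continuous.
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_rr_file(
    series: RRSeries, path: Optional[Union[str, Path]] = None, dialect: str = "plain"
) -> str:
    """Serialize a series in the named dialect; returns the text and,
    if ``path`` is given, writes it there.  Integer-valued intervals are
    emitted without a decimal point; fractional ones round-trip exactly."""
    lines: list[str] = []
    if dialect == "plain":
        for i, value in enumerate(series.intervals):
            star = "*" if series.beat_flags is not None and series.beat_flags[i] else ""
            lines.append(_format_ms(value) + star)
    elif dialect == "csv":
        start = series.start_clock or dtime(0, 0, 0)
        t = start.hour * 3600 + start.minute * 60 + start.second + start.microsecond / 1e6
        for i, value in enumerate(series.intervals):
            star = ",*" if series.beat_flags is not None and series.beat_flags[i] else ""
            lines.append(f"{_format_clock(t)},{_format_ms(value)}{star}")
            t += value / 1000.0
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def merge_nonsinus(series: RRSeries) -> RRSeries:
    """Merge intervals separated by escape beats into true sinus pauses.

    Each interval flagged as terminated by a non-sinus beat is summed
    into the following interval, so the result spans sinus beat to sinus
    beat and total elapsed time is conserved.  A flag on the final
    interval has no following sinus beat; that accumulated tail is
    dropped with a warning.
    """
    if series.beat_flags is None:
        raise ValueError("merge_nonsinus requires beat_flags")
    merged: list[float] = []
    acc = 0.0
    for value, flagged in zip(series.intervals, series.beat_flags):
        acc += value
        if not flagged:
            merged.append(acc)
            acc = 0.0
    if acc > 0.0:
        logger.warning(
            "final beat is non-sinus; dropping unpaired boundary interval of %.0f ms", acc
        )
    return RRSeries(
        intervals=np.array(merged, dtype=float),
        start_clock=series.start_clock,
        beat_flags=None,
        label=series.label,
    )


def extract_triples(series_or_intervals) -> np.ndarray:
    """Overlapping 3-interval windows, as an ``(n-2, 3)`` array.

    Row ``i`` is ``(RR_i, RR_i+1, RR_i+2)``; an interior interval
    therefore appears in three consecutive rows — the "rolling interval
    appraisal" unit used by both classifiers.  Fewer than three
    intervals yield an empty array.
    """
    if isinstance(series_or_intervals, RRSeries):
        intervals = series_or_intervals.intervals
    else:
        intervals = np.asarray(series_or_intervals, dtype=float)
    n = intervals.size
    if n < 3:
        return np.empty((0, 3), dtype=float)
    return np.lib.stride_tricks.sliding_window_view(intervals, 3).copy()


def to_bpm(interval_ms: float) -> float:
    """Instantaneous rate (beats/min) of one interval."""
    return 60000.0 / interval_ms


def nearest_multiple(interval_ms: float, base_ms: float) -> int:
    """Nearest integer exit-block ratio: how many base sinus cycles a
    conducted interval spans (e.g. 2633 ms on a 660 ms base -> 4)."""
    return int(round(interval_ms / base_ms))
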