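"""Poincaré-plot cluster quantification and tachogram preparation.

A Poincaré plot scatters each RR interval (x) against its successor
(y).  Runs of linear rate change lie on the line of identity (LOI,
y = x); exit-block clustering shows up as dense "arms" off the line at
integer multiples of the base cycle.  Four measurements summarize the
cluster geometry:

* shortest and longest interval on the line of identity,
* their difference (the beat-to-beat range of linear rate change),
* the shortest horizontal deviation — the lowest y value at which the
  point cloud leaves the line of identity (the minimum bifurcation
  interval).

Cluster boundaries were judged visually in the original workflow; here
they are operationalized with a band half-width around the LOI and a
per-bin density floor, both configurable and reported alongside any
metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import RRSeries

__all__ = [
    "PoincarePoints",
    "ClusterMetrics",
    "loi_band",
    "cluster_metrics",
    "tachogram_data",
    "plot_tachogram",
    "plot_poincare",
]

#: Half-width of the line-of-identity band, ms.
DEFAULT_BAND_HALFWIDTH = 40.0
#: Density-histogram bin width along either axis, ms.
DEFAULT_BIN_WIDTH = 20.0
#: Relative per-bin density floor (fraction of all plotted points).
DEFAULT_MIN_DENSITY_FRACTION = 0.001


@dataclass
class PoincarePoints:
    """The (RR_i, RR_i+1) point set of one recording."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    @classmethod
    def from_series(cls, series: RRSeries) -> "PoincarePoints":
        rr = series.intervals
        return cls(x=rr[:-1], y=rr[1:])

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass
class ClusterMetrics:
    shortest_loi: float
    longest_loi: float
    range_loi: float
    shortest_horizontal_deviation: float  # nan when no dense off-line arm exists


def loi_band(points: PoincarePoints, band_halfwidth: float = DEFAULT_BAND_HALFWIDTH) -> np.ndarray:
    """Boolean mask of points within ``|y - x| <= band_halfwidth``."""
    if band_halfwidth <= 0:
        raise ValueError("band_halfwidth must be positive")
    return np.abs(points.y - points.x) <= band_halfwidth


def _dense_mask(values: np.ndarray, bin_width: float, min_count: float) -> np.ndarray:
    """Mask of values falling in bins whose occupancy meets min_count."""
    if values.size == 0:
        return np.zeros(0, dtype=bool)
    bins = np.floor(values / bin_width).astype(np.int64)
    uniq, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    return counts[inverse] >= min_count


def cluster_metrics(
    points: PoincarePoints,
    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_density: Optional[float] = None,
) -> ClusterMetrics:
    """The four cluster measurements.

    ``min_density`` is an absolute per-bin point count; when omitted it
    defaults to 0.1 % of all plotted points, floored at 2 so an
    isolated stray point never registers as a cluster.  The extrema are
    taken over points whose bin passes the floor, mimicking the visual
    rule of reading only the dense part of the cloud.
    """
    n = len(points)
    if min_density is None:
        min_density = max(2.0, math.ceil(DEFAULT_MIN_DENSITY_FRACTION * n))

    on_line = loi_band(points, band_halfwidth)
    loi_x = points.x[on_line]
    dense_loi = _dense_mask(loi_x, bin_width, min_density)
    if not np.any(dense_loi):
        raise ValueError("no identifiable line-of-identity cluster")
    shortest = float(np.min(loi_x[dense_loi]))
    longest = float(np.max(loi_x[dense_loi]))

    off_y = points.y[~on_line]
    dense_off = _dense_mask(off_y, bin_width, min_density)
    deviation = float(np.min(off_y[dense_off])) if np.any(dense_off) else float("nan")

    return ClusterMetrics(
        shortest_loi=shortest,
        longest_loi=longest,
        range_loi=longest - shortest,
        shortest_horizontal_deviation=deviation,
    )


def tachogram_data(series: RRSeries) -> np.ndarray:
    """``(elapsed ms, interval ms)`` pairs using end-of-interval
    timestamps — the beat-interval-versus-time view of the recording."""
    rr = series.intervals
    if rr.size == 0:
        return np.empty((0, 2), dtype=float)
    return np.column_stack([np.cumsum(rr), rr])


def _class_colors(classes) -> list:
    from .core import Diagnosis

    palette = {Diagnosis.BALANCED: "green", Diagnosis.HPLSM: "blue", Diagnosis.SND: "red"}
    return [palette.get(c, "gray") for c in classes]


def plot_tachogram(series: RRSeries, path=None, classes=None, ax=None):
    """Render the tachogram (y range 100-6000 ms); per-interval class
    colors follow the green/blue/red convention when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = tachogram_data(series)
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    colors = _class_colors(classes) if classes is not None else "black"
    ax.scatter(data[:, 0] / 3.6e6, data[:, 1], s=2, c=colors)
    ax.set_xlabel("elapsed time (h)")
    ax.set_ylabel("RR interval (ms)")
    ax.set_ylim(100, 6000)
    if path is not None:
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
    return ax


def plot_poincare(points: PoincarePoints, path=None, classes=None, ax=None):
    """Render the 2-D Poincaré plot with 100-6000 ms axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    colors = _class_colors(classes) if classes is not None else "black"
    ax.scatter(points.x, points.y, s=2, c=colors)
    ax.set_xlabel("RR interval (ms)")
    ax.set_ylabel("RR +1 interval (ms)")
    ax.set_xlim(100, 6000)
    ax.set_ylim(100, 6000)
    if path is not None:
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
    return ax
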