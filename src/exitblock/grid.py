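"""The Poincaré density-grid classifier.

Labeled recordings are reduced to overlapping interval triples
(RR_i, RR_i+1, RR_i+2) and tallied into a 3-D histogram of 60 ms cubic
cells spanning [0, 6000) ms on each axis — one million cells.  A test
triple falling in a cell is assigned the class with the highest
*per-class normalized* occupancy of that cell; a triple in an empty
cell, or outside the grid altogether, receives NO_DECISION.  Unlike
the neural network, the grid never guesses: abstention is part of its
contract.

Each interval of a recording is judged in the first, second, and third
position of the rolling triple window, and the up-to-three votes are
resolved by plurality (ignoring abstentions).  Recording-level output
is the fraction of intervals per class — the "relative sureness" — and
the diagnosis is the class with the largest fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import CLASS_ORDER, Diagnosis, RRSeries, extract_triples

__all__ = [
    "OUTSIDE",
    "NO_DECISION",
    "GridModel",
    "ClassificationResult",
    "cell_index",
    "train_grid",
    "classify_triple",
    "classify_series",
    "confusion_matrix",
    "confusion_to_tsv",
]


class _Sentinel:
    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: A triple with any coordinate outside [0, axis_span).
OUTSIDE = _Sentinel("OUTSIDE")
#: Abstention: empty cell or out-of-grid triple.
NO_DECISION = _Sentinel("NO_DECISION")

N_CLASSES = len(CLASS_ORDER)


@dataclass
class GridModel:
    """Per-class triple occupancy over the cubic cell grid.

    Cells are stored sparsely: flat cell index -> per-class counts.
    ``normalized`` selects whether cell labels compare per-class
    densities (count / class total, the default) or raw counts.
    """

    cell_edge: float = 60.0
    axis_span: float = 6000.0
    counts: dict = field(default_factory=dict)  # flat index -> np.ndarray (N_CLASSES,)
    class_totals: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64))
    outside_counts: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64))
    normalized: bool = True

    @property
    def cells_per_axis(self) -> int:
        return int(round(self.axis_span / self.cell_edge))

    @property
    def n_cells(self) -> int:
        """Total number of cells in the grid (10^6 for the 60 ms /
        6000 ms geometry)."""
        return self.cells_per_axis**3

    def flatten(self, ijk: Tuple[int, int, int]) -> int:
        k = self.cells_per_axis
        return (ijk[0] * k + ijk[1]) * k + ijk[2]

    # -- persistence ---------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": "exitblock-grid-v1",
            "cell_edge": self.cell_edge,
            "axis_span": self.axis_span,
            "normalized": self.normalized,
            "classes": [d.name for d in CLASS_ORDER],
            "class_totals": self.class_totals.tolist(),
            "outside_counts": self.outside_counts.tolist(),
            "cells": {str(k): v.tolist() for k, v in self.counts.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "GridModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "exitblock-grid-v1":
            raise ValueError(f"{path}: not a grid model file")
        return cls(
            cell_edge=payload["cell_edge"],
            axis_span=payload["axis_span"],
            normalized=payload["normalized"],
            class_totals=np.array(payload["class_totals"], dtype=np.int64),
            outside_counts=np.array(payload["outside_counts"], dtype=np.int64),
            counts={int(k): np.array(v, dtype=np.int64) for k, v in payload["cells"].items()},
        )


@dataclass
class ClassificationResult:
    """Per-interval assignments plus recording-level summary."""

    interval_classes: list  # Diagnosis or NO_DECISION, one per interval
    fractions: dict  # {Diagnosis: fraction, NO_DECISION: fraction}; sums to 1

    @property
    def diagnosis(self):
        """Class with the largest interval fraction (abstentions are
        reported but excluded from the argmax); ties break by class
        order."""
        return max(CLASS_ORDER, key=lambda d: (self.fractions[d], -d.value))

    def ranked(self) -> list:
        """(class, fraction) pairs, most supported first."""
        order = sorted(CLASS_ORDER, key=lambda d: (-self.fractions[d], d.value))
        return [(d, self.fractions[d]) for d in order]


def cell_index(
    triple: Sequence[float], cell_edge: float = 60.0, axis_span: float = 6000.0
):
    """Cell coordinates of a triple, or OUTSIDE.

    Each axis is divided into half-open bins [m·edge, (m+1)·edge); any
    coordinate outside [0, axis_span) puts the whole triple off-grid.
    """
    vals = np.asarray(triple, dtype=float)
    if np.any(vals < 0) or np.any(vals >= axis_span):
        return OUTSIDE
    return tuple(int(v // cell_edge) for v in vals)


def _bin_triples(triples: np.ndarray, model: GridModel) -> Tuple[np.ndarray, np.ndarray]:
    """Flat cell indices of in-domain triples, plus the out-of-domain
    count."""
    inside = np.all((triples >= 0) & (triples < model.axis_span), axis=1)
    idx = np.floor_divide(triples[inside], model.cell_edge).astype(np.int64)
    k = model.cells_per_axis
    flat = (idx[:, 0] * k + idx[:, 1]) * k + idx[:, 2]
    return flat, int(np.sum(~inside))


def train_grid(
    labeled: Iterable[Tuple[RRSeries, Diagnosis]],
    cell_edge: float = 60.0,
    axis_span: float = 6000.0,
    normalized: bool = True,
) -> GridModel:
    """Accumulate labeled triples into a fresh grid.

    Every class must be represented by at least one recording;
    off-grid triples are tallied separately so that, per class, cell
    counts plus the outside tally equal the triples presented.
    """
    model = GridModel(cell_edge=cell_edge, axis_span=axis_span, normalized=normalized)
    seen = set()
    for series, label in labeled:
        seen.add(label)
        triples = extract_triples(series)
        if triples.shape[0] == 0:
            continue
        c = label.value
        flat, n_outside = _bin_triples(triples, model)
        model.outside_counts[c] += n_outside
        model.class_totals[c] += flat.size
        uniq, cnt = np.unique(flat, return_counts=True)
        for f, n in zip(uniq.tolist(), cnt.tolist()):
            cell = model.counts.get(f)
            if cell is None:
                cell = np.zeros(N_CLASSES, dtype=np.int64)
                model.counts[f] = cell
            cell[c] += n
    missing = [d.name for d in CLASS_ORDER if d not in seen]
    if missing:
        raise ValueError(f"training set is missing classes: {', '.join(missing)}")
    return model


def _cell_label_code(model: GridModel, flat: int) -> int:
    """Class code of one cell, or -1 for abstention."""
    cell = model.counts.get(flat)
    if cell is None:
        return -1
    if model.normalized:
        totals = np.maximum(model.class_totals, 1)
        score = cell / totals
    else:
        score = cell
    if not np.any(score > 0):
        return -1
    return int(np.argmax(score))  # first max -> fixed class order on ties


def classify_triple(model: GridModel, triple: Sequence[float]):
    """Diagnosis of a single triple, or NO_DECISION."""
    ijk = cell_index(triple, model.cell_edge, model.axis_span)
    if ijk is OUTSIDE:
        return NO_DECISION
    code = _cell_label_code(model, model.flatten(ijk))
    return NO_DECISION if code < 0 else CLASS_ORDER[code]


def _triple_votes(model: GridModel, triples: np.ndarray) -> np.ndarray:
    """Vote codes per triple: class value, or -1 for abstention."""
    flat, _ = _bin_triples(triples, model)
    inside = np.all((triples >= 0) & (triples < model.axis_span), axis=1)
    votes = np.full(triples.shape[0], -1, dtype=np.int64)
    cache: dict[int, int] = {}
    pos = 0
    for i in range(triples.shape[0]):
        if not inside[i]:
            continue
        f = int(flat[pos])
        pos += 1
        code = cache.get(f)
        if code is None:
            code = _cell_label_code(model, f)
            cache[f] = code
        votes[i] = code
    return votes


def rolling_vote(votes: np.ndarray, n_intervals: int) -> Tuple[list, dict]:
    """Resolve per-triple votes into per-interval assignments.

    Interval i inherits the votes of the (up to three) triples that
    contain it.  Assignment is the plurality class ignoring
    abstentions; exact ties break by the fixed class order; an interval
    whose every vote abstained is NO_DECISION.  Returns the assignment
    list and the fraction of intervals per outcome (summing to 1 over
    the three classes plus NO_DECISION).
    """
    n_triples = votes.size
    tallies = np.zeros((n_intervals, N_CLASSES), dtype=np.int64)
    any_vote = np.zeros(n_intervals, dtype=bool)
    for c in range(N_CLASSES):
        hit = (votes == c).astype(np.int64)
        for shift in range(3):  # triple j covers intervals j, j+1, j+2
            tallies[shift : shift + n_triples, c] += hit
    covered = np.zeros(n_intervals, dtype=np.int64)
    valid = (votes >= 0).astype(np.int64)
    for shift in range(3):
        covered[shift : shift + n_triples] += valid
    any_vote = covered > 0

    assignments: list = []
    for i in range(n_intervals):
        if not any_vote[i]:
            assignments.append(NO_DECISION)
        else:
            assignments.append(CLASS_ORDER[int(np.argmax(tallies[i]))])
    fractions = {
        d: assignments.count(d) / n_intervals for d in CLASS_ORDER
    }
    fractions[NO_DECISION] = assignments.count(NO_DECISION) / n_intervals
    return assignments, fractions


def classify_series(model: GridModel, series: RRSeries) -> ClassificationResult:
    """Classify every interval of a recording by the rolling-triple
    vote and summarize the class fractions."""
    n = len(series)
    if n < 3:
        raise ValueError("classification requires at least 3 intervals")
    votes = _triple_votes(model, extract_triples(series))
    assignments, fractions = rolling_vote(votes, n)
    return ClassificationResult(interval_classes=assignments, fractions=fractions)


def confusion_matrix(actual: Sequence[Diagnosis], predicted: Sequence[Diagnosis]) -> np.ndarray:
    """3x3 recording-level confusion counts; entry (p, a) counts
    recordings of actual class a predicted as p, so column sums equal
    the actual class sizes."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted label sequences differ in length")
    mat = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for a, p in zip(actual, predicted):
        mat[p.value, a.value] += 1
    return mat


def confusion_to_tsv(matrix: np.ndarray, path: Optional[Union[str, Path]] = None) -> str:
    """Confusion matrix as TSV with predicted classes as rows and
    actual classes as columns."""
    names = [d.name for d in CLASS_ORDER]
    df = pd.DataFrame(matrix, index=[f"predicted_{n}" for n in names],
                      columns=[f"actual_{n}" for n in names])
    text = df.to_csv(sep="\t")
    if path is not None:
        Path(path).write_text(text)
    return text
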