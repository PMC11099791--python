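"""Sine-feature shallow neural network classifier.

Each interval triple is mapped through a multiple-frequency sine
featurization — sin(2π·f_k·RR_j) for a dyadic set of frequencies plus
a linear RR_j/6000 term per interval — and fed to a three-layer
(input, hidden, output) network with rectified-linear hidden units and
a linear 3-unit output trained by mini-batch gradient descent on the
squared error against one-hot class targets.  Unlike the density
grid, the network always commits to a class: it generalizes (guesses)
in regions never seen during training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .core import CLASS_ORDER, Diagnosis, RRSeries, extract_triples
from .grid import ClassificationResult, rolling_vote

__all__ = [
    "SineFeatureMap",
    "SineNNModel",
    "featurize",
    "train_nn",
    "predict",
    "classify_series_nn",
    "loss_and_grads",
]

N_CLASSES = len(CLASS_ORDER)


@dataclass
class SineFeatureMap:
    """Frequencies (cycles per ms) of the sine featurization.

    The default is a dyadic ladder 1/(75·2^k) for k = 0..7, i.e.
    periods 75, 150, ..., 9600 ms — spanning everything from the
    fastest canine sinus cycle to the longest pauses on the grid.  The
    optional linear RR/6000 terms make the map injective on the
    [0, 6000) ms working range.
    """

    frequencies: np.ndarray = field(
        default_factory=lambda: 1.0 / (75.0 * 2.0 ** np.arange(8))
    )
    include_linear: bool = True
    axis_span: float = 6000.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)

    @property
    def n_features(self) -> int:
        k = self.frequencies.size
        return 3 * (k + (1 if self.include_linear else 0))

    def transform(self, triples: np.ndarray) -> np.ndarray:
        """Feature matrix of shape (n, 3·(K+1)); intervals are not
        clipped.  Layout: per interval position, K sine features then
        the linear term."""
        triples = np.atleast_2d(np.asarray(triples, dtype=float))
        n = triples.shape[0]
        blocks = []
        for j in range(3):
            rr = triples[:, j : j + 1]
            blocks.append(np.sin(2.0 * np.pi * rr * self.frequencies[None, :]))
            if self.include_linear:
                blocks.append(rr / self.axis_span)
        return np.hstack(blocks)


def featurize(triple: Sequence[float], fmap: Optional[SineFeatureMap] = None) -> np.ndarray:
    """Feature vector of a single triple."""
    fmap = fmap or SineFeatureMap()
    return fmap.transform(np.asarray(triple, dtype=float)[None, :])[0]


@dataclass
class SineNNModel:
    """Weights of the trained network plus its full training recipe."""

    fmap: SineFeatureMap
    w1: np.ndarray  # (n_features, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden, 3)
    b2: np.ndarray
    seed: int
    hyperparams: dict = field(default_factory=dict)
    loss_history: list = field(default_factory=list)

    def forward(self, x: np.ndarray) -> np.ndarray:
        hidden = np.maximum(x @ self.w1 + self.b1, 0.0)
        return hidden @ self.w2 + self.b2

    def scores(self, triples: np.ndarray) -> np.ndarray:
        return self.forward(self.fmap.transform(triples))

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": "exitblock-nn-v1",
            "frequencies": self.fmap.frequencies.tolist(),
            "include_linear": self.fmap.include_linear,
            "axis_span": self.fmap.axis_span,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "seed": self.seed,
            "hyperparams": self.hyperparams,
            "loss_history": self.loss_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SineNNModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "exitblock-nn-v1":
            raise ValueError(f"{path}: not a neural-network model file")
        fmap = SineFeatureMap(
            frequencies=np.array(payload["frequencies"], dtype=float),
            include_linear=payload["include_linear"],
            axis_span=payload["axis_span"],
        )
        return cls(
            fmap=fmap,
            w1=np.array(payload["w1"], dtype=float),
            b1=np.array(payload["b1"], dtype=float),
            w2=np.array(payload["w2"], dtype=float),
            b2=np.array(payload["b2"], dtype=float),
            seed=payload["seed"],
            hyperparams=payload["hyperparams"],
            loss_history=payload["loss_history"],
        )


def _loss_and_grads_raw(
    w1, b1, w2, b2, x: np.ndarray, y: np.ndarray
) -> Tuple[float, dict]:
    """Mean per-sample squared error and its analytic gradients."""
    z1 = x @ w1 + b1
    h = np.maximum(z1, 0.0)
    out = h @ w2 + b2
    resid = out - y
    loss = float(np.mean(np.sum(resid**2, axis=1)))
    n = x.shape[0]
    d_out = 2.0 * resid / n
    g_w2 = h.T @ d_out
    g_b2 = d_out.sum(axis=0)
    d_h = d_out @ w2.T
    d_z1 = d_h * (z1 > 0.0)
    g_w1 = x.T @ d_z1
    g_b1 = d_z1.sum(axis=0)
    return loss, {"w1": g_w1, "b1": g_b1, "w2": g_w2, "b2": g_b2}


def loss_and_grads(model: SineNNModel, x: np.ndarray, y: np.ndarray) -> Tuple[float, dict]:
    """Loss and analytic parameter gradients on raw feature input
    (exposed for gradient verification)."""
    return _loss_and_grads_raw(model.w1, model.b1, model.w2, model.b2, x, y)


def train_nn(
    triples: np.ndarray,
    labels: Sequence,
    fmap: Optional[SineFeatureMap] = None,
    hidden: int = 64,
    learning_rate: float = 0.01,
    epochs: int = 2000,
    batch_size: int = 256,
    seed: int = 0,
) -> SineNNModel:
    """Train the network by mini-batch gradient descent.

    ``labels`` may be :class:`Diagnosis` values or their integer codes;
    at least one triple per class is required.  Training is exactly
    reproducible for a given seed; the per-epoch mean loss trajectory
    is stored on the returned model.  A non-finite loss aborts with a
    divergence error naming the epoch.
    """
    fmap = fmap or SineFeatureMap()
    triples = np.asarray(triples, dtype=float)
    codes = np.array(
        [l.value if isinstance(l, Diagnosis) else int(l) for l in labels], dtype=np.int64
    )
    if triples.shape[0] != codes.size:
        raise ValueError("triples and labels differ in length")
    present = set(codes.tolist())
    if not all(d.value in present for d in CLASS_ORDER):
        missing = [d.name for d in CLASS_ORDER if d.value not in present]
        raise ValueError(f"training set is missing classes: {', '.join(missing)}")

    x = fmap.transform(triples)
    y = np.eye(N_CLASSES)[codes]
    n, d = x.shape

    rng = np.random.default_rng(seed)
    w1 = rng.standard_normal((d, hidden)) * np.sqrt(2.0 / d)
    b1 = np.zeros(hidden)
    w2 = rng.standard_normal((hidden, N_CLASSES)) * np.sqrt(1.0 / hidden)
    b2 = np.zeros(N_CLASSES)

    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        seen = 0
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            loss, grads = _loss_and_grads_raw(w1, b1, w2, b2, x[sel], y[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            w1 -= learning_rate * grads["w1"]
            b1 -= learning_rate * grads["b1"]
            w2 -= learning_rate * grads["w2"]
            b2 -= learning_rate * grads["b2"]
            epoch_loss += loss * sel.size
            seen += sel.size
        history.append(epoch_loss / seen)

    return SineNNModel(
        fmap=fmap,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        seed=seed,
        hyperparams={
            "hidden": hidden,
            "learning_rate": learning_rate,
            "epochs": epochs,
            "batch_size": batch_size,
        },
        loss_history=history,
    )


def predict(model: SineNNModel, triple: Sequence[float]) -> Tuple[np.ndarray, Diagnosis]:
    """Raw 3-vector of class scores and the argmax diagnosis for one
    triple.  The network never abstains."""
    scores = model.scores(np.asarray(triple, dtype=float)[None, :])[0]
    return scores, CLASS_ORDER[int(np.argmax(scores))]


def classify_series_nn(model: SineNNModel, series: RRSeries) -> ClassificationResult:
    """Rolling-triple classification of a recording, identical voting
    contract to the grid classifier except that every triple votes."""
    n = len(series)
    if n < 3:
        raise ValueError("classification requires at least 3 intervals")
    scores = model.scores(extract_triples(series))
    votes = np.argmax(scores, axis=1).astype(np.int64)
    assignments, fractions = rolling_vote(votes, n)
    return ClassificationResult(interval_classes=assignments, fractions=fractions)
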