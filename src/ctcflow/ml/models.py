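"""Trajectory phenotype classifiers.

* :class:`TrajectoryCNN` - two-branch convolutional network: position
  channels and velocity channels are processed by separate conv + pool
  stacks, concatenated, and fed to a dense head.
* :class:`TrajectoryRNN` - stacked bidirectional recurrent layers, each
  followed by batch normalization and dropout and subsampling the
  sequence, then two dense layers.
* :class:`SummaryBaseline` - logistic regression on summary features
  (mean lateral position, velocity variance, ...); a leakage guard, not
  a deep model.

Layer widths/epochs are reconstructions (the original hyper-parameters
are not public): CNN = 2 conv layers (16, 32 filters, kernel 5) with
max-pooling per branch, dense(64); RNN = 2 bidirectional layers of
hidden size 32 with batch-norm + dropout 0.3, dense(32); Adam, batch 32.
Training is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .layers import (Adam, BatchNorm, BiRNN, Conv1D, Dense, Dropout, Flatten,
                     LastTimestep, MaxPool1D, ReLU, Sequential, cross_entropy,
                     softmax)


@dataclass
class ModelSpec:
    kind: str = "cnn"                   # cnn | rnn | baseline
    n_classes: int = 2
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.3
    hidden: int = 32
    conv_filters: tuple = (16, 32)
    conv_kernel: int = 5
    dense_width: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("cnn", "rnn", "baseline"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


class _BaseClassifier:
    """Shared fit/predict loop for the numpy networks."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.history = {"train_acc": [], "val_acc": [], "loss": []}
        self._best = None

    def _build(self, input_shape):  # pragma: no cover - interface
        raise NotImplementedError

    def _forward(self, X, train=False):
        return self.net.forward(X, train=train)

    def predict_logits(self, X):
        return self._forward(X, train=False)

    def predict_proba(self, X):
        return softmax(self.predict_logits(X))

    def predict(self, X):
        return self.predict_logits(X).argmax(axis=1)

    def score(self, X, y):
        return float((self.predict(X) == y).mean())

    def fit(self, X, y, X_val=None, y_val=None):
        self._input_shape = X.shape[1:]
        self._build(X.shape[1:])
        opt = Adam(self.net.parameters(), lr=self.spec.learning_rate)
        n = len(X)
        for epoch in range(self.spec.epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, self.spec.batch_size):
                idx = order[start:start + self.spec.batch_size]
                logits = self._forward(X[idx], train=True)
                loss, grad = cross_entropy(logits, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError("non-finite training loss")
                self.net.backward(grad)
                opt.step()
                losses.append(loss)
            self.history["loss"].append(float(np.mean(losses)))
            self.history["train_acc"].append(self.score(X, y))
            if X_val is not None and len(X_val):
                va = self.score(X_val, y_val)
                self.history["val_acc"].append(va)
                if self._best is None or va >= self._best[0]:
                    self._best = (va, self._snapshot())
        if self._best is not None:
            self._restore(self._best[1])
        return self

    def _snapshot(self):
        return [p.copy() for p, _ in self.net.parameters()]

    def _restore(self, snap):
        for (p, _), s in zip(self.net.parameters(), snap):
            p[...] = s

    def save_weights(self, path) -> None:
        arrays = {f"p{k}": p for k, (p, _) in enumerate(self.net.parameters())}
        np.savez(path, input_shape=np.array(self._input_shape),
                 kind=np.array(self.spec.kind), **arrays)

    def load_weights(self, path) -> "_BaseClassifier":
        data = np.load(path, allow_pickle=False)
        if str(data["kind"]) != self.spec.kind:
            raise ValueError("weights belong to a different architecture")
        shape = tuple(int(v) for v in data["input_shape"])
        self._input_shape = shape
        self._build(shape)
        for k, (p, _) in enumerate(self.net.parameters()):
            p[...] = data[f"p{k}"]
        return self

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p, _ in self.net.parameters():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


class TrajectoryCNN(_BaseClassifier):
    """Two-branch CNN over (N, 6, T): position branch (channels 0-2) and
    velocity branch (channels 3-5) with separate conv/pool stacks."""

    def _make_branch(self, c_in):
        f1, f2 = self.spec.conv_filters
        k = self.spec.conv_kernel
        return Sequential(
            Conv1D(c_in, f1, k, self.rng), ReLU(), MaxPool1D(2),
            Conv1D(f1, f2, k, self.rng), ReLU(), MaxPool1D(2),
            Flatten(),
        )

    def _build(self, input_shape):
        C, T = input_shape
        if C != 6:
            raise ValueError("expected 6 kinematic channels")
        self.pos_branch = self._make_branch(3)
        self.vel_branch = self._make_branch(3)
        probe = np.zeros((1, 3, T))
        width = (self.pos_branch.forward(probe).shape[1]
                 + self.vel_branch.forward(probe).shape[1])
        self.head = Sequential(
            Dense(width, self.spec.dense_width, self.rng), ReLU(),
            Dropout(self.spec.dropout, self.rng),
            Dense(self.spec.dense_width, self.spec.n_classes, self.rng),
        )
        self.net = self  # Sequential-compatible facade

    # facade so _BaseClassifier can treat the branched net uniformly
    def forward(self, X, train=False):
        zp = self.pos_branch.forward(X[:, :3], train=train)
        zv = self.vel_branch.forward(X[:, 3:], train=train)
        self._wp = zp.shape[1]
        return self.head.forward(np.concatenate([zp, zv], axis=1), train=train)

    def backward(self, grad):
        g = self.head.backward(grad)
        gp = self.pos_branch.backward(g[:, :self._wp])
        gv = self.vel_branch.backward(g[:, self._wp:])
        return np.concatenate([gp, gv], axis=1)

    def parameters(self):
        yield from self.pos_branch.parameters()
        yield from self.vel_branch.parameters()
        yield from self.head.parameters()


class TrajectoryRNN(_BaseClassifier):
    """Stacked bidirectional recurrent layers with batch-norm + dropout."""

    def _build(self, input_shape):
        C, T = input_shape
        H = self.spec.hidden
        self.net = Sequential(
            BiRNN(C, H, self.rng, stride=2),
            BatchNorm(2 * H), Dropout(self.spec.dropout, self.rng),
            BiRNN(2 * H, H, self.rng, stride=2),
            BatchNorm(2 * H), Dropout(self.spec.dropout, self.rng),
            LastTimestep(),
            Dense(2 * H, self.spec.hidden, self.rng), ReLU(),
            Dense(self.spec.hidden, self.spec.n_classes, self.rng),
        )


def summary_features(X: np.ndarray) -> np.ndarray:
    """Per-trajectory summary statistics (N, 6, T) -> (N, F)."""
    feats = [
        X.mean(axis=2),            # per-channel means (6)
        X.std(axis=2),             # per-channel variability (6)
        X[:, :, -1] - X[:, :, 0],  # net change per channel (6)
    ]
    return np.concatenate(feats, axis=1)


class SummaryBaseline(_BaseClassifier):
    """Logistic-regression sanity baseline on summary features."""

    def _build(self, input_shape):
        self._built_for = input_shape
        probe = np.zeros((1, *input_shape))
        width = summary_features(probe).shape[1]
        self.net = Sequential(Dense(width, self.spec.n_classes, self.rng))

    def _forward(self, X, train=False):
        return self.net.forward(summary_features(X), train=train)


_MODELS = {"cnn": TrajectoryCNN, "rnn": TrajectoryRNN,
           "baseline": SummaryBaseline}


def make_classifier(spec: ModelSpec) -> _BaseClassifier:
    if spec.kind == "baseline":
        # a linear model on ~18 features wants a much larger step than the
        # deep nets; only override values the user left at the generic default
        defaults = ModelSpec()
        if spec.learning_rate == defaults.learning_rate:
            spec = replace(spec, learning_rate=5e-2)
        if spec.epochs == defaults.epochs:
            spec = replace(spec, epochs=200)
    return _MODELS[spec.kind](spec)


def train_classifier(splits, spec: ModelSpec):
    """Train per the spec on assembled splits; returns (model, history).

    ``splits`` is an :class:`ctcflow.ml.data.AssembledData`. The returned
    model carries the best-validation-accuracy weights.
    """
    model = make_classifier(spec)
    model.fit(splits.train.X, splits.train.y, splits.val.X, splits.val.y)
    return model, model.history
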