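"""Feed-forward cancer-score network.

A deliberately small multi-layer perceptron: normalized site depths enter the
input layer, pass through two hidden layers of 64 rectified-linear units, and
a two-way softmax output trained with cross-entropy for a fixed number of
epochs (120 by default) using Adam.  The positive-class softmax probability
is the cancer score.

Everything is plain numpy with an explicit seed: identical configuration and
data give bitwise-identical weights and scores, which the cross-validation
reproducibility contract relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DNNConfig:
    hidden_layers: tuple[int, ...] = (64, 64)
    epochs: int = 120
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be >= 1")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class CancerScoreNet:
    """Two-hidden-layer ReLU network with softmax output.

    Features are standardized with statistics of the training data only, so
    a fitted network never leaks information from samples it scores.
    """

    config: DNNConfig = field(default_factory=DNNConfig)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CancerScoreNet":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("degenerate training set: only one class present")
        if not np.array_equal(classes, np.array([0, 1])):
            raise ValueError("labels must be 0/1")
        n, d = X.shape
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        Xs = (X - self._mu) / self._sd

        sizes = [d, *cfg.hidden_layers, 2]
        self._W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self._b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

        mW = [np.zeros_like(w) for w in self._W]
        vW = [np.zeros_like(w) for w in self._W]
        mb = [np.zeros_like(b) for b in self._b]
        vb = [np.zeros_like(b) for b in self._b]
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = cfg.learning_rate
        t = 0
        onehot = np.eye(2)[y]
        self.loss_trajectory_: list[float] = []
        for _epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                xb, yb = Xs[idx], onehot[idx]
                acts = [xb]
                h = xb
                for W, b in zip(self._W[:-1], self._b[:-1]):
                    h = np.maximum(h @ W + b, 0.0)
                    acts.append(h)
                logits = h @ self._W[-1] + self._b[-1]
                p = _softmax(logits)
                losses.append(
                    float(-np.mean(np.sum(yb * np.log(p + 1e-12), axis=1)))
                )
                delta = (p - yb) / len(idx)
                grads_W, grads_b = [], []
                for li in range(len(self._W) - 1, -1, -1):
                    grads_W.append(acts[li].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if li > 0:
                        delta = (delta @ self._W[li].T) * (acts[li] > 0)
                grads_W.reverse()
                grads_b.reverse()
                t += 1
                for li in range(len(self._W)):
                    mW[li] = b1 * mW[li] + (1 - b1) * grads_W[li]
                    vW[li] = b2 * vW[li] + (1 - b2) * grads_W[li] ** 2
                    mb[li] = b1 * mb[li] + (1 - b1) * grads_b[li]
                    vb[li] = b2 * vb[li] + (1 - b2) * grads_b[li] ** 2
                    mhW = mW[li] / (1 - b1**t)
                    vhW = vW[li] / (1 - b2**t)
                    mhb = mb[li] / (1 - b1**t)
                    vhb = vb[li] / (1 - b2**t)
                    self._W[li] -= lr * mhW / (np.sqrt(vhW) + eps)
                    self._b[li] -= lr * mhb / (np.sqrt(vhb) + eps)
            self.loss_trajectory_.append(float(np.mean(losses)))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "_W"):
            raise RuntimeError("model is not fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self._W[0].shape[0]:
            raise ValueError(
                f"feature dimension mismatch: model expects {self._W[0].shape[0]}, "
                f"got {X.shape[1]}"
            )
        h = (X - self._mu) / self._sd
        for W, b in zip(self._W[:-1], self._b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return _softmax(h @ self._W[-1] + self._b[-1])

    def cancer_score(self, X: np.ndarray) -> np.ndarray:
        """Softmax probability of the positive (cancer) class."""
        return self.predict_proba(X)[:, 1]
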