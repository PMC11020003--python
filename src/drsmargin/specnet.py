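"""SpecNet: a five-layer 1D convolutional network for spectral classification.

Architecture: input (n1 bands) -> C1, a valid stride-1 convolution with 20
kernels of length k1 and ReLU (n2 = n1 - k1 + 1) -> M2, non-overlapping
max-pooling of width k2 (n3 = floor(n2 / k2)) -> F3, a fully connected ReLU
layer of width n4 -> softmax output with n5 = 2 nodes. Trainable parameter
counts per block are therefore 20*(k1+1), (20*n3+1)*n4 and (n4+1)*n5.

Implemented directly in numpy (forward and backward passes, Adam,
cross-entropy loss, early stopping on validation loss); the network is small
enough that vectorised einsum convolutions train in seconds on a CPU.
Deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SpecNetConfig", "SpecNetDescriptor", "SpecNet", "build_specnet"]

N_FILTERS = 20  # fixed filter count of the C1 layer


@dataclass(frozen=True)
class SpecNetConfig:
    """Architecture and training hyperparameters.

    n1 is the number of spectral bands (1922 on the default analysis grid);
    k1 the convolution kernel length, k2 the pooling width, n4 the fully
    connected width, n5 the number of output nodes (binary -> 2).
    """

    n1: int = 1922
    k1: int = 11
    k2: int = 2
    n4: int = 64
    n5: int = 2
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 >= self.n1:
            raise ValueError("conv kernel k1 must be shorter than the input n1")
        if min(self.n1, self.k1, self.k2, self.n4) < 1 or self.n5 != 2:
            raise ValueError("invalid SpecNet configuration")
        if self.n2 < self.k2:
            raise ValueError("pooling width k2 exceeds the convolution output")

    @property
    def n2(self) -> int:
        return self.n1 - self.k1 + 1

    @property
    def n3(self) -> int:
        return self.n2 // self.k2


@dataclass
class SpecNetDescriptor:
    """Ordered layer listing with per-block trainable parameter counts."""

    layers: list[dict] = field(default_factory=list)

    @property
    def total_parameters(self) -> int:
        return sum(l["parameters"] for l in self.layers)

    def __str__(self) -> str:
        rows = [f"{'layer':<10}{'output':>14}{'parameters':>12}"]
        for l in self.layers:
            rows.append(f"{l['name']:<10}{str(l['output_shape']):>14}{l['parameters']:>12}")
        rows.append(f"{'total':<10}{'':>14}{self.total_parameters:>12}")
        return "\n".join(rows)


def build_specnet(config: SpecNetConfig) -> SpecNetDescriptor:
    """Describe the network a config instantiates, with parameter counts."""
    c = config
    return SpecNetDescriptor(
        layers=[
            {"name": "input", "output_shape": (c.n1, 1), "parameters": 0},
            {
                "name": "C1",
                "output_shape": (N_FILTERS, c.n2),
                "parameters": N_FILTERS * (c.k1 + 1),
                "activation": "relu",
            },
            {"name": "M2", "output_shape": (N_FILTERS, c.n3), "parameters": 0},
            {
                "name": "F3",
                "output_shape": (c.n4,),
                "parameters": (N_FILTERS * c.n3 + 1) * c.n4,
                "activation": "relu",
            },
            {
                "name": "output",
                "output_shape": (c.n5,),
                "parameters": (c.n4 + 1) * c.n5,
                "activation": "softmax",
            },
        ]
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SpecNet:
    """Trainable SpecNet classifier with an sklearn-like surface."""

    def __init__(self, config: SpecNetConfig | None = None):
        self.config = config or SpecNetConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        he = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.W1 = he(c.k1, (N_FILTERS, c.k1))
        self.b1 = np.zeros(N_FILTERS)
        self.W3 = he(N_FILTERS * c.n3, (N_FILTERS * c.n3, c.n4))
        self.b3 = np.zeros(c.n4)
        self.W4 = he(c.n4, (c.n4, c.n5))
        self.b4 = np.zeros(c.n5)
        self._rng = rng
        self.classes_ = np.array([0, 1])
        self.history_: list[dict] = []

    # -- introspection -------------------------------------------------------

    def parameter_counts(self) -> dict[str, int]:
        """Counts of the instantiated arrays, block by block."""
        return {
            "C1": self.W1.size + self.b1.size,
            "F3": self.W3.size + self.b3.size,
            "output": self.W4.size + self.b4.size,
        }

    # -- forward / backward --------------------------------------------------

    def _forward(self, X: np.ndarray, cache: bool = False):
        c = self.config
        Xw = sliding_window_view(X, c.k1, axis=1)  # (N, n2, k1)
        z1 = np.einsum("nik,fk->nfi", Xw, self.W1, optimize=True) + self.b1[:, None]
        a1 = np.maximum(z1, 0.0)
        pool_in = a1[:, :, : c.n3 * c.k2].reshape(X.shape[0], N_FILTERS, c.n3, c.k2)
        arg = pool_in.argmax(axis=3)
        pooled = np.take_along_axis(pool_in, arg[..., None], axis=3)[..., 0]
        flat = pooled.reshape(X.shape[0], N_FILTERS * c.n3)
        z3 = flat @ self.W3 + self.b3
        a3 = np.maximum(z3, 0.0)
        z4 = a3 @ self.W4 + self.b4
        p = _softmax(z4)
        if not cache:
            return p
        return p, (Xw, z1, arg, flat, z3, a3)

    def _backward(self, X, y_onehot, p, caches):
        c = self.config
        Xw, z1, arg, flat, z3, a3 = caches
        n = X.shape[0]
        dz4 = (p - y_onehot) / n
        dW4 = a3.T @ dz4
        db4 = dz4.sum(axis=0)
        da3 = dz4 @ self.W4.T
        dz3 = da3 * (z3 > 0)
        dW3 = flat.T @ dz3
        db3 = dz3.sum(axis=0)
        dflat = dz3 @ self.W3.T
        dpool = dflat.reshape(n, N_FILTERS, c.n3)
        da1 = np.zeros((n, N_FILTERS, c.n2))
        da1_view = da1[:, :, : c.n3 * c.k2].reshape(n, N_FILTERS, c.n3, c.k2)
        np.put_along_axis(da1_view, arg[..., None], dpool[..., None], axis=3)
        dz1 = da1 * (z1 > 0)
        dW1 = np.einsum("nfi,nik->fk", dz1, Xw, optimize=True)
        db1 = dz1.sum(axis=(0, 2))
        return [dW1, db1, dW3, db3, dW4, db4]

    # -- training ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SpecNet":
        """Train with Adam and early stopping.

        A validation split of ``val_fraction`` (seeded, stratification-free)
        monitors the loss; with ``val_fraction=0`` the training loss is
        monitored instead. The best weights seen are restored at the end.
        """
        c = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training data must contain both classes")
        if X.shape[1] != c.n1:
            raise ValueError(f"expected {c.n1} spectral bands, got {X.shape[1]}")
        idx = self._rng.permutation(X.shape[0])
        n_val = int(round(c.val_fraction * X.shape[0]))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if np.unique(y[tr_idx]).size < 2:  # tiny sets: skip the split
            tr_idx, val_idx = idx, idx[:0]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        params = [self.W1, self.b1, self.W3, self.b3, self.W4, self.b4]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss, best_weights, since_best = np.inf, None, 0
        for epoch in range(c.epochs):
            order = self._rng.permutation(Xtr.shape[0])
            for start in range(0, Xtr.shape[0], c.batch_size):
                batch = order[start : start + c.batch_size]
                Xb, yb = Xtr[batch], ytr[batch]
                p, caches = self._forward(Xb, cache=True)
                onehot = np.eye(c.n5)[yb]
                grads = self._backward(Xb, onehot, p, caches)
                t += 1
                for i, (prm, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**t)
                    vhat = v[i] / (1 - beta2**t)
                    prm -= c.learning_rate * mhat / (np.sqrt(vhat) + eps)
            monitor_X, monitor_y = (Xval, yval) if Xval.size else (Xtr, ytr)
            loss = self._loss(monitor_X, monitor_y)
            self.history_.append(
                {"epoch": epoch, "loss": loss, "train_accuracy": self.score(Xtr, ytr)}
            )
            if loss < best_loss - 1e-6:
                best_loss = loss
                best_weights = [p.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best >= c.patience:
                    break
        if best_weights is not None:
            self.W1, self.b1, self.W3, self.b3, self.W4, self.b4 = best_weights
        return self

    def _loss(self, X, y) -> float:
        p = self.predict_proba(X)
        return float(-np.log(np.clip(p[np.arange(y.size), y], 1e-12, None)).mean())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for start in range(0, X.shape[0], 256):
            out.append(self._forward(X[start : start + 256]))
        return np.vstack(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())
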