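"""Minimal numpy neural-network trainer for the nonlinear enrichment models.

Implements exactly what the nonlinear scorers need: a 1-D convolution over
sequence positions, ReLU, global max-pooling, dense layers, Adam, an L1
penalty on all weight matrices (subgradient), and early stopping on a
held-out validation split. Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, d, l1: float):
        self.dW = self._x.T @ d + l1 * np.sign(self.W)
        self.db = d.sum(axis=0)
        return d @ self.W.T

    params = ("W", "b")
    penalized = ("W",)


class ReLU:
    params = ()

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d, l1):
        return d * self._mask


class Conv1D:
    """Valid 1-D convolution over positions of an (N, L, A) one-hot tensor."""

    params = ("W", "b")
    penalized = ("W",)

    def __init__(self, alphabet: int, kernel: int, channels: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        n_in = kernel * alphabet
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, channels))
        self.b = np.zeros(channels)

    def forward(self, x):  # x: (N, L, A)
        N, L, A = x.shape
        K = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)
        # win: (N, P, A, K) -> (N, P, K*A)
        self._win = win.transpose(0, 1, 3, 2).reshape(N, L - K + 1, K * A)
        return self._win @ self.W + self.b  # (N, P, C)

    def backward(self, d, l1):  # d: (N, P, C)
        N, P, C = d.shape
        flat_win = self._win.reshape(N * P, -1)
        self.dW = flat_win.T @ d.reshape(N * P, C) + l1 * np.sign(self.W)
        self.db = d.sum(axis=(0, 1))
        return None  # input gradient not needed (first layer)


class GlobalMaxPool:
    """Max over the position axis of an (N, P, C) activation."""

    params = ()

    def forward(self, x):
        self._idx = x.argmax(axis=1)  # (N, C)
        self._shape = x.shape
        return np.take_along_axis(x, self._idx[:, None, :], axis=1)[:, 0, :]

    def backward(self, d, l1):
        out = np.zeros(self._shape)
        np.put_along_axis(out, self._idx[:, None, :], d[:, None, :], axis=1)
        return out


class Network:
    def __init__(self, layers, l1: float):
        self.layers = layers
        self.l1 = l1

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0] if x.ndim == 2 and x.shape[1] == 1 else x

    def backward(self, d):
        if d.ndim == 1:
            d = d[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d, self.l1)

    def get_params(self):
        return [
            (layer, name) for layer in self.layers for name in layer.params
        ]

    def state(self):
        return [getattr(layer, name).copy() for layer, name in self.get_params()]

    def load_state(self, state):
        for (layer, name), value in zip(self.get_params(), state):
            setattr(layer, name, value.copy())


def make_cnn(length: int, alphabet: int, rng, l1: float,
             kernel: int = 5, channels: int = 32, hidden: int = 64) -> Network:
    return Network(
        [
            Conv1D(alphabet, kernel, channels, rng),
            ReLU(),
            GlobalMaxPool(),
            Dense(channels, hidden, rng),
            ReLU(),
            Dense(hidden, 1, rng),
        ],
        l1=l1,
    )


def make_mlp(n_in: int, rng, l1: float, hidden: int = 64) -> Network:
    return Network(
        [Dense(n_in, hidden, rng), ReLU(), Dense(hidden, 1, rng)], l1=l1
    )


def _loss_and_grad(z, y, task):
    if task == "classification":
        # binary cross-entropy with logits; stable softplus
        loss = np.mean(np.logaddexp(0.0, z) - y * z)
        grad = (1.0 / (1.0 + np.exp(-z)) - y) / len(z)
    else:
        r = z - y
        loss = np.mean(r * r)
        grad = 2.0 * r / len(z)
    return loss, grad


def train(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    epochs: int,
    seed: int,
    lr: float = 1e-3,
    batch_size: int = 256,
    val_fraction: float = 0.1,
    patience: int = 20,
) -> float:
    """Adam training with early stopping; returns the best validation loss.

    The validation split is a seeded random 1−val_fraction / val_fraction
    partition by sequence. The network is left holding the best-validation
    parameters.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n >= 10 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], np.asarray(y, dtype=float)[tr_idx]
    Xval, yval = X[val_idx], np.asarray(y, dtype=float)[val_idx]

    params = net.get_params()
    m = [np.zeros_like(getattr(l, name)) for l, name in params]
    v = [np.zeros_like(getattr(l, name)) for l, name in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_val = np.inf
    best_state = net.state()
    stale = 0

    for _ in range(epochs):
        order = rng.permutation(len(ytr))
        for start in range(0, len(ytr), batch_size):
            idx = order[start : start + batch_size]
            z = net.forward(Xtr[idx])
            _, grad = _loss_and_grad(z, ytr[idx], task)
            net.backward(grad)
            t += 1
            for k, (layer, name) in enumerate(params):
                g = getattr(layer, "d" + name)
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mh = m[k] / (1 - beta1**t)
                vh = v[k] / (1 - beta2**t)
                setattr(
                    layer, name,
                    getattr(layer, name) - lr * mh / (np.sqrt(vh) + eps),
                )
        if n_val:
            val_loss, _ = _loss_and_grad(net.forward(Xval), yval, task)
        else:
            val_loss, _ = _loss_and_grad(net.forward(Xtr), ytr, task)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = net.state()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if epochs > 0:
        net.load_state(best_state)
    return float(best_val) if np.isfinite(best_val) else float("nan")
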