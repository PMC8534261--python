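"""A numpy 1-D convolutional network classifier for spectral channels.

Architecture (for an input of ``n_freq`` samples by C channels):
three convolutional layers of 24, 48 and 48 kernels with receptive
field 5 and same padding, each followed by batch normalization and
ReLU; max-pooling of size 2 (stride 2) after the first two; then two
fully connected layers (default width 128, then one unit per class)
with dropout 0.5 between them and a softmax output.  Trained with Adam
at a constant learning rate (default 1e-4) on mini-batches.

Everything — initialization, batch order, dropout masks — is driven by
a single seeded generator, so training is bit-reproducible.  The
estimator follows the sklearn protocol (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) and accepts either a flat
``(n, n_freq * C)`` matrix (concatenated channel blocks) or an already
stacked ``(n, n_freq, C)`` array.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["Conv1dNetClassifier"]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _Conv1dSame:
    """1-D convolution with same zero padding over (N, L, Cin) input."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.k = k

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, length, c_in = x.shape
        pad = self.k // 2
        xp = np.zeros((n, length + 2 * pad, c_in))
        xp[:, pad:pad + length] = x
        cols = np.stack([xp[:, i:i + length] for i in range(self.k)], axis=2)
        return cols.reshape(n, length, self.k * c_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, length, c_in = self._x_shape
        flat_cols = self._cols.reshape(-1, self.W.shape[0])
        flat_dout = dout.reshape(-1, self.W.shape[1])
        self.dW = flat_cols.T @ flat_dout
        self.db = flat_dout.sum(axis=0)
        dcols = (dout @ self.W.T).reshape(n, length, self.k, c_in)
        pad = self.k // 2
        dxp = np.zeros((n, length + 2 * pad, c_in))
        for i in range(self.k):
            dxp[:, i:i + length] += dcols[:, :, i]
        return dxp[:, pad:pad + length]

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class _BatchNorm:
    """Per-channel batch normalization over the (N, L) axes."""

    def __init__(self, c: int, momentum: float = 0.9):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = 1e-5

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean) / self._std
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.run_mean) / np.sqrt(self.run_var + self.eps) + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m = dout.shape[0] * dout.shape[1]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 1))
        self.dbeta = dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 1)) / m
        ) / self._std

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    """Max pooling of size 2, stride 2 along the length axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        self._in_len = length
        l2 = length // 2
        xr = x[:, : 2 * l2].reshape(n, l2, 2, c)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, l2, c = dout.shape
        dxr = np.zeros((n, l2, 2, c))
        ni, li, ci = np.ogrid[:n, :l2, :c]
        dxr[ni, li, self._argmax, ci] = dout
        dx = np.zeros((n, self._in_len, c))
        dx[:, : 2 * l2] = dxr.reshape(n, 2 * l2, c)
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Conv1dNetClassifier(ClassifierMixin, BaseEstimator):
    """Seeded, deterministic 1-D convnet over multi-channel spectra.

    Parameters
    ----------
    n_frequencies : int
        Grid length per channel; a flat input row of width
        ``n_frequencies * C`` is reshaped to ``C`` channels.
    conv_channels : tuple of int
        Kernel counts of the three convolutional layers.
    kernel_size : int
        Receptive field of every convolutional layer.
    dense_units : int
        Width of the hidden fully connected layer.
    epochs, batch_size, learning_rate, dropout : training knobs.
    random_state : int or None
        Seeds initialization, batch shuffling and dropout.
    """

    def __init__(
        self,
        n_frequencies: int = 25,
        conv_channels: tuple[int, int, int] = (24, 48, 48),
        kernel_size: int = 5,
        dense_units: int = 128,
        epochs: int = 200,
        batch_size: int = 128,
        learning_rate: float = 1e-4,
        dropout: float = 0.5,
        random_state: int | None = None,
    ):
        self.n_frequencies = n_frequencies
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.random_state = random_state

    # -- input handling ----------------------------------------------------
    def _stack(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        nf = self.n_frequencies
        if X.ndim == 3:
            if X.shape[1] != nf:
                raise ValueError(f"expected (n, {nf}, C), got {X.shape}")
            return X
        if X.ndim == 2:
            if X.shape[1] % nf != 0:
                raise ValueError(
                    f"flat width {X.shape[1]} is not a multiple of n_frequencies={nf}"
                )
            c = X.shape[1] // nf
            return X.reshape(X.shape[0], c, nf).swapaxes(1, 2)
        raise ValueError("X must be 2-D or 3-D")

    # -- forward pass ------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        for conv, bn, relu, pool in self._blocks:
            x = conv.forward(x)
            x = bn.forward(x, train)
            x = relu.forward(x)
            if pool is not None:
                x = pool.forward(x)
        self._flat_shape = x.shape
        x = x.reshape(x.shape[0], -1)
        x = self._fc1.forward(x)
        x = self._fc_relu.forward(x)
        if train and self.dropout > 0.0:
            self._drop_mask = (rng.random(x.shape) >= self.dropout) / (1.0 - self.dropout)
            x = x * self._drop_mask
        x = self._fc2.forward(x)
        return x

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self._fc2.backward(dlogits)
        if self.dropout > 0.0:
            d = d * self._drop_mask
        d = self._fc_relu.backward(d)
        d = self._fc1.backward(d)
        d = d.reshape(self._flat_shape)
        for conv, bn, relu, pool in reversed(self._blocks):
            if pool is not None:
                d = pool.backward(d)
            d = relu.backward(d)
            d = bn.backward(d)
            d = conv.backward(d)

    # -- sklearn protocol --------------------------------------------------
    def fit(self, X, y):
        Xs = self._stack(X)
        y = np.asarray(y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(self.random_state)
        n, length, c_in = Xs.shape
        self.n_features_in_ = X.shape[1] if np.asarray(X).ndim == 2 else length

        c1, c2, c3 = self.conv_channels
        k = self.kernel_size
        self._blocks = [
            (_Conv1dSame(c_in, c1, k, rng), _BatchNorm(c1), _ReLU(), _MaxPool2()),
            (_Conv1dSame(c1, c2, k, rng), _BatchNorm(c2), _ReLU(), _MaxPool2()),
            (_Conv1dSame(c2, c3, k, rng), _BatchNorm(c3), _ReLU(), None),
        ]
        flat_dim = (length // 2 // 2) * c3
        self._fc1 = _Dense(flat_dim, self.dense_units, rng)
        self._fc_relu = _ReLU()
        self._fc2 = _Dense(self.dense_units, n_classes, rng)

        layers = [blk for group in self._blocks for blk in group[:2]] + [
            self._fc1, self._fc2
        ]
        params = [p for lay in layers for p in lay.params]
        opt = _Adam(params, self.learning_rate)

        onehot = np.eye(n_classes)[codes]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self._forward(Xs[idx], train=True, rng=rng)
                p = _softmax(logits)
                dlogits = (p - onehot[idx]) / idx.size
                self._backward(dlogits)
                opt.step([g for lay in layers for g in lay.grads])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        logits = self._forward(self._stack(X), train=False)
        return _softmax(logits)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
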