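"""Minimal numpy neural-network layers used by the base and meta learners.

Forward/backward passes are written explicitly; optimization is Adam
(first/second moment estimates with bias correction) optionally under a
cosine-annealing learning-rate schedule.  Everything is seeded through a
``numpy.random.Generator`` so training is bit-reproducible on one machine.
"""

from __future__ import annotations

import numpy as np

EPS_BN = 1e-5


def cosine_lr(t_cur: float, t_max: float, lr_min: float, lr_max: float) -> float:
    """Cosine-annealed learning rate.

    lr(t) = lr_min + 0.5 * (lr_max - lr_min) * (1 + cos(pi * t/T_max));
    lr(0) = lr_max and lr(T_max) = lr_min.
    """
    if not (0 <= t_cur <= t_max):
        raise ValueError(f"t_cur={t_cur} outside [0, {t_max}]")
    if lr_min > lr_max:
        raise ValueError("lr_min > lr_max")
    return lr_min + 0.5 * (lr_max - lr_min) * (1 + np.cos(np.pi * t_cur / t_max))


def cross_entropy(p_hat: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy; predictions clamped to [eps, 1-eps]."""
    p_hat = np.clip(np.asarray(p_hat, dtype=float), eps, 1 - eps)
    p = np.asarray(p, dtype=float)
    return float(-np.mean(p * np.log(p_hat) + (1 - p) * np.log(1 - p_hat)))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V for 2-D token matrices."""
    Q, K, V = (np.atleast_2d(np.asarray(m, dtype=float)) for m in (Q, K, V))
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of rows")
    if Q.shape[1] != K.shape[1]:
        raise ValueError("Q and K widths differ")
    d_k = K.shape[1]
    weights = softmax(Q @ K.T / np.sqrt(d_k), axis=-1)
    return weights @ V


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w, np.zeros(n_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    """Batch normalization over the batch (and, for 3-D input, length) axis.

    Accepts (N, F) feature matrices or (N, C, L) channel maps; learns a scale
    and shift per feature/channel and keeps running estimates for inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.1) -> None:
        super().__init__()
        self.params = [np.ones(n_features), np.zeros(n_features)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, train):
        axes, shape = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + EPS_BN).reshape(shape)
        self._xhat = (x - mean.reshape(shape)) / self._std
        self._train = train
        return self.params[0].reshape(shape) * self._xhat + self.params[1].reshape(shape)

    def backward(self, dout):
        axes, shape = self._axes(dout), self._shape(dout)
        m = dout.shape[0] if dout.ndim == 2 else dout.shape[0] * dout.shape[2]
        self.grads[0][...] = (dout * self._xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        gamma = self.params[0].reshape(shape)
        dxhat = dout * gamma
        if not self._train:
            return dxhat / self._std
        return (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        ) / self._std


class Conv1dSame(Layer):
    """1-D convolution, kernel 3, stride 1, zero padding 1 (length-preserving)."""

    def __init__(
        self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3
    ) -> None:
        super().__init__()
        assert kernel % 2 == 1
        self.kernel, self.pad = kernel, kernel // 2
        w = rng.normal(
            0.0, np.sqrt(2.0 / (c_in * kernel)), size=(c_out, c_in, kernel)
        )
        self.params = [w, np.zeros(c_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        # x: (N, C_in, L)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp = xp
        self._L = x.shape[2]
        windows = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=2
        )  # (N, C_in, L, K)
        self._windows = windows
        out = np.einsum("nclk,ock->nol", windows, self.params[0], optimize=True)
        return out + self.params[1][None, :, None]

    def backward(self, dout):
        self.grads[0][...] = np.einsum(
            "nclk,nol->ock", self._windows, dout, optimize=True
        )
        self.grads[1][...] = dout.sum(axis=(0, 2))
        dxp = np.zeros_like(self._xp)
        w = self.params[0]
        for k in range(self.kernel):
            # dout[:, o, l] contributes to xp[:, c, l + k] via w[o, c, k]
            dxp[:, :, k : k + self._L] += np.einsum(
                "nol,oc->ncl", dout, w[:, :, k], optimize=True
            )
        return dxp[:, :, self.pad : self.pad + self._L]


class MaxPool1d(Layer):
    """Max pooling, kernel 2 stride 2, floor division on odd lengths."""

    def forward(self, x, train):
        n, c, L = x.shape
        L2 = L // 2
        self._in_shape = x.shape
        xt = x[:, :, : 2 * L2].reshape(n, c, L2, 2)
        self._argmax = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, dout):
        n, c, L = self._in_shape
        L2 = L // 2
        dx = np.zeros((n, c, L2, 2))
        np.put_along_axis(dx, self._argmax[..., None], dout[..., None], axis=3)
        out = np.zeros(self._in_shape)
        out[:, :, : 2 * L2] = dx.reshape(n, c, 2 * L2)
        return out


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class SingleTokenMHA(Layer):
    """Multi-head attention where each sample is one token of width d_model.

    Q, K, V are linear maps of the (batch-normalized) sample vector, split
    into h heads of width d_model/h.  With a single token per sample the
    softmax over keys is over one item, so each head's output equals its V
    projection and only W_v and the output projection W_o receive gradient;
    the general scaled-dot-product path is exercised by
    :func:`scaled_dot_attention`.
    """

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator) -> None:
        super().__init__()
        if d_model % heads:
            raise ValueError(f"d_model={d_model} not divisible by heads={heads}")
        self.heads = heads
        self.d_head = d_model // heads
        s = np.sqrt(1.0 / d_model)
        wq, wk, wv, wo = (
            rng.normal(0.0, s, size=(d_model, d_model)) for _ in range(4)
        )
        self.params = [wq, wk, wv, wo]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        self._x = x
        wv, wo = self.params[2], self.params[3]
        n, d = x.shape
        vh = (x @ wv).reshape(n, self.heads, self.d_head)
        # one token per sample: softmax(q k^T / sqrt(d_k)) over a single key
        # is exactly 1, so each head's attention output equals its V slice
        self._concat = vh.reshape(n, d)
        return self._concat @ wo

    def backward(self, dout):
        wo, wv = self.params[3], self.params[2]
        self.grads[3][...] = self._concat.T @ dout
        dconcat = dout @ wo.T
        self.grads[2][...] = self._x.T @ dconcat
        # W_q / W_k receive no gradient: single-token softmax is constant 1
        self.grads[0][...] = 0.0
        self.grads[1][...] = 0.0
        return dconcat @ wv.T


class Adam:
    """Adam with optional decoupled-from-schedule L2 weight decay."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]
        self.v = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                if self.weight_decay:
                    g = g + self.weight_decay * p
                m = self.m[li][pi]
                v = self.v[li][pi]
                m += (1 - self.beta1) * (g - m)
                v += (1 - self.beta2) * (g * g - v)
                p -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


class Network:
    """A plain sequential network with softmax cross-entropy training."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [
            softmax(self.forward(x[i : i + batch], train=False), axis=1)
            for i in range(0, x.shape[0], batch)
        ]
        return np.vstack(outs)

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator,
        epochs: int,
        batch: int,
        lr: float,
        weight_decay: float = 0.0,
        cosine_eta_min: float | None = None,
    ) -> list[float]:
        """Minibatch Adam training under softmax cross-entropy.

        If ``cosine_eta_min`` is given the learning rate follows the cosine
        schedule from ``lr`` down to ``cosine_eta_min`` over ``epochs``.
        Returns the per-epoch mean training loss.
        """
        n = X.shape[0]
        opt = Adam(self.layers, lr=lr, weight_decay=weight_decay)
        losses = []
        for epoch in range(epochs):
            lr_t = (
                cosine_lr(epoch, epochs, cosine_eta_min, lr)
                if cosine_eta_min is not None
                else lr
            )
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                logits = self.forward(X[idx], train=True)
                probs = softmax(logits, axis=1)
                yb = y[idx]
                epoch_loss += cross_entropy(probs[:, 1], yb) * idx.size
                dlogits = probs.copy()
                dlogits[np.arange(idx.size), yb] -= 1.0
                self.backward(dlogits / idx.size)
                opt.step(lr=lr_t)
            losses.append(epoch_loss / n)
        return losses
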