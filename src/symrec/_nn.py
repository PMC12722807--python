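"""Minimal convolutional-network engine (numpy, CPU).

Implements exactly the layers the twin-branch encoder needs — valid-padding
3×3 convolution, 2×2 max pooling, flatten, dense — with hand-written
backpropagation and an Adam optimizer.  Convolutions are lowered to GEMM by
materializing the im2col buffer with nine strided slice copies, so the heavy
arithmetic runs in BLAS and the data movement stays sequential; everything
is float32.  Initialization is Glorot-uniform from a seeded generator,
making runs bit-reproducible on a fixed BLAS backend.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D:
    """Valid-padding k×k convolution with fused ReLU, NHWC layout."""

    def __init__(self, rng, in_ch: int, out_ch: int, k: int = 3):
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        # rows ordered (ki, kj, cin) to match the im2col column layout
        self.W = _glorot(rng, (k * k * in_ch, out_ch), k * k * in_ch, k * k * out_ch)
        self.b = np.zeros(out_ch, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, H, Wd, C = x.shape
        k = self.k
        Ho, Wo = H - k + 1, Wd - k + 1
        buf = np.empty((B, Ho, Wo, k, k, C), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                buf[:, :, :, i, j, :] = x[:, i : i + Ho, j : j + Wo, :]
        return buf.reshape(B * Ho * Wo, k * k * C)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, Wd, C = x.shape
        Ho, Wo = H - self.k + 1, Wd - self.k + 1
        cols = self._im2col(x)
        y = cols @ self.W
        y += self.b
        np.maximum(y, 0.0, out=y)          # fused ReLU
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return y.reshape(B, Ho, Wo, self.out_ch)

    def backward(self, dy: np.ndarray, relu_out: np.ndarray, need_dx: bool = True):
        """`dy` is the gradient at the ReLU output `relu_out` of this layer."""
        B, Ho, Wo, F = dy.shape
        k = self.k
        dy = dy * (relu_out > 0)
        dy_mat = dy.reshape(-1, F)
        self.dW = self._cols.T @ dy_mat
        self.db = dy_mat.sum(axis=0)
        self._cols = None
        if not need_dx:
            return None
        dcols = (dy_mat @ self.W.T).reshape(B, Ho, Wo, k, k, self.in_ch)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + Ho, j : j + Wo, :] += dcols[:, :, :, i, j, :]
        return dx

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class MaxPool2:
    """2×2 max pooling with stride 2; odd trailing rows/columns are dropped.

    Gradient is routed to every maximal element of a window.  Ties between
    positive activations are measure-zero; ties at zero receive gradient here
    but it is annihilated by the preceding ReLU mask, so the subgradient
    choice is inconsequential.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        Ho, Wo = H // 2, W // 2
        v = [x[:, i : 2 * Ho : 2, j : 2 * Wo : 2, :] for i in (0, 1) for j in (0, 1)]
        y = np.maximum(np.maximum(v[0], v[1]), np.maximum(v[2], v[3]))
        if train:
            self._x = x
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, y = self._x, self._y
        B, H, W, C = x.shape
        Ho, Wo = H // 2, W // 2
        dx = np.zeros_like(x)
        for i in (0, 1):
            for j in (0, 1):
                view = x[:, i : 2 * Ho : 2, j : 2 * Wo : 2, :]
                dx[:, i : 2 * Ho : 2, j : 2 * Wo : 2, :] += dy * (view == y)
        self._x = self._y = None
        return dx


class Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T if need_dx else None

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ConvEncoder:
    """conv(32,3×3)+ReLU → pool → conv(64,3×3)+ReLU → pool → flatten → dense+ReLU."""

    def __init__(self, rng: np.random.Generator, input_hw: int = 128,
                 filters: tuple[int, int] = (32, 64), embed_dim: int = 128):
        self.input_hw = input_hw
        self.embed_dim = embed_dim
        self.conv1 = Conv2D(rng, 1, filters[0])
        self.pool1 = MaxPool2()
        self.conv2 = Conv2D(rng, filters[0], filters[1])
        self.pool2 = MaxPool2()
        h = input_hw
        h = (h - 2) // 2       # conv1 (valid) then pool
        h = (h - 2) // 2       # conv2 then pool
        self.flat_dim = h * h * filters[1]
        self.dense = Dense(rng, self.flat_dim, embed_dim)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, H, W) or (B, H, W, 1) in [0,1] -> (B, embed_dim) embeddings."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] != self.input_hw or x.shape[2] != self.input_hw:
            raise ValueError(
                f"expected {self.input_hw}×{self.input_hw} inputs, got {x.shape[1]}×{x.shape[2]}"
            )
        r1 = self.conv1.forward(x, train=train)
        p1 = self.pool1.forward(r1, train=train)
        r2 = self.conv2.forward(p1, train=train)
        p2 = self.pool2.forward(r2, train=train)
        flat = p2.reshape(p2.shape[0], -1)
        z = self.dense.forward(flat, train=train)
        out = np.maximum(z, 0.0)
        if train:
            self._cache = (r1, r2, z, p2.shape)
        return out

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients for the last `forward(train=True)`."""
        r1, r2, z, p2_shape = self._cache
        dz = (dout * (z > 0)).astype(np.float32)
        dflat = self.dense.backward(dz)
        dp2 = dflat.reshape(p2_shape)
        dr2 = self.pool2.backward(dp2)
        dp1 = self.conv2.backward(dr2, r2)
        dr1 = self.pool1.backward(dp1)
        self.conv1.backward(dr1, r1, need_dx=False)
        self._cache = None

    @property
    def layers(self):
        return [self.conv1, self.conv2, self.dense]

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            out[f"{i}_W"] = layer.W.copy()
            out[f"{i}_b"] = layer.b.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            layer.W[...] = weights[f"{i}_W"]
            layer.b[...] = weights[f"{i}_b"]


class Adam:
    """Adaptive-moment optimizer (β1=0.9, β2=0.999, eps=1e-8)."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}
        for li, layer in enumerate(layers):
            for name, value, _ in layer.params:
                self._m[(li, name)] = np.zeros_like(value)
                self._v[(li, name)] = np.zeros_like(value)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for li, layer in enumerate(self.layers):
            for name, value, grad_attr in layer.params:
                g = getattr(layer, grad_attr)
                m = self._m[(li, name)]
                v = self._v[(li, name)]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * np.square(g)
                value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
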