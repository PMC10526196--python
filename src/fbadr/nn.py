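"""Adaptor and critic networks for adversarial feature adaptation.

Layer plans follow the published tables: the adaptor reshapes the
length-F tangent-feature vector to F x 1, applies two kernel-3 1-D
convolutions (32 then 8 filters, leaky-ReLU + batch-norm), flattens to
8F and maps densely back to F with a tanh output.  The critic maps F
densely to 32, reshapes to 32 x 1, applies two kernel-2 convolutions
(32 then 64 filters, leaky-ReLU + batch-norm), flattens to 2048 and
passes through 256 -> 64 -> 1 dense layers.  The critic output is linear
by default (Wasserstein objective); a sigmoid variant is available.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, pad_axis, narrow

LEAKY_SLOPE = 0.2


def _glorot(rng: np.random.Generator, shape, dtype=np.float64) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    fan_out = int(shape[-1])
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.w = Tensor(_glorot(rng, (n_in, n_out), dtype), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self):
        return [self.w, self.b]


class Conv1D:
    """Stride-1, same-padding 1-D convolution over channels-last input."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.kernel, self.c_in, self.c_out = kernel, c_in, c_out
        self.w = Tensor(_glorot(rng, (kernel, c_in, c_out), dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        length = x.shape[1]
        left = (self.kernel - 1) // 2
        xp = pad_axis(x, 1, left, self.kernel - 1 - left)
        out = None
        for t in range(self.kernel):
            w_t = narrow(self.w, 0, t, 1).reshape((self.c_in, self.c_out))
            term = narrow(xp, 1, t, length) @ w_t
            out = term if out is None else out + term
        return out + self.b

    def params(self):
        return [self.w, self.b]


class BatchNorm:
    """Batch normalization over the trailing channel axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            axes = tuple(range(x.ndim - 1))
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
        else:
            mean = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mean) / (var + self.eps) ** 0.5
        return xhat * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class LayerNorm:
    """Per-sample normalization over all non-batch axes (critic option)."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(1, x.ndim))
        mean = x.mean(axis=axes, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
        xhat = (x - mean) / (var + self.eps) ** 0.5
        return xhat * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class Adaptor:
    """Source-feature -> target-like-feature generator network."""

    def __init__(self, n_features: int, rng: np.random.Generator,
                 n_extra_in: int = 0, dtype=np.float64):
        self.n_features = n_features
        self.n_extra_in = n_extra_in
        self.dtype = dtype
        self.conv1 = Conv1D(3, 1, 32, rng, dtype)
        self.bn1 = BatchNorm(32, dtype=dtype)
        self.conv2 = Conv1D(3, 32, 8, rng, dtype)
        self.bn2 = BatchNorm(8, dtype=dtype)
        n_flat = 8 * (n_features + n_extra_in)
        self.dense = Dense(n_flat, n_features, rng, dtype)

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        b = x.shape[0]
        h = x.reshape((b, x.shape[1], 1))
        h = self.bn1(self.conv1(h).leaky_relu(LEAKY_SLOPE), training)
        h = self.bn2(self.conv2(h).leaky_relu(LEAKY_SLOPE), training)
        h = h.reshape((b, 8 * (self.n_features + self.n_extra_in)))
        return self.dense(h).tanh()

    def trace_shapes(self, batch: int = 2):
        """Forward a dummy batch, returning each stage's output shape."""
        x = Tensor(np.zeros((batch, self.n_features + self.n_extra_in)))
        shapes = {"input": x.shape}
        h = x.reshape((batch, x.shape[1], 1))
        shapes["reshape"] = h.shape
        h = self.bn1(self.conv1(h).leaky_relu(LEAKY_SLOPE), False)
        shapes["conv1"] = h.shape
        h = self.bn2(self.conv2(h).leaky_relu(LEAKY_SLOPE), False)
        shapes["conv2"] = h.shape
        h = h.reshape((batch, 8 * (self.n_features + self.n_extra_in)))
        shapes["flatten"] = h.shape
        shapes["dense"] = self.dense(h).tanh().shape
        return shapes

    def params(self):
        out = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.dense):
            out += layer.params()
        return out


class Critic:
    """Scalar-output domain critic."""

    def __init__(
        self,
        n_features: int,
        rng: np.random.Generator,
        sigmoid: bool = False,
        norm: str = "batch",
        dtype=np.float64,
    ):
        self.n_features = n_features
        self.sigmoid = sigmoid
        norm_cls = BatchNorm if norm == "batch" else LayerNorm
        self.dense_in = Dense(n_features, 32, rng, dtype)
        self.conv1 = Conv1D(2, 1, 32, rng, dtype)
        self.bn1 = norm_cls(32, dtype=dtype)
        self.conv2 = Conv1D(2, 32, 64, rng, dtype)
        self.bn2 = norm_cls(64, dtype=dtype)
        self.dense1 = Dense(32 * 64, 256, rng, dtype)
        self.dense2 = Dense(256, 64, rng, dtype)
        self.dense_out = Dense(64, 1, rng, dtype)

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        b = x.shape[0]
        h = self.dense_in(x).leaky_relu(LEAKY_SLOPE)
        h = h.reshape((b, 32, 1))
        h = self.bn1(self.conv1(h).leaky_relu(LEAKY_SLOPE), training)
        h = self.bn2(self.conv2(h).leaky_relu(LEAKY_SLOPE), training)
        h = h.reshape((b, 32 * 64))
        h = self.dense1(h).leaky_relu(LEAKY_SLOPE)
        h = self.dense2(h).leaky_relu(LEAKY_SLOPE)
        out = self.dense_out(h)
        return out.sigmoid() if self.sigmoid else out

    def trace_shapes(self, batch: int = 2):
        x = Tensor(np.zeros((batch, self.n_features)))
        shapes = {"input": x.shape}
        h = self.dense_in(x).leaky_relu(LEAKY_SLOPE)
        shapes["dense_in"] = h.shape
        h = h.reshape((batch, 32, 1))
        shapes["reshape"] = h.shape
        h = self.bn1(self.conv1(h).leaky_relu(LEAKY_SLOPE), False)
        shapes["conv1"] = h.shape
        h = self.bn2(self.conv2(h).leaky_relu(LEAKY_SLOPE), False)
        shapes["conv2"] = h.shape
        h = h.reshape((batch, 32 * 64))
        shapes["flatten"] = h.shape
        h = self.dense1(h).leaky_relu(LEAKY_SLOPE)
        shapes["fc1"] = h.shape
        h = self.dense2(h).leaky_relu(LEAKY_SLOPE)
        shapes["fc2"] = h.shape
        shapes["output"] = self.dense_out(h).shape
        return shapes

    def params(self):
        out = []
        for layer in (
            self.dense_in,
            self.conv1,
            self.bn1,
            self.conv2,
            self.bn2,
            self.dense1,
            self.dense2,
            self.dense_out,
        ):
            out += layer.params()
        return out


class Adam:
    """Adam optimizer updating parameter tensors in place."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else g
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
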