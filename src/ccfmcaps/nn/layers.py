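"""Layers with explicit forward/backward passes, channels-last (NHWC).

Everything is float64 NumPy.  Convolutions are im2col-style via
``sliding_window_view`` + ``tensordot`` so the heavy lifting lands in BLAS.
Max-pooling uses 2x2/stride-2 windows with ceil-mode (same-padded) output,
matching the 13x13 -> 7x7 reductions of the architecture.

Gradient convention for dynamic routing (:class:`ClassCaps`): the coupling
coefficients produced by the routing loop are treated as constants of the
forward pass, and gradients flow through the final weighted sum, the squash
nonlinearity and the prediction transform ``W_ij u_i``.  With a single
routing iteration the couplings are the uniform softmax of zero logits and
the convention is exact.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..capsules import coupling, route, squash, squash_backward


class Param:
    """A named trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer: stateless unless overridden."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[Param]:
        return []

    def param_count(self) -> int:
        """Total parameters including non-trainable statistics."""
        return sum(p.size for p in self.params)

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv2D(Layer):
    """Valid-padding 2-D convolution, NHWC, optional ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, activation: str | None = None,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * in_channels
        scale = np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.stride = stride
        self.activation = activation
        self.name = name
        self.w = Param(f"{name}/kernel",
                       rng.normal(0.0, scale, (kernel, kernel, in_channels,
                                               out_channels)))
        self.b = Param(f"{name}/bias", np.zeros(out_channels))
        self._cache = None

    @staticmethod
    def out_size(n: int, kernel: int, stride: int) -> int:
        if n < kernel:
            raise ValueError(f"spatial size {n} smaller than kernel {kernel}")
        return (n - kernel) // stride + 1

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s = self.kernel, self.stride
        # (B, OH', OW', C, k, k) view, strided to the requested step
        cols = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        z = np.tensordot(cols, self.w.value, axes=([4, 5, 3], [0, 1, 2]))
        z += self.b.value
        self._cache = (x.shape, cols, z if self.activation else None)
        return _relu(z) if self.activation == "relu" else z

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols, z = self._cache
        if self.activation == "relu":
            grad = grad * (z > 0)
        self.b.grad += grad.sum(axis=(0, 1, 2))
        # dW[k1,k2,c,f] = sum_{b,oh,ow} cols[b,oh,ow,c,k1,k2] grad[b,oh,ow,f]
        self.w.grad += np.tensordot(cols, grad, axes=([0, 1, 2], [0, 1, 2])
                                    ).transpose(1, 2, 0, 3)
        # scatter the column gradients back to the input
        dcols = np.tensordot(grad, self.w.value, axes=([3], [3]))  # B,OH,OW,k,k,C
        dx = np.zeros(x_shape)
        k, s = self.kernel, self.stride
        oh, ow = grad.shape[1], grad.shape[2]
        for i in range(k):
            for j in range(k):
                dx[:, i:i + s * oh:s, j:j + s * ow:s, :] += dcols[:, :, :, i, j, :]
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (B, H, W) with moving statistics.

    Four parameters per channel: scale, shift, moving mean, moving variance
    (the last two non-trainable but included in parameter totals, following
    the usual "total parameters" accounting).
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "bn"):
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self.gamma = Param(f"{name}/gamma", np.ones(channels))
        self.beta = Param(f"{name}/beta", np.zeros(channels))
        self.moving_mean = np.zeros(channels)
        self.moving_var = np.ones(channels)
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def param_count(self) -> int:
        return self.gamma.size + self.beta.size + self.moving_mean.size \
            + self.moving_var.size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean = m * self.moving_mean + (1 - m) * mean
            self.moving_var = m * self.moving_var + (1 - m) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        self._cache = (x_hat, inv_std, training, x.shape, axes)
        return self.gamma.value * x_hat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_hat, inv_std, training, shape, axes = self._cache
        self.gamma.grad += (grad * x_hat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not training:
            return g * inv_std
        n = np.prod([shape[a] for a in axes])
        return (inv_std / n) * (n * g - g.sum(axis=axes)
                                - x_hat * (g * x_hat).sum(axis=axes))


class MaxPool2D(Layer):
    """2x2 stride-2 max pooling with ceil-mode output (odd edges padded)."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self._cache = None

    @staticmethod
    def out_size(n: int) -> int:
        return (n + 1) // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                       constant_values=-np.inf)
        oh, ow = x.shape[1] // 2, x.shape[2] // 2
        win = x.reshape(b, oh, 2, ow, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(b, oh, ow, c, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = ((b, h, w, c), (ph, pw), idx)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (b, h, w, c), (ph, pw), idx = self._cache
        oh, ow = grad.shape[1], grad.shape[2]
        dwin = np.zeros((b, oh, ow, c, 4))
        np.put_along_axis(dwin, idx[..., None], grad[..., None], axis=-1)
        dx = dwin.reshape(b, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = dx.reshape(b, oh * 2, ow * 2, c)
        return dx[:, :h, :w, :]


class Dropout(Layer):
    """Inverted dropout; identity at inference. Parameter-free."""

    def __init__(self, rate: float = 0.5, name: str = "dropout"):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.name = name
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    """Fully connected layer with optional ReLU / sigmoid."""

    def __init__(self, in_features: int, out_features: int,
                 activation: str | None = None,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        if activation == "relu":
            scale = np.sqrt(2.0 / in_features)
        else:
            scale = np.sqrt(1.0 / in_features)
        self.activation = activation
        self.name = name
        self.w = Param(f"{name}/kernel",
                       rng.normal(0.0, scale, (in_features, out_features)))
        self.b = Param(f"{name}/bias", np.zeros(out_features))
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x @ self.w.value + self.b.value
        if self.activation == "relu":
            out = _relu(z)
        elif self.activation == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-z))
        else:
            out = z
        self._cache = (x, z, out)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, out = self._cache
        if self.activation == "relu":
            grad = grad * (z > 0)
        elif self.activation == "sigmoid":
            grad = grad * out * (1.0 - out)
        self.w.grad += x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class PrimaryCaps(Layer):
    """Convolutional capsule layer: conv -> reshape to capsules -> squash.

    ``channels`` capsule types of dimension ``dim`` share one convolution of
    ``channels * dim`` filters; the spatial grid of outputs is flattened so
    the layer emits ``grid_h * grid_w * channels`` capsule vectors.
    """

    def __init__(self, in_channels: int, channels: int = 16, dim: int = 8,
                 kernel: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None,
                 name: str = "primary_caps"):
        self.channels = channels
        self.dim = dim
        self.name = name
        self.conv = Conv2D(in_channels, channels * dim, kernel, stride,
                           activation=None, rng=rng, name=name)
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return self.conv.params

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = self.conv.forward(x, training=training)
        b = z.shape[0]
        s = z.reshape(b, -1, self.dim)  # (B, n_caps, dim)
        self._cache = (s, z.shape)
        return squash(s, axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s, z_shape = self._cache
        ds = squash_backward(s, grad, axis=-1)
        return self.conv.backward(ds.reshape(z_shape))


class ClassCaps(Layer):
    """Class-capsule layer connected by dynamic routing.

    Holds only the prediction transform ``W`` of shape
    (n_in, n_classes, out_dim, in_dim); routing logits are transient state,
    not parameters.  Backward treats the final couplings as constants (see
    module docstring).
    """

    def __init__(self, n_in: int, in_dim: int, n_classes: int,
                 out_dim: int = 16, iterations: int = 3,
                 rng: np.random.Generator | None = None,
                 name: str = "class_caps"):
        rng = rng or np.random.default_rng(0)
        self.iterations = iterations
        self.name = name
        self.W = Param(f"{name}/W",
                       rng.normal(0.0, 0.05, (n_in, n_classes, out_dim, in_dim)))
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, u: np.ndarray, training: bool = False) -> np.ndarray:
        u_hat = np.einsum("bip,ijdp->bijd", u, self.W.value)
        v, c = route(u_hat, iterations=self.iterations, return_couplings=True)
        s = np.einsum("bij,bijd->bjd", c, u_hat)
        self._cache = (u, u_hat, c, s)
        return v

    def backward(self, grad_v: np.ndarray) -> np.ndarray:
        u, u_hat, c, s = self._cache
        ds = squash_backward(s, grad_v, axis=-1)
        du_hat = c[..., None] * ds[:, None, :, :]
        self.W.grad += np.einsum("bijd,bip->ijdp", du_hat, u)
        return np.einsum("bijd,ijdp->bip", du_hat, self.W.value)


class Sequential(Layer):
    """A simple forward/backward chain of layers."""

    def __init__(self, layers: list[Layer], name: str = "sequential"):
        self.layers = layers
        self.name = name

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
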