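"""Minimal NumPy layer framework with explicit backward passes.

Tensors are float32 with shape (batch, channels, length). Each layer caches
what its backward pass needs during forward; gradients accumulate into
``layer.grads`` aligned with ``layer.params``. Designed for the small CPU
configurations this package trains; correctness is checked against finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

F32 = np.float32


class Layer:
    """Base layer: stateless by default, no parameters."""

    def __init__(self):
        self.params: List[np.ndarray] = []
        self.grads: List[np.ndarray] = []
        self.param_names: List[str] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0

    def state(self) -> Dict[str, np.ndarray]:
        """Non-parameter buffers to persist in checkpoints."""
        return {}


class Conv1d(Layer):
    """Dilated 1-D convolution with 'same' zero padding.

    Implemented as a sum over kernel taps of channel-mixing matmuls, which is
    efficient for the short kernels (<= 15) used here.
    """

    def __init__(self, in_ch: int, out_ch: int, width: int, dilation: int = 1,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_ch * width))
        self.weight = rng.normal(0.0, std, size=(out_ch, in_ch, width)).astype(F32)
        self.bias = np.zeros(out_ch, dtype=F32)
        self.width = width
        self.dilation = dilation
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self.param_names = ["weight", "bias"]
        pad_total = (width - 1) * dilation
        self.pad_left = pad_total // 2
        self.pad_right = pad_total - self.pad_left

    def forward(self, x, train=False):
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        self._xp, self._L = xp, L
        y = np.empty((B, self.weight.shape[0], L), dtype=F32)
        y[:] = self.bias[None, :, None]
        for k in range(self.width):
            off = k * self.dilation
            # (O,C) x (B,C,L) -> (O,B,L)
            y += np.tensordot(self.weight[:, :, k], xp[:, :, off : off + L],
                              axes=([1], [1])).transpose(1, 0, 2)
        return y

    def backward(self, dy):
        xp, L = self._xp, self._L
        dxp = np.zeros_like(xp)
        self.grads[1] += dy.sum(axis=(0, 2))
        for k in range(self.width):
            off = k * self.dilation
            xk = xp[:, :, off : off + L]
            # (B,O,L) x (B,C,L) -> (O,C)
            self.grads[0][:, :, k] += np.tensordot(dy, xk, axes=([0, 2], [0, 2]))
            # (O,C)^T applied to dy -> (C,B,L)
            dxp[:, :, off : off + L] += np.tensordot(
                self.weight[:, :, k], dy, axes=([0], [1])
            ).transpose(1, 0, 2)
        if self.pad_right:
            return dxp[:, :, self.pad_left : -self.pad_right]
        return dxp[:, :, self.pad_left :]


class BatchNorm1d(Layer):
    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.param_names = ["gamma", "beta"]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
            self._n = x.shape[0] * x.shape[2]
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._train = train
        self._xhat, self._inv = xhat.astype(F32), inv.astype(F32)
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        self.grads[0] += (dy * xhat).sum(axis=(0, 2))
        self.grads[1] += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        if not self._train:
            return dxhat * inv[None, :, None]
        n = self._n
        t = dxhat - dxhat.mean(axis=(0, 2), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / n
        return t * inv[None, :, None]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))
_GELU_A = np.float32(0.044715)


class GELU(Layer):
    """Gaussian Error Linear Unit, tanh approximation (x * Phi(x))."""

    def forward(self, x, train=False):
        self._x = x
        u = _GELU_C * (x + _GELU_A * x * x * x)
        self._t = np.tanh(u)
        return (0.5 * x) * (1.0 + self._t)

    def backward(self, dy):
        x, t = self._x, self._t
        du = _GELU_C * (1.0 + 3.0 * _GELU_A * x * x)
        return dy * (0.5 * (1.0 + t) + (0.5 * x) * (1.0 - t * t) * du)


class MaxPool1d(Layer):
    def __init__(self, width: int = 2):
        super().__init__()
        self.width = width

    def forward(self, x, train=False):
        B, C, L = x.shape
        if L % self.width:
            raise ValueError(f"length {L} not divisible by pool width {self.width}")
        self._shape = x.shape
        xr = x.reshape(B, C, L // self.width, self.width)
        if self.width == 2:
            a, b = xr[..., 0], xr[..., 1]
            self._mask2 = b > a
            return np.where(self._mask2, b, a)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy):
        B, C, L = self._shape
        dxr = np.zeros((B, C, L // self.width, self.width), dtype=F32)
        if self.width == 2:
            np.copyto(dxr[..., 1], dy, where=self._mask2)
            np.copyto(dxr[..., 0], dy, where=~self._mask2)
        else:
            np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        return dxr.reshape(B, C, L)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Softplus(Layer):
    def forward(self, x, train=False):
        self._x = x
        return np.logaddexp(0.0, x).astype(F32)

    def backward(self, dy):
        return dy / (1.0 + np.exp(-self._x))


class Sequential(Layer):
    def __init__(self, layers: List[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, Residual)):
                yield from layer.iter_layers()
            else:
                yield layer


class Residual(Layer):
    """y = x + body(x); requires the body to preserve shape."""

    def __init__(self, body: Sequential):
        super().__init__()
        self.body = body

    def forward(self, x, train=False):
        return x + self.body.forward(x, train=train)

    def backward(self, dy):
        return dy + self.body.backward(dy)

    def iter_layers(self):
        yield from self.body.iter_layers()


def collect_params(root: Layer) -> List[Tuple[str, np.ndarray, np.ndarray]]:
    """Flat (name, param, grad) triples over a layer tree."""
    out = []
    layers = root.iter_layers() if isinstance(root, (Sequential, Residual)) else [root]
    for i, layer in enumerate(layers):
        for name, p, g in zip(layer.param_names, layer.params, layer.grads):
            out.append((f"{i}.{type(layer).__name__}.{name}", p, g))
    return out


def collect_state(root: Layer) -> List[Tuple[str, np.ndarray]]:
    out = []
    layers = root.iter_layers() if isinstance(root, (Sequential, Residual)) else [root]
    for i, layer in enumerate(layers):
        for name, buf in layer.state().items():
            out.append((f"{i}.{type(layer).__name__}.{name}", buf))
    return out


class SGD:
    """SGD with classical momentum; velocities keyed by parameter identity so
    a parameter absent from a step's param list is left untouched."""

    def __init__(self, lr: float = 0.005, momentum: float = 0.99):
        self.lr = lr
        self.momentum = momentum
        self._velocity: Dict[int, np.ndarray] = {}

    def step(self, params_grads: List[Tuple[str, np.ndarray, np.ndarray]]):
        for _name, p, g in params_grads:
            v = self._velocity.get(id(p))
            if v is None:
                v = np.zeros_like(p)
                self._velocity[id(p)] = v
            v *= self.momentum
            v += g
            p -= self.lr * v
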