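"""Minimal CPU neural-network engine.

Layers, losses and the Adam optimizer used by the contour-quality classifier,
implemented directly on numpy.  The engine is deliberately small: 2D
convolution (im2col + BLAS matmul), batch normalization, ReLU, dense layers,
inverted dropout and global average pooling — exactly the pieces a residual
image/mask classifier with an MC-dropout head needs.  Everything is
deterministic given the generators passed in; no global random state is used.

Layers cache their forward inputs and expose ``backward(grad)``; parameters
accumulate gradients in ``Parameter.grad`` until the optimizer consumes them.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dense",
    "Dropout",
    "GlobalAvgPool",
    "ResidualBlock",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


class Parameter:
    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def sigmoid(z: np.ndarray) -> np.ndarray:
    # stable two-sided formulation
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    # log(1 + e^z) - y z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


class Conv2d:
    """3x3-style convolution via im2col; NCHW layout, zero padding."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.weight = Parameter(rng.normal(0.0, std, size=(cout, cin * k * k)))
        self.bias = Parameter(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.weight.value.T + self.bias.value
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, c, h, w), cols, ho, wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.weight.grad += g2.T @ cols
        self.bias.grad += g2.sum(axis=0)
        dcols = (g2 @ self.weight.value).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std, train, shape = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return g / std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        gm = g.mean(axis=axes)[None, :, None, None]
        gxm = (g * xhat).mean(axis=axes)[None, :, None, None]
        return (g - gm - xhat * gxm) / std[None, :, None, None]


class ReLU:
    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / nin)
        self.weight = Parameter(rng.normal(0.0, std, size=(nout, nin)))
        self.bias = Parameter(np.zeros(nout))

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Dropout:
    """Inverted dropout; active only when a generator is supplied."""

    def __init__(self, p: float):
        if not (0.0 < p < 1.0):
            raise ValueError(f"dropout rate must be in (0, 1), got {p}")
        self.p = p

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class GlobalAvgPool:
    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class ResidualBlock:
    """conv-bn-relu-conv-bn with identity (or 1x1-projected) skip, then relu."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride, 0, rng)
            self.bn_proj = BatchNorm2d(cout)
        else:
            self.proj = None
        self.relu_out = ReLU()

    def parameters(self):
        params = (self.conv1.parameters() + self.bn1.parameters()
                  + self.conv2.parameters() + self.bn2.parameters())
        if self.proj is not None:
            params += self.proj.parameters() + self.bn_proj.parameters()
        return params

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.bn1.forward(self.conv1.forward(x), train)
        out = self.relu1.forward(out)
        out = self.bn2.forward(self.conv2.forward(out), train)
        if self.proj is not None:
            skip = self.bn_proj.forward(self.proj.forward(x), train)
        else:
            skip = x
        return self.relu_out.forward(out + skip)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        if self.proj is not None:
            gskip = self.proj.backward(self.bn_proj.backward(g))
        else:
            gskip = g
        gmain = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))))
        return gmain + gskip


class Adam:
    def __init__(self, params: list[Parameter], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
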