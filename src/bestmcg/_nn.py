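"""Minimal NumPy neural-network layers with manual backpropagation.

Supports exactly what the lesion classifier needs: 3x3 / 1x1 convolutions
(im2col), batch normalisation, ReLU, squeeze-and-excitation channel
attention, average pooling, dense (concatenative) blocks, linear heads,
softmax cross-entropy and Adam.  Arrays are NCHW, float64.  The layer set
is deliberately small; it is not a general autodiff system.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "SELayer",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
    "DenseLayer",
    "DenseBlock",
    "Transition",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Module):
    """Stride-1 convolution with symmetric zero padding, via im2col."""

    def __init__(self, cin: int, cout: int, ksize: int, pad: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * ksize * ksize))  # He initialisation
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin * ksize * ksize)))
        self.b = Param(np.zeros(cout))
        self.ksize = ksize
        self.pad = pad
        self.cin = cin
        self.cout = cout

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.ksize, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (N, C, H', W', k, k) -> (N, H', W', C, k, k)
        ho, wo = windows.shape[2], windows.shape[3]
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (ho, wo) = self._cache
        k, p = self.ksize, self.pad
        g2 = grad.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.w.grad += g2.T @ cols
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.value).reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0, 2, 3)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv_std[None, :, None, None]
        return dx


class ReLU(Module):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SELayer(Module):
    """Squeeze-and-excitation channel attention: GAP -> FC -> ReLU -> FC ->
    sigmoid gate multiplying each channel."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.w1 = Param(rng.normal(0.0, np.sqrt(2.0 / channels), size=(hidden, channels)))
        self.b1 = Param(np.zeros(hidden))
        self.w2 = Param(rng.normal(0.0, np.sqrt(2.0 / hidden), size=(channels, hidden)))
        self.b2 = Param(np.zeros(channels))

    def params(self) -> list[Param]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        s = x.mean(axis=(2, 3))  # (N, C)
        z1 = s @ self.w1.value.T + self.b1.value
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.w2.value.T + self.b2.value
        gate = _sigmoid(z2)
        self._cache = (x, s, z1, a1, gate)
        return x * gate[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, s, z1, a1, gate = self._cache
        h, w = x.shape[2], x.shape[3]
        dx = grad * gate[:, :, None, None]
        dgate = (grad * x).sum(axis=(2, 3))
        dz2 = dgate * gate * (1.0 - gate)
        self.w2.grad += dz2.T @ a1
        self.b2.grad += dz2.sum(axis=0)
        da1 = dz2 @ self.w2.value
        dz1 = da1 * (z1 > 0)
        self.w1.grad += dz1.T @ s
        self.b1.grad += dz1.sum(axis=0)
        ds = dz1 @ self.w1.value
        dx += ds[:, :, None, None] / (h * w)
        return dx


class AvgPool2d(Module):
    """2x2 average pooling (odd trailing rows/columns are cropped)."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : h2 * 2, : w2 * 2]
        return xc.reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dx = np.zeros((n, c, h, w))
        h2, w2 = h // 2, w // 2
        dx[:, :, : h2 * 2, : w2 * 2] = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return dx


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], self._in_shape) / (h * w)


class Flatten(Module):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fin), size=(fout, fin)))
        self.b = Param(np.zeros(fout))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def params(self) -> list[Param]:
        return [p for m in self.modules for p in m.params()]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


class DenseLayer(Module):
    """One dense-block unit: BN-ReLU-1x1 conv (bottleneck), BN-ReLU-3x3 conv,
    then squeeze-and-excitation on the produced feature maps."""

    def __init__(self, cin: int, growth: int, se_reduction: int, rng: np.random.Generator):
        bottleneck = 4 * growth
        self.body = Sequential(
            BatchNorm2d(cin),
            ReLU(),
            Conv2d(cin, bottleneck, 1, 0, rng),
            BatchNorm2d(bottleneck),
            ReLU(),
            Conv2d(bottleneck, growth, 3, 1, rng),
            SELayer(growth, se_reduction, rng),
        )
        self.growth = growth

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.body.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(grad)


class DenseBlock(Module):
    """Concatenative block: each layer sees every preceding feature map."""

    def __init__(self, cin: int, n_layers: int, growth: int, se_reduction: int,
                 rng: np.random.Generator):
        self.layers = [
            DenseLayer(cin + i * growth, growth, se_reduction, rng)
            for i in range(n_layers)
        ]
        self.cout = cin + n_layers * growth

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._widths = [x.shape[1]]
        feats = x
        for layer in self.layers:
            y = layer.forward(feats, training)
            feats = np.concatenate([feats, y], axis=1)
            self._widths.append(feats.shape[1])
        return feats

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer, width in zip(reversed(self.layers), reversed(self._widths[:-1])):
            gprev, gy = grad[:, :width], grad[:, width:]
            grad = gprev + layer.backward(gy)
        return grad


class Transition(Module):
    """Between dense blocks: BN-ReLU-1x1 conv halving channels + 2x2 avg pool."""

    def __init__(self, cin: int, rng: np.random.Generator):
        self.cout = cin // 2
        self.body = Sequential(
            BatchNorm2d(cin), ReLU(), Conv2d(cin, self.cout, 1, 0, rng), AvgPool2d()
        )

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.body.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(grad)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy loss, its gradient w.r.t. logits, and the probs."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits, probs
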