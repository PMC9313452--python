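"""Minimal feed-forward neural-network layers with manual backpropagation.

Implements exactly the layer set the workflow's models need — 2D convolution,
batch normalization, ReLU/Sigmoid, linear layers, global average pooling,
residual bottleneck blocks — plus the Adam optimizer.  All arrays are float64
NHW-batched numpy arrays; convolutions use an im2col/col2im formulation.

Every module follows the same protocol:

* ``forward(x, train)`` caches whatever the backward pass needs,
* ``backward(dout)`` returns the gradient w.r.t. the input and accumulates
  parameter gradients in place,
* ``parameters()`` yields ``Param`` objects (value + grad buffers).

Parameter initialization is driven by an explicit ``numpy.random.Generator``
so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Linear",
    "GlobalAvgPool2d",
    "Sequential",
    "Bottleneck",
    "Adam",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- checkpoint support -------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"{i}:{p.name}"] = p.value.copy()
        for j, (name, buf) in enumerate(self._buffers()):
            state[f"buf{j}:{name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"{i}:{p.name}"]
        for j, (name, buf) in enumerate(self._buffers()):
            buf[...] = state[f"buf{j}:{name}"]

    def _buffers(self):
        """Non-trainable state (batch-norm running moments)."""
        return []


# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, oh*ow, C*kh*kw) patch matrix."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    oh = (H + 2 * pad - kh) // stride + 1
    ow = (W + 2 * pad - kw) // stride + 1
    cols = np.empty((B, C, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    # (B, oh*ow, C*kh*kw)
    return cols.transpose(0, 4, 5, 1, 2, 3).reshape(B, oh * ow, C * kh * kw), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int, oh: int, ow: int):
    """Adjoint of _im2col: scatter-add patch gradients back to image grid."""
    B, C, H, W = x_shape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(B, oh, ow, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    """2D convolution, He-initialized, optional bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = False):
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.w = Param("conv.w", w)
        self.b = Param("conv.b", np.zeros(out_ch)) if bias else None
        self._cache = None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        out = cols @ self.w.value.T  # (B, oh*ow, out_ch)
        if self.b is not None:
            out = out + self.b.value
        self._cache = (x.shape, cols, oh, ow)
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.out_ch, oh, ow)

    def backward(self, dout):
        x_shape, cols, oh, ow = self._cache
        B = x_shape[0]
        dflat = dout.reshape(B, self.out_ch, oh * ow).transpose(0, 2, 1)  # (B, ohw, out_ch)
        fan_in = cols.shape[-1]
        self.w.grad += dflat.reshape(-1, self.out_ch).T @ cols.reshape(-1, fan_in)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ self.w.value  # (B, ohw, fan_in)
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, self.pad, oh, ow)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (B, H, W) with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param("bn.gamma", np.ones(channels))
        self.beta = Param("bn.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def _buffers(self):
        return [("bn.running_mean", self.running_mean), ("bn.running_var", self.running_var)]

    def forward(self, x, train=True):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        self._cache = (xhat, inv, x.shape, train)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dout):
        xhat, inv, shape, train = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value[:, None, None]
        if not train:
            return dout * g * inv[:, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        return (inv[:, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=axes)[:, None, None]
        )


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Module):
    def forward(self, x, train=True):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.w = Param("linear.w", w)
        self.b = Param("linear.b", np.zeros(out_dim)) if bias else None
        self._x = None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        self._x = x
        out = x @ self.w.value.T
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, dout):
        self.w.grad += dout.T @ self._x
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class GlobalAvgPool2d(Module):
    """(B,C,H,W) -> (B,C) spatial mean."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        B, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def _buffers(self):
        return [b for layer in self.layers for b in layer._buffers()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Bottleneck(Module):
    """Residual bottleneck: 1x1 reduce, 3x3, 1x1 expand, each followed by
    batch norm; ReLU activations; identity (or 1x1-projection) shortcut."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, rng: np.random.Generator, stride: int = 1):
        self.conv1 = Conv2d(in_ch, mid_ch, 1, rng, pad=0)
        self.bn1 = BatchNorm2d(mid_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, rng, stride=stride, pad=1)
        self.bn2 = BatchNorm2d(mid_ch)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid_ch, out_ch, 1, rng, pad=0)
        self.bn3 = BatchNorm2d(out_ch)
        self.relu_out = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.proj = Sequential(Conv2d(in_ch, out_ch, 1, rng, stride=stride, pad=0), BatchNorm2d(out_ch))
        else:
            self.proj = None
        self.in_ch, self.mid_ch, self.out_ch, self.stride = in_ch, mid_ch, out_ch, stride

    def _main(self):
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2, self.conv3, self.bn3]

    def parameters(self):
        ps = [p for m in self._main() for p in m.parameters()]
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps

    def _buffers(self):
        bs = [b for m in self._main() for b in m._buffers()]
        if self.proj is not None:
            bs += self.proj._buffers()
        return bs

    def forward(self, x, train=True):
        out = x
        for m in self._main():
            out = m.forward(out, train=train)
        shortcut = x if self.proj is None else self.proj.forward(x, train=train)
        return self.relu_out.forward(out + shortcut, train=train)

    def backward(self, dout):
        dsum = self.relu_out.backward(dout)
        dmain = dsum
        for m in reversed(self._main()):
            dmain = m.backward(dmain)
        if self.proj is None:
            return dmain + dsum
        return dmain + self.proj.backward(dsum)


class Adam:
    """Adam with the standard bias correction; one `step` consumes the
    accumulated gradients and zeroes them."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.zero_grad()
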