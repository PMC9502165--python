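"""Minimal layer-wise neural-network substrate (NumPy, float64).

Every layer implements ``forward(x, cache=True)`` and ``backward(dout)``.
``backward`` *accumulates* into each parameter's ``.grad`` so that gradients
summed over several forward/backward passes (as in checkpointed training)
equal the gradient of the summed loss. Calling ``forward`` with
``cache=False`` drops the stored activations, which is what bounds peak
memory during the checkpointed forward sweep.

Layout convention is NCHW for all spatial layers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A named tensor with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self.children():
            child.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- (de)serialization ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r}")
            val = np.asarray(state[p.name], dtype=np.float64)
            if val.shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {p.name!r}: {val.shape} vs {p.value.shape}"
                )
            p.value[...] = val


def _he_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def children(self) -> list[Layer]:
        return self.layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, cache=cache)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# Dense / pointwise layers
# ---------------------------------------------------------------------------


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 name: str = "linear") -> None:
        self.W = Param(_he_init((in_features, out_features), in_features, rng), f"{name}.W")
        self.b = Param(np.zeros(out_features), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        out = x @ self.W.value + self.b.value
        self._x = x if cache else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called without a cached forward")
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = (x > 0.0) if cache else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Softmax(Layer):
    """Softmax over a given axis (classes); numerically stabilized."""

    def __init__(self, axis: int = 1) -> None:
        self.axis = axis
        self._p: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        z = x - x.max(axis=self.axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=self.axis, keepdims=True)
        self._p = p if cache else None
        return p

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self._p
        inner = (dout * p).sum(axis=self.axis, keepdims=True)
        return p * (dout - inner)


# ---------------------------------------------------------------------------
# Convolution / pooling
# ---------------------------------------------------------------------------


def _pad_nchw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride >= 1, symmetric zero pad."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = True,
                 name: str = "conv") -> None:
        if pad is None:
            pad = kernel // 2  # "same" for stride 1, odd kernels
        self.stride, self.pad, self.kernel = stride, pad, kernel
        fan_in = in_ch * kernel * kernel
        self.W = Param(_he_init((out_ch, in_ch, kernel, kernel), fan_in, rng), f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b") if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def out_channels(self) -> int:
        return self.W.value.shape[0]

    def n_weight_params(self) -> int:
        return self.W.value.size

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        xp = _pad_nchw(x, self.pad)
        ho = (h + 2 * self.pad - k) // s + 1
        wo = (w + 2 * self.pad - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, ho, wo, k, k) -> (n*ho*wo, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wmat = self.W.value.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b.value
        out = out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, ho, wo) if cache else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward")
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, pad = self.kernel, self.stride, self.pad
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.W.grad += (dmat.T @ cols).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value.reshape(self.out_channels, -1))
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, pad:pad + h, pad:pad + w]


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, pad: int = 0) -> None:
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        xp = x if self.pad == 0 else np.pad(
            x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
            constant_values=-np.inf)
        ho = (xp.shape[2] - k) // s + 1
        wo = (xp.shape[3] - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape, xp.shape, ho, wo) if cache else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, xshape, xpshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s = self.kernel, self.stride
        dxp = np.zeros((n, c) + xpshape[2:])
        ki, kj = np.unravel_index(arg, (k, k))
        ii = np.arange(ho)[None, None, :, None] * s + ki
        jj = np.arange(wo)[None, None, None, :] * s + kj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, ii, jj), dout)
        p = self.pad
        return dxp[:, :, p:p + h, p:p + w]


class AvgPool2d(Layer):
    def __init__(self, kernel: int, stride: int) -> None:
        self.kernel, self.stride = kernel, stride
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._shape = x.shape
        return win.mean(axis=(-1, -2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, s = self.kernel, self.stride
        dx = np.zeros(self._shape)
        ho, wo = dout.shape[2], dout.shape[3]
        g = dout / (k * k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + ho * s:s, j:j + wo * s:s] += g
        return dx


def _adaptive_bins(size: int, out: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * size / out)), int(np.ceil((i + 1) * size / out)))
            for i in range(out)]


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output size, torch-style bin boundaries."""

    def __init__(self, out_h: int, out_w: int) -> None:
        self.out_h, self.out_w = out_h, out_w
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        out = np.empty((n, c, self.out_h, self.out_w))
        for oi, (r0, r1) in enumerate(_adaptive_bins(h, self.out_h)):
            for oj, (c0, c1) in enumerate(_adaptive_bins(w, self.out_w)):
                out[:, :, oi, oj] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dx = np.zeros(self._shape)
        for oi, (r0, r1) in enumerate(_adaptive_bins(h, self.out_h)):
            for oj, (c0, c1) in enumerate(_adaptive_bins(w, self.out_w)):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += dout[:, :, oi, oj][:, :, None, None] / area
        return dx


class GlobalAvgPool(Layer):
    """Mean over spatial dims; (N, C, H, W) -> (N, C)."""

    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, name: str = "bn", eps: float = 1e-5,
                 momentum: float = 0.1) -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps, self.momentum = eps, momentum
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv, x.shape) if cache else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        if not self.training:
            return dout * (self.gamma.value * inv)[None, :, None, None]
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        term1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        term2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (dxhat - term1 / m - xhat * term2 / m)


# ---------------------------------------------------------------------------
# Composite blocks
# ---------------------------------------------------------------------------


class ResidualBlock(Layer):
    """Basic two-conv residual block; batch norm optional (deleted, not
    replaced, when ``use_batchnorm`` is False)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 stride: int = 1, use_batchnorm: bool = False, name: str = "block") -> None:
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, stride=stride, pad=1,
                            bias=not use_batchnorm, name=f"{name}.conv1")
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, stride=1, pad=1,
                            bias=not use_batchnorm, name=f"{name}.conv2")
        self.bn1 = BatchNorm2d(out_ch, f"{name}.bn1") if use_batchnorm else None
        self.bn2 = BatchNorm2d(out_ch, f"{name}.bn2") if use_batchnorm else None
        self.relu1, self.relu2 = ReLU(), ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down: Conv2d | None = Conv2d(in_ch, out_ch, 1, rng, stride=stride,
                                              pad=0, bias=not use_batchnorm,
                                              name=f"{name}.down")
            self.bn_down = BatchNorm2d(out_ch, f"{name}.bn_down") if use_batchnorm else None
        else:
            self.down, self.bn_down = None, None

    def children(self) -> list[Layer]:
        out: list[Layer] = [self.conv1, self.conv2, self.relu1, self.relu2]
        out.extend(l for l in (self.bn1, self.bn2, self.down, self.bn_down) if l is not None)
        return out

    def params(self) -> list[Param]:
        out: list[Param] = []
        for child in self.children():
            out.extend(child.params())
        return out

    def conv_layers(self) -> list[Conv2d]:
        return [l for l in (self.conv1, self.conv2, self.down) if l is not None]

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        y = self.conv1.forward(x, cache)
        if self.bn1 is not None:
            y = self.bn1.forward(y, cache)
        y = self.relu1.forward(y, cache)
        y = self.conv2.forward(y, cache)
        if self.bn2 is not None:
            y = self.bn2.forward(y, cache)
        if self.down is not None:
            sc = self.down.forward(x, cache)
            if self.bn_down is not None:
                sc = self.bn_down.forward(sc, cache)
        else:
            sc = x
        return self.relu2.forward(y + sc, cache)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dsc = d
        dy = d
        if self.bn2 is not None:
            dy = self.bn2.backward(dy)
        dy = self.conv2.backward(dy)
        dy = self.relu1.backward(dy)
        if self.bn1 is not None:
            dy = self.bn1.backward(dy)
        dx = self.conv1.backward(dy)
        if self.down is not None:
            if self.bn_down is not None:
                dsc = self.bn_down.backward(dsc)
            dx = dx + self.down.backward(dsc)
        else:
            dx = dx + dsc
        return dx
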