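"""Densely connected convolutional blocks (DenseNet-BC style)."""

from __future__ import annotations

import numpy as np

from .core import AvgPool2d, BatchNorm2d, Conv2d, Layer, Param, ReLU, Sequential


class DenseLayer(Layer):
    """BN - ReLU - 1x1 conv (bottleneck) - BN - ReLU - 3x3 conv (growth)."""

    def __init__(self, in_ch: int, growth: int, bn_size: int,
                 rng: np.random.Generator, name: str) -> None:
        mid = bn_size * growth
        self.bn1 = BatchNorm2d(in_ch, f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv1 = Conv2d(in_ch, mid, 1, rng, pad=0, bias=False, name=f"{name}.conv1")
        self.bn2 = BatchNorm2d(mid, f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv2 = Conv2d(mid, growth, 3, rng, pad=1, bias=False, name=f"{name}.conv2")

    def children(self) -> list[Layer]:
        return [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2, self.conv2]

    def params(self) -> list[Param]:
        out: list[Param] = []
        for c in self.children():
            out.extend(c.params())
        return out

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        for layer in self.children():
            x = layer.forward(x, cache)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.children()):
            dout = layer.backward(dout)
        return dout


class DenseBlock(Layer):
    """Concatenative block: each layer consumes all previous feature maps."""

    def __init__(self, n_layers: int, in_ch: int, growth: int, bn_size: int,
                 rng: np.random.Generator, name: str) -> None:
        self.growth = growth
        self.in_ch = in_ch
        self.dense_layers = [
            DenseLayer(in_ch + i * growth, growth, bn_size, rng, f"{name}.layer{i}")
            for i in range(n_layers)
        ]

    @property
    def out_channels(self) -> int:
        return self.in_ch + len(self.dense_layers) * self.growth

    def children(self) -> list[Layer]:
        return list(self.dense_layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for c in self.dense_layers:
            out.extend(c.params())
        return out

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        feats = [x]
        for layer in self.dense_layers:
            feats.append(layer.forward(np.concatenate(feats, axis=1), cache))
        return np.concatenate(feats, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        sizes = [self.in_ch] + [self.growth] * len(self.dense_layers)
        bounds = np.cumsum(sizes)[:-1]
        acc = list(np.split(dout, bounds, axis=1))
        for idx in range(len(self.dense_layers) - 1, -1, -1):
            dinp = self.dense_layers[idx].backward(acc[idx + 1])
            inner = np.split(dinp, np.cumsum(sizes[:idx + 1])[:-1], axis=1)
            for k, g in enumerate(inner):
                acc[k] = acc[k] + g
        return acc[0]


def transition(in_ch: int, out_ch: int, rng: np.random.Generator, name: str) -> Sequential:
    return Sequential(
        BatchNorm2d(in_ch, f"{name}.bn"),
        ReLU(),
        Conv2d(in_ch, out_ch, 1, rng, pad=0, bias=False, name=f"{name}.conv"),
        AvgPool2d(2, 2),
    )
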