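"""GridNet model components.

The hybrid registration network composes a *patch classifier* ``f`` (one
probability vector per foreground image patch, Nclass foreground classes)
with a *global corrector* ``g`` (a shallow grid-resolution CNN that refines
the (H_ST, W_ST, Nclass) map of class probabilities using neighborhood
context). Background positions are decided as class 0 from the background
mask alone — the network can never confuse tissue with slide background.

Also provided: a pure-segmentation baseline (a filter-reduced 34-layer
residual network over the stitched patch mosaic, adaptively pooled to grid
resolution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .grid_data import (DEFAULT_CHANNEL_MEANS, DEFAULT_CHANNEL_STDS,
                        LabelGrid, PatchArray, detect_background)
from .nn.densenet import DenseBlock, transition

BACKBONES = ("reduced_resnet18_nobn", "densenet121", "tiny_test_cnn")


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchClassifierConfig:
    backbone: str
    n_classes: int
    patch_px: int
    filter_reduction: int = 4
    use_batchnorm: bool = False

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


@dataclass(frozen=True)
class GlobalCorrectorConfig:
    """Stride-1, same-padding corrector over the class-probability grid.

    ``layer_spec`` is an ordered list of ``(kind, size, n_filters)`` with
    ``kind`` in {"conv", "hex"}; rectifiers are inserted between layers and
    the final layer always has ``n_classes`` filters followed by a softmax.
    ``size`` is the square kernel size for "conv" and the number of
    concentric rings for "hex".
    """

    layout: str
    n_classes: int
    layer_spec: tuple = ()
    row_offset_parity: str = "odd"

    def __post_init__(self) -> None:
        if self.layout not in ("cartesian", "hexagonal"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if not self.layer_spec:
            if self.layout == "cartesian":
                spec = (("conv", 3, 64), ("conv", 3, 64), ("conv", 1, self.n_classes))
            else:
                spec = (("hex", 1, 64), ("hex", 1, 64), ("conv", 1, self.n_classes))
            object.__setattr__(self, "layer_spec", spec)
        else:
            object.__setattr__(self, "layer_spec",
                               tuple((k, int(s), int(f)) for k, s, f in self.layer_spec))
        if self.layer_spec[-1][2] != self.n_classes:
            raise ValueError("final corrector layer must have n_classes filters")


# ---------------------------------------------------------------------------
# Network builders
# ---------------------------------------------------------------------------


def build_patch_classifier(config: PatchClassifierConfig, rng: np.random.Generator) -> nn.Sequential:
    """Instantiate the configured f backbone; output is softmax probabilities."""
    n = config.n_classes
    if config.backbone == "tiny_test_cnn":
        return nn.Sequential(
            nn.Conv2d(3, 16, 3, rng, pad=1, name="f.conv1"),
            nn.ReLU(),
            nn.MaxPool2d(2, 2),
            nn.Conv2d(16, 32, 3, rng, pad=1, name="f.conv2"),
            nn.ReLU(),
            nn.GlobalAvgPool(),
            nn.Linear(32, n, rng, name="f.head"),
            nn.Softmax(axis=1),
        )
    if config.backbone == "reduced_resnet18_nobn":
        # 18-layer residual backbone, batch norm deleted, filters / reduction
        base = max(64 // config.filter_reduction, 1)
        layers: list[nn.Layer] = [
            nn.Conv2d(3, base, 7, rng, stride=2, pad=3, name="f.stem"),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, pad=1),
        ]
        ch = base
        for stage, mult in enumerate((1, 2, 4, 8)):
            out = base * mult
            for b in range(2):
                stride = 2 if (stage > 0 and b == 0) else 1
                layers.append(nn.ResidualBlock(ch, out, rng, stride=stride,
                                               use_batchnorm=False,
                                               name=f"f.s{stage}b{b}"))
                ch = out
        layers += [nn.GlobalAvgPool(), nn.Linear(ch, n, rng, name="f.head"),
                   nn.Softmax(axis=1)]
        return nn.Sequential(*layers)
    if config.backbone == "densenet121":
        growth, bn_size = 32, 4
        block_cfg = (6, 12, 24, 16)
        ch = 64
        layers = [
            nn.Conv2d(3, ch, 7, rng, stride=2, pad=3, bias=False, name="f.stem"),
            nn.BatchNorm2d(ch, "f.stem_bn"),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, pad=1),
        ]
        for bi, n_layers in enumerate(block_cfg):
            block = DenseBlock(n_layers, ch, growth, bn_size, rng, f"f.dense{bi}")
            layers.append(block)
            ch = block.out_channels
            if bi != len(block_cfg) - 1:
                layers.append(transition(ch, ch // 2, rng, f"f.trans{bi}"))
                ch = ch // 2
        layers += [nn.BatchNorm2d(ch, "f.final_bn"), nn.ReLU(), nn.GlobalAvgPool(),
                   nn.Linear(ch, n, rng, name="f.head"), nn.Softmax(axis=1)]
        return nn.Sequential(*layers)
    raise ValueError(config.backbone)


def build_global_corrector(config: GlobalCorrectorConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    in_ch = config.n_classes
    for idx, (kind, size, filters) in enumerate(config.layer_spec):
        if kind == "conv":
            layers.append(nn.Conv2d(in_ch, filters, size, rng, pad=size // 2,
                                    name=f"g.layer{idx}"))
        elif kind == "hex":
            if config.layout != "hexagonal":
                raise ValueError("hex layers require hexagonal layout")
            layers.append(nn.HexConv2d(in_ch, filters, size, rng,
                                       row_offset_parity=config.row_offset_parity,
                                       name=f"g.layer{idx}"))
        else:
            raise ValueError(f"unknown corrector layer kind {kind!r}")
        if idx != len(config.layer_spec) - 1:
            layers.append(nn.ReLU())
        in_ch = filters
    layers.append(nn.Softmax(axis=1))
    return nn.Sequential(*layers)


def walk(layer: nn.Layer):
    yield layer
    for child in layer.children():
        yield from walk(child)


def conv_parameter_count(net: nn.Layer) -> int:
    """Total number of convolution weight parameters (biases excluded)."""
    total = 0
    for layer in walk(net):
        if isinstance(layer, (nn.Conv2d, nn.HexConv2d)):
            total += layer.n_weight_params()
    return total


def parameter_count(net: nn.Layer) -> int:
    return sum(p.value.size for p in net.params())


def _net_state(net: nn.Layer) -> dict[str, np.ndarray]:
    state = net.state_dict()
    for layer in walk(net):
        if isinstance(layer, nn.BatchNorm2d):
            prefix = layer.gamma.name[: -len(".gamma")]
            state[f"{prefix}.running_mean"] = layer.running_mean.copy()
            state[f"{prefix}.running_var"] = layer.running_var.copy()
    return state


def _load_net_state(net: nn.Layer, state: dict[str, np.ndarray]) -> None:
    net.load_state_dict({k: v for k, v in state.items()
                         if not k.endswith(("running_mean", "running_var"))})
    for layer in walk(net):
        if isinstance(layer, nn.BatchNorm2d):
            prefix = layer.gamma.name[: -len(".gamma")]
            layer.running_mean[...] = state[f"{prefix}.running_mean"]
            layer.running_var[...] = state[f"{prefix}.running_var"]


# ---------------------------------------------------------------------------
# Probability grids and forward passes
# ---------------------------------------------------------------------------


@dataclass
class ClassProbGrid:
    """(H_ST, W_ST, Nclass) per-spot class probabilities plus background mask.

    Foreground rows sum to 1; background rows are placeholders (zeros) and
    are decided as class 0 downstream.
    """

    probs: np.ndarray
    background_mask: np.ndarray
    layout: str | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.probs.shape[:2] != self.background_mask.shape:
            raise ValueError("probs and background_mask disagree on grid shape")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]

    def decisions(self) -> LabelGrid:
        """Argmax over foreground classes (1..Nclass); background -> 0."""
        labels = self.probs.argmax(axis=2) + 1
        labels[self.background_mask] = 0
        return LabelGrid(labels, n_classes=self.n_classes)


def classify_patches(f: nn.Sequential, patches: PatchArray,
                     minibatch: int | None = None,
                     layout: str | None = None) -> ClassProbGrid:
    """Apply the patch classifier to every foreground patch of the grid.

    Patches are flattened to a list, pushed through ``f`` (optionally in
    ``minibatch``-sized chunks, which bounds memory), and the outputs are
    scattered back to grid layout. Background positions carry zero vectors
    and are masked at decision time.
    """
    if not patches.normalized:
        raise ValueError("classify_patches expects normalized patches")
    bg = detect_background(patches)
    h, w = patches.grid_shape
    fg_idx = np.nonzero(~bg)
    probs = np.zeros((h, w, _head_classes(f)))
    if fg_idx[0].size:
        flat = patches.values[fg_idx]  # (M, hp, wp, C)
        x = flat.transpose(0, 3, 1, 2)
        out = _forward_chunks(f, x, minibatch)
        probs[fg_idx] = out
    return ClassProbGrid(probs, bg, layout=layout)


def _head_classes(f: nn.Sequential) -> int:
    for layer in reversed(list(walk(f))):
        if isinstance(layer, nn.Linear):
            return layer.W.value.shape[1]
        if isinstance(layer, (nn.Conv2d, nn.HexConv2d)):
            return layer.out_channels
    raise ValueError("cannot infer class count from network head")


def _forward_chunks(net: nn.Sequential, x: np.ndarray, minibatch: int | None) -> np.ndarray:
    if minibatch is None or minibatch >= x.shape[0]:
        return net.forward(x, cache=False)
    outs = [net.forward(x[k:k + minibatch], cache=False)
            for k in range(0, x.shape[0], minibatch)]
    return np.concatenate(outs, axis=0)


def correct_grid(g: nn.Sequential, probs: ClassProbGrid,
                 g_layout: str | None = None) -> ClassProbGrid:
    """Refine a class-probability grid with the global corrector."""
    if g_layout is not None and probs.layout is not None and g_layout != probs.layout:
        raise ValueError(f"corrector layout {g_layout!r} does not match grid layout "
                         f"{probs.layout!r}")
    x = probs.probs.transpose(2, 0, 1)[None]  # (1, N, H, W)
    out = g.forward(x, cache=False)[0].transpose(1, 2, 0)
    return ClassProbGrid(out, probs.background_mask, layout=probs.layout)


class GridNet:
    """The f/g composition with background masking."""

    def __init__(self, f: nn.Sequential, g: nn.Sequential,
                 f_config: PatchClassifierConfig, g_config: GlobalCorrectorConfig) -> None:
        self.f, self.g = f, g
        self.f_config, self.g_config = f_config, g_config

    @classmethod
    def create(cls, f_config: PatchClassifierConfig, g_config: GlobalCorrectorConfig,
               seed: int = 0) -> "GridNet":
        rng = np.random.default_rng(seed)
        return cls(build_patch_classifier(f_config, rng),
                   build_global_corrector(g_config, rng), f_config, g_config)

    def set_training(self, mode: bool) -> None:
        self.f.set_training(mode)
        self.g.set_training(mode)

    def forward(self, patches: PatchArray, minibatch: int | None = None) -> ClassProbGrid:
        local = classify_patches(self.f, patches, minibatch=minibatch,
                                 layout=self.g_config.layout)
        return correct_grid(self.g, local, g_layout=self.g_config.layout)


def gridnet_forward(model: "GridNet | ModelBundle", patches: PatchArray,
                    minibatch: int | None = None) -> tuple[ClassProbGrid, LabelGrid]:
    """Full forward pass: probabilities and the masked decision map.

    The decision map is 0 exactly on the background mask and the foreground
    argmax over classes 1..Nclass elsewhere.
    """
    if isinstance(model, ModelBundle):
        model = model.model
    probs = model.forward(patches, minibatch=minibatch)
    return probs, probs.decisions()


# ---------------------------------------------------------------------------
# Pure-segmentation baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineSegConfig:
    n_classes: int
    grid_shape: tuple[int, int]
    filter_reduction: int = 4
    use_batchnorm: bool = True


def build_baseline_seg(config: BaselineSegConfig, rng: np.random.Generator) -> nn.Sequential:
    """34-layer residual segmentation net over the stitched patch mosaic.

    The classification head is replaced by adaptive average pooling to the
    grid shape followed by a 1x1 convolution with Nclass filters, and every
    convolution's filter count is divided by ``filter_reduction``.
    """
    r = config.filter_reduction
    base = max(64 // r, 1)
    bn = config.use_batchnorm
    layers: list[nn.Layer] = [
        nn.Conv2d(3, base, 7, rng, stride=2, pad=3, bias=not bn, name="seg.stem"),
    ]
    if bn:
        layers.append(nn.BatchNorm2d(base, "seg.stem_bn"))
    layers += [nn.ReLU(), nn.MaxPool2d(3, 2, pad=1)]
    ch = base
    for stage, (mult, blocks) in enumerate(zip((1, 2, 4, 8), (3, 4, 6, 3))):
        out = base * mult
        for b in range(blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(nn.ResidualBlock(ch, out, rng, stride=stride,
                                           use_batchnorm=bn, name=f"seg.s{stage}b{b}"))
            ch = out
    layers += [
        nn.AdaptiveAvgPool2d(*config.grid_shape),
        nn.Conv2d(ch, config.n_classes, 1, rng, pad=0, name="seg.head"),
        nn.Softmax(axis=1),
    ]
    return nn.Sequential(*layers)


def stitch_patches(patches: PatchArray) -> np.ndarray:
    """Tile the patch array into one (H_ST*Hp, W_ST*Hp, C) mosaic image."""
    h, w, hp, wp, c = patches.values.shape
    return patches.values.transpose(0, 2, 1, 3, 4).reshape(h * hp, w * wp, c)


def baseline_seg_forward(net: nn.Sequential, stitched: np.ndarray,
                         grid_shape: tuple[int, int]) -> ClassProbGrid:
    """Forward the stitched mosaic; background masking as in GridNet."""
    stitched = np.asarray(stitched, dtype=np.float64)
    h_st, w_st = grid_shape
    hi, wi, c = stitched.shape
    if hi % h_st or wi % w_st:
        raise ValueError(f"stitched image {hi}x{wi} not divisible into a "
                         f"{h_st}x{w_st} grid")
    hp, wp = hi // h_st, wi // w_st
    tiles = stitched.reshape(h_st, hp, w_st, wp, c).transpose(0, 2, 1, 3, 4)
    bg = tiles.max(axis=(2, 3, 4)) == 0
    out = net.forward(stitched.transpose(2, 0, 1)[None], cache=False)[0]
    return ClassProbGrid(out.transpose(1, 2, 0), bg)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


@dataclass
class ModelBundle:
    """Trained f/g parameters plus everything needed to reapply them."""

    model: GridNet
    channel_means: tuple[float, ...] = DEFAULT_CHANNEL_MEANS
    channel_stds: tuple[float, ...] = DEFAULT_CHANNEL_STDS
    class_vocabulary: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def predict(self, patches: PatchArray, minibatch: int | None = 32
                ) -> tuple[ClassProbGrid, LabelGrid]:
        """Normalize raw patches (if needed) with the bundle's constants and run."""
        from .grid_data import normalize_patches
        if not patches.normalized:
            patches = normalize_patches(patches, self.channel_means, self.channel_stds)
        self.model.set_training(False)
        return gridnet_forward(self.model, patches, minibatch=minibatch)

    def copy(self) -> "ModelBundle":
        clone = ModelBundle(
            GridNet.create(self.model.f_config, self.model.g_config, seed=0),
            self.channel_means, self.channel_stds,
            list(self.class_vocabulary), dict(self.provenance))
        _load_net_state(clone.model.f, _net_state(self.model.f))
        _load_net_state(clone.model.g, _net_state(self.model.g))
        return clone

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "f_config": asdict(self.model.f_config),
            "g_config": asdict(self.model.g_config),
            "channel_means": list(self.channel_means),
            "channel_stds": list(self.channel_stds),
            "class_vocabulary": list(self.class_vocabulary),
            "provenance": self.provenance,
        }
        (directory / "bundle.json").write_text(json.dumps(meta, indent=2))
        arrays = {f"f::{k}": v for k, v in _net_state(self.model.f).items()}
        arrays.update({f"g::{k}": v for k, v in _net_state(self.model.g).items()})
        np.savez(directory / "params.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        f_config = PatchClassifierConfig(**meta["f_config"])
        gc = dict(meta["g_config"])
        gc["layer_spec"] = tuple(tuple(e) for e in gc["layer_spec"])
        g_config = GlobalCorrectorConfig(**gc)
        model = GridNet.create(f_config, g_config, seed=0)
        with np.load(directory / "params.npz") as data:
            f_state = {k[3:]: data[k] for k in data.files if k.startswith("f::")}
            g_state = {k[3:]: data[k] for k in data.files if k.startswith("g::")}
        _load_net_state(model.f, f_state)
        _load_net_state(model.g, g_state)
        model.set_training(False)
        return cls(model, tuple(meta["channel_means"]), tuple(meta["channel_stds"]),
                   list(meta["class_vocabulary"]), meta["provenance"])


__all__ = [
    "PatchClassifierConfig", "GlobalCorrectorConfig", "BaselineSegConfig",
    "ClassProbGrid", "GridNet", "ModelBundle",
    "build_patch_classifier", "build_global_corrector", "build_baseline_seg",
    "classify_patches", "correct_grid", "gridnet_forward",
    "baseline_seg_forward", "stitch_patches",
    "conv_parameter_count", "parameter_count", "walk",
]
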