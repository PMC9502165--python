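import numpy as np
import pytest

from gridnet.grid_data import LabelGrid, PatchArray, normalize_patches
from gridnet.models import GlobalCorrectorConfig, GridNet, PatchClassifierConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_patch_array(rng, grid_shape=(4, 4), patch_px=8, bg_fraction=0.3,
                       n_classes=4):
    """Random foreground textures + zero background, with matching labels."""
    h, w = grid_shape
    values = rng.random((h, w, patch_px, patch_px, 3)) * 0.9 + 0.05
    bg = rng.random((h, w)) < bg_fraction
    if bg.all():  # keep at least one foreground spot
        bg[h // 2, w // 2] = False
    values[bg] = 0.0
    patches = PatchArray(values, normalized=False)
    patches.background = bg
    labels = np.where(~bg, rng.integers(1, n_classes + 1, size=(h, w)), 0)
    return patches, LabelGrid(labels, n_classes)


def tiny_gridnet(seed=0, n_classes=4, patch_px=8, layout="cartesian",
                 g_spec=None):
    """Desk-scale f/g pair for fast randomized tests."""
    if g_spec is None:
        if layout == "cartesian":
            g_spec = (("conv", 3, 8), ("conv", 1, n_classes))
        else:
            g_spec = (("hex", 1, 8), ("conv", 1, n_classes))
    fc = PatchClassifierConfig("tiny_test_cnn", n_classes, patch_px)
    gc = GlobalCorrectorConfig(layout, n_classes, layer_spec=g_spec)
    return GridNet.create(fc, gc, seed=seed)


@pytest.fixture
def small_instance(rng):
    patches, labels = random_patch_array(rng)
    return normalize_patches(patches), labels
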