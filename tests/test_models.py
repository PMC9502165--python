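"""Model components: f/g composition, masking, hex convolution, baseline."""

import numpy as np
import pytest

from gridnet import nn
from gridnet.grid_data import detect_background, normalize_patches
from gridnet.models import (BaselineSegConfig, ClassProbGrid,
                            GlobalCorrectorConfig, ModelBundle,
                            PatchClassifierConfig, baseline_seg_forward,
                            build_baseline_seg, build_global_corrector,
                            build_patch_classifier, classify_patches,
                            conv_parameter_count, correct_grid,
                            gridnet_forward, stitch_patches, walk)
from gridnet.nn.hexconv import hex_conv, hex_neighbor_offsets

from conftest import random_patch_array, tiny_gridnet


def brute_force_hex_neighbors(i, j, h, w, parity):
    """Independent oracle: neighbors = spots at unit center distance."""
    sqrt3_2 = np.sqrt(3) / 2

    def xy(r, c):
        shifted = (r % 2 == 1) if parity == "odd" else (r % 2 == 0)
        return (c + (0.5 if shifted else 0.0), r * sqrt3_2)

    out = []
    for r in range(h):
        for c in range(w):
            if (r, c) != (i, j) and np.isclose(
                    np.hypot(*(np.subtract(xy(r, c), xy(i, j)))), 1.0):
                out.append((r, c))
    return sorted(out)


class TestHexConv:
    def test_identity_kernel(self, rng):
        v = rng.random((5, 7, 2))
        assert np.allclose(hex_conv(v, [1.0, 0.0], "odd"), v)

    @pytest.mark.parametrize("parity", ["odd", "even"])
    def test_impulse_reaches_exactly_six_neighbors(self, parity):
        v = np.zeros((7, 7))
        v[3, 3] = 1.0
        out = hex_conv(v, [1.0, 1.0], parity)
        nz = sorted(map(tuple, np.argwhere(out)))
        expected = sorted(brute_force_hex_neighbors(3, 3, 7, 7, parity) + [(3, 3)])
        assert nz == expected
        assert out.sum() == 7.0

    @pytest.mark.parametrize("parity", ["odd", "even"])
    def test_boundary_spot_sums_in_grid_neighbors_only(self, parity):
        # corner/edge spots have fewer than six in-grid neighbors
        v = np.ones((4, 4))
        out = hex_conv(v, [1.0, 1.0], parity)
        for i in range(4):
            for j in range(4):
                n = len(brute_force_hex_neighbors(i, j, 4, 4, parity))
                assert out[i, j] == n + 1

    @pytest.mark.parametrize("parity", ["odd", "even"])
    def test_matches_bruteforce_on_all_small_grids(self, parity, rng):
        for h in range(1, 7):
            for w in range(1, 7):
                v = rng.integers(-5, 6, size=(h, w)).astype(float)
                out = hex_conv(v, [2.0, 3.0], parity)
                for i in range(h):
                    for j in range(w):
                        acc = 2.0 * v[i, j] + 3.0 * sum(
                            v[a, b] for a, b in
                            brute_force_hex_neighbors(i, j, h, w, parity))
                        assert out[i, j] == acc

    def test_neighbor_offsets_match_geometry(self):
        for parity in ("odd", "even"):
            for i in (2, 3):
                offs = {(i + di, 3 + dj) for di, dj in hex_neighbor_offsets(i, parity)}
                assert offs == set(brute_force_hex_neighbors(i, 3, 8, 8, parity))

    def test_hexconv_layer_matches_functional(self, rng):
        layer = nn.HexConv2d(1, 1, 1, rng, bias=False)
        layer.W.value[0, 0, 0] = 2.0
        layer.W.value[0, 0, 1:] = 3.0
        v = rng.random((5, 5))
        out = layer.forward(v[None, None], cache=False)[0, 0]
        assert np.allclose(out, hex_conv(v, [2.0, 3.0], "odd"))


class TestClassifyPatches:
    def test_matches_per_patch_loop(self, small_instance):
        patches, _ = small_instance
        model = tiny_gridnet(seed=3)
        grid = classify_patches(model.f, patches, minibatch=5)
        for i in range(4):
            for j in range(4):
                if patches.background[i, j]:
                    assert np.all(grid.probs[i, j] == 0)
                else:
                    single = model.f.forward(
                        patches.values[i, j].transpose(2, 0, 1)[None], cache=False)[0]
                    assert np.allclose(grid.probs[i, j], single, atol=1e-12)

    def test_foreground_rows_sum_to_one(self, small_instance):
        patches, _ = small_instance
        grid = classify_patches(tiny_gridnet(seed=1).f, patches)
        fg = ~grid.background_mask
        assert np.allclose(grid.probs[fg].sum(axis=1), 1.0, atol=1e-9)

    def test_unnormalized_input_rejected(self, rng):
        patches, _ = random_patch_array(rng)
        with pytest.raises(ValueError):
            classify_patches(tiny_gridnet().f, patches)


class TestCorrectGrid:
    def _probs(self, rng, n=4, shape=(3, 3)):
        p = rng.random(shape + (n,))
        p /= p.sum(axis=2, keepdims=True)
        bg = np.zeros(shape, bool)
        return ClassProbGrid(p, bg, layout="cartesian")

    def test_identity_corrector_preserves_argmax(self, rng):
        n = 4
        gc = GlobalCorrectorConfig("cartesian", n, layer_spec=(("conv", 1, n),))
        g = build_global_corrector(gc, rng)
        conv = g.layers[0]
        conv.W.value[...] = 0.0
        for c in range(n):
            conv.W.value[c, c, 0, 0] = 1.0
        conv.b.value[...] = 0.0
        probs = self._probs(rng, n)
        out = correct_grid(g, probs)
        assert np.array_equal(out.probs.argmax(axis=2), probs.probs.argmax(axis=2))

    def test_uniform_kernel_constant_input_constant_interior(self, rng):
        n = 2
        gc = GlobalCorrectorConfig("cartesian", n, layer_spec=(("conv", 3, n),))
        g = build_global_corrector(gc, rng)
        probs = ClassProbGrid(np.full((5, 5, n), 0.5), np.zeros((5, 5), bool))
        out = correct_grid(g, probs).probs[1:-1, 1:-1]
        assert np.allclose(out, out[0, 0], atol=1e-12)

    def test_layout_mismatch_rejected(self, rng):
        gc = GlobalCorrectorConfig("hexagonal", 4)
        g = build_global_corrector(gc, rng)
        probs = self._probs(rng)  # cartesian layout
        with pytest.raises(ValueError, match="layout"):
            correct_grid(g, probs, g_layout="hexagonal")

    def test_hex_single_ring_impulse_response(self, rng):
        # uniform single-ring kernel: pre-softmax response is nonzero exactly
        # at the impulse and its six hexagonal neighbors
        layer = nn.HexConv2d(1, 1, 1, rng, bias=False)
        layer.W.value[...] = 1.0
        v = np.zeros((1, 1, 6, 6))
        v[0, 0, 2, 2] = 1.0
        out = layer.forward(v, cache=False)[0, 0]
        nz = sorted(map(tuple, np.argwhere(out)))
        assert nz == sorted(brute_force_hex_neighbors(2, 2, 6, 6, "odd") + [(2, 2)])


class TestGridNetForward:
    @pytest.mark.parametrize("layout", ["cartesian", "hexagonal"])
    def test_masking_contract(self, rng, layout):
        for seed in range(5):
            local = np.random.default_rng(seed)
            patches, _ = random_patch_array(local, grid_shape=(5, 4))
            norm = normalize_patches(patches)
            model = tiny_gridnet(seed=seed, layout=layout)
            _, decisions = gridnet_forward(model, norm)
            assert np.array_equal(decisions.labels == 0, detect_background(patches))
            fg = ~detect_background(patches)
            assert decisions.labels[fg].min() >= 1
            assert decisions.labels[fg].max() <= 4

    def test_identity_corrector_equals_patch_decisions(self, small_instance):
        patches, _ = small_instance
        n = 4
        model = tiny_gridnet(seed=2, g_spec=(("conv", 1, n),))
        conv = model.g.layers[0]
        conv.W.value[...] = 0.0
        for c in range(n):
            conv.W.value[c, c, 0, 0] = 1.0
        conv.b.value[...] = 0.0
        _, decisions = gridnet_forward(model, patches)
        local = classify_patches(model.f, patches)
        expected = local.probs.argmax(axis=2) + 1
        expected[local.background_mask] = 0
        assert np.array_equal(decisions.labels, expected)

    def test_minibatched_forward_equals_monolithic(self, small_instance):
        patches, _ = small_instance
        model = tiny_gridnet(seed=4)
        mono, _ = gridnet_forward(model, patches, minibatch=None)
        chunked, _ = gridnet_forward(model, patches, minibatch=3)
        rel = np.abs(mono.probs - chunked.probs).max() / max(mono.probs.max(), 1e-30)
        assert rel <= 1e-5

    def test_probability_normalization_invariant(self, rng):
        for seed in range(3):
            local = np.random.default_rng(100 + seed)
            patches, _ = random_patch_array(local, grid_shape=(3, 6))
            norm = normalize_patches(patches)
            model = tiny_gridnet(seed=seed)
            probs, _ = gridnet_forward(model, norm)
            fg = ~probs.background_mask
            assert np.allclose(probs.probs[fg].sum(axis=1), 1.0, atol=1e-6)


class TestBackbones:
    @pytest.mark.parametrize("backbone,patch_px", [
        ("tiny_test_cnn", 8),
        ("reduced_resnet18_nobn", 32),
    ])
    def test_outputs_probability_vectors(self, rng, backbone, patch_px):
        cfg = PatchClassifierConfig(backbone, 5, patch_px)
        f = build_patch_classifier(cfg, rng)
        f.set_training(False)
        out = f.forward(rng.standard_normal((2, 3, patch_px, patch_px)), cache=False)
        assert out.shape == (2, 5)
        assert np.allclose(out.sum(axis=1), 1.0)
        assert out.min() > 0

    def test_reduced_resnet_has_no_batchnorm(self, rng):
        cfg = PatchClassifierConfig("reduced_resnet18_nobn", 3, 32)
        f = build_patch_classifier(cfg, rng)
        assert not any(isinstance(l, nn.BatchNorm2d) for l in walk(f))

    def test_densenet121_structure(self, rng):
        from gridnet.models import parameter_count
        cfg = PatchClassifierConfig("densenet121", 7, 32)
        f = build_patch_classifier(cfg, rng)
        # DenseNet-121: 120 convolutions + classification head
        n_conv = sum(isinstance(l, nn.Conv2d) for l in walk(f))
        assert n_conv == 120
        assert 6_000_000 < parameter_count(f) < 9_000_000
        f.set_training(False)
        out = f.forward(rng.standard_normal((1, 3, 32, 32)), cache=False)
        assert out.shape == (1, 7)
        assert np.allclose(out.sum(axis=1), 1.0)


class TestBaselineSeg:
    def test_output_spatial_dims(self, rng):
        cfg = BaselineSegConfig(4, (3, 5), filter_reduction=16)
        net = build_baseline_seg(cfg, rng)
        net.set_training(False)
        stitched = rng.random((3 * 16, 5 * 16, 3))
        out = baseline_seg_forward(net, stitched, (3, 5))
        assert out.probs.shape == (3, 5, 4)

    def test_all_background_stitched_image(self, rng):
        cfg = BaselineSegConfig(4, (2, 2), filter_reduction=16)
        net = build_baseline_seg(cfg, rng)
        net.set_training(False)
        out = baseline_seg_forward(net, np.zeros((64, 64, 3)), (2, 2))
        assert out.background_mask.all()
        assert np.all(out.decisions().labels == 0)

    def test_indivisible_stitched_dims_rejected(self, rng):
        cfg = BaselineSegConfig(4, (3, 3), filter_reduction=16)
        net = build_baseline_seg(cfg, rng)
        with pytest.raises(ValueError, match="divisible"):
            baseline_seg_forward(net, np.zeros((50, 48, 3)), (3, 3))

    def test_filter_reduction_parameter_audit(self, rng):
        reduced = build_baseline_seg(BaselineSegConfig(4, (2, 2), 4), rng)
        full = build_baseline_seg(BaselineSegConfig(4, (2, 2), 1), rng)
        convs_r = [l for l in walk(reduced) if isinstance(l, nn.Conv2d)]
        convs_f = [l for l in walk(full) if isinstance(l, nn.Conv2d)]
        assert len(convs_r) == len(convs_f)
        # per-layer filter counts divided by four (except the Nclass head)
        for lr, lf in zip(convs_r[:-1], convs_f[:-1]):
            assert lf.out_channels == 4 * lr.out_channels
        ratio = conv_parameter_count(reduced) / conv_parameter_count(full)
        # in/out both /4 for interior layers => ~1/16 overall
        assert 1 / 16 - 0.005 < ratio < 1 / 14

    def test_stitch_patches_tiles(self, rng):
        patches, _ = random_patch_array(rng, grid_shape=(2, 3), patch_px=4)
        mosaic = stitch_patches(patches)
        assert mosaic.shape == (8, 12, 3)
        assert np.array_equal(mosaic[4:8, 4:8], patches.values[1, 1])


class TestModelBundle:
    def test_save_load_bit_identical_predictions(self, small_instance, tmp_path):
        patches, _ = small_instance
        model = tiny_gridnet(seed=9)
        bundle = ModelBundle(model, class_vocabulary=["a", "b", "c", "d"],
                             provenance={"regimen": "two_stage", "seed": 9})
        before, _ = bundle.predict(patches)
        bundle.save(tmp_path / "bundle")
        loaded = ModelBundle.load(tmp_path / "bundle")
        after, _ = loaded.predict(patches)
        assert np.array_equal(before.probs, after.probs)
        assert loaded.class_vocabulary == ["a", "b", "c", "d"]
        assert loaded.provenance["regimen"] == "two_stage"

    def test_copy_is_independent(self, small_instance):
        patches, _ = small_instance
        bundle = ModelBundle(tiny_gridnet(seed=5))
        clone = bundle.copy()
        p0, _ = bundle.predict(patches)
        clone.model.f.params()[0].value += 1.0
        p1, _ = bundle.predict(patches)
        assert np.array_equal(p0.probs, p1.probs)
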