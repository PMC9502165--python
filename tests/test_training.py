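"""Losses, checkpointed gradients, regimens, hyperparameter sampling."""

import numpy as np
import pytest

from gridnet.grid_data import normalize_patches
from gridnet.models import GlobalCorrectorConfig, PatchClassifierConfig
from gridnet.nn import Adam, Param
from gridnet.synthetic_data import SyntheticSpec, generate_dataset
from gridnet.training import (FitResult, TrainConfig, accumulate_and_update,
                              checkpointed_gradients, checkpointed_step,
                              grid_loss, load_optimizer_state,
                              monolithic_gradients, patch_loss,
                              sample_hyperparameters, save_optimizer_state,
                              train_at_once, train_fine_tune, train_two_stage)

from conftest import random_patch_array, tiny_gridnet


class TestPatchLoss:
    def test_one_hot_predictions_give_zero(self):
        p = np.eye(4)[[0, 2, 3]]
        assert patch_loss(p, np.array([1, 3, 4])) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_give_log_nclass(self):
        p = np.full((5, 4), 0.25)
        assert patch_loss(p, np.array([1, 2, 3, 4, 1])) == pytest.approx(
            np.log(4), abs=1e-9)

    def test_hand_computed_batch(self):
        p = np.array([[0.5, 0.5, 0.0, 0.0], [0.25, 0.25, 0.25, 0.25]])
        expected = (-np.log(0.5) - np.log(0.25)) / 2
        assert patch_loss(p, np.array([1, 2])) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.03972, abs=1e-5)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            patch_loss(np.full((2, 4), 0.25), np.array([0, 1]))


class TestGridLoss:
    def test_single_foreground_spot_closed_form(self):
        probs = np.full((1, 2, 2, 3), 1 / 3)
        probs[0, 0, 0] = [np.exp(-2.0), (1 - np.exp(-2.0)) / 2, (1 - np.exp(-2.0)) / 2]
        labels = np.zeros((1, 2, 2), dtype=int)
        labels[0, 0, 0] = 1
        assert grid_loss(probs, labels) == pytest.approx(2.0, abs=1e-9)

    def test_background_perturbations_do_not_change_loss(self, rng):
        probs = rng.random((2, 3, 3, 4))
        probs /= probs.sum(axis=3, keepdims=True)
        labels = rng.integers(0, 5, size=(2, 3, 3))
        base = grid_loss(probs, labels)
        perturbed = probs.copy()
        perturbed[labels == 0] = rng.random((int((labels == 0).sum()), 4))
        assert grid_loss(perturbed, labels) == base

    def test_all_background_batch_is_zero_with_warning(self):
        probs = np.full((2, 2, 2, 3), 1 / 3)
        with pytest.warns(UserWarning, match="empty foreground"):
            assert grid_loss(probs, np.zeros((2, 2, 2), dtype=int)) == 0.0

    def test_batch_averaging_over_arrays(self):
        probs = np.full((2, 1, 1, 4), 0.25)
        labels = np.ones((2, 1, 1), dtype=int)
        # each array contributes -log(0.25); mean over B=2 arrays
        assert grid_loss(probs, labels) == pytest.approx(np.log(4), abs=1e-12)


def _max_relative_grad_diff(m1, m2):
    diffs = []
    for p1, p2 in zip(m1.f.params() + m1.g.params(), m2.f.params() + m2.g.params()):
        scale = max(np.abs(p1.grad).max(), np.abs(p2.grad).max(), 1e-30)
        diffs.append(np.abs(p1.grad - p2.grad).max() / scale)
    return max(diffs)


def _random_batch(seed, layout="cartesian", grid_shape=(4, 4), b=1):
    rng = np.random.default_rng(seed)
    batch = []
    for _ in range(b):
        patches, labels = random_patch_array(rng, grid_shape=grid_shape)
        batch.append((normalize_patches(patches), labels))
    return batch


class TestCheckpointing:
    @pytest.mark.parametrize("layout", ["cartesian", "hexagonal"])
    def test_matches_monolithic_backprop(self, layout):
        batch = _random_batch(11, layout=layout)
        m1 = tiny_gridnet(seed=11, layout=layout)
        m2 = tiny_gridnet(seed=11, layout=layout)
        for m in (m1, m2):
            for p in m.f.params() + m.g.params():
                p.grad[...] = 0.0
        l1 = monolithic_gradients(m1, batch)
        l2 = checkpointed_gradients(m2, batch, D=3)
        assert l1 == pytest.approx(l2, rel=1e-9)
        assert _max_relative_grad_diff(m1, m2) <= 1e-5

    def test_large_D_degrades_to_single_minibatch(self):
        batch = _random_batch(5)
        m1 = tiny_gridnet(seed=5)
        m2 = tiny_gridnet(seed=5)
        for m in (m1, m2):
            for p in m.f.params() + m.g.params():
                p.grad[...] = 0.0
        monolithic_gradients(m1, batch)
        checkpointed_gradients(m2, batch, D=10_000)
        assert _max_relative_grad_diff(m1, m2) == 0.0

    def test_step_updates_parameters(self):
        batch = _random_batch(6)
        model = tiny_gridnet(seed=6)
        opts = [Adam([{"params": model.f.params(), "lr": 1e-3}]),
                Adam([{"params": model.g.params(), "lr": 1e-3}])]
        before = [p.value.copy() for p in model.f.params() + model.g.params()]
        loss = checkpointed_step(model, batch, opts, D=3)
        assert np.isfinite(loss)
        moved = [not np.array_equal(b, p.value)
                 for b, p in zip(before, model.f.params() + model.g.params())]
        assert any(moved)

    def test_invalid_D_rejected(self):
        with pytest.raises(ValueError):
            checkpointed_gradients(tiny_gridnet(), _random_batch(1), D=0)


class _PlainSGD:
    """Minimal gradient-descent rule for the accumulation linearity oracle."""

    def __init__(self, params, lr):
        self.params, self.lr = params, lr

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            p.value -= self.lr * p.grad


class TestAccumulation:
    def _setup(self):
        p = Param(np.array([1.0, -2.0]), "w")

        def grad_fn():
            p.grad += np.array([0.5, 0.25])  # constant batch gradient
            return 0.0

        return p, grad_fn

    def test_steps_one_is_ordinary_updates(self):
        p, fn = self._setup()
        accumulate_and_update(_PlainSGD([p], 0.1), [fn, fn, fn], 1)
        assert np.allclose(p.value, np.array([1.0, -2.0]) - 3 * 0.1 * np.array([0.5, 0.25]))

    def test_summed_gradients_equal_scaled_single_update(self):
        # k identical batches with accumulation k == one update with k*gradient
        k = 5
        p1, fn1 = self._setup()
        accumulate_and_update(_PlainSGD([p1], 0.1), [fn1] * k, k)
        p2, fn2 = self._setup()
        opt = _PlainSGD([p2], 0.1)
        opt.zero_grad()
        for _ in range(k):
            fn2()
        opt.step()
        assert np.array_equal(p1.value, p2.value)

    def test_trailing_partial_group_still_updates(self):
        p, fn = self._setup()
        accumulate_and_update(_PlainSGD([p], 0.1), [fn, fn, fn], 2)
        # one update of 2 summed gradients + one update of the trailing 1
        assert np.allclose(p.value, np.array([1.0, -2.0]) - 0.1 * 3 * np.array([0.5, 0.25]))

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            accumulate_and_update(_PlainSGD([], 0.1), [], 0)


@pytest.fixture(scope="module")
def small_dataset():
    spec = SyntheticSpec(n_rows=6, n_cols=6, patch_px=16, n_arrays=10,
                         n_classes=3, seed=5)
    return generate_dataset(spec)


def _configs(spec):
    return (PatchClassifierConfig("tiny_test_cnn", spec.n_classes, spec.patch_px),
            GlobalCorrectorConfig(spec.layout, spec.n_classes,
                                  layer_spec=(("conv", 3, 16),
                                              ("conv", 1, spec.n_classes))))


class TestRegimens:
    def test_two_stage_freezes_f_in_stage_two(self, small_dataset):
        fc, gc = _configs(small_dataset.spec)
        tc = TrainConfig(E1=1, E2=2, lr=1e-3, B=2, D=32, seed=3)
        fit = train_two_stage(small_dataset, tc, fc, gc)
        # the returned bundle's f and a fresh stage-1-only run's f agree:
        # stage 2 never touches f parameters
        tc2 = TrainConfig(E1=1, E2=1, lr=1e-3, B=2, D=32, seed=3)
        fit2 = train_two_stage(small_dataset, tc2, fc, gc)
        for p1, p2 in zip(fit.bundle.model.f.params(), fit2.bundle.model.f.params()):
            assert np.array_equal(p1.value, p2.value)
        assert len(fit.val_accuracy) == 2
        assert len(fit.stage1_val_accuracy) == 1
        assert fit.g_optimizer_state is not None

    def test_two_stage_selects_best_validation_epoch(self, small_dataset):
        fc, gc = _configs(small_dataset.spec)
        tc = TrainConfig(E1=1, E2=3, lr=1e-3, B=2, D=32, seed=3)
        fit = train_two_stage(small_dataset, tc, fc, gc)
        assert fit.best_val_accuracy == max(fit.val_accuracy)
        assert fit.best_epoch == int(np.argmax(fit.val_accuracy))  # earliest tie

    def test_at_once_deterministic_under_seed(self, small_dataset):
        fc, gc = _configs(small_dataset.spec)
        tc = TrainConfig(regimen="at_once", E=2, lr=1e-3, alpha=0.05, B=2,
                         D=16, accumulation_steps=1, seed=8)
        fit1 = train_at_once(small_dataset, tc, fc, gc)
        fit2 = train_at_once(small_dataset, tc, fc, gc)
        assert fit1.val_accuracy == fit2.val_accuracy
        assert fit1.train_accuracy == fit2.train_accuracy
        sample = small_dataset.val[0]
        p1, _ = fit1.bundle.predict(sample.patches)
        p2, _ = fit2.bundle.predict(sample.patches)
        assert np.array_equal(p1.probs, p2.probs)

    def test_at_once_alpha_zero_freezes_f(self, small_dataset):
        fc, gc = _configs(small_dataset.spec)
        tc = TrainConfig(regimen="at_once", E=1, lr=1e-3, alpha=0.0, B=2,
                         D=16, accumulation_steps=1, seed=8)
        fit = train_at_once(small_dataset, tc, fc, gc)
        rng = np.random.default_rng(tc.seed)
        from gridnet.models import GridNet
        init = GridNet.create(fc, gc, seed=int(rng.integers(0, 2 ** 31 - 1)))
        for p_trained, p_init in zip(fit.bundle.model.f.params(), init.f.params()):
            assert np.array_equal(p_trained.value, p_init.value)

    def test_fine_tune_zero_epochs_returns_pretrained(self, small_dataset):
        fc, gc = _configs(small_dataset.spec)
        tc = TrainConfig(E1=1, E2=1, lr=1e-3, B=2, D=32, seed=4)
        pre = train_two_stage(small_dataset, tc, fc, gc)
        tc_ft = TrainConfig(regimen="fine_tune", E3=0, lr=1e-3, alpha=0.05,
                            B=2, D=32, seed=4)
        fit = train_fine_tune(small_dataset, tc_ft, pre)
        sample = small_dataset.val[0]
        p0, _ = pre.bundle.predict(sample.patches)
        p1, _ = fit.bundle.predict(sample.patches)
        assert np.array_equal(p0.probs, p1.probs)

    def test_fine_tune_requires_optimizer_state(self, small_dataset):
        fc, gc = _configs(small_dataset.spec)
        tc = TrainConfig(E1=1, E2=1, lr=1e-3, B=2, D=32, seed=4)
        pre = train_two_stage(small_dataset, tc, fc, gc)
        stripped = FitResult(pre.bundle, pre.train_accuracy, pre.val_accuracy,
                             pre.best_epoch)
        with pytest.raises(ValueError, match="optimizer state"):
            train_fine_tune(small_dataset, tc, stripped)

    def test_optimizer_state_roundtrip(self, small_dataset, tmp_path):
        fc, gc = _configs(small_dataset.spec)
        tc = TrainConfig(E1=1, E2=2, lr=1e-3, B=2, D=32, seed=4)
        pre = train_two_stage(small_dataset, tc, fc, gc)
        path = tmp_path / "opt.npz"
        save_optimizer_state(pre.g_optimizer_state, path)
        back = load_optimizer_state(path)
        assert back["t"] == pre.g_optimizer_state["t"]
        for a, b in zip(back["m"][0], pre.g_optimizer_state["m"][0]):
            assert np.array_equal(a, b)
        for a, b in zip(back["v"][0], pre.g_optimizer_state["v"][0]):
            assert np.array_equal(a, b)


class TestHyperparameterSampling:
    def test_ranges(self):
        draws = sample_hyperparameters(10, seed=0)
        assert len(draws) == 10
        for lr, alpha in draws:
            assert 1e-4 < lr < 1e-3
            assert 0 < alpha < 0.1

    def test_reproducible_under_seed(self):
        assert sample_hyperparameters(5, seed=7) == sample_hyperparameters(5, seed=7)

    def test_log_lr_mean(self):
        draws = sample_hyperparameters(10_000, seed=123)
        mean = np.mean([np.log10(lr) for lr, _ in draws])
        assert mean == pytest.approx(-3.5, abs=0.01)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            sample_hyperparameters(0, seed=0)
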