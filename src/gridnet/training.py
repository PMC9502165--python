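"""Losses, memory-bounded gradient computation, and training regimens.

The grid objective is the cross-entropy of the corrected map restricted to
foreground spots, averaged over arrays in the batch:

    L = (1/B) * sum_b sum_{(i,j) in FG(Y_b)} -log P_b[i, j, y_bij]

Background spots contribute exactly nothing. When a full array of patch
activations does not fit in memory, gradients are computed with *gradient
checkpointing*: the patch classifier f is run forward in D-sized mini-batches
keeping only its outputs, the corrector g is run forward/backward once, and
each f mini-batch is then re-run forward with activations cached so its
parameter gradients can be back-propagated from the corresponding slice of
dL/dY'. Contributions are summed across mini-batches so the result equals
the monolithic gradient of the same loss (up to float reordering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid_data import (DEFAULT_CHANNEL_MEANS, DEFAULT_CHANNEL_STDS,
                        LabelGrid, normalize_patches)
from .models import (GlobalCorrectorConfig, GridNet, ModelBundle,
                     PatchClassifierConfig, classify_patches)
from .nn import Adam

PROB_FLOOR = 1e-12  # floor inside logs; numerical safety only

REGIMENS = ("two_stage", "at_once", "fine_tune")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters shared by the three regimens.

    ``lr`` is the learning rate for g; f is stepped at ``alpha * lr`` during
    joint training. ``B`` counts arrays per batch, ``D`` the checkpointing
    mini-batch size in patches, and ``accumulation_steps`` how many batch
    gradients are summed per optimizer update during joint training.
    """

    regimen: str = "two_stage"
    E1: int = 50
    E2: int = 50
    E3: int = 100
    E: int = 300
    lr: float = 1e-3
    alpha: float = 0.05
    B: int = 2
    D: int = 32
    accumulation_steps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.D < 1 or self.B < 1 or self.accumulation_steps < 1:
            raise ValueError("B, D and accumulation_steps must be >= 1")


@dataclass
class FitResult:
    """Outcome of a training run: best-on-validation bundle plus traces."""

    bundle: ModelBundle
    train_accuracy: list[float]
    val_accuracy: list[float]
    best_epoch: int
    stage1_train_accuracy: list[float] = field(default_factory=list)
    stage1_val_accuracy: list[float] = field(default_factory=list)
    g_optimizer_state: dict | None = None

    @property
    def best_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch]


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def patch_loss(pred_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of a patch batch; labels are 1-based class indices."""
    p = np.asarray(pred_probs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if y.min() < 1 or y.max() > p.shape[1]:
        raise ValueError("labels must lie in [1, Nclass]")
    true = p[np.arange(len(y)), y - 1]
    return float(-np.log(np.maximum(true, PROB_FLOOR)).mean())


def _patch_loss_grad(pred_probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    p = np.asarray(pred_probs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    idx = (np.arange(len(y)), y - 1)
    true = np.maximum(p[idx], PROB_FLOOR)
    grad = np.zeros_like(p)
    grad[idx] = -1.0 / (true * len(y))
    return float(-np.log(true).mean()), grad


def grid_loss(pred, labels) -> float:
    """Foreground cross-entropy of Eq.-style grid batches, averaged over arrays.

    ``pred`` is (B, H, W, Nclass) probabilities (or a list of per-array
    (H, W, Nclass) grids / ClassProbGrid); ``labels`` is (B, H, W) with 0 for
    background. Background positions contribute exactly nothing; an array
    with empty foreground contributes 0 (with a warning).
    """
    probs, ygrids = _as_grid_batch(pred, labels)
    total = 0.0
    for p, y in zip(probs, ygrids):
        fg = y > 0
        if not fg.any():
            warnings.warn("array with empty foreground contributes 0 to grid_loss")
            continue
        true = p[fg][np.arange(fg.sum()), y[fg] - 1]
        total += float(-np.log(np.maximum(true, PROB_FLOOR)).sum())
    return total / len(probs)


def _as_grid_batch(pred, labels):
    from .models import ClassProbGrid
    if isinstance(pred, np.ndarray) and pred.ndim == 4:
        probs = list(pred)
    else:
        probs = [p.probs if isinstance(p, ClassProbGrid) else np.asarray(p) for p in pred]
    if isinstance(labels, np.ndarray) and labels.ndim == 3:
        ygrids = list(labels)
    else:
        ygrids = [l.labels if isinstance(l, LabelGrid) else np.asarray(l) for l in labels]
    if len(probs) != len(ygrids):
        raise ValueError("prediction and label batches differ in length")
    for p, y in zip(probs, ygrids):
        if p.shape[:2] != y.shape:
            raise ValueError("prediction and label grids differ in shape")
    return probs, ygrids


def _grid_loss_grad(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and dL/dprobs for a stacked (B, H, W, N) batch."""
    b = probs.shape[0]
    fg = labels > 0
    grad = np.zeros_like(probs)
    total = 0.0
    if fg.any():
        bi, ii, ji = np.nonzero(fg)
        true = np.maximum(probs[bi, ii, ji, labels[fg] - 1], PROB_FLOOR)
        total = float(-np.log(true).sum())
        grad[bi, ii, ji, labels[fg] - 1] = -1.0 / (true * b)
    return total / b, grad


# ---------------------------------------------------------------------------
# Gradient computation: monolithic and checkpointed
# ---------------------------------------------------------------------------


def _gather_batch(batch):
    """Stack a batch of (PatchArray, LabelGrid) into flat foreground tensors."""
    patch_arrays, label_grids = [], []
    for item in batch:
        if isinstance(item, tuple):
            pa, lg = item
        else:
            pa, lg = item.patches, item.labels
        if not pa.normalized:
            raise ValueError("training expects normalized patches")
        patch_arrays.append(pa)
        label_grids.append(lg.labels if isinstance(lg, LabelGrid) else np.asarray(lg))
    h, w = patch_arrays[0].grid_shape
    b = len(patch_arrays)
    labels = np.stack(label_grids)
    fg = np.stack([~pa.background for pa in patch_arrays])
    bi, ii, ji = np.nonzero(fg)
    x = np.concatenate([patch_arrays[k].values[ii[bi == k], ji[bi == k]]
                        for k in range(b)], axis=0) if bi.size else \
        np.zeros((0,) + patch_arrays[0].values.shape[2:])
    x = x.transpose(0, 3, 1, 2)  # (M, C, hp, wp)
    return x, (bi, ii, ji), labels, fg, (b, h, w)


def _scatter_probs(flat: np.ndarray, idx, shape, n_classes: int) -> np.ndarray:
    b, h, w = shape
    grid = np.zeros((b, n_classes, h, w))
    bi, ii, ji = idx
    grid[bi, :, ii, ji] = flat
    return grid


def _g_forward_backward(model: GridNet, yprime: np.ndarray, labels: np.ndarray,
                        idx) -> tuple[float, np.ndarray]:
    """Forward/backward g on the Y' grid; returns loss and dL/dY' at fg rows."""
    out = model.g.forward(yprime, cache=True)  # (B, N, H, W) probabilities
    loss, dprobs = _grid_loss_grad(out.transpose(0, 2, 3, 1), labels)
    dyprime = model.g.backward(dprobs.transpose(0, 3, 1, 2))
    bi, ii, ji = idx
    return loss, dyprime[bi, :, ii, ji]


def monolithic_gradients(model: GridNet, batch) -> float:
    """Single forward/backward of the grid loss, all activations stored.

    Accumulates parameter gradients on the model; returns the loss.
    """
    x, idx, labels, fg, shape = _gather_batch(batch)
    flat = model.f.forward(x, cache=True)
    yprime = _scatter_probs(flat, idx, shape, flat.shape[1])
    loss, dflat = _g_forward_backward(model, yprime, labels, idx)
    model.f.backward(dflat)
    return loss


def checkpointed_gradients(model: GridNet, batch, D: int) -> float:
    """Memory-bounded equivalent of :func:`monolithic_gradients`.

    Peak stored activations are one D-sized f mini-batch plus g's; parameter
    gradients match the monolithic computation within float tolerance. A D
    larger than the patch count degrades gracefully to one mini-batch.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    x, idx, labels, fg, shape = _gather_batch(batch)
    m = x.shape[0]
    # 1) forward f in D-sized mini-batches, saving only the outputs
    outs = [model.f.forward(x[k:k + D], cache=False) for k in range(0, m, D)] or \
           [model.f.forward(x, cache=False)]
    flat = np.concatenate(outs, axis=0) if m else np.zeros((0, 1))
    yprime = _scatter_probs(flat, idx, shape, flat.shape[1])
    # 2) forward/backward g once
    loss, dflat = _g_forward_backward(model, yprime, labels, idx)
    # 3) re-forward each mini-batch with caches and back-propagate its slice;
    #    gradients sum across mini-batches into the monolithic f gradient
    for k in range(0, m, D):
        model.f.forward(x[k:k + D], cache=True)
        model.f.backward(dflat[k:k + D])
    return loss


def checkpointed_step(model: GridNet, batch, optimizers, D: int = 32) -> float:
    """One parameter update from the checkpointed gradients of a batch."""
    if not isinstance(optimizers, (list, tuple)):
        optimizers = [optimizers]
    for opt in optimizers:
        opt.zero_grad()
    loss = checkpointed_gradients(model, batch, D)
    for opt in optimizers:
        opt.step()
    return loss


def accumulate_and_update(optimizers, gradient_fns, accumulation_steps: int) -> list[float]:
    """Sum gradients over ``accumulation_steps`` batches per optimizer update.

    ``gradient_fns`` is an iterable of zero-argument callables, each of which
    accumulates one batch's gradients into the parameters and returns the
    batch loss. A trailing partial group still triggers an update.
    """
    if accumulation_steps < 1:
        raise ValueError("accumulation_steps must be >= 1")
    if not isinstance(optimizers, (list, tuple)):
        optimizers = [optimizers]
    losses: list[float] = []
    pending = 0
    for opt in optimizers:
        opt.zero_grad()
    for fn in gradient_fns:
        losses.append(fn())
        pending += 1
        if pending == accumulation_steps:
            for opt in optimizers:
                opt.step()
                opt.zero_grad()
            pending = 0
    if pending:
        for opt in optimizers:
            opt.step()
            opt.zero_grad()
    return losses


# ---------------------------------------------------------------------------
# Data preparation and accuracy helpers
# ---------------------------------------------------------------------------


def _prepare_samples(samples, means, stds):
    """Normalize raw samples; returns list of (PatchArray, labels, truth)."""
    out = []
    for s in samples:
        pa = s.patches if hasattr(s, "patches") else s[0]
        labels = s.labels if hasattr(s, "labels") else s[1]
        truth = getattr(s, "truth", labels)
        if not pa.normalized:
            pa = normalize_patches(pa, means, stds)
        lab = labels.labels if isinstance(labels, LabelGrid) else np.asarray(labels)
        tru = truth.labels if isinstance(truth, LabelGrid) else np.asarray(truth)
        out.append((pa, lab, tru))
    return out


def _grid_accuracy(model: GridNet, samples, D: int) -> float:
    correct = total = 0
    for pa, _, truth in samples:
        probs = model.forward(pa, minibatch=D)
        dec = probs.decisions().labels
        fg = truth > 0
        correct += int((dec[fg] == truth[fg]).sum())
        total += int(fg.sum())
    return correct / total if total else float("nan")


def _patch_stage_accuracy(model: GridNet, samples, D: int) -> float:
    """Accuracy of f alone (argmax of local probabilities) on foreground."""
    correct = total = 0
    for pa, _, truth in samples:
        local = classify_patches(model.f, pa, minibatch=D)
        dec = local.probs.argmax(axis=2) + 1
        fg = truth > 0
        correct += int((dec[fg] == truth[fg]).sum())
        total += int(fg.sum())
    return correct / total if total else float("nan")


def _snapshot(model: GridNet, means, stds, vocab, provenance) -> ModelBundle:
    bundle = ModelBundle(model, means, stds, list(vocab), dict(provenance))
    return bundle.copy()


def _vocab_of(data, n_classes: int) -> list[str]:
    vocab = getattr(data, "class_vocabulary", None)
    return list(vocab) if vocab else [f"class_{k}" for k in range(1, n_classes + 1)]


# ---------------------------------------------------------------------------
# Regimens
# ---------------------------------------------------------------------------


def train_two_stage(data, config: TrainConfig,
                    f_config: PatchClassifierConfig,
                    g_config: GlobalCorrectorConfig,
                    channel_means=DEFAULT_CHANNEL_MEANS,
                    channel_stds=DEFAULT_CHANNEL_STDS) -> FitResult:
    """Stage 1: fit f on all foreground training patches; stage 2: freeze f
    and fit g on the grid loss. Returns the best-on-validation model.

    Patch-stage batches hold B*H_ST*W_ST patches so their information content
    matches grid-stage batches of B arrays.
    """
    rng = np.random.default_rng(config.seed)
    model = GridNet.create(f_config, g_config,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
    train = _prepare_samples(data.train, channel_means, channel_stds)
    val = _prepare_samples(data.val, channel_means, channel_stds)
    if not train:
        raise ValueError("empty training set")

    # ---- stage 1: patch classifier ------------------------------------
    xs, ys = [], []
    for pa, lab, _ in train:
        fg = lab > 0
        xs.append(pa.values[fg].transpose(0, 3, 1, 2))
        ys.append(lab[fg])
    x = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0)
    if len(y) == 0:
        raise ValueError("no foreground patches in the training set")
    h, w = train[0][0].grid_shape
    patch_batch = max(config.B * h * w, 1)
    opt_f = Adam([{"params": model.f.params(), "lr": config.lr}])
    s1_train, s1_val = [], []
    model.set_training(True)
    for _ in range(config.E1):
        perm = rng.permutation(len(y))
        correct = 0
        for k in range(0, len(y), patch_batch):
            sel = perm[k:k + patch_batch]
            opt_f.zero_grad()
            probs = model.f.forward(x[sel], cache=True)
            _, dprobs = _patch_loss_grad(probs, y[sel])
            model.f.backward(dprobs)
            opt_f.step()
            correct += int((probs.argmax(axis=1) + 1 == y[sel]).sum())
        s1_train.append(correct / len(y))
        model.set_training(False)
        s1_val.append(_patch_stage_accuracy(model, val, config.D))
        model.set_training(True)

    # ---- stage 2: global corrector, f frozen ---------------------------
    model.set_training(False)  # f is a fixed feature extractor from here on
    def _local_grid(pa):
        return classify_patches(model.f, pa, minibatch=config.D).probs.transpose(2, 0, 1)

    yp_train = [_local_grid(pa) for pa, _, _ in train]
    yp_val = [_local_grid(pa) for pa, _, _ in val]
    opt_g = Adam([{"params": model.g.params(), "lr": config.lr}])
    train_acc, val_acc = [], []
    best = (-np.inf, -1, None, None)
    vocab = _vocab_of(data, g_config.n_classes)
    prov = {"regimen": "two_stage", "lr": config.lr, "alpha": config.alpha,
            "seed": config.seed, "epochs": [config.E1, config.E2]}
    for epoch in range(config.E2):
        order = rng.permutation(len(train))
        correct = total = 0
        for k in range(0, len(order), config.B):
            sel = order[k:k + config.B]
            yp = np.stack([yp_train[i] for i in sel])
            labels = np.stack([train[i][1] for i in sel])
            opt_g.zero_grad()
            out = model.g.forward(yp, cache=True)
            _, dprobs = _grid_loss_grad(out.transpose(0, 2, 3, 1), labels)
            model.g.backward(dprobs.transpose(0, 3, 1, 2))
            opt_g.step()
            dec = out.argmax(axis=1) + 1
            fg = labels > 0
            correct += int((dec[fg] == labels[fg]).sum())
            total += int(fg.sum())
        train_acc.append(correct / total if total else float("nan"))
        vc = vt = 0
        for (pa, _, truth), yp in zip(val, yp_val):
            out = model.g.forward(yp[None], cache=False)[0]
            dec = out.argmax(axis=0) + 1
            dec[pa.background] = 0
            fg = truth > 0
            vc += int((dec[fg] == truth[fg]).sum())
            vt += int(fg.sum())
        va = vc / vt if vt else float("nan")
        val_acc.append(va)
        if va > best[0]:
            best = (va, epoch,
                    _snapshot(model, channel_means, channel_stds, vocab, prov),
                    opt_g.state_dict())
    if best[2] is None:
        best = (val_acc[-1] if val_acc else float("nan"), max(config.E2 - 1, 0),
                _snapshot(model, channel_means, channel_stds, vocab, prov),
                opt_g.state_dict())
    return FitResult(best[2], train_acc, val_acc, best[1],
                     stage1_train_accuracy=s1_train, stage1_val_accuracy=s1_val,
                     g_optimizer_state=best[3])


def _joint_train(model: GridNet, data, config: TrainConfig, epochs: int,
                 channel_means, channel_stds, regimen: str,
                 g_optimizer_state: dict | None = None,
                 include_initial: bool = False) -> FitResult:
    rng = np.random.default_rng(config.seed + 1)
    train = _prepare_samples(data.train, channel_means, channel_stds)
    val = _prepare_samples(data.val, channel_means, channel_stds)
    vocab = _vocab_of(data, model.g_config.n_classes)
    prov = {"regimen": regimen, "lr": config.lr, "alpha": config.alpha,
            "seed": config.seed, "epochs": epochs}
    opt_g = Adam([{"params": model.g.params(), "lr": config.lr}])
    opt_f = Adam([{"params": model.f.params(), "lr": config.alpha * config.lr}])
    if g_optimizer_state is not None:
        opt_g.load_state_dict(g_optimizer_state)
    train_acc, val_acc = [], []
    best = (-np.inf, -1, None)
    if include_initial:
        model.set_training(False)
        va = _grid_accuracy(model, val, config.D)
        val_acc.append(va)
        train_acc.append(_grid_accuracy(model, train, config.D))
        best = (va, 0, _snapshot(model, channel_means, channel_stds, vocab, prov))
    for epoch in range(epochs):
        model.set_training(True)
        order = rng.permutation(len(train))
        batches = [order[k:k + config.B] for k in range(0, len(order), config.B)]

        def _fns():
            for sel in batches:
                batch = [(train[i][0], train[i][1]) for i in sel]
                yield lambda b=batch: checkpointed_gradients(model, b, config.D)

        accumulate_and_update([opt_g, opt_f], _fns(), config.accumulation_steps)
        model.set_training(False)
        train_acc.append(_grid_accuracy(model, train, config.D))
        va = _grid_accuracy(model, val, config.D)
        val_acc.append(va)
        if va > best[0]:
            best = (va, len(val_acc) - 1,
                    _snapshot(model, channel_means, channel_stds, vocab, prov))
    if best[2] is None:
        best = (val_acc[-1], len(val_acc) - 1,
                _snapshot(model, channel_means, channel_stds, vocab, prov))
    return FitResult(best[2], train_acc, val_acc, best[1])


def train_at_once(data, config: TrainConfig,
                  f_config: PatchClassifierConfig,
                  g_config: GlobalCorrectorConfig,
                  channel_means=DEFAULT_CHANNEL_MEANS,
                  channel_stds=DEFAULT_CHANNEL_STDS) -> FitResult:
    """Joint optimization of f and g from random initialization, with f
    stepped at alpha*lr and g at lr."""
    rng = np.random.default_rng(config.seed)
    model = GridNet.create(f_config, g_config,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
    return _joint_train(model, data, config, config.E, channel_means,
                        channel_stds, "at_once")


def train_fine_tune(data, config: TrainConfig, pretrained: FitResult,
                    channel_means=DEFAULT_CHANNEL_MEANS,
                    channel_stds=DEFAULT_CHANNEL_STDS) -> FitResult:
    """Resume from a two-stage result: g's optimizer state is restored, f
    gets a fresh optimizer at alpha*lr, and both train jointly for E3 epochs.

    The pretrained model itself is a selection candidate (epoch 0), so zero
    further epochs returns it unchanged.
    """
    if pretrained.g_optimizer_state is None:
        raise ValueError("pretrained FitResult carries no optimizer state for g")
    model = pretrained.bundle.copy().model
    return _joint_train(model, data, config, config.E3, channel_means,
                        channel_stds, "fine_tune",
                        g_optimizer_state=pretrained.g_optimizer_state,
                        include_initial=True)


def save_optimizer_state(state: dict, path) -> None:
    """Persist a single-group Adam state (fine-tuning resumes g's optimizer)."""
    arrays = {"t": np.asarray(state["t"]), "lrs": np.asarray(state["lrs"])}
    for i, a in enumerate(state["m"][0]):
        arrays[f"m_{i}"] = a
    for i, a in enumerate(state["v"][0]):
        arrays[f"v_{i}"] = a
    np.savez(path, **arrays)


def load_optimizer_state(path) -> dict:
    with np.load(path) as data:
        n = sum(1 for k in data.files if k.startswith("m_"))
        return {
            "t": int(data["t"]),
            "lrs": data["lrs"].tolist(),
            "m": [[data[f"m_{i}"] for i in range(n)]],
            "v": [[data[f"v_{i}"] for i in range(n)]],
        }


def sample_hyperparameters(n: int, seed: int) -> list[tuple[float, float]]:
    """Draw (lr, alpha) pairs: log10(lr) ~ U(-4, -3), alpha ~ U(0, 0.1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lrs = 10.0 ** rng.uniform(-4.0, -3.0, size=n)
    alphas = rng.uniform(0.0, 0.1, size=n)
    return list(zip(lrs.tolist(), alphas.tolist()))


__all__ = [
    "TrainConfig", "FitResult", "patch_loss", "grid_loss",
    "monolithic_gradients", "checkpointed_gradients", "checkpointed_step",
    "accumulate_and_update", "train_two_stage", "train_at_once",
    "train_fine_tune", "sample_hyperparameters", "PROB_FLOOR",
]
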