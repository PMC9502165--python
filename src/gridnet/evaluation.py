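"""Registration metrics: foreground accuracy, one-vs-rest AUROC/AUPRC,
row-normalized confusion matrices, class adjacency, misclassification-density
maps, and unweighted-vote ensembling.

All metrics are computed over foreground spots only: background is decided
deterministically by masking and would inflate every score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .grid_data import LabelGrid
from .models import ClassProbGrid


def _label_batch(batch) -> list[np.ndarray]:
    if isinstance(batch, np.ndarray) and batch.ndim == 3:
        return list(batch)
    if isinstance(batch, (LabelGrid, np.ndarray)):
        batch = [batch]
    return [b.labels if isinstance(b, LabelGrid) else np.asarray(b) for b in batch]


def _prob_batch(batch) -> list[tuple[np.ndarray, np.ndarray | None]]:
    if isinstance(batch, (ClassProbGrid, np.ndarray)):
        batch = [batch]
    out = []
    for b in batch:
        if isinstance(b, ClassProbGrid):
            out.append((b.probs, b.background_mask))
        else:
            out.append((np.asarray(b), None))
    return out


def foreground_accuracy(pred, truth) -> float:
    """Fraction of foreground spots with matching labels (background excluded).

    Returns NaN (with a warning) when there are no foreground positions.
    """
    preds, truths = _label_batch(pred), _label_batch(truth)
    correct = total = 0
    for p, t in zip(preds, truths):
        if p.shape != t.shape:
            raise ValueError("prediction and truth grids differ in shape")
        fg = t > 0
        correct += int((p[fg] == t[fg]).sum())
        total += int(fg.sum())
    if total == 0:
        warnings.warn("no foreground positions; accuracy undefined")
        return float("nan")
    return correct / total


def _flatten_foreground(prob, truth) -> tuple[np.ndarray, np.ndarray]:
    probs, truths = _prob_batch(prob), _label_batch(truth)
    scores, labels = [], []
    for (p, _), t in zip(probs, truths):
        fg = t > 0
        scores.append(p[fg])
        labels.append(t[fg])
    return np.concatenate(scores, axis=0), np.concatenate(labels, axis=0)


def ovr_curves(prob, truth) -> dict:
    """One-vs-rest AUROC (trapezoidal) and AUPRC (step integration) per class.

    Each class is scored by its probability column against the binary
    indicator truth == class; macro values are unweighted means over the
    classes whose curves are defined. A class absent from the truth (or
    covering all of it) has an undefined curve: it is reported as NaN and
    excluded from the macro average, with a warning.
    """
    scores, labels = _flatten_foreground(prob, truth)
    n_classes = scores.shape[1]
    auroc = np.full(n_classes, np.nan)
    auprc = np.full(n_classes, np.nan)
    for c in range(1, n_classes + 1):
        pos = labels == c
        if pos.sum() == 0 or pos.sum() == len(pos):
            warnings.warn(f"class {c} has no {'positives' if pos.sum() == 0 else 'negatives'}; "
                          "its one-vs-rest curves are undefined and excluded from the macro")
            continue
        auroc[c - 1] = roc_auc_score(pos, scores[:, c - 1])
        auprc[c - 1] = average_precision_score(pos, scores[:, c - 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        macro_auroc = float(np.nanmean(auroc)) if np.isfinite(auroc).any() else float("nan")
        macro_auprc = float(np.nanmean(auprc)) if np.isfinite(auprc).any() else float("nan")
    return {"auroc": auroc, "auprc": auprc,
            "macro_auroc": macro_auroc, "macro_auprc": macro_auprc}


def confusion_matrix(pred, truth, n_classes: int) -> np.ndarray:
    """Row-stochastic confusion matrix over foreground spots.

    Entry (r, c) is the fraction of true-class-(r+1) spots predicted as
    class (c+1); rows without support are left as zeros and flagged.
    """
    preds, truths = _label_batch(pred), _label_batch(truth)
    counts = np.zeros((n_classes, n_classes))
    for p, t in zip(preds, truths):
        fg = t > 0
        np.add.at(counts, (t[fg] - 1, p[fg] - 1), 1)
    sums = counts.sum(axis=1)
    empty = sums == 0
    if empty.any():
        warnings.warn(f"classes {list(np.nonzero(empty)[0] + 1)} have no foreground "
                      "support; their confusion rows are zero")
    out = np.zeros_like(counts)
    out[~empty] = counts[~empty] / sums[~empty, None]
    return out


@dataclass
class AdjacencyMatrix:
    """Counts of neighboring foreground patch pairs by class pair.

    Each unordered neighboring pair (a, b) increments counts[a-1][b-1] and
    counts[b-1][a-1], so the counts matrix is symmetric and its total equals
    twice the number of foreground-foreground edges. ``normalized`` divides
    each row by its sum (the frequency with which patches of class [row]
    neighbor patches of class [column]).
    """

    counts: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        out = np.zeros(self.counts.shape)
        nz = sums[:, 0] > 0
        out[nz] = self.counts[nz] / sums[nz]
        return out


def class_adjacency(truth, layout: str, n_classes: int,
                    row_offset_parity: str = "odd") -> AdjacencyMatrix:
    """Class adjacency over foreground spots; 4-neighborhood on cartesian
    grids, true 6-neighborhood on hexagonal grids."""
    truths = _label_batch(truth)
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t in truths:
        h, w = t.shape
        for i in range(h):
            # keep only "forward" offsets so each undirected edge is visited once
            if layout == "cartesian":
                offs = [(0, 1), (1, 0)]
            else:
                from .nn.hexconv import hex_neighbor_offsets
                offs = [(di, dj) for di, dj in hex_neighbor_offsets(i, row_offset_parity)
                        if di > 0 or (di == 0 and dj > 0)]
            for j in range(w):
                a = t[i, j]
                if a == 0:
                    continue
                for di, dj in offs:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and t[ni, nj] > 0:
                        b = t[ni, nj]
                        counts[a - 1, b - 1] += 1
                        counts[b - 1, a - 1] += 1
    return AdjacencyMatrix(counts)


def misclassification_map(prob, truth) -> np.ndarray:
    """Per-spot 1 - P(true class); background carries NaN as a sentinel."""
    (p, _), = _prob_batch(prob)
    (t,) = _label_batch(truth)
    if p.shape[:2] != t.shape:
        raise ValueError("probability grid and truth differ in shape")
    out = np.full(t.shape, np.nan)
    fg = t > 0
    ii, jj = np.nonzero(fg)
    out[ii, jj] = 1.0 - p[ii, jj, t[fg] - 1]
    return out


def ensemble_vote(predictions, probabilities=None):
    """Unweighted modal vote across predictors, per position.

    ``predictions`` is a list of predictors, each a LabelGrid / 2-D array or
    a batch thereof. Ties are broken by the mean predicted probability of the
    tied classes when ``probabilities`` (one ClassProbGrid batch per
    predictor) is supplied, otherwise by the lowest class index. All
    predictors must agree on shapes and background masks.
    """
    if len(predictions) < 1:
        raise ValueError("need at least one predictor")
    batches = [_label_batch(p) for p in predictions]
    n_arrays = len(batches[0])
    if any(len(b) != n_arrays for b in batches):
        raise ValueError("predictors disagree on batch length")
    prob_batches = None
    if probabilities is not None:
        prob_batches = [_prob_batch(p) for p in probabilities]
    out = []
    for a in range(n_arrays):
        grids = [b[a] for b in batches]
        shape = grids[0].shape
        if any(g.shape != shape for g in grids):
            raise ValueError("predictors disagree on grid shape")
        masks = [g == 0 for g in grids]
        if any((m != masks[0]).any() for m in masks[1:]):
            raise ValueError("predictors disagree on background masks")
        stack = np.stack(grids)  # (P, H, W)
        n_classes = int(max(stack.max(), 1))
        votes = np.zeros((n_classes + 1,) + shape, dtype=np.int64)
        for c in range(1, n_classes + 1):
            votes[c] = (stack == c).sum(axis=0)
        result = np.zeros(shape, dtype=np.int64)
        fg = ~masks[0]
        counts = votes[1:, fg]  # (C, M)
        top = counts.max(axis=0)
        winners = counts == top
        n_tied = winners.sum(axis=0)
        choice = counts.argmax(axis=0) + 1  # lowest index among maxima
        if prob_batches is not None and (n_tied > 1).any():
            mean_p = np.mean([pb[a][0][fg] for pb in prob_batches], axis=0)  # (M, C)
            tied_cols = np.nonzero(n_tied > 1)[0]
            for col in tied_cols:
                cands = np.nonzero(winners[:, col])[0]
                choice[col] = cands[np.argmax(mean_p[col, cands])] + 1
        result[fg] = choice
        out.append(result)
    return out if len(out) > 1 else out[0]


@dataclass
class MetricReport:
    """Aggregate evaluation: accuracy, per-class/macro AUROC & AUPRC,
    row-stochastic confusion matrix and per-class foreground support."""

    accuracy: float
    auroc: np.ndarray
    auprc: np.ndarray
    macro_auroc: float
    macro_auprc: float
    confusion: np.ndarray
    support: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auroc": [None if not np.isfinite(v) else float(v) for v in self.auroc],
            "auprc": [None if not np.isfinite(v) else float(v) for v in self.auprc],
            "macro_auroc": self.macro_auroc,
            "macro_auprc": self.macro_auprc,
            "confusion": self.confusion.tolist(),
            "support": self.support.tolist(),
            "class_names": self.class_names,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def per_class_frame(self) -> pd.DataFrame:
        names = self.class_names or [f"class_{k+1}" for k in range(len(self.auroc))]
        return pd.DataFrame({"class": names, "auroc": self.auroc,
                             "auprc": self.auprc, "support": self.support})


def evaluate(prob, pred, truth, n_classes: int,
             class_names: list[str] | None = None) -> MetricReport:
    """Full metric suite over a batch of predictions."""
    curves = ovr_curves(prob, truth)
    truths = _label_batch(truth)
    support = np.zeros(n_classes, dtype=np.int64)
    for t in truths:
        fg = t > 0
        np.add.at(support, t[fg] - 1, 1)
    return MetricReport(
        accuracy=foreground_accuracy(pred, truth),
        auroc=curves["auroc"], auprc=curves["auprc"],
        macro_auroc=curves["macro_auroc"], macro_auprc=curves["macro_auprc"],
        confusion=confusion_matrix(pred, truth, n_classes),
        support=support, class_names=list(class_names or []),
    )


__all__ = [
    "foreground_accuracy", "ovr_curves", "confusion_matrix",
    "class_adjacency", "AdjacencyMatrix", "misclassification_map",
    "ensemble_vote", "MetricReport", "evaluate",
]
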