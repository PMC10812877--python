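"""Optimization loop: Adam on the 2-class cross-entropy, two stopping rules.

The loss is the mean negative log-softmax of the true-class output over the
batch. Two early-stopping rules are provided: a batch-loss plateau (stop once
the mean loss of the previous ``loss_window`` batches exceeds the current
batch loss by less than ``loss_delta``) and a validation-F1 plateau (stop
once none of ``f1_window`` consecutive epochs improves the F1 of the
reference epoch by at least ``f1_delta`` percentage points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .evaluation import confusion
from .model_core import TFTFModel, loss_from_logits


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2500
    max_epochs: int = 100
    stop_rule: str | None = "f1_plateau"  # f1_plateau | loss_plateau | None
    loss_window: int = 50
    loss_delta: float = 0.01
    loss_patience: int = 1  # consecutive plateau hits required
    f1_window: int = 4
    f1_delta: float = 0.2  # percentage points
    min_epochs: int = 0  # warm-up before the F1 plateau rule may fire
    val_fraction: float = 0.1  # used when no validation set is supplied
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate and batch size must be positive")


def eq_loss(x1: np.ndarray, x2: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-softmax of the true-class output.

    ``labels`` are in {1, 2}: label 1 means x1 is the true-class output.
    Numerically stabilized by max subtraction.
    """
    x1, x2, labels = map(np.asarray, (x1, x2, labels))
    if x1.size == 0:
        raise ValueError("empty batch")
    if not np.isin(labels, (1, 2)).all():
        raise ValueError("labels must be in {1, 2}")
    logits = np.stack([x1, x2], axis=1).astype(np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(labels)), labels - 1].mean())


def loss_plateau_stop(losses: list, window: int = 50, delta: float = 0.01) -> bool:
    """True when mean(previous ``window`` batch losses) - current < delta.

    Requires at least ``window`` prior batches.
    """
    if len(losses) <= window:
        return False
    prev = np.mean(losses[-window - 1 : -1])
    return bool(prev - losses[-1] < delta)


def f1_plateau_stop(f1s: list, window: int = 4, delta: float = 0.2) -> bool:
    """True when ``window`` consecutive epochs improved the reference epoch's
    validation F1 (in percent) by less than ``delta`` percentage points."""
    if len(f1s) <= window:
        return False
    ref = f1s[-window - 1]
    return all(f < ref + delta for f in f1s[-window:])


def _subset(data: dict, idx: np.ndarray) -> dict:
    return {
        "dna": data["dna"][idx],
        "omics": data["omics"][:, idx] if data["omics"].size else data["omics"],
        "mask": data["mask"][idx],
    }


def _val_f1(model: TFTFModel, data: dict, labels: np.ndarray) -> float:
    conf = model.confidences(data)
    report = confusion(conf, labels == 1, threshold=0.0)
    return 100.0 * report.f1


def train(
    model: TFTFModel,
    data: dict,
    labels: np.ndarray,
    config: TrainConfig,
    val_data: dict | None = None,
    val_labels: np.ndarray | None = None,
) -> dict:
    """Train in place; returns a history dict.

    ``data`` is an encoded batch (see tokenization.encode_batch); ``labels``
    are in {1, 2} (1 = positive). With the f1_plateau rule and no explicit
    validation set, a stratified ``val_fraction`` split is held out.
    """
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == 2).any()):
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)

    n = len(labels)
    train_idx = np.arange(n)
    if config.stop_rule == "f1_plateau" and val_data is None:
        val_parts = []
        for cls in (1, 2):
            cls_idx = np.flatnonzero(labels == cls)
            k = max(1, int(round(config.val_fraction * len(cls_idx))))
            val_parts.append(rng.permutation(cls_idx)[:k])
        val_idx = np.concatenate(val_parts)
        train_idx = np.setdiff1d(train_idx, val_idx)
        val_data = _subset(data, val_idx)
        val_labels = labels[val_idx]

    opt = Adam(model.params, lr=config.learning_rate)
    history = {"batch_loss": [], "val_f1": [], "epochs": 0, "stopped": "max_epochs"}
    plateau_hits = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        stop = False
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            logits, _, _ = model.forward(_subset(data, idx))
            loss = loss_from_logits(logits, labels[idx])
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: loss={lval} at epoch {epoch}, "
                    f"batch {len(history['batch_loss'])}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            history["batch_loss"].append(lval)
            if config.stop_rule == "loss_plateau":
                if loss_plateau_stop(
                    history["batch_loss"], config.loss_window, config.loss_delta
                ):
                    plateau_hits += 1
                    if plateau_hits >= config.loss_patience:
                        history["stopped"] = "loss_plateau"
                        stop = True
                        break
                else:
                    plateau_hits = 0
        history["epochs"] = epoch + 1
        if stop:
            break
        if config.stop_rule == "f1_plateau":
            history["val_f1"].append(_val_f1(model, val_data, val_labels))
            if epoch + 1 >= config.min_epochs and f1_plateau_stop(
                history["val_f1"], config.f1_window, config.f1_delta
            ):
                history["stopped"] = "f1_plateau"
                break
    return history


def make_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold ids (0..k-1) forming a near-equal partition of n items."""
    ids = np.arange(n) % k
    return ids[rng.permutation(n)]


def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment keeping positives and negatives balanced per fold."""
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        folds[idx] = make_folds(len(idx), k, rng)
    return folds


def crossvalidate(
    model_factory,
    cell_data: dict,
    config: TrainConfig,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """k-fold cross-validation over multiple cells.

    ``cell_data`` maps cell id -> (encoded batch, labels in {1,2}). Each
    cell's samples are partitioned into k class-balanced folds; run ``i``
    trains a fresh model on the union of the other k-1 folds of ALL cells and
    tests on fold i of all cells. Cells with fewer than k positives are
    excluded with a warning. Returns per-fold and pooled metrics.
    """
    rng = np.random.default_rng(seed)
    fold_assignment = {}
    usable = {}
    for cell, (data, labels) in cell_data.items():
        if int((np.asarray(labels) == 1).sum()) < k:
            warnings.warn(f"cell {cell!r} has fewer than {k} positives; excluded")
            continue
        usable[cell] = (data, np.asarray(labels))
        fold_assignment[cell] = stratified_folds(usable[cell][1], k, rng)
    if not usable:
        raise ValueError("no cell has enough positives for cross-validation")

    per_fold, per_cell_f1 = [], {c: [] for c in usable}
    for fold in range(k):
        tr_parts, te_parts = [], []
        for cell, (data, labels) in usable.items():
            test_mask = fold_assignment[cell] == fold
            tr_parts.append((_subset(data, np.flatnonzero(~test_mask)), labels[~test_mask]))
            te_parts.append((cell, _subset(data, np.flatnonzero(test_mask)), labels[test_mask]))
        tr_data = {
            "dna": np.concatenate([d["dna"] for d, _ in tr_parts]),
            "omics": np.concatenate([d["omics"] for d, _ in tr_parts], axis=1)
            if tr_parts[0][0]["omics"].size
            else tr_parts[0][0]["omics"],
            "mask": np.concatenate([d["mask"] for d, _ in tr_parts]),
        }
        tr_labels = np.concatenate([l for _, l in tr_parts])
        model = model_factory()
        train(model, tr_data, tr_labels, config)
        all_conf = np.concatenate([model.confidences(d) for _, d, _ in te_parts])
        all_lab = np.concatenate([l for _, _, l in te_parts])
        per_fold.append(confusion(all_conf, all_lab == 1))
        for cell, d, l in te_parts:
            per_cell_f1[cell].append(confusion(model.confidences(d), l == 1).f1)

    return {
        "per_fold": per_fold,
        "mean_f1": float(np.mean([r.f1 for r in per_fold])),
        "per_cell_f1": {c: float(np.mean(v)) for c, v in per_cell_f1.items()},
        "fold_assignment": fold_assignment,
    }
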