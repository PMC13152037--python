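"""Cross-validated training of the attention residual network.

Implements the study protocol: stratified 5-fold cross-validation,
cross-entropy loss, Adam at learning rate 0.001 with step decay
(gamma 0.1 every 7 epochs), batch size 8, 50 epochs, He initialization,
and checkpointing of the weights with the best validation accuracy.
Scaled-down configurations (fewer epochs/folds, smaller images) use the
same code path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .nn.optim import Adam, softmax_cross_entropy, step_lr
from .nn.resnet import (CamResNet18, NetworkConfig, build_cam_resnet18,
                        load_checkpoint, recalibrate_batchnorm, save_checkpoint,
                        softmax_scores)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every sample id to exactly one validation fold."""

    k: int
    assignment: dict  # sample_id -> fold index

    def fold_ids(self, fold: int) -> list:
        return [sid for sid, f in self.assignment.items() if f == fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the study settings."""

    lr: float = 0.001
    epochs: int = 50
    batch_size: int = 8
    step_size: int = 7
    gamma: float = 0.1
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    seed: int = 0


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0
    best_checkpoint: Optional[str] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": self.epochs, "lr": self.lr,
            "train_loss": self.train_loss, "val_acc": self.val_accuracy,
        })


def make_folds(sample_ids: Sequence, labels: Sequence, k: int = 5, seed: int = 0,
               stratified: bool = True) -> FoldPlan:
    """Partition sample ids into k near-equal (optionally stratified) folds."""
    sample_ids = list(sample_ids)
    labels = list(labels)
    if len(sample_ids) != len(labels):
        raise ValueError("sample_ids and labels must have equal length")
    if len(sample_ids) < k:
        raise ValueError(f"cannot split {len(sample_ids)} samples into {k} folds")
    splitter = (StratifiedKFold(k, shuffle=True, random_state=seed) if stratified
                else KFold(k, shuffle=True, random_state=seed))
    y = np.asarray(labels)
    assignment = {}
    for fold, (_, val_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        for i in val_idx:
            assignment[sample_ids[i]] = fold
    return FoldPlan(k, assignment)


def cross_entropy_loss(p_true: np.ndarray, q_pred: np.ndarray, eps: float = 1e-12) -> float:
    """H(p, q) = -sum_i p_i log q_i; for one-hot p this is -log q(true).

    Accepts a single pair of distributions or a batch (rows), in which
    case the batch mean is returned. Zero predicted probability at the
    true class is clamped at ``eps``.
    """
    p = np.atleast_2d(np.asarray(p_true, dtype=np.float64))
    q = np.atleast_2d(np.asarray(q_pred, dtype=np.float64))
    if p.shape != q.shape:
        raise ValueError("p and q must have the same shape")
    losses = -(p * np.log(np.maximum(q, eps))).sum(axis=1)
    return float(losses.mean())


def _as_nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:  # (n, H, W) -> single channel
        x = x[:, None, :, :]
    if x.ndim != 4:
        raise ValueError("expected (n, H, W) or (n, C, H, W) input images")
    return x


def evaluate_accuracy(model: CamResNet18, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 64) -> float:
    x = _as_nchw(x)
    correct = 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return correct / len(x)


def train_model(x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray, y_val: np.ndarray,
                cfg: TrainConfig | None = None,
                net_cfg: NetworkConfig | None = None,
                checkpoint_path: Optional[str] = None,
                model: Optional[CamResNet18] = None) -> tuple[CamResNet18, TrainHistory]:
    """Train with per-epoch validation; keep the best-validation weights.

    Ties in validation accuracy go to the earliest epoch. If
    ``checkpoint_path`` is given the best weights are persisted there;
    they are also restored into the returned model.
    """
    cfg = cfg or TrainConfig()
    x_train, x_val = _as_nchw(x_train), _as_nchw(x_val)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("both training and validation splits must be non-empty")
    n_classes = (net_cfg.num_classes if net_cfg is not None
                 else model.cfg.num_classes if model is not None else 5)
    present = np.unique(y_train)
    if len(present) < n_classes:
        raise ValueError(
            f"training split contains {len(present)} of {n_classes} classes")

    if model is None:
        net_cfg = net_cfg or NetworkConfig(input_size=x_train.shape[-1])
        model = build_cam_resnet18(net_cfg, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.adam_betas, eps=cfg.adam_eps)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    best_state = None
    for epoch in range(cfg.epochs):
        lr = step_lr(cfg.lr, epoch, cfg.step_size, cfg.gamma)
        opt.lr = lr
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        # precise BN: inference statistics re-estimated under final weights
        recalibrate_batchnorm(model, x_train, seed=cfg.seed + epoch)
        val_acc = evaluate_accuracy(model, x_val, y_val)
        hist.epochs.append(epoch)
        hist.lr.append(lr)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_accuracy.append(val_acc)
        if val_acc > hist.best_val_accuracy:
            hist.best_val_accuracy = val_acc
            hist.best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model,
                        meta={"best_epoch": hist.best_epoch,
                              "best_val_accuracy": hist.best_val_accuracy,
                              "train_config": asdict(cfg)})
        hist.best_checkpoint = checkpoint_path
    return model, hist


def predict(model_or_checkpoint, x: np.ndarray, batch_size: int = 64):
    """Class predictions and softmax probabilities for a batch of images.

    Arg-max ties break toward the lowest class index (numpy argmax rule).
    """
    if isinstance(model_or_checkpoint, (str, os.PathLike)):
        model, _ = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    x = _as_nchw(x)
    expected = model.cfg.input_size
    if x.shape[-1] != expected or x.shape[-2] != expected:
        raise ValueError(
            f"input geometry {x.shape[-2:]} does not match model input_size {expected}")
    probs = []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        probs.append(softmax_scores(logits))
    probs = np.concatenate(probs, axis=0)
    return probs.argmax(axis=1), probs


def cross_validate(x: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0,
                   cfg: TrainConfig | None = None,
                   net_cfg: NetworkConfig | None = None,
                   out_dir: Optional[str] = None):
    """Run the k-fold protocol; every sample is validated exactly once.

    Returns (fold_plan, per-fold histories, out-of-fold predictions,
    out-of-fold probabilities) with predictions aligned to the input order.
    """
    cfg = cfg or TrainConfig(seed=seed)
    y = np.asarray(y, dtype=np.int64)
    ids = np.arange(len(y))
    plan = make_folds(ids, y, k=k, seed=seed)
    fold_of = np.array([plan.assignment[i] for i in ids])
    oof_pred = np.full(len(y), -1, dtype=np.int64)
    n_classes = net_cfg.num_classes if net_cfg is not None else 5
    oof_proba = np.zeros((len(y), n_classes))
    histories = []
    for fold in range(k):
        val_mask = fold_of == fold
        ckpt = os.path.join(out_dir, f"fold{fold}.npz") if out_dir else None
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + fold})
        model, hist = train_model(x[~val_mask], y[~val_mask], x[val_mask], y[val_mask],
                                  fold_cfg, net_cfg, checkpoint_path=ckpt)
        pred, proba = predict(model, x[val_mask])
        oof_pred[val_mask] = pred
        oof_proba[val_mask] = proba
        histories.append(hist)
    assert (oof_pred >= 0).all()
    return plan, histories, oof_pred, oof_proba
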