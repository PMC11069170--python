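"""Masked-MAE objective and the two-stage training schedule.

Stage 1 fits the R-former together with the distance head by mean absolute
error over residue pairs whose true distance lies in (0, 36 Å) — the
"small loss" mask that keeps far, poorly determined pairs out of the
objective.  Stage 2 freezes everything trained in stage 1 and fits the
error head against the realized absolute errors |d - d_pred| of the frozen
distance predictions, under the same mask.

All losses are computed in Å after denormalization; targets above the
100 Å head range are clipped (the clip count is reported per run).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor
from .network import FreeProtMapModel
from .nn import Adam

__all__ = [
    "EmptyMaskError",
    "eval_mask",
    "masked_mae_loss",
    "TrainConfig",
    "train_stage1",
    "train_stage2",
    "constant_baseline_mae",
    "heldout_masked_mae",
]

SMALL_LOSS_THRESHOLD = 36.0  # Å


class EmptyMaskError(ValueError):
    """No residue pair of a protein falls inside the (0, 36 Å) mask."""


def eval_mask(reference: np.ndarray,
              threshold: float = SMALL_LOSS_THRESHOLD) -> np.ndarray:
    """Boolean mask of residue pairs with reference distance in (0, threshold)."""
    ref = np.asarray(reference, dtype=float)
    return (ref > 0.0) & (ref < threshold)


def masked_mae_loss(pred, target, mask) -> Tensor:
    """Mean |pred - target| over masked pairs; differentiable in ``pred``."""
    mask = np.asarray(mask, dtype=bool)
    target = np.asarray(target, dtype=float)
    if mask.shape != target.shape:
        raise ValueError(f"mask shape {mask.shape} != target {target.shape}")
    n = int(mask.sum())
    if n == 0:
        raise EmptyMaskError("no residue pair inside the (0, 36 Å) mask")
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    diff = (pred - Tensor(target)).abs() * Tensor(mask.astype(float))
    return diff.sum() / float(n)


@dataclass
class TrainConfig:
    """Optimizer schedule: Adam, weight decay 0.01, lr 1e-3, batch size 1,
    30 + 5 epochs."""

    lr: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 1
    epochs_stage1: int = 30
    epochs_stage2: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.epochs_stage1 < 1 or self.epochs_stage2 < 0:
            raise ValueError("epoch counts must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")


def _clip_targets(d: np.ndarray, scale: float) -> tuple[np.ndarray, int]:
    clipped = np.clip(d, 0.0, scale)
    return clipped, int((d > scale).sum())


def _epoch_pass(model, items, optimizer, rng, head: str,
                targets: Sequence[np.ndarray] | None = None) -> float:
    """One epoch, batch size 1; returns mean per-protein loss in Å."""
    order = rng.permutation(len(items)) if optimizer is not None \
        else np.arange(len(items))
    losses = []
    for idx in order:
        item = items[idx]
        tgt = targets[idx] if targets is not None else item.distance
        mask = item.mask
        if not mask.any():
            continue
        tgt, _ = _clip_targets(tgt, model.config.denorm_scale)
        dist, err = model(Tensor(item.pooled))
        pred = dist if head == "distance" else err
        loss = masked_mae_loss(pred, tgt, mask)
        if not np.isfinite(loss.numpy()):
            raise RuntimeError(
                f"non-finite loss at item {idx}: {float(loss.numpy())!r}; "
                "training aborted"
            )
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        losses.append(float(loss.numpy()))
    if not losses:
        raise EmptyMaskError("every protein in the epoch had an empty mask")
    return float(np.mean(losses))


def train_stage1(model: FreeProtMapModel, train_items, config: TrainConfig,
                 val_items=None,
                 callback: Callable[[dict], None] | None = None) -> list[dict]:
    """Fit R-former + distance head; the error head is untouched.

    Returns the per-epoch history of train (and validation) masked MAE.
    """
    model.rformer.set_trainable(True)
    model.heads.distance_head.set_trainable(True)
    model.heads.error_head.set_trainable(False)
    params = (model.rformer.parameters()
              + model.heads.distance_head.parameters())
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    scale = model.config.denorm_scale
    n_clipped = int(sum((item.distance > scale).sum()
                        for item in train_items))
    history = []
    for epoch in range(1, config.epochs_stage1 + 1):
        record = {"stage": 1, "epoch": epoch,
                  "n_clipped_targets": n_clipped,
                  "train_loss": _epoch_pass(model, train_items, opt, rng,
                                            "distance")}
        if val_items:
            record["val_loss"] = heldout_masked_mae(model, val_items)
        history.append(record)
        if callback:
            callback(record)
    return history


def train_stage2(model: FreeProtMapModel, train_items, config: TrainConfig,
                 val_items=None,
                 callback: Callable[[dict], None] | None = None) -> list[dict]:
    """Freeze R-former + distance head; fit the error head on realized
    absolute errors of the frozen distance predictions."""
    model.rformer.set_trainable(False)
    model.heads.distance_head.set_trainable(False)
    model.heads.error_head.set_trainable(True)

    # realized-AE targets from the frozen stage-1 predictor
    def realized_ae(items):
        out = []
        for item in items:
            dist, _ = model(Tensor(item.pooled))
            out.append(np.abs(item.distance - dist.numpy()))
        return out

    ae_train = realized_ae(train_items)
    ae_val = realized_ae(val_items) if val_items else None
    opt = Adam(model.heads.error_head.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    for epoch in range(1, config.epochs_stage2 + 1):
        record = {"stage": 2, "epoch": epoch,
                  "train_loss": _epoch_pass(model, train_items, opt, rng,
                                            "error", targets=ae_train)}
        if ae_val is not None:
            record["val_loss"] = _epoch_pass(model, val_items, None, rng,
                                             "error", targets=ae_val)
        history.append(record)
        if callback:
            callback(record)
    model.rformer.set_trainable(True)
    model.heads.distance_head.set_trainable(True)
    return history


def constant_baseline_mae(train_items, eval_items) -> float:
    """Masked MAE of the constant predictor (mean masked training distance)."""
    pooled_all = np.concatenate(
        [item.distance[item.mask] for item in train_items if item.mask.any()]
    )
    const = float(pooled_all.mean())
    errs = [np.abs(item.distance[item.mask] - const).mean()
            for item in eval_items if item.mask.any()]
    return float(np.mean(errs))


def heldout_masked_mae(model: FreeProtMapModel, items) -> float:
    """Mean per-protein masked MAE of the distance head on held-out items."""
    flags = [(p, p.requires_grad) for p in model.parameters()]
    for p, _ in flags:          # inference only: skip graph construction
        p.requires_grad = False
    try:
        vals = []
        for item in items:
            dist, _ = model(Tensor(item.pooled))
            vals.append(
                float(np.abs(dist.numpy() - item.distance)[item.mask].mean())
            )
    finally:
        for p, flag in flags:
            p.requires_grad = flag
    return float(np.mean(vals))
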