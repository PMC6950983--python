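"""Training objective and protocol.

The loss is a negative-log soft-Dice term plus a weighted binary
cross-entropy term, averaged over the batch:

    L = lambda_BCE * BCE(y, p) + (1/M) * sum_i -log D(y_i, p_i)

with the soft Dice coefficient

    D(y, p) = (2 * sum(y * p) + s) / (sum(y) + sum(p) + s)

where the small smoothing constant s keeps -log D finite on empty
intersections.  Optimization is Adam at learning rate 5e-4 for 20 epochs by
default; the checkpoint with the lowest validation loss is kept.  A
fine-tuning phase continues for a few epochs at a smaller learning rate
(1e-4) under the same checkpoint rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, GraphModel
from .patches import PatchRecord

__all__ = ["TrainConfig", "dice_coefficient", "loss", "train", "finetune"]

_CLIP = 1e-7


@dataclass
class TrainConfig:
    lr: float = 0.0005
    lambda_bce: float = 1.0
    epochs: int = 20
    finetune_epochs: int = 5
    finetune_lr: float = 0.0001
    batch_size: int = 16
    seed: int = 0
    dice_smooth: float = 1e-6

    def __post_init__(self):
        if self.lr <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.lambda_bce < 0:
            raise ValueError("lambda_bce must be >= 0")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be > 0")


def dice_coefficient(y_true, y_pred, smooth: float = 1e-6) -> float:
    """Soft Dice between a mask/probability map pair of equal shape."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("dice_coefficient: shape mismatch "
                         f"{y_true.shape} vs {y_pred.shape}")
    inter = float((y_true * y_pred).sum())
    denom = float(y_true.sum() + y_pred.sum())
    return (2.0 * inter + smooth) / (denom + smooth)


def _check_probs(y_pred):
    if (y_pred < 0).any() or (y_pred > 1).any():
        raise ValueError("predicted values must be probabilities in [0, 1]")


def loss(y_true_batch, y_pred_batch, config: TrainConfig = TrainConfig()) -> float:
    """Batch loss: lambda_BCE * mean BCE + mean_i(-log soft-Dice_i)."""
    y = np.asarray(y_true_batch, dtype=float)
    p = np.asarray(y_pred_batch, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"loss: shape mismatch {y.shape} vs {p.shape}")
    _check_probs(p)
    pc = np.clip(p, _CLIP, 1.0 - _CLIP)
    bce = float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
    m = y.shape[0]
    neg_log_dice = 0.0
    for i in range(m):
        neg_log_dice -= np.log(dice_coefficient(y[i], p[i], config.dice_smooth))
    return config.lambda_bce * bce + neg_log_dice / m


def _loss_grad(y, p, config: TrainConfig):
    """Loss value and its gradient w.r.t. the probability map p."""
    m = y.shape[0]
    pc = np.clip(p, _CLIP, 1.0 - _CLIP)
    bce = float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
    grad = config.lambda_bce * (pc - y) / (pc * (1.0 - pc)) / y.size
    s = config.dice_smooth
    total = config.lambda_bce * bce
    for i in range(m):
        inter = float((y[i] * p[i]).sum())
        denom = float(y[i].sum() + p[i].sum())
        num_s = 2.0 * inter + s
        den_s = denom + s
        total -= np.log(num_s / den_s) / m
        # d(-log D)/dp = -(2 y / num_s) + 1 / den_s, averaged over the batch
        grad[i] += (1.0 / den_s - 2.0 * y[i] / num_s) / m
    return total, grad


def _as_arrays(patch_set):
    """Accept PatchRecords or (N,H,W) arrays; return float32 NHWC + masks."""
    if isinstance(patch_set, (list, tuple)) and len(patch_set) and \
            isinstance(patch_set[0], PatchRecord):
        imgs = np.stack([p.image_patch for p in patch_set])
        msks = np.stack([(p.mask_patch > 0).astype(np.float32) for p in patch_set])
    elif isinstance(patch_set, tuple) and len(patch_set) == 2:
        imgs, msks = np.asarray(patch_set[0]), np.asarray(patch_set[1])
    else:
        raise ValueError("expected a list of PatchRecord or an "
                         "(images, masks) tuple")
    x = imgs.astype(np.float32)[..., None]
    t = msks.astype(np.float32)[..., None]
    return x, t


def _eval_loss(model: GraphModel, x, t, config: TrainConfig, batch: int) -> float:
    total, n = 0.0, x.shape[0]
    for i in range(0, n, batch):
        p = model.forward(x[i:i + batch], train=False).data.astype(np.float64)
        total += loss(t[i:i + batch], np.clip(p, 0.0, 1.0), config) * (
            x[i:i + batch].shape[0])
    return total / n


def _run_training(model, train_patches, val_patches, config, lr, epochs):
    if train_patches is None or not len(train_patches):
        raise ValueError("training set is empty")
    x, t = _as_arrays(train_patches)
    if x.shape[0] == 0:
        raise ValueError("training set is empty")
    if val_patches is not None and len(val_patches):
        xv, tv = _as_arrays(val_patches)
    else:
        xv, tv = x, t
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=lr)
    kernels = model.kernel_parameters()
    lam = model.meta.get("l2_lambda", 0.0)
    batch = max(1, min(config.batch_size, x.shape[0]))
    history = []
    # seed the checkpoint with the entry state so continued training
    # (fine-tuning) can never end worse than it started
    best_val = _eval_loss(model, xv, tv, config, batch)
    best_state = model.get_state()
    for epoch in range(epochs):
        order = rng.permutation(x.shape[0])
        train_loss = 0.0
        for i in range(0, len(order), batch):
            idx = order[i:i + batch]
            opt.zero_grad()
            out = model.forward(x[idx], train=True)
            p = np.clip(out.data.astype(np.float64), _CLIP, 1.0 - _CLIP)
            lval, grad = _loss_grad(t[idx].astype(np.float64), p, config)
            out.backward(grad.astype(out.data.dtype))
            if lam > 0:
                for kp in kernels:
                    kp.grad = kp.grad + (2.0 * lam) * kp.data
                    lval += lam * float((kp.data ** 2).sum())
            opt.step()
            train_loss += lval * len(idx)
        train_loss /= len(order)
        val_loss = _eval_loss(model, xv, tv, config, batch)
        history.append({"epoch": epoch + 1, "train_loss": float(train_loss),
                        "val_loss": float(val_loss)})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
    if best_state is not None:
        model.set_state(best_state)
    return model, history


def train(model: GraphModel, train_patches, val_patches,
          config: TrainConfig = TrainConfig()):
    """Adam training with best-validation-loss checkpointing.

    Returns (best_model, history); history has one entry per epoch with
    train and validation losses.  The returned model carries the parameters
    of the epoch with the lowest validation loss.
    """
    return _run_training(model, train_patches, val_patches, config,
                         config.lr, config.epochs)


def finetune(model: GraphModel, train_patches, val_patches,
             config: TrainConfig = TrainConfig()):
    """Continue training at the smaller fine-tuning learning rate."""
    if config.finetune_lr >= config.lr:
        raise ValueError("finetune_lr must be smaller than the initial lr")
    if config.finetune_epochs == 0:
        return model, []
    return _run_training(model, train_patches, val_patches, config,
                         config.finetune_lr, config.finetune_epochs)
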