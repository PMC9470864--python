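"""Dice and cross-entropy losses and their equal-weight combination.

The coarse (binary) task uses a single-class soft Dice on the foreground
plus voxel-wise cross entropy; the fine (4-class) task averages soft Dice
with equal weights over the three ossicle classes (background excluded by
default) plus cross entropy. Total loss = Dice part + CE part with unit
weights on each.

Soft Dice per class c:  ``1 - 2 * sum(p_c * t_c) / (sum(p_c) + sum(t_c) + eps)``
with eps = 1e-5 to define the empty-prediction case; empty-vs-empty is
defined as zero loss. Values lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import UsageError

EPS = 1e-5

COARSE_CLASSES = (1,)        # "single-class" Dice: foreground only
FINE_CLASSES = (1, 2, 3)     # malleus, incus, stapes; background excluded


@dataclass(frozen=True)
class LossValue:
    """Combined loss with its components; total = dice_part + ce_part."""

    total: float
    dice_part: float
    ce_part: float


def _as_class_axis(pred: np.ndarray) -> np.ndarray:
    """Accept (C, ...) or (N, C, ...); normalize to (N, C, ...)."""
    pred = np.asarray(pred)
    if pred.ndim == 4:
        return pred[None]
    if pred.ndim == 5:
        return pred
    raise UsageError(f"pred must be (C, D, H, W) or (N, C, D, H, W), got {pred.shape}")


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer label array -> one-hot float32 with leading class axis."""
    labels = np.asarray(labels)
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def _prep(pred, target):
    p = _as_class_axis(pred).astype(np.float64)
    t = np.asarray(target)
    if t.shape == p.shape[1:] and np.issubdtype(t.dtype, np.integer):
        t = one_hot(t, p.shape[1])
    t = _as_class_axis(t).astype(np.float64)
    if t.shape != p.shape:
        raise UsageError(f"pred shape {p.shape} and target shape {t.shape} differ")
    return p, t


def dice_loss(pred, target, class_set=None, eps: float = EPS) -> float:
    """Soft Dice loss averaged with equal weight over ``class_set``."""
    p, t = _prep(pred, target)
    if class_set is None:
        class_set = tuple(range(p.shape[1]))
    class_set = tuple(class_set)
    if not class_set:
        raise UsageError("class_set must not be empty")
    losses = []
    for c in class_set:
        pc, tc = p[:, c], t[:, c]
        sp, st = pc.sum(), tc.sum()
        if sp == 0.0 and st == 0.0:
            losses.append(0.0)  # empty-vs-empty: perfect by definition
        else:
            losses.append(1.0 - 2.0 * (pc * tc).sum() / (sp + st + eps))
    return float(np.mean(losses))


def dice_loss_grad(pred, target, class_set=None, eps: float = EPS):
    """(loss, d loss / d pred) for the soft Dice; gradient matches pred's shape."""
    p, t = _prep(pred, target)
    orig_shape = np.asarray(pred).shape
    if class_set is None:
        class_set = tuple(range(p.shape[1]))
    class_set = tuple(class_set)
    if not class_set:
        raise UsageError("class_set must not be empty")
    grad = np.zeros_like(p)
    losses = []
    k = len(class_set)
    for c in class_set:
        pc, tc = p[:, c], t[:, c]
        sp, st = pc.sum(), tc.sum()
        if sp == 0.0 and st == 0.0:
            losses.append(0.0)
            continue
        inter = (pc * tc).sum()
        u = sp + st + eps
        losses.append(1.0 - 2.0 * inter / u)
        # d/dp [1 - 2I/U] = -2 (t*U - I) / U^2, averaged over the class set
        grad[:, c] = (-2.0 * (tc * u - inter) / (u * u)) / k
    loss = float(np.mean(losses))
    return loss, grad.reshape(orig_shape).astype(np.float32)


def cross_entropy_loss(pred, target, eps: float = 1e-12) -> float:
    """Mean per-voxel negative log probability of the true class."""
    p, t = _prep(pred, target)
    n_vox = t[:, 0].size
    return float(-(t * np.log(np.maximum(p, eps))).sum() / n_vox)


def cross_entropy_grad(pred, target, eps: float = 1e-12):
    """(loss, d loss / d pred) for the cross entropy."""
    p, t = _prep(pred, target)
    orig_shape = np.asarray(pred).shape
    n_vox = t[:, 0].size
    loss = float(-(t * np.log(np.maximum(p, eps))).sum() / n_vox)
    grad = (-t / np.maximum(p, eps)) / n_vox
    return loss, grad.reshape(orig_shape).astype(np.float32)


def _task_classes(task: str, n_classes: int):
    if task == "coarse":
        if n_classes != 2:
            raise UsageError(f"coarse task requires 2 classes, got {n_classes}")
        return COARSE_CLASSES
    if task == "fine":
        if n_classes != 4:
            raise UsageError(f"fine task requires 4 classes, got {n_classes}")
        return FINE_CLASSES
    raise UsageError(f"task must be 'coarse' or 'fine', got {task!r}")


def combined_loss(pred, target, task: str, include_background: bool = False) -> LossValue:
    """Equal-weight Dice + cross-entropy loss for one task.

    ``include_background=True`` adds class 0 to the Dice average (off by
    default; the coarse task's "single-class" Dice sets the
    foreground-centric reading).
    """
    p = _as_class_axis(pred)
    classes = _task_classes(task, p.shape[1])
    if include_background:
        classes = (0,) + tuple(classes)
    d = dice_loss(pred, target, classes)
    ce = cross_entropy_loss(pred, target)
    return LossValue(total=d + ce, dice_part=d, ce_part=ce)


def combined_loss_grad(pred, target, task: str, include_background: bool = False):
    """(LossValue, gradient w.r.t. pred) for training."""
    p = _as_class_axis(pred)
    classes = _task_classes(task, p.shape[1])
    if include_background:
        classes = (0,) + tuple(classes)
    d, gd = dice_loss_grad(pred, target, classes)
    ce, gce = cross_entropy_grad(pred, target)
    return LossValue(total=d + ce, dice_part=d, ce_part=ce), gd + gce
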