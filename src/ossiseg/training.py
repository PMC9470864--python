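"""Training targets, patch sampling, cohort splitting, optimization, cross-validation.

The coarse stage learns a binary "ossicle region" task: the three structure
labels are merged and dilated by 1 cm in each direction (axis-aligned box
structuring element) to form its ground truth, and training patches are
centered at points drawn uniformly over the whole image. The fine stage
learns the 4-class task at high resolution, with patch centers drawn
uniformly from the voxels within a Chebyshev distance of 20 voxels of the
merged foreground. Optimization is Adam with a step learning-rate schedule,
combined Dice + cross-entropy loss, and early stopping on validation loss
(the checkpoint kept is the one with the minimum validation loss).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .losses import combined_loss_grad, combined_loss
from .vbnet import VBNet, NetConfig, build_network, DOWN_FACTOR
from .volume_io import (
    ImageVolume,
    LabelVolume,
    UsageError,
    crop_patch,
    normalize_intensity,
    resample,
)


class TrainingError(RuntimeError):
    """Optimization failed (e.g. non-finite loss)."""


class SamplingError(ValueError):
    """Patch-center sampling called outside its contract."""


@dataclass(frozen=True)
class TrainConfig:
    """One stage's training configuration (desk-scale defaults)."""

    task: str = "coarse"  # coarse | fine
    patch_size: tuple[int, int, int] = (32, 32, 32)
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    learning_rate: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    patience: int = 20  # epochs without validation improvement before stopping
    max_epochs: int = 30
    batch_size: int = 4
    patches_per_epoch: int = 64
    val_patches: int = 8
    seed: int = 0
    lr_milestones: tuple[float, float] = (0.5, 0.75)  # fractions of max_epochs
    lr_factor: float = 0.1
    expansion_mm: float = 10.0  # coarse ground-truth dilation (1 cm)
    window_level: float = 1000.0
    window_width: float = 3000.0

    def validate(self) -> None:
        if self.task not in ("coarse", "fine"):
            raise UsageError(f"task must be coarse|fine, got {self.task!r}")
        bad = [s for s in self.patch_size if s % DOWN_FACTOR]
        if bad:
            raise UsageError(
                f"patch_size components must be divisible by {DOWN_FACTOR}, "
                f"got {self.patch_size}"
            )
        if self.patience < 1:
            raise UsageError(f"patience must be >= 1, got {self.patience}")
        if self.max_epochs < 1 or self.batch_size < 1 or self.patches_per_epoch < 1:
            raise UsageError("max_epochs, batch_size, patches_per_epoch must be >= 1")

    @property
    def n_classes(self) -> int:
        return 2 if self.task == "coarse" else 4


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def make_coarse_target(labels: LabelVolume, expansion_mm: float = 10.0) -> LabelVolume:
    """Merged foreground dilated by ``ceil(expansion_mm / spacing)`` voxels per axis.

    The structuring element is an axis-aligned box ("expansion in each
    direction"), so the dilation is a Chebyshev ball in voxel space. Larger
    expansions give supersets; 0 mm is the merged foreground itself.
    """
    if expansion_mm < 0:
        raise UsageError(f"expansion_mm must be >= 0, got {expansion_mm}")
    fg = labels.data > 0
    radii = [int(math.ceil(expansion_mm / s)) if expansion_mm > 0 else 0 for s in labels.spacing]
    if any(radii):
        fg = ndimage.maximum_filter(
            fg, size=[2 * r + 1 for r in radii], mode="constant", cval=0
        )
    return LabelVolume(fg.astype(np.uint8), labels.spacing, labels.origin)


def sample_patch_center(
    labels: np.ndarray | LabelVolume,
    task: str,
    rng: np.random.Generator,
    margin_voxels: int = 20,
) -> tuple[int, int, int]:
    """Draw one patch-center voxel index.

    coarse: uniform over all voxel indices of the grid.
    fine: uniform over voxels within a Chebyshev distance of
    ``margin_voxels`` (default 20) of the merged foreground.
    """
    data = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    if task == "coarse":
        return tuple(int(rng.integers(0, n)) for n in data.shape)
    if task != "fine":
        raise UsageError(f"task must be coarse|fine, got {task!r}")
    fg = data > 0
    if not fg.any():
        raise SamplingError("fine-task sampling requires non-empty foreground labels")
    eligible = ndimage.maximum_filter(
        fg, size=2 * margin_voxels + 1, mode="constant", cval=0
    )
    idx = np.flatnonzero(eligible)
    pick = idx[int(rng.integers(0, idx.size))]
    return tuple(int(v) for v in np.unravel_index(pick, data.shape))


def split_dataset(case_ids, ratios=(8, 1, 1), seed: int = 0, fold_index: int = 0) -> FoldSplit:
    """Random 8:1:1 train/val/test split, deterministic in ``seed``.

    Test and validation sizes are ``round(n * r)`` (at least 1 case each);
    the training set absorbs the remainder so counts sum to n. 158 cases
    give 126/16/16.
    """
    case_ids = list(case_ids)
    n = len(case_ids)
    if n < 3:
        raise UsageError(f"need at least 3 cases to split, got {n}")
    total = float(sum(ratios))
    n_val = max(1, round(n * ratios[1] / total))
    n_test = max(1, round(n * ratios[2] / total))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise UsageError(f"cannot form a non-empty training set from {n} cases")
    order = np.random.default_rng(seed).permutation(n)
    ids = [case_ids[i] for i in order]
    return FoldSplit(
        fold_index=fold_index,
        train_ids=tuple(ids[:n_train]),
        val_ids=tuple(ids[n_train : n_train + n_val]),
        test_ids=tuple(ids[n_train + n_val :]),
    )


def prepare_case(
    image: ImageVolume, labels: LabelVolume, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Resample/normalize one case into (input array, integer target array)."""
    img = resample(image, cfg.target_spacing, mode="linear")
    img = normalize_intensity(img, cfg.window_level, cfg.window_width)
    lab = resample(labels, cfg.target_spacing, mode="nearest")
    if cfg.task == "coarse":
        lab = make_coarse_target(lab, cfg.expansion_mm)
    return img.data.astype(np.float32), lab.data.astype(np.int64)


class EarlyStopper:
    """Minimum-validation-loss early stopping with patience in epochs."""

    def __init__(self, patience: int):
        if patience < 1:
            raise UsageError(f"patience must be >= 1, got {patience}")
        self.patience = int(patience)
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch's validation loss; return True when training should stop."""
        if val_loss < self.best:
            self.best = float(val_loss)
            self.best_epoch = int(epoch)
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


@dataclass
class TrainResult:
    net: VBNet
    log: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    stopped_early: bool


def _make_center_sampler(y: np.ndarray, task: str, margin_voxels: int = 20):
    """Per-case sampler equivalent to :func:`sample_patch_center`, with the
    fine task's eligible set precomputed once."""
    if task == "coarse":
        shape = y.shape
        return lambda rng: tuple(int(rng.integers(0, n)) for n in shape)
    fg = y > 0
    if not fg.any():
        raise SamplingError("fine-task sampling requires non-empty foreground labels")
    eligible = ndimage.maximum_filter(fg, size=2 * margin_voxels + 1, mode="constant", cval=0)
    idx = np.flatnonzero(eligible)

    def draw(rng):
        pick = idx[int(rng.integers(0, idx.size))]
        return tuple(int(v) for v in np.unravel_index(pick, y.shape))

    return draw


def _crop_pair(x, y, spacing, center, size):
    xi, _ = crop_patch(ImageVolume(x, spacing), center, size)
    yi, _ = crop_patch(LabelVolume(y.astype(np.uint8), spacing), center, size)
    return xi.data, yi.data.astype(np.int64)


def train_model(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    net_cfg: NetConfig | None = None,
    val_dataset: list[tuple[np.ndarray, np.ndarray]] | None = None,
    out_dir: str | None = None,
    net: VBNet | None = None,
) -> TrainResult:
    """Optimize a VB-Net stage on prepared cases.

    ``dataset`` holds (normalized image array, integer target array) pairs
    at the stage's target spacing (see :func:`prepare_case`). Validation
    patches come from ``val_dataset`` (training cases if None) at fixed,
    seeded locations; the returned network carries the parameters of the
    epoch with minimum validation loss.
    """
    cfg.validate()
    if not dataset:
        raise UsageError("dataset must be non-empty")
    if net is None:
        if net_cfg is None:
            from .vbnet import DESK_CONFIG

            net_cfg = NetConfig(**{**asdict(DESK_CONFIG), "n_classes": cfg.n_classes})
        if net_cfg.n_classes != cfg.n_classes:
            raise UsageError(
                f"net has {net_cfg.n_classes} classes but task {cfg.task!r} "
                f"needs {cfg.n_classes}"
            )
        net = build_network(net_cfg, seed=cfg.seed)
    spacing = tuple(cfg.target_spacing)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    val_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    val_cases = val_dataset if val_dataset else dataset

    samplers = [_make_center_sampler(y, cfg.task) for _, y in dataset]

    # Fixed validation patch locations for comparable per-epoch losses.
    val_samplers = (
        samplers if val_cases is dataset
        else [_make_center_sampler(y, cfg.task) for _, y in val_cases]
    )
    val_set = []
    for j in range(cfg.val_patches):
        ci = int(val_rng.integers(0, len(val_cases)))
        x, y = val_cases[ci]
        center = val_samplers[ci](val_rng)
        val_set.append(_crop_pair(x, y, spacing, center, cfg.patch_size))

    opt = nn.Adam(
        net.params(),
        lr=cfg.learning_rate,
        betas=cfg.betas,
        weight_decay=cfg.weight_decay,
    )
    stopper = EarlyStopper(cfg.patience)
    best_params = [p.value.copy() for p in net.params()]
    log_rows = []
    milestones = {int(m * cfg.max_epochs) for m in cfg.lr_milestones}
    stopped_early = False

    for epoch in range(cfg.max_epochs):
        if epoch in milestones and epoch > 0:
            opt.lr *= cfg.lr_factor
        n_steps = math.ceil(cfg.patches_per_epoch / cfg.batch_size)
        train_losses = []
        for _ in range(n_steps):
            xb, yb = [], []
            for _ in range(cfg.batch_size):
                ci = int(rng.integers(0, len(dataset)))
                x, y = dataset[ci]
                center = samplers[ci](rng)
                xp, yp = _crop_pair(x, y, spacing, center, cfg.patch_size)
                xb.append(xp)
                yb.append(yp)
            xb = np.stack(xb)[:, None]  # (N, 1, D, H, W)
            yb = np.stack(yb)
            logits = net.forward_logits(xb, train=True)
            probs = nn.softmax(logits, axis=1)
            targets = _batch_one_hot(yb, cfg.n_classes)
            loss, gprobs = combined_loss_grad(probs, targets, cfg.task)
            if not np.isfinite(loss.total):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(nn.softmax_backward(probs, gprobs, axis=1))
            opt.step()
            train_losses.append(loss.total)

        val_losses = []
        for xp, yp in val_set:
            probs = net.predict(xp[None, None])
            targets = _batch_one_hot(yp[None], cfg.n_classes)
            val_losses.append(combined_loss(probs, targets, cfg.task).total)
        val_loss = float(np.mean(val_losses))
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        log_rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_params = [p.value.copy() for p in net.params()]
        if stop:
            stopped_early = True
            break

    for p, best in zip(net.params(), best_params):
        p.value = best
    log = pd.DataFrame(log_rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        net.save(os.path.join(out_dir, f"{cfg.task}_checkpoint.npz"))
        log.to_csv(os.path.join(out_dir, f"{cfg.task}_training_log.csv"), index=False)
    return TrainResult(
        net=net,
        log=log,
        best_epoch=stopper.best_epoch,
        best_val_loss=stopper.best,
        stopped_early=stopped_early,
    )


def _batch_one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def cross_validate(
    cases: dict[str, tuple[ImageVolume, LabelVolume]],
    coarse_cfg: TrainConfig,
    fine_cfg: TrainConfig,
    coarse_net_cfg: NetConfig,
    fine_net_cfg: NetConfig,
    n_folds: int = 5,
    seed: int = 0,
    infer_kwargs: dict | None = None,
):
    """Repeated random-subsampling validation: n seeded 8:1:1 splits.

    Each fold redraws a random 8:1:1 split (rather than classic disjoint
    folds), trains both cascade stages on its training set and evaluates the
    full cascade on its test set. Returns (per-fold report DataFrame,
    summary DataFrame, fold splits).
    """
    from .inference import cascade_predict
    from .metrics import evaluate_case, metrics_report

    if n_folds < 2:
        raise UsageError(f"n_folds must be >= 2, got {n_folds}")
    ids = sorted(cases)
    splits = []
    fold_rows = []
    all_case_metrics: dict[str, dict] = {}
    for fold in range(n_folds):
        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % 2**31)
        split = split_dataset(ids, seed=fold_seed, fold_index=fold)
        splits.append(split)
        c_cfg = TrainConfig(**{**asdict(coarse_cfg), "seed": fold_seed})
        f_cfg = TrainConfig(**{**asdict(fine_cfg), "seed": fold_seed})
        coarse_ds = [prepare_case(*cases[i], c_cfg) for i in split.train_ids]
        coarse_val = [prepare_case(*cases[i], c_cfg) for i in split.val_ids]
        fine_ds = [prepare_case(*cases[i], f_cfg) for i in split.train_ids]
        fine_val = [prepare_case(*cases[i], f_cfg) for i in split.val_ids]
        coarse = train_model(coarse_ds, c_cfg, coarse_net_cfg, val_dataset=coarse_val)
        fine = train_model(fine_ds, f_cfg, fine_net_cfg, val_dataset=fine_val)
        fold_metrics = {}
        for cid in split.test_ids:
            img, lab = cases[cid]
            pred = cascade_predict(img, coarse.net, fine.net, **(infer_kwargs or {}))
            fold_metrics[cid] = evaluate_case(pred, lab)
        rep = metrics_report(fold_metrics)
        rep.insert(0, "fold", fold)
        fold_rows.append(rep)
        all_case_metrics.update({f"f{fold}:{k}": v for k, v in fold_metrics.items()})
    report = pd.concat(fold_rows, ignore_index=True)
    summary = (
        report.groupby(["fold", "structure"])[["dsc", "asd", "hd", "hd95"]]
        .mean()
        .groupby("structure")
        .agg(["mean", "std"])
    )
    return report, summary, splits
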