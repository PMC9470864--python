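"""The coarse-to-fine cascade at test time.

A low-resolution pass over the whole image (resampled to 1 mm isotropic)
roughly locates the ossicle region; its largest connected foreground
component's bounding box, extended by 2 cm on every face, is cropped from
the original image, resampled to fine spacing, segmented by the
high-resolution network with overlapping tiles, and pasted back onto the
original grid. Voxels outside the region of interest are background, and
the output geometry equals the input's exactly.

Predictors are duck-typed: anything with ``predict(x, geometry=None) ->
(N, C, D, H, W)`` probabilities and an ``n_classes`` attribute works, which
lets tests inject ground-truth-emitting oracles in place of trained
networks. ``geometry`` is ``(origin_mm, spacing_mm)`` of each input block.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .vbnet import DOWN_FACTOR
from .volume_io import ImageVolume, LabelVolume, UsageError, normalize_intensity, resample


class LocalizationError(RuntimeError):
    """The coarse stage found no foreground above threshold."""


DEFAULT_COARSE_SPACING = (1.0, 1.0, 1.0)
DEFAULT_FINE_SPACING = (0.2, 0.2, 0.335)  # full-scale; desk runs use 0.3 mm isotropic
DEFAULT_MARGIN_MM = 20.0  # "extended by 2 cm"


@dataclass(frozen=True)
class BoundingBox:
    """Index-space ROI: low inclusive, high exclusive, with spacing context (mm)."""

    low: tuple[int, int, int]
    high: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if any(l >= h for l, h in zip(self.low, self.high)):
            raise UsageError(f"degenerate box: low={self.low}, high={self.high}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.low, self.high))

    def to_json(self) -> str:
        return json.dumps(
            {"low": list(self.low), "high": list(self.high), "spacing": list(self.spacing)}
        )

    @classmethod
    def from_json(cls, s: str) -> "BoundingBox":
        d = json.loads(s)
        return cls(tuple(d["low"]), tuple(d["high"]), tuple(d["spacing"]))


def _pad_to_multiple(data: np.ndarray, multiple: int, fill: float):
    pads = [(0, (-n) % multiple) for n in data.shape]
    if any(p[1] for p in pads):
        data = np.pad(data, pads, constant_values=fill)
    return data


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def coarse_locate(
    image: ImageVolume,
    coarse_net,
    coarse_spacing=DEFAULT_COARSE_SPACING,
    threshold: float = 0.5,
    window_level: float = 1000.0,
    window_width: float = 3000.0,
) -> BoundingBox:
    """Whole-image low-resolution pass -> bounding box in coarse index space.

    The image is resampled to ``coarse_spacing``, normalized, zero-axis
    padded to the next multiple of 16 and pushed through the coarse network
    in one pass; the foreground probability is thresholded and the largest
    26-connected component's bounding box is returned.
    """
    if getattr(coarse_net, "n_classes", 2) != 2:
        raise UsageError("coarse network must have 2 classes")
    low_res = resample(image, coarse_spacing, mode="linear")
    norm = normalize_intensity(low_res, window_level, window_width)
    padded = _pad_to_multiple(norm.data, DOWN_FACTOR, fill=-1.0)
    probs = coarse_net.predict(
        padded[None, None].astype(np.float32),
        geometry=(norm.origin, norm.spacing),
    )[0]
    fg = probs[1][tuple(slice(0, n) for n in norm.data.shape)]
    mask = fg >= threshold
    if not mask.any():
        raise LocalizationError(
            f"coarse stage: no voxel reached foreground probability {threshold}"
        )
    comp, n_comp = ndimage.label(mask, structure=_CONN26)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
        mask = comp == (1 + int(np.argmax(sizes)))
    idx = np.argwhere(mask)
    low = tuple(int(v) for v in idx.min(axis=0))
    high = tuple(int(v) + 1 for v in idx.max(axis=0))
    return BoundingBox(low, high, tuple(norm.spacing))


def expand_box(box: BoundingBox, margin_mm: float = DEFAULT_MARGIN_MM, grid=None) -> BoundingBox:
    """Move each face outward by ``round(margin_mm / spacing)`` voxels, clamped to grid."""
    r = [int(round(margin_mm / s)) for s in box.spacing]
    low = [l - ri for l, ri in zip(box.low, r)]
    high = [h + ri for h, ri in zip(box.high, r)]
    if grid is not None:
        low = [max(0, l) for l in low]
        high = [min(int(g), h) for h, g in zip(high, grid)]
    return BoundingBox(tuple(low), tuple(high), box.spacing)


def _tile_starts(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    starts = list(range(0, extent - tile, stride))
    starts.append(extent - tile)
    return starts


def stitch_tiles(
    data: np.ndarray,
    predictor,
    n_classes: int,
    tile_size,
    stride,
    origin=(0.0, 0.0, 0.0),
    spacing=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Cover ``data`` with overlapping tiles and average per-class probabilities.

    Tiles start every ``stride`` voxels with a final tile flush against each
    axis end; every voxel's probability is the arithmetic mean over the
    tiles that contain it. Returns an (n_classes, D, H, W) array.
    """
    tile_size = tuple(int(t) for t in tile_size)
    stride = tuple(int(s) for s in stride)
    acc = np.zeros((n_classes,) + data.shape, dtype=np.float32)
    cnt = np.zeros(data.shape, dtype=np.float32)
    starts = [_tile_starts(n, t, st) for n, t, st in zip(data.shape, tile_size, stride)]
    for sz in starts[0]:
        for sy in starts[1]:
            for sx in starts[2]:
                sl = (
                    slice(sz, sz + tile_size[0]),
                    slice(sy, sy + tile_size[1]),
                    slice(sx, sx + tile_size[2]),
                )
                tile_origin = tuple(
                    o + s * sp for o, s, sp in zip(origin, (sz, sy, sx), spacing)
                )
                probs = predictor.predict(
                    data[sl][None, None].astype(np.float32),
                    geometry=(tile_origin, tuple(spacing)),
                )[0]
                acc[(slice(None),) + sl] += probs
                cnt[sl] += 1.0
    acc /= np.maximum(cnt, 1.0)
    return acc


def fine_segment(
    image: ImageVolume,
    box: BoundingBox,
    fine_net,
    fine_spacing=DEFAULT_FINE_SPACING,
    tile_size=(96, 96, 96),
    stride=None,
    window_level: float = 1000.0,
    window_width: float = 3000.0,
) -> LabelVolume:
    """High-resolution segmentation of the (already expanded) ROI.

    The ROI is cropped from the original image, resampled to
    ``fine_spacing``, normalized and covered by overlapping tiles (stride =
    half the tile by default); per-class probabilities are averaged over
    overlaps and argmaxed. ROIs smaller than one tile are padded out to one
    tile. The result lives on the ROI's fine-resolution grid.
    """
    n_classes = getattr(fine_net, "n_classes", 4)
    tile_size = tuple(int(t) for t in tile_size)
    if any(t % DOWN_FACTOR for t in tile_size):
        raise UsageError(f"tile_size must be divisible by {DOWN_FACTOR}, got {tile_size}")
    stride = tuple(t // 2 for t in tile_size) if stride is None else tuple(stride)

    # ROI in original-image index space (box is in coarse index space).
    lo_mm = [l * s for l, s in zip(box.low, box.spacing)]
    hi_mm = [h * s for h, s in zip(box.high, box.spacing)]
    lo = [max(0, int(math.floor(l / s))) for l, s in zip(lo_mm, image.spacing)]
    hi = [
        min(n, max(int(math.ceil(h / s)), li + 1))
        for h, s, n, li in zip(hi_mm, image.spacing, image.shape, lo)
    ]
    roi = ImageVolume(
        image.data[tuple(slice(l, h) for l, h in zip(lo, hi))],
        image.spacing,
        tuple(o + l * s for o, l, s in zip(image.origin, lo, image.spacing)),
    )
    fine = resample(roi, fine_spacing, mode="linear")
    norm = normalize_intensity(fine, window_level, window_width)
    data = _pad_to_multiple(norm.data, DOWN_FACTOR, fill=-1.0)
    pads = [(t - n if n < t else 0) for n, t in zip(data.shape, tile_size)]
    if any(pads):
        data = np.pad(data, [(0, p) for p in pads], constant_values=-1.0)

    acc = stitch_tiles(
        data, fine_net, n_classes, tile_size, stride, norm.origin, tuple(norm.spacing)
    )
    labels = np.argmax(acc, axis=0).astype(np.uint8)
    labels = labels[tuple(slice(0, n) for n in norm.data.shape)]
    return LabelVolume(labels, tuple(norm.spacing), norm.origin)


def cascade_predict(
    image: ImageVolume,
    coarse_net,
    fine_net,
    coarse_spacing=DEFAULT_COARSE_SPACING,
    fine_spacing=DEFAULT_FINE_SPACING,
    margin_mm: float = DEFAULT_MARGIN_MM,
    tile_size=(96, 96, 96),
    stride=None,
    threshold: float = 0.5,
    window_level: float = 1000.0,
    window_width: float = 3000.0,
    return_box: bool = False,
):
    """coarse_locate -> expand_box -> fine_segment -> paste back to the input grid.

    The fine-resolution labels are resampled (nearest) onto the portion of
    the original grid covered by the ROI; everything outside is background.
    """
    box = coarse_locate(
        image, coarse_net, coarse_spacing, threshold, window_level, window_width
    )
    coarse_grid = tuple(
        int(round(n * s / t))
        for n, s, t in zip(image.shape, image.spacing, coarse_spacing)
    )
    box = expand_box(box, margin_mm, grid=[max(1, g) for g in coarse_grid])
    fine_labels = fine_segment(
        image, box, fine_net, fine_spacing, tile_size, stride, window_level, window_width
    )

    out = np.zeros(image.shape, dtype=np.uint8)
    # Original-grid extent covered by the fine result.
    lo = [
        int(math.ceil((fo - io) / s - 1e-9))
        for fo, io, s in zip(fine_labels.origin, image.origin, image.spacing)
    ]
    hi = [
        min(
            n,
            int(
                math.floor(
                    ((fo - io) + (m - 1) * fs) / s + 1e-9
                )
            )
            + 1,
        )
        for fo, io, fs, s, n, m in zip(
            fine_labels.origin,
            image.origin,
            fine_labels.spacing,
            image.spacing,
            image.shape,
            fine_labels.shape,
        )
    ]
    lo = [max(0, l) for l in lo]
    if all(l < h for l, h in zip(lo, hi)):
        # Nearest-neighbor lookup of each original voxel center in the fine grid.
        idx = []
        for ax in range(3):
            coords = (
                np.arange(lo[ax], hi[ax]) * image.spacing[ax]
                + image.origin[ax]
                - fine_labels.origin[ax]
            ) / fine_labels.spacing[ax]
            idx.append(
                np.clip(
                    np.floor(coords + 0.5).astype(np.intp), 0, fine_labels.shape[ax] - 1
                )
            )
        out[tuple(slice(l, h) for l, h in zip(lo, hi))] = fine_labels.data[np.ix_(*idx)]
    result = LabelVolume(out, image.spacing, image.origin)
    if return_box:
        return result, box
    return result


class OraclePredictor:
    """Geometry-aware stand-in predictor emitting near-one-hot truth probabilities.

    Synthetic test double: instead of a trained network it carries the true
    label volume and, for each requested block, nearest-resamples the truth
    onto the block's grid and returns the corresponding class probabilities.
    Used to exercise cascade plumbing (cropping, tiling, stitching,
    paste-back) independently of learning.
    """

    def __init__(self, truth: LabelVolume, n_classes: int, binarize: bool = False):
        self.truth = truth
        self.n_classes = int(n_classes)
        self.binarize = binarize

    def predict(self, x: np.ndarray, geometry=None) -> np.ndarray:
        if geometry is None:
            raise UsageError("OraclePredictor needs block geometry")
        origin, spacing = geometry
        n, _, *shape = x.shape
        labels = np.zeros(shape, dtype=np.uint8)
        idx = []
        inside = np.ones(shape, dtype=bool)
        for ax in range(3):
            coords = (
                np.arange(shape[ax]) * spacing[ax] + origin[ax] - self.truth.origin[ax]
            ) / self.truth.spacing[ax]
            near = np.floor(coords + 0.5).astype(np.intp)
            ok = (near >= 0) & (near < self.truth.shape[ax])
            sl = [None, None, None]
            sl[ax] = slice(None)
            inside &= ok[tuple(sl)]
            idx.append(np.clip(near, 0, self.truth.shape[ax] - 1))
        labels = self.truth.data[np.ix_(*idx)].copy()
        labels[~inside] = 0
        if self.binarize:
            labels = (labels > 0).astype(np.uint8)
        probs = np.zeros((n, self.n_classes) + tuple(shape), dtype=np.float32)
        for c in range(self.n_classes):
            probs[:, c] = labels == c
        return probs
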