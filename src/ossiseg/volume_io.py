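"""Volume containers, file I/O, resampling, intensity normalization and patch cropping.

All volumes are axis-aligned. Voxel indices are 0-based and node-centered:
the physical position of voxel ``(i, j, k)`` is ``origin + index * spacing``
(mm). Arrays are indexed ``data[i, j, k]`` with ``spacing[a]`` the voxel
size along array axis ``a``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage


class FormatError(ValueError):
    """Unsupported or corrupt volume file."""


class UsageError(ValueError):
    """Operation called outside its contract."""


VALID_LABELS = (0, 1, 2, 3)
STRUCTURE_NAMES = {1: "malleus", 2: "incus", 3: "stapes"}


@dataclass
class ImageVolume:
    """3D scalar grid (HU or normalized) with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise UsageError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise UsageError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise UsageError("image data must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "ImageVolume | LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LabelVolume:
    """3D integer grid on the same geometry; codes 0=background, 1=malleus, 2=incus, 3=stapes."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise UsageError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise UsageError("label data must be an integer array")
        bad = np.setdiff1d(np.unique(self.data), VALID_LABELS)
        if bad.size:
            raise UsageError(f"label values outside {VALID_LABELS}: {bad.tolist()}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise UsageError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "ImageVolume | LabelVolume", atol: float = 1e-6) -> bool:
        return ImageVolume.same_geometry(self, other, atol)  # type: ignore[arg-type]


Volume = ImageVolume | LabelVolume

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


def _has_supported_ext(path: str) -> bool:
    low = path.lower()
    return any(low.endswith(e) for e in _SUPPORTED_EXT)


def read_volume(path: str, as_labels: bool = False) -> Volume:
    """Read a NIfTI or MetaImage volume.

    SimpleITK stores spacing in (x, y, z) order while arrays come back
    (z, y, x); we keep array order throughout, so spacing/origin are reversed
    on the way in and out.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if not _has_supported_ext(path):
        raise FormatError(f"unsupported volume format: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # pragma: no cover - message branch
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    data = sitk.GetArrayFromImage(img)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if as_labels:
        return LabelVolume(data.astype(np.uint8), spacing, origin)
    return ImageVolume(data, spacing, origin)


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume as NIfTI/MetaImage; images as int16 HU, labels as uint8."""
    if not _has_supported_ext(path):
        raise FormatError(f"unsupported volume format: {path}")
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data
        if np.issubdtype(data.dtype, np.integer) or np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int16)
        else:
            data = data.astype(np.float32)
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    sitk.WriteImage(img, path, useCompression=path.lower().endswith(".gz"))


def _output_shape(shape, spacing, target_spacing) -> tuple[int, ...]:
    return tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(shape, spacing, target_spacing)
    )


def resample(vol: Volume, target_spacing, mode: str | None = None) -> Volume:
    """Resample to a new voxel spacing.

    Output shape is ``round(shape * spacing / target)`` per axis (clamped to
    >= 1); the origin is preserved, so physical extent matches within one
    target voxel. Images use trilinear interpolation, labels nearest
    neighbor; nearest never introduces labels absent from the input.
    """
    target_spacing = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise UsageError(f"target spacing must be positive, got {target_spacing}")
    is_labels = isinstance(vol, LabelVolume)
    if mode is None:
        mode = "nearest" if is_labels else "linear"
    if is_labels and mode != "nearest":
        raise UsageError("label volumes must be resampled with mode='nearest'")
    if mode not in ("linear", "nearest"):
        raise UsageError(f"unknown resampling mode {mode!r}")

    out_shape = _output_shape(vol.shape, vol.spacing, target_spacing)
    # Continuous input-index coordinate of each output voxel center.
    axes = [
        np.arange(n, dtype=np.float64) * t / s
        for n, t, s in zip(out_shape, target_spacing, vol.spacing)
    ]
    if mode == "nearest":
        idx = [
            np.clip(np.floor(a + 0.5).astype(np.intp), 0, dim - 1)
            for a, dim in zip(axes, vol.shape)
        ]
        out = vol.data[np.ix_(*idx)]
        return replace(vol, data=out, spacing=target_spacing)
    grid = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        vol.data.astype(np.float32), np.stack(grid), order=1, mode="nearest"
    )
    return ImageVolume(out, target_spacing, vol.origin)


def normalize_intensity(
    vol: ImageVolume, level: float = 1000.0, width: float = 3000.0
) -> ImageVolume:
    """Window an HU image to [-1, 1]: ``clip((x - level) / (width / 2), -1, 1)``.

    Defaults are the bone window used for ossicle CT (level 1000 HU, width
    3000 HU), which maps 1000 HU to 0 and saturates at -500/2500 HU; any
    value above the window (e.g. metal-bright > 4000 HU) maps to exactly 1.
    """
    if width <= 0:
        raise UsageError(f"window width must be positive, got {width}")
    out = np.clip((vol.data.astype(np.float32) - level) / (width / 2.0), -1.0, 1.0)
    return ImageVolume(out, vol.spacing, vol.origin)


@dataclass(frozen=True)
class PatchPlacement:
    """Record of where a patch came from, sufficient for exact paste-back."""

    start: tuple[int, int, int]  # index of patch voxel (0,0,0) in the source grid
    size: tuple[int, int, int]
    source_shape: tuple[int, int, int]


def crop_patch(vol: Volume, center, size) -> tuple[Volume, PatchPlacement]:
    """Crop a fixed-size patch centered at a voxel index.

    Out-of-volume regions are padded: -1 for (normalized) images, 0 for
    labels. Out-of-bounds centers are legal.
    """
    size = tuple(int(s) for s in size)
    if any(s < 1 for s in size):
        raise UsageError(f"patch size components must be >= 1, got {size}")
    center = tuple(int(c) for c in center)
    start = tuple(c - s // 2 for c, s in zip(center, size))
    is_labels = isinstance(vol, LabelVolume)
    fill = 0 if is_labels else -1.0
    out = np.full(size, fill, dtype=vol.data.dtype if is_labels else np.float32)

    src_lo = [max(0, st) for st in start]
    src_hi = [min(dim, st + sz) for st, sz, dim in zip(start, size, vol.shape)]
    if all(lo < hi for lo, hi in zip(src_lo, src_hi)):
        dst_lo = [lo - st for lo, st in zip(src_lo, start)]
        dst_hi = [hi - st for hi, st in zip(src_hi, start)]
        out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = vol.data[
            tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
        ]
    origin = tuple(o + st * sp for o, st, sp in zip(vol.origin, start, vol.spacing))
    patch: Volume
    if is_labels:
        patch = LabelVolume(out, vol.spacing, origin)
    else:
        patch = ImageVolume(out, vol.spacing, origin)
    return patch, PatchPlacement(start, size, vol.shape)


def paste_patch(vol: Volume, patch: Volume, placement: PatchPlacement) -> Volume:
    """Paste a (possibly modified) patch back where :func:`crop_patch` took it."""
    if placement.source_shape != vol.shape:
        raise UsageError("placement does not match the target volume shape")
    if tuple(patch.shape) != placement.size:
        raise UsageError("patch shape does not match its placement record")
    out = vol.data.copy()
    start, size = placement.start, placement.size
    src_lo = [max(0, st) for st in start]
    src_hi = [min(dim, st + sz) for st, sz, dim in zip(start, size, vol.shape)]
    if all(lo < hi for lo, hi in zip(src_lo, src_hi)):
        dst_lo = [lo - st for lo, st in zip(src_lo, start)]
        dst_hi = [hi - st for hi, st in zip(src_hi, start)]
        out[tuple(slice(a, b) for a, b in zip(src_lo, src_hi))] = patch.data[
            tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
        ]
    return replace(vol, data=out)
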