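"""Synthetic temporal-bone CT phantoms with paired ossicle label maps.

Each phantom is a block of petrous-bone-intensity material containing one
ellipsoidal air pocket (the tympanic cavity) in which three ossicle-like
structures sit, rendered at calibrated HU: a malleus (sphere head fused with
a cylindrical handle), an incus (ellipsoid body with two thin processes) and
a stapes (two oblique crura joining a flat elliptical footplate). The stapes
is the smallest structure by construction, matching the ~3 mm scale of the
adult stapes that makes it the hardest of the three to segment. Per-case
pose/size jitter, trilinear-like partial volume (a small Gaussian blur) and
additive Gaussian HU noise provide case-to-case variability; CT physics
(beam hardening, scatter) is not simulated.

Output is deterministic: a phantom is a pure function of (spec, case_seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import ImageVolume, LabelVolume, write_volume, STRUCTURE_NAMES


class PhantomSizingError(ValueError):
    """The requested grid cannot contain the structures at their sizes."""


class SpecError(ValueError):
    """PhantomSpec violates one of its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; defaults give a 64**3, 0.3 mm desk-scale phantom.

    HU defaults place every compartment inside the CT normalization window
    used downstream (-2000..4000 HU): exterior air -1000, petrous bone
    +1800, ossicles +2200, cavity air -900, additive noise sd 40 HU.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)  # mm
    hu_air: float = -1000.0
    hu_bone: float = 1800.0
    hu_ossicle: float = 2200.0
    hu_cavity: float = -900.0
    noise_sd: float = 40.0  # HU
    malleus_length: float = 8.0  # mm
    incus_length: float = 6.5  # mm
    stapes_length: float = 3.0  # mm
    jitter: float = 0.1  # fractional size jitter; also sets pose jitter scale
    seed: int = 0

    def validate(self) -> None:
        if not (
            self.stapes_length < self.incus_length
            and self.stapes_length < self.malleus_length
        ):
            raise SpecError(
                "stapes_length must be the smallest structure length "
                f"(got stapes={self.stapes_length}, incus={self.incus_length}, "
                f"malleus={self.malleus_length})"
            )
        mx = max(self.spacing)
        for name, ln in (
            ("malleus", self.malleus_length),
            ("incus", self.incus_length),
            ("stapes", self.stapes_length),
        ):
            if ln <= 2 * mx:
                raise SpecError(
                    f"{name}_length={ln} mm is not resolvable at spacing {self.spacing}"
                )
        if not (self.hu_air < self.hu_bone <= self.hu_ossicle):
            raise SpecError("require hu_air < hu_bone <= hu_ossicle")
        if any(s <= 0 for s in self.spacing) or any(n < 1 for n in self.grid_shape):
            raise SpecError("grid_shape and spacing must be positive")
        if not (0 <= self.jitter < 0.5):
            raise SpecError("jitter must lie in [0, 0.5)")


FULL_SCALE = dict(grid_shape=(256, 256, 256), spacing=(0.2, 0.2, 0.2))


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    """Small intrinsic XYZ Euler rotation."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _capsule(pts: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    """Boolean mask of points within distance r of segment a-b (mm)."""
    ab = b - a
    denom = float(ab @ ab)
    t = ((pts - a) @ ab) / denom if denom > 0 else np.zeros(len(pts))
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.sum((pts - closest) ** 2, axis=1) <= r * r


def _ellipsoid(pts: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    return np.sum(((pts - center) / semi) ** 2, axis=1) <= 1.0


def _malleus(pts: np.ndarray, length: float, min_r: float) -> np.ndarray:
    """Sphere head fused with a cylindrical handle, long axis = local z."""
    rh = max(0.21 * length, min_r)
    head_c = np.array([0.0, 0.0, length / 2 - rh])
    handle_r = max(0.09 * length, min_r)
    tip = np.array([0.0, 0.0, -length / 2 + handle_r])
    head = np.sum((pts - head_c) ** 2, axis=1) <= rh * rh
    handle = _capsule(pts, head_c, tip, handle_r)
    return head | handle


def _incus(pts: np.ndarray, length: float, min_r: float) -> np.ndarray:
    """Ellipsoid body with a long and a short process."""
    body_semi = np.array([0.28, 0.22, 0.26]) * length
    body_c = np.array([0.0, 0.0, length / 2 - body_semi[2]])
    body = _ellipsoid(pts, body_c, body_semi)
    pr = max(0.09 * length, min_r)
    long_tip = np.array([0.12 * length, 0.0, -length / 2 + pr])
    short_tip = body_c + np.array([0.0, 0.38 * length, 0.0])
    long_p = _capsule(pts, body_c, long_tip, pr)
    short_p = _capsule(pts, body_c, short_tip, pr)
    return body | long_p | short_p


def _stapes(pts: np.ndarray, length: float, min_r: float) -> np.ndarray:
    """Flat elliptical footplate joined to a small head by two oblique crura."""
    t = max(0.2 * length, 2 * min_r)  # footplate thickness
    plate_c = np.array([0.0, 0.0, -length / 2 + t / 2])
    a, b = 0.33 * length, max(0.23 * length, min_r)  # footplate semi-axes
    plate = (np.abs(pts[:, 2] - plate_c[2]) <= t / 2) & (
        (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 <= 1.0
    )
    rh = max(0.13 * length, min_r)
    head_c = np.array([0.0, 0.0, length / 2 - rh])
    head = np.sum((pts - head_c) ** 2, axis=1) <= rh * rh
    cr = max(0.10 * length, min_r)
    crus1 = _capsule(pts, np.array([0.6 * a, 0.0, plate_c[2]]), head_c, cr)
    crus2 = _capsule(pts, np.array([-0.6 * a, 0.0, plate_c[2]]), head_c, cr)
    return plate | head | crus1 | crus2


_SHAPES = {1: _malleus, 2: _incus, 3: _stapes}
# Conservative bounding radius of each canonical shape, as a fraction of length.
_BOUND_FRAC = {1: 0.52, 2: 0.55, 3: 0.55}


def _layout(spec: PhantomSpec):
    """Cavity geometry and nominal structure centers, all in mm."""
    extent = np.array(spec.grid_shape) * np.array(spec.spacing)
    center = (np.array(spec.grid_shape) - 1) * np.array(spec.spacing) / 2
    cavity_semi = 0.33 * extent
    offsets = {
        1: np.array([-0.50 * cavity_semi[0], 0.0, 0.0]),
        2: np.array([0.0, -0.10 * cavity_semi[1], 0.0]),
        3: np.array([0.53 * cavity_semi[0], 0.15 * cavity_semi[1], 0.0]),
    }
    return extent, center, cavity_semi, offsets


def _check_sizing(spec: PhantomSpec) -> None:
    lengths = {1: spec.malleus_length, 2: spec.incus_length, 3: spec.stapes_length}
    _, _, cavity_semi, offsets = _layout(spec)
    for lab, ln in lengths.items():
        r = _BOUND_FRAC[lab] * ln * (1 + spec.jitter)
        # Room left inside the cavity ellipsoid at this structure's offset.
        u = np.linalg.norm(offsets[lab] / cavity_semi)
        room = min(cavity_semi) * max(0.0, np.sqrt(max(0.0, 1 - u * u)))
        if r > room:
            raise PhantomSizingError(
                f"grid {spec.grid_shape} at spacing {spec.spacing} is too small to "
                f"contain the {STRUCTURE_NAMES[lab]} (needs {r:.1f} mm of cavity "
                f"room, has {room:.1f} mm)"
            )


def generate_phantom(
    spec: PhantomSpec, case_seed: int
) -> tuple[ImageVolume, LabelVolume]:
    """Generate one phantom image/label pair.

    Labels mark voxels whose centers lie inside each structure's solid;
    the image renders the compartments at their HU, applies a small
    Gaussian partial-volume blur (sigma 0.35 voxel) and additive noise,
    then rounds to integer HU.
    """
    spec.validate()
    _check_sizing(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(case_seed)]))

    shape = tuple(int(n) for n in spec.grid_shape)
    sp = np.array(spec.spacing)
    _, center, cavity_semi, offsets = _layout(spec)
    axes = [np.arange(n) * s for n, s in zip(shape, sp)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid.astype(np.float64)

    lengths = {1: spec.malleus_length, 2: spec.incus_length, 3: spec.stapes_length}
    labels = np.zeros(int(np.prod(shape)), dtype=np.uint8)
    masks = {}
    for lab in (1, 2, 3):
        scale = 1.0 + rng.uniform(-spec.jitter, spec.jitter)
        angles = rng.uniform(-spec.jitter, spec.jitter, size=3)  # radians
        shift = rng.uniform(-3 * spec.jitter, 3 * spec.jitter, size=3)  # mm
        rot = _rotation_matrix(angles)
        pos = center + offsets[lab] + shift
        local = (grid - pos) @ rot  # world -> canonical frame
        # thin parts never fall below ~2/3 voxel radius, keeping every
        # structure a single 26-connected component at any valid spacing
        min_r = 0.62 * max(spec.spacing)
        mask = _SHAPES[lab](local, lengths[lab] * scale, min_r)
        masks[lab] = mask
        labels[mask] = lab

    cavity = _ellipsoid(grid, center, cavity_semi)
    img = np.full(len(grid), spec.hu_bone, dtype=np.float32)
    img[grid[:, 0] < 4 * sp[0]] = spec.hu_air  # exterior air at one face
    img[cavity] = spec.hu_cavity
    for lab in (1, 2, 3):
        img[masks[lab]] = spec.hu_ossicle

    img = img.reshape(shape)
    img = ndimage.gaussian_filter(img, sigma=0.35)
    img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(np.round(img), -32768, 32767).astype(np.int16)

    spacing = tuple(float(s) for s in sp)
    return (
        ImageVolume(img, spacing),
        LabelVolume(labels.reshape(shape), spacing),
    )


def case_seed_for(spec_seed: int, case_index: int) -> int:
    """Deterministic per-case seed: first word of SeedSequence([spec.seed, index])."""
    ss = np.random.SeedSequence([int(spec_seed), int(case_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n_cases: int, spec: PhantomSpec, out_dir: str, compress: bool = True
) -> pd.DataFrame:
    """Write ``n_cases`` image/label NIfTI pairs plus a CSV manifest.

    Re-running with the same inputs overwrites with identical files. The
    manifest (``manifest.csv``) lists case_id, image_path, label_path and
    the per-case seed; paths are relative to ``out_dir``.
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    spec.validate()
    os.makedirs(out_dir, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    rows = []
    for i in range(int(n_cases)):
        cid = f"case_{i:03d}"
        seed = case_seed_for(spec.seed, i)
        image, label = generate_phantom(spec, seed)
        ipath, lpath = f"{cid}_image{ext}", f"{cid}_label{ext}"
        write_volume(image, os.path.join(out_dir, ipath))
        write_volume(label, os.path.join(out_dir, lpath))
        rows.append(
            {"case_id": cid, "image_path": ipath, "label_path": lpath, "seed": seed}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    spec_row = pd.Series(asdict(spec)).astype(str)
    spec_row.to_csv(os.path.join(out_dir, "phantom_spec.csv"), header=False)
    return manifest
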