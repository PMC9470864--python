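"""Segmentation evaluation: DSC, ASD, HD, HD95 per structure, paired t-tests.

Definitions follow the standard surface-distance formulation:

* DSC = 2|P ∩ T| / (|P| + |T|), in [0, 1]; >= 0.7 is conventionally read
  as good automatic/manual consistency for ossicle segmentation.
* The boundary of a mask is the set of physical centers (mm) of foreground
  voxels with at least one background 6-neighbor (out-of-grid counts as
  background).
* Directed ASD(X, Y) = mean over x in X of min over y in Y of ||x - y||;
  the reported ASD averages both directions.
* HD is the maximum of the pooled two-directional nearest-neighbor
  distance set; HD95 is that set's 95th percentile (linear interpolation),
  so HD95 <= HD always.

Distances are physical (mm) via the voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .volume_io import LabelVolume, UsageError, STRUCTURE_NAMES


class UndefinedSurfaceError(ValueError):
    """A surface was requested for an empty mask."""


def dsc(mask_t: np.ndarray, mask_p: np.ndarray) -> float:
    """Dice similarity coefficient of two boolean masks (empty-vs-empty -> 1)."""
    mask_t = np.asarray(mask_t, dtype=bool)
    mask_p = np.asarray(mask_p, dtype=bool)
    if mask_t.shape != mask_p.shape:
        raise UsageError(f"mask shapes differ: {mask_t.shape} vs {mask_p.shape}")
    st, sp = int(mask_t.sum()), int(mask_p.sum())
    if st == 0 and sp == 0:
        return 1.0
    return 2.0 * int((mask_t & mask_p).sum()) / (st + sp)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical centers (mm) of boundary voxels; (n, 3) array."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise UndefinedSurfaceError("cannot take the surface of an empty mask")
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    boundary = mask & ~interior
    return np.argwhere(boundary) * np.asarray(spacing, dtype=float)


def _directed(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distances from each point of x to the set y."""
    return cKDTree(y).query(x, k=1)[0]


def asd(x: np.ndarray, y: np.ndarray, symmetric: bool = True) -> float:
    """Average surface distance in mm (symmetric mean of both directions by default)."""
    x, y = np.atleast_2d(x), np.atleast_2d(y)
    if x.size == 0 or y.size == 0:
        raise UndefinedSurfaceError("ASD is undefined for an empty point set")
    d_xy = _directed(x, y).mean()
    if not symmetric:
        return float(d_xy)
    return float((d_xy + _directed(y, x).mean()) / 2.0)


def hausdorff(x: np.ndarray, y: np.ndarray, pooled: bool = True) -> tuple[float, float]:
    """(HD, HD95) in mm over the pooled two-directional distance set.

    With ``pooled=False`` only the X -> Y direction is used.
    """
    x, y = np.atleast_2d(x), np.atleast_2d(y)
    if x.size == 0 or y.size == 0:
        raise UndefinedSurfaceError("HD is undefined for an empty point set")
    d = _directed(x, y)
    if pooled:
        d = np.concatenate([d, _directed(y, x)])
    return float(d.max()), float(np.percentile(d, 95, method="linear"))


@dataclass
class StructureMetrics:
    dsc: float
    asd: float  # mm; nan if undefined
    hd: float  # mm; nan if undefined
    hd95: float  # mm; nan if undefined
    undefined_distances: bool = False


@dataclass
class SegMetrics:
    """Per-structure metrics for one case; the unit of statistical comparison."""

    per_structure: dict[str, StructureMetrics] = field(default_factory=dict)

    def as_row(self, case_id: str = "") -> list[dict]:
        rows = []
        for name, m in self.per_structure.items():
            rows.append(
                {
                    "case_id": case_id,
                    "structure": name,
                    "dsc": m.dsc,
                    "asd": m.asd,
                    "hd": m.hd,
                    "hd95": m.hd95,
                    "undefined_distances": m.undefined_distances,
                }
            )
        return rows


def evaluate_case(pred: LabelVolume, truth: LabelVolume) -> SegMetrics:
    """All four metrics per structure label for one predicted/true pair.

    Structures absent from both volumes score DSC 1 and zero distances;
    structures absent from exactly one score DSC 0 with distances flagged
    undefined (NaN).
    """
    if not truth.same_geometry(pred):
        raise UsageError("prediction and truth must share grid geometry")
    out = SegMetrics()
    for label, name in STRUCTURE_NAMES.items():
        mt = truth.data == label
        mp = pred.data == label
        has_t, has_p = bool(mt.any()), bool(mp.any())
        if not has_t and not has_p:
            out.per_structure[name] = StructureMetrics(1.0, 0.0, 0.0, 0.0)
            continue
        d = dsc(mt, mp)
        if has_t and has_p:
            st = surface_points(mt, truth.spacing)
            sp = surface_points(mp, pred.spacing)
            a = asd(st, sp)
            hd, hd95 = hausdorff(st, sp)
            out.per_structure[name] = StructureMetrics(d, a, hd, hd95)
        else:
            out.per_structure[name] = StructureMetrics(
                d, np.nan, np.nan, np.nan, undefined_distances=True
            )
    return out


@dataclass(frozen=True)
class PairedTTest:
    t: float
    p: float
    degenerate: bool = False

    def __iter__(self):  # allow t, p = paired_ttest(...)
        yield self.t
        yield self.p


def paired_ttest(metric_a, metric_b) -> PairedTTest:
    """Two-sided paired t-test on per-case metric values.

    All-equal differences (zero variance, e.g. identical methods) yield a
    degenerate flag instead of a number.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise UsageError("paired t-test needs two equal-length 1D value lists")
    if a.size < 2:
        raise UsageError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.allclose(d, d[0]) and (np.all(d == d[0])):
        return PairedTTest(np.nan, np.nan, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTTest(float(res.statistic), float(res.pvalue))


def metrics_report(cases: dict[str, SegMetrics]) -> pd.DataFrame:
    """One row per (case, structure) with dsc/asd/hd/hd95."""
    rows = []
    for cid, m in cases.items():
        rows.extend(m.as_row(cid))
    return pd.DataFrame(rows)


def comparison_report(
    cases_a: dict[str, SegMetrics], cases_b: dict[str, SegMetrics],
    name_a: str = "method_a", name_b: str = "method_b",
) -> pd.DataFrame:
    """Per (structure, metric) mean +/- sd for two methods plus paired t and p."""
    ra = metrics_report(cases_a).set_index(["case_id", "structure"]).sort_index()
    rb = metrics_report(cases_b).set_index(["case_id", "structure"]).sort_index()
    rows = []
    for structure in sorted(set(ra.index.get_level_values("structure"))):
        for metric in ("dsc", "asd", "hd", "hd95"):
            va = ra.xs(structure, level="structure")[metric].astype(float)
            vb = rb.xs(structure, level="structure")[metric].astype(float)
            va, vb = va.align(vb, join="inner")
            tt = paired_ttest(va.values, vb.values)
            rows.append(
                {
                    "structure": structure,
                    "metric": metric,
                    f"{name_a}_mean": va.mean(),
                    f"{name_a}_sd": va.std(ddof=1),
                    f"{name_b}_mean": vb.mean(),
                    f"{name_b}_sd": vb.std(ddof=1),
                    "t": tt.t,
                    "p": tt.p,
                    "degenerate": tt.degenerate,
                }
            )
    return pd.DataFrame(rows)
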