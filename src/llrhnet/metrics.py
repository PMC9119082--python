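"""Overlap and surface-distance metrics for segmentation masks.

Implements the five standard lesion-segmentation scores between a predicted
pixel set P and a ground-truth set G on a rectangular lattice:

* ``dice``      — DC(P,G)   = 2|P∩G| / (|P|+|G|)
* ``voe``       — VOE(P,G)  = 1 − |P∩G| / |P∪G|     (1 − Jaccard)
* ``rvd``       — RVD(P,G)  = (|G|−|P|) / |P|        (signed, asymmetric)
* ``hausdorff`` — HD(P,G)   = max of the two directed max–min Euclidean
  nearest-neighbour distances
* ``assd``      — ASSD(P,G) = mean of the two directed mean nearest-neighbour
  distances

The distance metrics range over *all* foreground pixels by default, exactly
as the max/min formulas are written; set ``boundary_only=True`` to restrict
both sets to their morphological boundaries first.  Distances are Euclidean
on pixel centres, scaled per axis by ``pixel_spacing`` (mm), and are
computed with a KD-tree — numerically identical to the O(|P||G|) double
loop, just faster.  Masks may be 2D (slices) or 3D (stacked volumes).

Empty-mask conventions: DC=1 and VOE=0 when both masks are empty; RVD is
undefined for |P|=0 and HD/ASSD are undefined when either mask is empty.
The scalar functions raise :class:`UndefinedMetricError` in those cases;
:func:`evaluate_multiclass` converts them to NaN entries carrying a reason
code, so that undefined values are never silently reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given mask pair (e.g. an empty mask)."""

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        self.reason = reason
        super().__init__(f"{metric} undefined: {reason}")


@dataclass(frozen=True)
class BinaryMask:
    """One class's pixel set on a rectangular lattice.

    Parameters
    ----------
    grid : boolean array, 2D or 3D
    pixel_spacing : physical size per pixel along each axis, in mm
    """

    grid: np.ndarray
    pixel_spacing: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        if any(s < 1 for s in g.shape):
            raise ValueError("mask must have extent >= 1 on every axis")
        sp = tuple(float(s) for s in np.atleast_1d(self.pixel_spacing))
        if len(sp) == 1:
            sp = sp * g.ndim
        if len(sp) != g.ndim:
            raise ValueError("pixel_spacing length must match mask dimensionality")
        if any(s <= 0 for s in sp):
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "pixel_spacing", sp)

    @property
    def size(self) -> int:
        return int(self.grid.sum())


@dataclass
class MetricReport:
    """Per-class metric values; NaN entries carry a reason in ``missing``."""

    class_label: int
    dc: float
    voe: float
    rvd: float
    assd: float
    hd: float
    missing: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "class": self.class_label,
            "dc": self.dc, "voe": self.voe, "rvd": self.rvd,
            "assd": self.assd, "hd": self.hd,
            "missing": dict(self.missing),
        }


def _coerce(m) -> BinaryMask:
    if isinstance(m, BinaryMask):
        return m
    return BinaryMask(np.asarray(m, dtype=bool), (1.0,) * np.asarray(m).ndim)


def _check_pair(p: BinaryMask, g: BinaryMask):
    if p.grid.shape != g.grid.shape:
        raise ValueError(f"mask shape mismatch: {p.grid.shape} vs {g.grid.shape}")
    if p.pixel_spacing != g.pixel_spacing:
        raise ValueError("mask pixel spacings differ")


def dice(p, g) -> float:
    """Dice coefficient 2|P∩G|/(|P|+|G|); 1.0 when both masks are empty."""
    p, g = _coerce(p), _coerce(g)
    _check_pair(p, g)
    denom = p.size + g.size
    if denom == 0:
        return 1.0
    inter = int(np.logical_and(p.grid, g.grid).sum())
    return 2.0 * inter / denom


def voe(p, g) -> float:
    """Volumetric overlap error 1 − |P∩G|/|P∪G|; 0.0 when both are empty."""
    p, g = _coerce(p), _coerce(g)
    _check_pair(p, g)
    union = int(np.logical_or(p.grid, g.grid).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(p.grid, g.grid).sum())
    return 1.0 - inter / union


def rvd(p, g) -> float:
    """Relative volume difference (|G|−|P|)/|P|; undefined for empty P."""
    p, g = _coerce(p), _coerce(g)
    _check_pair(p, g)
    if p.size == 0:
        raise UndefinedMetricError("rvd", "empty prediction")
    return (g.size - p.size) / p.size


def _coords(mask: BinaryMask, boundary_only: bool) -> np.ndarray:
    grid = mask.grid
    if boundary_only:
        interior = binary_erosion(grid, border_value=0)
        grid = grid & ~interior
    pts = np.argwhere(grid).astype(float)
    return pts * np.asarray(mask.pixel_spacing)


def _directed_min_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For every point in a, distance to its nearest neighbour in b."""
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return d


def hausdorff(p, g, boundary_only: bool = False) -> float:
    """Symmetric Hausdorff distance (mm); undefined if either mask is empty."""
    p, g = _coerce(p), _coerce(g)
    _check_pair(p, g)
    if p.size == 0 or g.size == 0:
        raise UndefinedMetricError("hd", "empty mask")
    cp, cg = _coords(p, boundary_only), _coords(g, boundary_only)
    return float(max(_directed_min_dists(cp, cg).max(),
                     _directed_min_dists(cg, cp).max()))


def assd(p, g, boundary_only: bool = False) -> float:
    """Average symmetric surface distance (mm); undefined on empty masks."""
    p, g = _coerce(p), _coerce(g)
    _check_pair(p, g)
    if p.size == 0 or g.size == 0:
        raise UndefinedMetricError("assd", "empty mask")
    cp, cg = _coords(p, boundary_only), _coords(g, boundary_only)
    return float(0.5 * (_directed_min_dists(cp, cg).mean()
                        + _directed_min_dists(cg, cp).mean()))


def evaluate_multiclass(pred_labels: np.ndarray, gt_labels: np.ndarray,
                        classes=(1, 2), pixel_spacing=(1.0, 1.0),
                        boundary_only: bool = False) -> list[MetricReport]:
    """Score each class against the rest; one :class:`MetricReport` per class.

    Metrics that are undefined for a class (empty prediction and/or ground
    truth) are reported as NaN with a reason code in ``report.missing``.
    """
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("label map shapes differ")
    allowed = {0, *(int(c) for c in classes)}
    present = set(np.unique(pred_labels)) | set(np.unique(gt_labels))
    unknown = {int(v) for v in present} - allowed
    if unknown:
        raise ValueError(f"unknown labels present: {sorted(unknown)}")

    reports = []
    for c in classes:
        sp = tuple(np.atleast_1d(pixel_spacing))
        if len(sp) == 1:
            sp = sp * pred_labels.ndim
        p = BinaryMask(pred_labels == c, sp)
        g = BinaryMask(gt_labels == c, sp)
        missing: dict[str, str] = {}
        dc_v = dice(p, g)
        voe_v = voe(p, g)
        try:
            rvd_v = rvd(p, g)
        except UndefinedMetricError as e:
            rvd_v, missing["rvd"] = float("nan"), e.reason
        try:
            hd_v = hausdorff(p, g, boundary_only)
        except UndefinedMetricError:
            hd_v, missing["hd"] = float("nan"), "empty"
        try:
            assd_v = assd(p, g, boundary_only)
        except UndefinedMetricError:
            assd_v, missing["assd"] = float("nan"), "empty"
        reports.append(MetricReport(int(c), dc_v, voe_v, rvd_v, assd_v, hd_v, missing))
    return reports


def evaluate_volume(pred_slices, gt_slices, classes=(1, 2),
                    pixel_spacing=(1.0, 1.0, 1.0)) -> list[MetricReport]:
    """Stack ordered 2D label slices into 3D volumes and score them jointly."""
    pred = np.stack([np.asarray(s) for s in pred_slices], axis=0)
    gt = np.stack([np.asarray(s) for s in gt_slices], axis=0)
    return evaluate_multiclass(pred, gt, classes=classes, pixel_spacing=pixel_spacing)
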