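"""Alignment quality metrics: Dice overlap, barycentre distance, landmark TRE.

All geometric quantities are computed in world mm (barycentres are voxel-count
weighted world centroids), so anisotropic grids are handled transparently.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .imagecore import AffineTransform, VolumeGrid, GridMismatchError, max_euler_rotation


@dataclass
class LandmarkSet:
    """Named world-coordinate (mm) points from one image."""

    points: dict[str, tuple[float, float, float]]
    image_id: str = ""

    def __post_init__(self) -> None:
        pts = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r} must be a finite 3-vector")
            pts[str(name)] = tuple(arr)
        self.points = pts

    @classmethod
    def from_csv(cls, path, image_id: str = "") -> "LandmarkSet":
        pts = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("name", "#"):
                    continue
                pts[row[0].strip()] = tuple(float(v) for v in row[1:4])
        return cls(pts, image_id)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x", "y", "z"])
            for name, p in self.points.items():
                w.writerow([name, *p])


def dice_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A| + |B|); 0 (with a warning) when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("dice_overlap of two empty masks defined as 0")
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def barycentre(mask: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("barycentre of an empty mask")
    idx = np.argwhere(mask).mean(axis=0)
    return grid.index_to_world(idx)


def barycentre_distance(
    a: np.ndarray, grid_a: VolumeGrid, b: np.ndarray, grid_b: VolumeGrid,
    t: AffineTransform | None = None,
) -> float:
    """Distance (mm) between the t-mapped barycentre of ``a`` and that of ``b``."""
    t = t or AffineTransform.identity()
    ca = t.apply(barycentre(a, grid_a))
    cb = barycentre(b, grid_b)
    return float(np.linalg.norm(ca - cb))


def mean_tre(lm_fixed: LandmarkSet, lm_moving: LandmarkSet, t: AffineTransform | None = None) -> float:
    """Mean distance between t-mapped moving landmarks and fixed landmarks."""
    t = t or AffineTransform.identity()
    fixed_names = set(lm_fixed.points)
    moving_names = set(lm_moving.points)
    if fixed_names != moving_names:
        raise ValueError(
            f"landmark name mismatch; only in fixed: {sorted(fixed_names - moving_names)}, "
            f"only in moving: {sorted(moving_names - fixed_names)}"
        )
    dists = [
        np.linalg.norm(np.asarray(t.apply(np.asarray(lm_moving.points[n]))) - np.asarray(lm_fixed.points[n]))
        for n in sorted(fixed_names)
    ]
    return float(np.mean(dists))


@dataclass
class MetricReport:
    dice: dict[str, float] = field(default_factory=dict)
    barycentre_mm: dict[str, float] = field(default_factory=dict)
    mtre_mm: float | None = None
    max_euler_deg: float | None = None

    def __post_init__(self) -> None:
        for v in self.dice.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("Dice values must lie in [0, 1]")
        for v in self.barycentre_mm.values():
            if v < 0:
                raise ValueError("distances must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"dice": self.dice, "barycentre_mm": self.barycentre_mm,
                 "mtre_mm": self.mtre_mm, "max_euler_deg": self.max_euler_deg},
                fh, indent=2,
            )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "structure", "value"])
            for k, v in self.dice.items():
                w.writerow(["dice", k, v])
            for k, v in self.barycentre_mm.items():
                w.writerow(["barycentre_mm", k, v])
            if self.mtre_mm is not None:
                w.writerow(["mtre_mm", "", self.mtre_mm])
            if self.max_euler_deg is not None:
                w.writerow(["max_euler_deg", "", self.max_euler_deg])


def report_alignment(
    source_labels, target_labels, t: AffineTransform,
    structures: list[str] | None = None,
) -> MetricReport:
    """Per-structure Dice / barycentre distances after mapping source to target.

    Dice is computed on the target grid by nearest-neighbour resampling of the
    source label masks through the transform.
    """
    from .imagecore import ScalarVolume, resample_volume

    names = structures or sorted(
        set(source_labels.scheme.values()) & set(target_labels.scheme.values()) - {"background"}
    )
    rep = MetricReport()
    inv = t.inverse()
    for name in names:
        src_m = source_labels.mask(name)
        tgt_m = target_labels.mask(name)
        if not src_m.any() or not tgt_m.any():
            continue
        moved = resample_volume(
            ScalarVolume(source_labels.grid, src_m.astype(float)), inv, target_labels.grid, "nearest"
        ).values > 0.5
        rep.dice[name] = dice_overlap(moved, tgt_m)
        rep.barycentre_mm[name] = barycentre_distance(src_m, source_labels.grid, tgt_m, target_labels.grid, t)
    rep.max_euler_deg = max_euler_rotation(t)
    return rep
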