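"""Shared volumetric data model and transform algebra.

All modules work with axis-aligned voxel grids in physical (mm) world
coordinates.  Conventions, used consistently across the package:

* world coordinates are in mm; voxel indices are 0-based ``(i, j, k)`` along
  the grid axes; the world position of a voxel is ``origin + index * spacing``;
* transforms are 4x4 homogeneous maps of world coordinates.  Resampling uses
  the pull-back convention: the output value at world point ``p`` is the input
  volume interpolated at ``t(p)``;
* Euler angles are reported in the intrinsic z-y-x convention, in degrees in
  ``(-180, 180]``.  They are used only for reporting (e.g. the maximum Euler
  rotation of a recovered transform), never to parameterise optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.linalg import polar
from scipy.spatial.transform import Rotation


class GridMismatchError(ValueError):
    """Two volumes expected on the same grid are not."""


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel lattice embedded in world (mm) space."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world map."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def corners_world(self) -> np.ndarray:
        """World coordinates of the 8 grid corners (voxel-centre extremes)."""
        hi = np.asarray(self.shape) - 1
        corners = np.array([[x, y, z] for x in (0, hi[0]) for y in (0, hi[1]) for z in (0, hi[2])], dtype=float)
        return self.index_to_world(corners)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinate arrays broadcastable to ``shape``."""
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


@dataclass
class ScalarVolume:
    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class LabelVolume:
    """Integer structure labels on a grid; label 0 is reserved for background."""

    grid: VolumeGrid
    labels: np.ndarray
    scheme: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.labels = self.labels.astype(np.int32, copy=False)
        if self.labels.shape != self.grid.shape:
            raise ValueError(f"labels shape {self.labels.shape} != grid shape {self.grid.shape}")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        scheme = dict(self.scheme)
        scheme.setdefault(0, "background")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(scheme)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in volume but absent from scheme")
        self.scheme = scheme

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named structures."""
        wanted = {k for k, v in self.scheme.items() if v in names}
        unknown = set(names) - set(self.scheme.values())
        if unknown:
            raise KeyError(f"structures {sorted(unknown)} not in scheme")
        return np.isin(self.labels, sorted(wanted))

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid, self.labels.copy(), dict(self.scheme))


class AffineTransform:
    """Invertible 4x4 homogeneous map of world (mm) coordinates."""

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("last row of a homogeneous transform must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("transform 3x3 block is singular")
        self.matrix = m.copy()
        self.matrix[3] = [0, 0, 0, 1]

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rigid(
        cls,
        translation=(0.0, 0.0, 0.0),
        euler_deg=(0.0, 0.0, 0.0),
        centre=(0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Rigid transform rotating (intrinsic z-y-x) about ``centre``."""
        r = Rotation.from_euler("ZYX", euler_deg, degrees=True).as_matrix()
        c = np.asarray(centre, dtype=float)
        t = np.asarray(translation, dtype=float)
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = c - r @ c + t
        return cls(m)

    @classmethod
    def from_scaling(cls, factor: float, centre=(0.0, 0.0, 0.0)) -> "AffineTransform":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        c = np.asarray(centre, dtype=float)
        m = np.eye(4)
        m[:3, :3] *= factor
        m[:3, 3] = c * (1.0 - factor)
        return cls(m)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self o other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return self.compose(other)

    def rigid_params(self) -> "RigidParams":
        """Translation and Euler angles of the rotation factor (polar decomposition)."""
        rot, _ = polar(self.matrix[:3, :3])
        if np.linalg.det(rot) < 0:
            raise ValueError("transform contains a reflection; no rigid parameterisation")
        ang = Rotation.from_matrix(rot).as_euler("ZYX", degrees=True)
        ang = np.where(ang <= -180.0, ang + 360.0, ang)
        return RigidParams(tuple(self.matrix[:3, 3]), tuple(ang))

    def __repr__(self) -> str:
        return f"AffineTransform(\n{np.array_str(self.matrix, precision=4)})"


@dataclass(frozen=True)
class RigidParams:
    translation: tuple[float, float, float]
    euler_angles_deg: tuple[float, float, float]


# ---------------------------------------------------------------------------
# operations


def resample_volume(
    vol: ScalarVolume,
    t: AffineTransform,
    out_grid: VolumeGrid,
    interpolation: str = "linear",
) -> ScalarVolume:
    """Pull-back resampling: output value at world ``p`` is input at ``t(p)``.

    Points mapping outside the input support are filled with 0.
    """
    orders = {"nearest": 0, "linear": 1}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}; expected one of {sorted(orders)}")
    # world -> world map composed with both grids' index/world maps
    src_grid = vol.grid
    a = np.diag(np.r_[np.asarray(src_grid.spacing), 1.0])
    a[:3, 3] = src_grid.origin
    b = np.diag(np.r_[np.asarray(out_grid.spacing), 1.0])
    b[:3, 3] = out_grid.origin
    m = np.linalg.inv(a) @ t.matrix @ b  # out index -> source index
    idx = np.indices(out_grid.shape, dtype=float).reshape(3, -1)
    src_idx = m[:3, :3] @ idx + m[:3, 3:4]
    out = ndimage.map_coordinates(
        vol.values, src_idx, order=orders[interpolation], mode="constant", cval=0.0, prefilter=False
    )
    return ScalarVolume(out_grid, out.reshape(out_grid.shape))


def gaussian_smooth(vol: ScalarVolume, sigma_mm: float) -> ScalarVolume:
    """Separable Gaussian smoothing with sigma given in mm (reflective boundary)."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    sigma_vox = [sigma_mm / s for s in vol.grid.spacing]
    out = ndimage.gaussian_filter(vol.values, sigma_vox, mode="reflect")
    return ScalarVolume(vol.grid, out)


def distance_map(mask, grid: VolumeGrid | None = None) -> ScalarVolume:
    """Euclidean distance (mm) from every voxel to the nearest mask voxel.

    ``mask`` may be a LabelVolume (non-zero labels are foreground) or a boolean
    array with an explicit ``grid``.
    """
    if isinstance(mask, LabelVolume):
        grid = mask.grid
        fg = mask.labels > 0
    else:
        if grid is None:
            raise ValueError("grid required when mask is a bare array")
        fg = np.asarray(mask, dtype=bool)
    if not fg.any():
        raise ValueError("distance_map: mask is empty")
    d = ndimage.distance_transform_edt(~fg, sampling=grid.spacing)
    return ScalarVolume(grid, d)


def max_euler_rotation(t: AffineTransform) -> float:
    """Largest absolute Euler angle (degrees) of the transform's rotation factor.

    Scale and shear are removed by polar decomposition before extracting
    intrinsic z-y-x angles, so the result is invariant to pure scaling.
    """
    params = t.rigid_params()
    return float(np.max(np.abs(params.euler_angles_deg)))


def max_corner_displacement(a: AffineTransform, b: AffineTransform, grid: VolumeGrid) -> float:
    """Max distance (mm) between images of the grid corners under two transforms.

    Used as the convergence / agreement measure for registration: it bounds the
    displacement difference over the whole field of view for affine maps.
    """
    corners = grid.corners_world()
    return float(np.max(np.linalg.norm(a.apply(corners) - b.apply(corners), axis=1)))


# ---------------------------------------------------------------------------
# I/O


def _grid_from_nifti(img) -> tuple[VolumeGrid, np.ndarray]:
    img = nib.as_closest_canonical(img)
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.sqrt((lin**2).sum(axis=0))
    # after canonical reorientation the linear part should be near-diagonal
    if np.max(np.abs(lin - np.diag(np.diag(lin)))) > 1e-3 * spacing.max():
        raise ValueError("oblique NIfTI grids are not supported; resample to an axis-aligned grid first")
    data = np.asanyarray(img.dataobj)
    grid = VolumeGrid(tuple(data.shape[:3]), tuple(spacing), tuple(aff[:3, 3]))
    return grid, data


def load_scalar(path) -> ScalarVolume:
    grid, data = _grid_from_nifti(nib.load(str(path)))
    return ScalarVolume(grid, np.asarray(data, dtype=np.float64))


def load_labels(path, scheme: dict[int, str] | None = None) -> LabelVolume:
    grid, data = _grid_from_nifti(nib.load(str(path)))
    labels = np.rint(np.asarray(data)).astype(np.int32)
    if scheme is None:
        scheme = {int(v): f"label_{int(v)}" for v in np.unique(labels)}
        scheme[0] = "background"
    return LabelVolume(grid, labels, scheme)


def save_volume(vol, path) -> None:
    """Write a ScalarVolume or LabelVolume as NIfTI-1."""
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int16)
    else:
        data = vol.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.grid.affine), str(path))


def load_transform(path) -> AffineTransform:
    """Read a 4x4 transform from a whitespace-delimited 4-line text file."""
    m = np.loadtxt(str(path))
    return AffineTransform(m)


def save_transform(t: AffineTransform, path) -> None:
    np.savetxt(str(path), t.matrix, fmt="%.12g")
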