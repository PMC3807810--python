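"""Synthetic phantoms and simulated MR / ultrasound appearance.

Every pipeline stage is testable without clinical data through a nested-
ellipsoid fetal-head phantom: a head (brain + CSF) ellipsoid wrapped in a
thin skull shell, two white-matter lobes under a cortical shell separated by
a one-voxel inter-hemispheric gap, deep grey matter, brainstem, cerebellum
(with optional darker cerebellar WM for the younger-gestation preset),
choroid plexus blobs and a septum pellucidum slab.

MR appearance is per-class Gaussian intensity plus a smooth multiplicative
bias field exp(g) with a random low-order polynomial log-field g.  Ultrasound
appearance starts from the pseudo-ultrasound rendition of the structure map
and layers on the artefacts that make real fetal US hard: multiplicative
log-normal speckle, exponential depth attenuation along the beam, a probe
shadow cone, and additive noise, all under a known rigid/affine ground-truth
transform.  Each generator is bitwise-reproducible per seed and returns its
ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .imagecore import AffineTransform, LabelVolume, ScalarVolume, VolumeGrid, resample_volume
from .pseudous import EchogenicityTable, assign_pseudo_intensities
from .structures import (
    NAME_TO_LABEL,
    STRUCTURE_LABELS,
    build_structure_map,
    estimate_skull_shell,
    extract_brain_surface,
    split_hemispheres,
)
from .superres import PSFModel, SliceStack, simulate_slices

TISSUE_LABELS = {0: "background", 1: "wm", 2: "cortex", 3: "dgm", 4: "brainstem",
                 5: "cerebellum", 6: "csf"}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry (all mm, world coordinates centred on the head) of the phantom."""

    shape: tuple[int, int, int] = (113, 97, 89)
    spacing_mm: float = 0.75
    head_semi_axes: tuple[float, float, float] = (27.0, 23.0, 21.0)
    tissue_semi_axes: tuple[float, float, float] = (24.5, 20.5, 18.5)
    cortex_thickness_mm: float = 2.5
    skull_thickness_mm: float = 2.0
    lobe_centres_x: tuple[float, float] = (-9.5, 9.5)
    lobe_semi_axes: tuple[float, float, float] = (10.5, 15.0, 12.5)
    dgm_centre: tuple[float, float, float] = (0.0, 2.0, 0.0)
    dgm_semi_axes: tuple[float, float, float] = (9.0, 7.0, 6.0)
    brainstem_centre: tuple[float, float, float] = (0.0, 5.0, -12.0)
    brainstem_semi_axes: tuple[float, float, float] = (4.5, 4.5, 7.0)
    cerebellum_centre: tuple[float, float, float] = (0.0, 10.5, -9.5)
    cerebellum_semi_axes: tuple[float, float, float] = (9.5, 5.5, 5.5)
    choroid_centres: tuple = ((-7.0, -4.0, 3.5), (7.0, -4.0, 3.5))
    choroid_semi_axes: tuple[float, float, float] = (3.0, 7.0, 2.5)
    septum_centre: tuple[float, float, float] = (0.0, -8.0, 2.0)
    septum_half_extent: tuple[float, float, float] = (0.8, 4.5, 2.5)
    ga_mode: str = "young"
    seed: int = 0

    def grid(self) -> VolumeGrid:
        s = self.spacing_mm
        origin = tuple(-(n - 1) / 2.0 * s for n in self.shape)
        return VolumeGrid(self.shape, (s, s, s), origin)

    def mirrored(self) -> "PhantomSpec":
        """Left-right mirrored geometry (negate every x coordinate)."""
        flip = lambda c: (-c[0], c[1], c[2])
        return replace(
            self,
            lobe_centres_x=tuple(sorted(-x for x in self.lobe_centres_x)),
            dgm_centre=flip(self.dgm_centre),
            brainstem_centre=flip(self.brainstem_centre),
            cerebellum_centre=flip(self.cerebellum_centre),
            choroid_centres=tuple(sorted((flip(c) for c in self.choroid_centres))),
            septum_centre=flip(self.septum_centre),
        )


def _ellipsoid(grids, centre, semi) -> np.ndarray:
    x, y, z = grids
    return ((x - centre[0]) / semi[0]) ** 2 + ((y - centre[1]) / semi[1]) ** 2 + (
        (z - centre[2]) / semi[2]
    ) ** 2 <= 1.0


def _box(grids, centre, half) -> np.ndarray:
    x, y, z = grids
    return (
        (np.abs(x - centre[0]) <= half[0])
        & (np.abs(y - centre[1]) <= half[1])
        & (np.abs(z - centre[2]) <= half[2])
    )


def make_tissue_phantom(spec: PhantomSpec | None = None) -> tuple[LabelVolume, dict[str, np.ndarray]]:
    """Tissue-class label phantom plus auxiliary (manually-segmented-style) masks.

    Returns the EM-style tissue map (wm/cortex/dgm/brainstem/cerebellum/csf)
    and aux masks for choroid plexus, septum pellucidum and (young mode)
    cerebellar WM.
    """
    spec = spec or PhantomSpec()
    grid = spec.grid()
    g = grid.coordinate_grids()
    head = _ellipsoid(g, (0, 0, 0), spec.head_semi_axes)
    tissue = _ellipsoid(g, (0, 0, 0), spec.tissue_semi_axes)
    if not (tissue <= head).all():
        raise ValueError("tissue ellipsoid exceeds the head bounds")

    lab = np.zeros(grid.shape, dtype=np.int32)
    lab[head] = 6  # csf fills the head; tissues carve into it
    # cortical shell: outer rind of the tissue ellipsoid
    inner = _ellipsoid(
        g, (0, 0, 0), tuple(a - spec.cortex_thickness_mm for a in spec.tissue_semi_axes)
    )
    lab[tissue] = 2  # cortex
    # WM lobes inside the cortex
    wm = np.zeros(grid.shape, dtype=bool)
    for cx in spec.lobe_centres_x:
        wm |= _ellipsoid(g, (cx, 0.0, 0.0), spec.lobe_semi_axes)
    wm &= inner
    gap = np.abs(g[0]) <= 0.5 * spec.spacing_mm  # one-voxel inter-hemispheric gap
    wm &= ~gap
    lab[wm] = 1
    for centre, semi, code in (
        (spec.dgm_centre, spec.dgm_semi_axes, 3),
        (spec.brainstem_centre, spec.brainstem_semi_axes, 4),
        (spec.cerebellum_centre, spec.cerebellum_semi_axes, 5),
    ):
        m = _ellipsoid(g, centre, semi)
        if not (m <= head).all():
            raise ValueError(f"structure {TISSUE_LABELS[code]} exceeds the head bounds")
        lab[m & tissue] = code

    aux: dict[str, np.ndarray] = {}
    choroid = np.zeros(grid.shape, dtype=bool)
    for c in spec.choroid_centres:
        choroid |= _ellipsoid(g, c, spec.choroid_semi_axes)
    aux["choroid_plexus"] = choroid & head
    aux["septum_pellucidum"] = _box(g, spec.septum_centre, spec.septum_half_extent) & head
    if spec.ga_mode == "young":
        cereb = lab == 5
        cereb_wm = _ellipsoid(
            g, spec.cerebellum_centre, tuple(0.5 * a for a in spec.cerebellum_semi_axes)
        )
        aux["cerebellar_wm"] = cereb_wm & cereb
    return LabelVolume(grid, lab, dict(TISSUE_LABELS)), aux


def make_label_phantom(spec: PhantomSpec | None = None) -> LabelVolume:
    """Full ultrasound-visible structure map of the phantom.

    Chains the tissue phantom through the real hemisphere-split / skull /
    surface operators so the phantom exercises the same code path as a
    segmented MR volume.
    """
    spec = spec or PhantomSpec()
    tissue, aux = make_tissue_phantom(spec)
    grid = tissue.grid
    wm = tissue.mask("wm")
    brain = tissue.labels > 0
    _, midline, side = split_hemispheres(wm, brain, grid)
    skull = estimate_skull_shell(brain, grid, spec.skull_thickness_mm)
    brain_tissue = brain & ~tissue.mask("csf")
    surface = extract_brain_surface(brain_tissue, grid, 2.0 * spec.spacing_mm)
    return build_structure_map(tissue, skull, surface, midline, side, aux, spec.ga_mode)


# ---------------------------------------------------------------------------
# MR simulation

DEFAULT_MR_MEANS = {  # T2w-like: fluid bright, white matter mid-grey
    "background": 5.0, "wm": 62.0, "cortex": 45.0, "dgm": 52.0, "brainstem": 48.0,
    "cerebellum": 47.0, "csf": 100.0,
}
AMNIOTIC_MEAN = 85.0


def _polynomial_log_bias(grid: VolumeGrid, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Random second-order polynomial g with max |g| equal to ``amplitude``."""
    if amplitude == 0.0:
        return np.zeros(grid.shape)
    x, y, z = grid.coordinate_grids()
    half = [max(abs(grid.origin[a]), abs(grid.origin[a] + grid.spacing[a] * (grid.shape[a] - 1)), 1e-9)
            for a in range(3)]
    u, v, w = x / half[0], y / half[1], z / half[2]
    coeffs = rng.standard_normal(9)
    gfield = (
        coeffs[0] * u + coeffs[1] * v + coeffs[2] * w
        + coeffs[3] * u * v + coeffs[4] * u * w + coeffs[5] * v * w
        + coeffs[6] * (u**2 - 1 / 3) + coeffs[7] * (v**2 - 1 / 3) + coeffs[8] * (w**2 - 1 / 3)
    )
    peak = float(np.abs(gfield).max())
    return gfield * (amplitude / peak) if peak > 0 else np.zeros(grid.shape)


def simulate_mr(
    labels: LabelVolume,
    class_means: dict[str, float] | None = None,
    class_sds: dict[str, float] | float = 2.5,
    bias_amplitude: float = 0.0,
    seed: int = 0,
    amniotic_mean: float = AMNIOTIC_MEAN,
) -> tuple[ScalarVolume, np.ndarray]:
    """Per-class Gaussian MR intensities under a smooth multiplicative bias.

    Returns the simulated volume and the ground-truth log-bias field g
    (the image is ``clean * exp(g)``).  The background outside the head is a
    two-population mixture — dark air far from the head, bright amniotic
    fluid in a layer hugging it — matching the model the segmentation's
    background class assumes.
    """
    rng = np.random.default_rng(seed)
    means = dict(DEFAULT_MR_MEANS if class_means is None else class_means)
    grid = labels.grid
    clean = np.zeros(grid.shape)
    sds = class_sds if isinstance(class_sds, dict) else {n: float(class_sds) for n in means}
    for code, name in labels.scheme.items():
        m = labels.labels == code
        if not m.any():
            continue
        if name not in means:
            raise ValueError(f"no MR intensity model for structure {name!r}")
        clean[m] = means[name] + sds.get(name, 0.0) * rng.standard_normal(int(m.sum()))
    if "background" in means:
        # amniotic-fluid layer: background voxels within 6 mm of the head
        from scipy.ndimage import distance_transform_edt

        bg = labels.labels == 0
        if bg.any() and (~bg).any():
            d = distance_transform_edt(bg, sampling=grid.spacing)
            fluid = bg & (d <= 6.0)
            n = int(fluid.sum())
            clean[fluid] = amniotic_mean + sds.get("background", 0.0) * rng.standard_normal(n)
    gfield = _polynomial_log_bias(grid, bias_amplitude, rng)
    out = np.clip(clean, 1e-3, None) * np.exp(gfield)
    return ScalarVolume(grid, out), gfield


# ---------------------------------------------------------------------------
# ultrasound simulation


@dataclass(frozen=True)
class UsArtifactSpec:
    """Artefact model for simulated ultrasound.

    The probe sits at ``apex_mm`` and looks along ``axis``; attenuation grows
    with depth along the beam, and a cone of half-angle ``shadow_half_angle_deg``
    about the axis is multiplied by ``shadow_factor`` (0 = fully occluded).
    """

    speckle_sigma: float = 0.2           # log-normal multiplicative speckle
    attenuation_per_mm: float = 0.008    # beam attenuation coefficient
    apex_mm: tuple[float, float, float] = (0.0, 0.0, 55.0)
    axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    shadow_half_angle_deg: float = 0.0   # 0 disables the shadow cone
    shadow_factor: float = 0.25
    noise_sd: float = 2.0                # additive, in output (8-bit-like) units
    gain: float = 180.0                  # pseudo intensity 1.0 -> this output value
    transform: AffineTransform = field(default_factory=AffineTransform.identity)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shadow_factor <= 1.0):
            raise ValueError("shadow_factor must lie in [0, 1]")
        if self.attenuation_per_mm < 0 or self.speckle_sigma < 0 or self.noise_sd < 0:
            raise ValueError("artefact magnitudes must be non-negative")


def cone_mask(grid: VolumeGrid, apex_mm, axis, half_angle_deg: float) -> np.ndarray:
    """Voxels inside the cone with the given apex, axis and half-angle."""
    if half_angle_deg <= 0:
        return np.zeros(grid.shape, dtype=bool)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    x, y, z = grid.coordinate_grids()
    dx, dy, dz = x - apex_mm[0], y - apex_mm[1], z - apex_mm[2]
    along = dx * ax[0] + dy * ax[1] + dz * ax[2]
    norm = np.sqrt(dx**2 + dy**2 + dz**2)
    cosang = np.divide(along, norm, out=np.ones_like(norm), where=norm > 0)
    return cosang >= np.cos(np.deg2rad(half_angle_deg))


def shadow_half_angle_for_fraction(
    mask: np.ndarray, grid: VolumeGrid, apex_mm, axis, fraction: float, tol: float = 0.005
) -> float:
    """Half-angle whose cone occludes the requested fraction of ``mask``."""
    total = int(np.count_nonzero(mask))
    if total == 0:
        raise ValueError("empty mask")
    lo, hi = 0.0, 90.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        frac = np.count_nonzero(cone_mask(grid, apex_mm, axis, mid) & mask) / total
        if abs(frac - fraction) <= tol:
            return mid
        if frac < fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_us(
    pseudo: ScalarVolume,
    art: UsArtifactSpec | None = None,
    out_grid: VolumeGrid | None = None,
) -> tuple[ScalarVolume, AffineTransform]:
    """Simulated ultrasound from a pseudo-US image under a known transform.

    The ground-truth transform maps pseudo (source) world coordinates to
    ultrasound (target) world coordinates; the returned volume lives on
    ``out_grid`` (default: the pseudo grid).
    """
    art = art or UsArtifactSpec()
    grid = out_grid or pseudo.grid
    rng = np.random.default_rng(art.seed)
    moved = resample_volume(pseudo, art.transform.inverse(), grid, "linear")
    vals = moved.values * art.gain

    ax = np.asarray(art.axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    x, y, z = grid.coordinate_grids()
    depth = (x - art.apex_mm[0]) * ax[0] + (y - art.apex_mm[1]) * ax[1] + (z - art.apex_mm[2]) * ax[2]
    vals = vals * np.exp(-art.attenuation_per_mm * np.clip(depth, 0.0, None))
    if art.shadow_half_angle_deg > 0:
        shadow = cone_mask(grid, art.apex_mm, art.axis, art.shadow_half_angle_deg)
        vals = np.where(shadow, vals * art.shadow_factor, vals)
    if art.speckle_sigma > 0:
        vals = vals * np.exp(rng.normal(-0.5 * art.speckle_sigma**2, art.speckle_sigma, grid.shape))
    if art.noise_sd > 0:
        vals = vals + rng.normal(0.0, art.noise_sd, grid.shape)
    return ScalarVolume(grid, vals), art.transform


# ---------------------------------------------------------------------------
# thick-slice MR stacks


def simulate_stacks(
    volume: ScalarVolume,
    psf: PSFModel,
    n_stacks: int = 3,
    corrupt_fraction: float = 0.0,
    seed: int = 0,
    in_plane_resolution: float = 1.2,
    slice_thickness: float = 2.5,
) -> tuple[list[SliceStack], list[np.ndarray]]:
    """Orthogonal-orientation thick-slice stacks sampled from a volume.

    Slices are simulated through the PSF; ``corrupt_fraction`` of the slices
    in each stack (rounded) get their intensities scrambled to emulate motion
    corruption.  Returns the stacks and per-stack boolean corruption masks.
    """
    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    if not (0.0 <= corrupt_fraction < 1.0):
        raise ValueError("corrupt_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    grid = volume.grid
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    # slice-normal axis cycles through z, y, x
    normals = [2, 1, 0]
    stacks: list[SliceStack] = []
    masks: list[np.ndarray] = []
    for s in range(n_stacks):
        nrm = normals[s % 3]
        inplane = [a for a in range(3) if a != nrm]
        n_slices = int(np.floor((hi[nrm] - lo[nrm]) / slice_thickness)) + 1
        shape2 = tuple(int(np.floor((hi[a] - lo[a]) / in_plane_resolution)) + 1 for a in inplane)
        slices, poses = [], []
        for k in range(n_slices):
            m = np.zeros((4, 4))
            m[3, 3] = 1.0
            m[inplane[0], 0] = 1.0
            m[inplane[1], 1] = 1.0
            m[nrm, 2] = 1.0
            m[:3, 3] = lo
            m[nrm, 3] = lo[nrm] + k * slice_thickness
            poses.append(AffineTransform(m))
            slices.append(np.zeros(shape2))
        stack = SliceStack(slices, poses, in_plane_resolution, slice_thickness, stack_id=f"stack{s}")
        stack.slices = simulate_slices(volume, stack, psf)
        corrupted = np.zeros(n_slices, dtype=bool)
        n_bad = int(round(corrupt_fraction * n_slices))
        if n_bad:
            bad = rng.choice(n_slices, size=n_bad, replace=False)
            corrupted[bad] = True
            for k in np.flatnonzero(corrupted):
                flat = stack.slices[k].ravel()
                stack.slices[k] = rng.permutation(flat).reshape(stack.slices[k].shape)
        stacks.append(stack)
        masks.append(corrupted)
    return stacks, masks
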