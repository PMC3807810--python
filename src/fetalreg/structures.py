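"""From tissue posteriors to the ultrasound-visible structure map.

Fetal ultrasound shows the brain split into left/right halves by the strongly
echogenic falx, surrounded by the bright skull, with the choroid plexus,
septum pellucidum, cerebellum and deep grey matter as the dominant internal
landmarks.  This module converts an EM tissue segmentation (plus manually
delineated auxiliary labels) into that inventory:

* the WM segmentation is eroded (voxels closer than 1.5 mm to the WM surface
  removed) to produce two hemisphere "cores"; smoothed distance maps from the
  cores assign every brain voxel to a side, and the equidistant locus becomes
  the midline/falx;
* the skull is a shell of configurable thickness (default 2 mm) around the
  brain+CSF mask; the brain surface is a thin echogenic layer just inside it;
* WM and cortex are merged per side into "cortical hemispheres" (their
  boundary is invisible in ultrasound); the cerebellum is homogeneous for
  older fetuses, while for younger ones a separately provided cerebellar WM
  label is kept as its own (darker) class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imagecore import LabelVolume, ScalarVolume, VolumeGrid, GridMismatchError, distance_map

# canonical structure label scheme, shared by synthetic phantoms and pipelines
STRUCTURE_LABELS: dict[int, str] = {
    0: "background",
    1: "cortical_hemisphere_L",
    2: "cortical_hemisphere_R",
    3: "dgm",
    4: "brainstem",
    5: "cerebellum",
    6: "cerebellar_wm",
    7: "csf",
    8: "skull",
    9: "choroid_plexus",
    10: "septum_pellucidum",
    11: "midline_falx",
    12: "brain_surface",
}
NAME_TO_LABEL = {v: k for k, v in STRUCTURE_LABELS.items()}

# on overlap, higher-priority structures win (first entry wins over all others)
PRECEDENCE = [
    "skull",
    "choroid_plexus",
    "septum_pellucidum",
    "midline_falx",
    "brain_surface",
    "cerebellum",
    "cerebellar_wm",
    "dgm",
    "brainstem",
    "cortical_hemisphere_L",
    "cortical_hemisphere_R",
    "csf",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class HemisphereField:
    """Regularised distances (mm) from the left/right WM cores."""

    grid: VolumeGrid
    d_left: np.ndarray
    d_right: np.ndarray
    core_left: np.ndarray
    core_right: np.ndarray


def split_hemispheres(
    wm_mask: np.ndarray,
    brain_mask: np.ndarray,
    grid: VolumeGrid,
    erosion_mm: float = 1.5,
    reg_sigma_mm: float = 10.0,
    midline_tol_mm: float | None = None,
) -> tuple[HemisphereField, np.ndarray, np.ndarray]:
    """Split the brain into left/right by distance to eroded WM cores.

    Returns the hemisphere distance field, the midline mask (voxels within
    ``midline_tol_mm`` — default one voxel size — of equidistance) and a side
    map (0 none / 1 left / 2 right) over ``brain_mask``.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if midline_tol_mm is None:
        midline_tol_mm = float(max(grid.spacing))
    if not wm_mask.any():
        raise ValueError("WM mask is empty")
    # depth inside WM: distance to the WM surface (i.e. to the complement)
    depth = ndimage.distance_transform_edt(wm_mask, sampling=grid.spacing)
    cores = depth >= erosion_mm
    lab, n = ndimage.label(cores, structure=_CONN26)
    if n < 2:
        raise ValueError(
            f"found {n} WM core component(s) after removing voxels closer than "
            f"{erosion_mm} mm to the WM surface; try a smaller erosion distance"
        )
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    top2 = np.argsort(sizes)[::-1][:2] + 1
    core_a, core_b = (lab == top2[0]), (lab == top2[1])
    # left = smaller centroid x-coordinate (deterministic tie-break)
    cx_a = ndimage.center_of_mass(core_a)[0]
    cx_b = ndimage.center_of_mass(core_b)[0]
    core_left, core_right = (core_a, core_b) if cx_a <= cx_b else (core_b, core_a)

    sigma_vox = [reg_sigma_mm / s for s in grid.spacing]
    d_l = ndimage.gaussian_filter(
        ndimage.distance_transform_edt(~core_left, sampling=grid.spacing), sigma_vox, mode="nearest"
    )
    d_r = ndimage.gaussian_filter(
        ndimage.distance_transform_edt(~core_right, sampling=grid.spacing), sigma_vox, mode="nearest"
    )
    midline = brain_mask & (np.abs(d_l - d_r) <= midline_tol_mm)
    side = np.zeros(grid.shape, dtype=np.int8)
    side[brain_mask & (d_l < d_r)] = 1
    side[brain_mask & (d_r < d_l)] = 2
    side[brain_mask & (d_l == d_r)] = 1  # exact ties (midline anyway) default left
    field = HemisphereField(grid, d_l, d_r, core_left, core_right)
    return field, midline, side


def estimate_skull_shell(brain_mask: np.ndarray, grid: VolumeGrid, thickness_mm: float = 2.0) -> np.ndarray:
    """Shell of voxels outside the brain mask within ``thickness_mm`` of it."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be positive")
    d = distance_map(brain_mask, grid).values
    return (d > 0) & (d <= thickness_mm)


def extract_brain_surface(brain_mask: np.ndarray, grid: VolumeGrid, layer_mm: float = 0.66) -> np.ndarray:
    """Thin echogenic layer: mask voxels within ``layer_mm`` of the exterior."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if layer_mm <= 0:
        raise ValueError("layer_mm must be positive")
    if brain_mask.all():
        # no exterior: the layer degenerates to the faces of the volume
        surface = np.zeros(grid.shape, dtype=bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            sl[ax] = 0
            surface[tuple(sl)] = True
            sl[ax] = -1
            surface[tuple(sl)] = True
        return surface
    d_in = ndimage.distance_transform_edt(brain_mask, sampling=grid.spacing)
    return brain_mask & (d_in <= layer_mm)


def build_structure_map(
    em_labels: LabelVolume,
    skull: np.ndarray,
    surface: np.ndarray,
    midline: np.ndarray,
    side: np.ndarray,
    aux_labels: dict[str, np.ndarray] | None = None,
    ga_mode: str = "young",
) -> LabelVolume:
    """Assemble the final structure map with a fixed overlap precedence.

    ``em_labels`` must use structure names from :data:`STRUCTURE_LABELS` (with
    WM/cortex already expressed as per-voxel tissue classes named ``wm`` /
    ``cortex`` or as hemispheres); ``side`` assigns WM/cortex voxels to L/R.
    ``aux_labels`` may carry ``choroid_plexus``, ``septum_pellucidum`` and
    (young mode) ``cerebellar_wm`` masks.
    """
    if ga_mode not in ("young", "old"):
        raise ValueError("ga_mode must be 'young' or 'old'")
    aux = dict(aux_labels or {})
    grid = em_labels.grid
    for name, m in aux.items():
        if np.asarray(m).shape != grid.shape:
            raise GridMismatchError(f"aux label {name!r} is not on the EM grid")
    for name, m in (("skull", skull), ("surface", surface), ("midline", midline)):
        if np.asarray(m).shape != grid.shape:
            raise GridMismatchError(f"{name} mask is not on the EM grid")

    names = em_labels.scheme
    def em_mask(*want):
        ids = [k for k, v in names.items() if v in want]
        return np.isin(em_labels.labels, ids)

    hemis = em_mask("wm", "cortex", "cortical_hemisphere_L", "cortical_hemisphere_R")
    masks: dict[str, np.ndarray] = {
        "cortical_hemisphere_L": hemis & (side == 1),
        "cortical_hemisphere_R": hemis & (side == 2),
        "dgm": em_mask("dgm"),
        "brainstem": em_mask("brainstem"),
        "csf": em_mask("csf"),
        "skull": np.asarray(skull, dtype=bool),
        "brain_surface": np.asarray(surface, dtype=bool),
        "midline_falx": np.asarray(midline, dtype=bool),
        "choroid_plexus": np.asarray(aux.get("choroid_plexus", np.zeros(grid.shape, bool)), dtype=bool),
        "septum_pellucidum": np.asarray(aux.get("septum_pellucidum", np.zeros(grid.shape, bool)), dtype=bool),
    }
    cereb = em_mask("cerebellum")
    cereb_wm = np.asarray(aux.get("cerebellar_wm", np.zeros(grid.shape, bool)), dtype=bool)
    if ga_mode == "old":
        if cereb_wm.any():
            warnings.warn("old-mode structure map: cerebellar_wm label ignored (cerebellum kept homogeneous)")
        masks["cerebellum"] = cereb | cereb_wm
        masks["cerebellar_wm"] = np.zeros(grid.shape, bool)
    else:
        if not cereb_wm.any() and cereb.any():
            warnings.warn("young mode without a cerebellar_wm label: falling back to homogeneous cerebellum")
        masks["cerebellum"] = cereb & ~cereb_wm
        masks["cerebellar_wm"] = cereb_wm

    out = np.zeros(grid.shape, dtype=np.int32)
    # iterate lowest precedence first so later (higher-priority) writes win
    for name in reversed(PRECEDENCE):
        out[masks[name]] = NAME_TO_LABEL[name]
    return LabelVolume(grid, out, dict(STRUCTURE_LABELS))


def structure_map_from_em(
    em_labels: LabelVolume,
    aux_labels: dict[str, np.ndarray] | None = None,
    ga_mode: str = "young",
    erosion_mm: float = 1.5,
    skull_thickness_mm: float = 2.0,
    surface_layer_mm: float | None = None,
) -> LabelVolume:
    """Convenience wrapper chaining hemisphere split, skull, surface and merge.

    The brain-surface layer defaults to two voxels of the input grid (0.66 mm
    on the reference 0.33 mm template grid).
    """
    grid = em_labels.grid
    if surface_layer_mm is None:
        surface_layer_mm = 2.0 * max(grid.spacing)
    wm = em_labels.mask("wm") if "wm" in em_labels.scheme.values() else em_labels.mask(
        "cortical_hemisphere_L", "cortical_hemisphere_R"
    )
    tissue_names = [v for v in em_labels.scheme.values() if v not in ("background",)]
    brain = em_labels.mask(*tissue_names)
    _, midline, side = split_hemispheres(wm, brain, grid, erosion_mm=erosion_mm)
    skull = estimate_skull_shell(brain, grid, skull_thickness_mm)
    brain_tissue = brain & ~em_labels.mask("csf") if "csf" in em_labels.scheme.values() else brain
    surface = extract_brain_surface(brain_tissue, grid, surface_layer_mm)
    return build_structure_map(em_labels, skull, surface, midline, side, aux_labels, ga_mode)
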