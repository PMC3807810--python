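"""Reproducible phantom studies exercising the full pipeline.

Each function generates its own synthetic inputs from a seed, runs one
component (or the whole chain) under the package's standard study
conditions, and returns plain-float summary statistics.  The test suite and
the acceptance script both drive these functions, so the numbers reported by
either are recomputed from scratch on every run.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .blockmatch import (
    DisplacementField,
    MatchSettings,
    exhaustive_match_oracle,
    lts_estimate,
    match_blocks,
    register,
)
from .em_segmentation import AtlasPriors, EmSettings, segment_em
from .evaluation import LandmarkSet, barycentre_distance, dice_overlap, mean_tre
from .imagecore import AffineTransform, ScalarVolume, VolumeGrid, max_corner_displacement, max_euler_rotation
from .pseudous import EchogenicityTable, assign_pseudo_intensities, preprocess_us
from .superres import SuperresSettings, make_psf, reconstruct
from .synthetic import (
    PhantomSpec,
    UsArtifactSpec,
    make_label_phantom,
    shadow_half_angle_for_fraction,
    simulate_stacks,
    simulate_us,
)

PROBE_APEX = (0.0, 0.0, 55.0)
PROBE_AXIS = (0.0, 0.0, -1.0)


def _standard_phantom():
    spec = PhantomSpec()
    smap = make_label_phantom(spec)
    pseudo = assign_pseudo_intensities(smap)
    brain = smap.labels > 0
    half_angle = shadow_half_angle_for_fraction(brain, smap.grid, PROBE_APEX, PROBE_AXIS, 0.2)
    return spec, smap, pseudo, brain, half_angle


def _padded_grid(grid: VolumeGrid, pad_vox: int = 12) -> VolumeGrid:
    return VolumeGrid(
        tuple(s + 2 * pad_vox for s in grid.shape),
        grid.spacing,
        tuple(o - pad_vox * sp for o, sp in zip(grid.origin, grid.spacing)),
    )


def _random_rigid(rng, max_rot_deg=30.0, max_shift_mm=4.0) -> tuple[AffineTransform, float]:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_rot_deg)
    m = np.eye(4)
    m[:3, :3] = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
    m[:3, 3] = rng.uniform(-max_shift_mm, max_shift_mm, 3)
    return AffineTransform(m), float(angle)


def _mean_displacement(t_est, t_true, mask, grid, stride=7) -> float:
    pts = grid.index_to_world(np.argwhere(mask)[::stride])
    return float(np.linalg.norm(t_est.apply(pts) - t_true.apply(pts), axis=1).mean())


def transform_recovery(seed: int = 0, n_cases: int = 10) -> dict:
    """Register the phantom pseudo-US to simulated US under random rigid
    transforms with rotations up to 30 degrees, speckle, attenuation and a
    shadow cone occluding 20% of the brain."""
    _, smap, pseudo, brain, half_angle = _standard_phantom()
    us_grid = _padded_grid(smap.grid)
    errors = []
    angles = []
    for case in range(n_cases):
        rng = np.random.default_rng([seed, case])
        truth, angle = _random_rigid(rng)
        art = UsArtifactSpec(
            transform=truth,
            shadow_half_angle_deg=half_angle,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        us, _ = simulate_us(pseudo, art, out_grid=us_grid)
        us_sm, _ = preprocess_us(us)
        t_est, diag = register(pseudo, us_sm)
        errors.append(_mean_displacement(t_est, truth, brain, smap.grid))
        angles.append(angle)
    errors = np.asarray(errors)
    return {
        "errors_mm": errors.tolist(),
        "rotations_deg": angles,
        "n_success": int((errors < 1.0).sum()),
        "n_cases": n_cases,
        "mean_error_mm": float(errors.mean()),
        "median_error_mm": float(np.median(errors)),
    }


def lts_robustness(seed: int = 0, n: int = 200, outlier_frac: float = 0.2) -> dict:
    """Exact affine recovery from a noiseless displacement field with gross
    outliers; ordinary least squares (h=1) breaks where LTS does not."""
    rng = np.random.default_rng(seed)
    true_t = AffineTransform(np.array([
        [1.05, 0.02, -0.01, 2.0],
        [-0.03, 0.98, 0.02, -1.0],
        [0.01, -0.02, 1.02, 3.0],
        [0.0, 0.0, 0.0, 1.0],
    ]))
    p = rng.uniform(-30, 30, (n, 3))
    d = true_t.apply(p) - p
    n_out = int(round(outlier_frac * n))
    idx = rng.choice(n, n_out, replace=False)
    d[idx] += rng.uniform(20.0, 40.0, (n_out, 3)) * rng.choice([-1.0, 1.0], (n_out, 3))
    field = DisplacementField(p, d, np.ones(n))
    err075 = float(np.abs(lts_estimate(field, "affine", 0.75).matrix - true_t.matrix).max())
    err100 = float(np.abs(lts_estimate(field, "affine", 1.0).matrix - true_t.matrix).max())
    return {
        "h075_max_abs_error": err075,
        "h100_max_abs_error": err100,
        "h100_over_h075": err100 / max(err075, 1e-300),
    }


def _three_class_phantom(grid, means, sds, seed, bias_amp):
    x, y, z = grid.coordinate_grids()
    lab = np.zeros(grid.shape, dtype=np.int32)
    lab[(x / 28) ** 2 + (y / 26) ** 2 + (z / 24) ** 2 <= 1] = 1
    lab[(x / 18) ** 2 + (y / 16) ** 2 + (z / 15) ** 2 <= 1] = 2
    lab[(x / 9) ** 2 + ((y - 3) / 8) ** 2 + (z / 7) ** 2 <= 1] = 3
    rng = np.random.default_rng(seed)
    img = np.asarray(means)[lab] + rng.normal(0.0, 1.0, grid.shape) * np.asarray(sds)[lab]
    gfield = np.zeros(grid.shape)
    if bias_amp:
        u, v, w = x / 32, y / 32, z / 32
        gfield = 0.6 * u + 0.3 * v * w - 0.5 * (w**2 - 1 / 3)
        gfield *= bias_amp / np.abs(gfield).max()
        img = np.clip(img, 1.0, None) * np.exp(gfield)
    probs = np.stack([(lab == k).astype(float) for k in range(4)])
    probs = np.stack([ndimage.gaussian_filter(p, 2.0) for p in probs])
    probs /= probs.sum(axis=0)
    return lab, np.clip(img, 0.5, None), AtlasPriors(grid, probs), gfield


def em_recovery(seed: int = 0, snr: float = 10.0, bias_amp: float = 0.2) -> dict:
    """Segment a 3-class 64^3 phantom at SNR 10 under a 0.2-amplitude
    multiplicative bias; report off-boundary label accuracy, gauge-corrected
    class-mean error and bias-field RMS error."""
    grid = VolumeGrid((64, 64, 64), (1.0, 1.0, 1.0), (-31.5, -31.5, -31.5))
    means = np.array([10.0, 40.0, 70.0, 100.0])
    rng_range = 90.0
    sd = rng_range / snr
    lab, img, priors, g = _three_class_phantom(grid, means, [sd] * 4, seed, bias_amp)
    res = segment_em(ScalarVolume(grid, img), priors, EmSettings(sigma_bias_mm=20.0, max_iter=15))
    bnd = np.zeros(grid.shape, bool)
    for k in np.unique(lab):
        m = lab == k
        bnd |= m & ~ndimage.binary_erosion(m)
    interior = ~bnd
    acc = float((res.labels.labels[interior] == lab[interior]).mean())
    mask = priors.brain_mask()
    # the model fixes mean(log-bias)=0 over the mask; compare in that gauge
    gauge = float(np.exp(g[mask].mean()))
    mean_err = float(np.abs(res.params.means[1:] / gauge - means[1:]).max())
    resid = res.bias.log_bias[mask] - g[mask]
    resid -= resid.mean()
    bias_rms = float(np.sqrt((resid**2).mean()))
    return {
        "label_accuracy": acc,
        "mean_error_frac_of_range": mean_err / rng_range,
        "bias_rms_error": bias_rms,
        "converged": bool(res.converged),
    }


def block_search_oracle(seed: int = 0) -> dict:
    """Compiled block search vs the plain-python exhaustive oracle on an
    integer-translated texture: every chosen displacement must agree."""
    rng = np.random.default_rng(seed)
    shape = (28, 28, 28)
    vals = ndimage.gaussian_filter(rng.normal(size=shape), 1.0) * 40.0 + 100.0
    grid = VolumeGrid(shape, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    src = ScalarVolume(grid, vals)
    tgt = ScalarVolume(grid, np.roll(vals, (3, -2, 1), (0, 1, 2)))
    s = MatchSettings(block_step=3)
    fast = match_blocks(src, tgt, AffineTransform.identity(), s, 0.5)
    slow = exhaustive_match_oracle(src, tgt, AffineTransform.identity(), s, 0.5)
    same_pts = len(fast) == len(slow) and np.allclose(fast.points, slow.points)
    agree = same_pts and np.array_equal(fast.displacements, slow.displacements)
    frac = 0.0
    if same_pts:
        frac = float((np.all(fast.displacements == slow.displacements, axis=1)).mean())
    return {"n_blocks": int(len(fast)), "all_agree": bool(agree), "agreement_fraction": frac}


def _superres_truth(grid):
    x, y, z = grid.coordinate_grids()
    vals = 50.0 * np.exp(-(((x + 6) / 14) ** 2 + (y / 12) ** 2 + (z / 10) ** 2))
    vals += 30.0 * np.exp(-(((x - 10) / 8) ** 2 + ((y - 5) / 9) ** 2 + ((z + 4) / 8) ** 2))
    vals += 20.0 * np.cos(x / 6) * np.sin(y / 7)
    return ScalarVolume(grid, vals)


def superres_sanity(seed: int = 0, corrupt_fraction: float = 0.2) -> dict:
    """Reconstruct a 64^3 phantom from 3 orthogonal simulated stacks, clean
    and with a fraction of slices scrambled; report RMSE and weight split."""
    grid = VolumeGrid((64, 64, 64), (1.0, 1.0, 1.0), (-31.5, -31.5, -31.5))
    vol = _superres_truth(grid)
    psf = make_psf(slice_thickness=2.5, in_plane_res=1.2, recon_spacing=1.0)
    rng_range = float(np.ptp(vol.values))
    out = {}
    for tag, cf in (("clean", 0.0), ("corrupt", corrupt_fraction)):
        stacks, masks = simulate_stacks(vol, psf, 3, cf, seed=seed)
        state = reconstruct(stacks, psf, grid, SuperresSettings())
        rmse = float(np.sqrt(((state.volume.values - vol.values) ** 2).mean()) / rng_range)
        out[f"rmse_{tag}_frac"] = rmse
        if cf > 0:
            bad_w, good_w = [], []
            for sw, m in zip(state.slice_weights, masks):
                bad_w += list(np.asarray(sw)[m])
                good_w += list(np.asarray(sw)[~m])
            out["corrupt_slice_mean_weight"] = float(np.mean(bad_w))
            out["inlier_slice_mean_weight"] = float(np.mean(good_w))
    out["corrupt_over_clean_rmse"] = out["rmse_corrupt_frac"] / out["rmse_clean_frac"]
    return out


def metric_hand_values() -> dict:
    """The evaluation metrics on constructed cases with hand-computed answers."""
    g = VolumeGrid((20, 20, 20))
    a = np.zeros(g.shape, bool)
    b = np.zeros(g.shape, bool)
    a.flat[:100] = True
    b.flat[60:120] = True
    dice = dice_overlap(a, b)  # 2*40/(100+60)
    m1 = np.zeros(g.shape, bool)
    m2 = np.zeros(g.shape, bool)
    m1[2:5, 2:5, 2:5] = True
    m2[5:8, 6:9, 2:5] = True  # (3, 4, 0) voxel shift on a 1 mm grid
    bary = barycentre_distance(m1, g, m2, g)
    fixed = LandmarkSet({"a": (0, 0, 0), "b": (0, 0, 0), "c": (0, 0, 0)})
    moving = LandmarkSet({"a": (1, 0, 0), "b": (0, 2, 0), "c": (0, 0, 3)})
    tre = mean_tre(fixed, moving)
    rot = max_euler_rotation(
        AffineTransform(AffineTransform.from_rigid(euler_deg=(0.0, 30.0, 0.0)).matrix
                        @ np.diag([1.1, 1.1, 1.1, 1.0]))
    )
    return {"dice": dice, "barycentre_mm": bary, "mtre_mm": tre, "max_euler_deg": rot}


def echogenicity_remap(seed: int = 0, gamma: float = 2.0) -> dict:
    """Register the standard phantom twice — default echogenicity table vs a
    strictly increasing remap (gamma curve) — and compare the transforms."""
    _, smap, pseudo, brain, half_angle = _standard_phantom()
    us_grid = _padded_grid(smap.grid)
    rng = np.random.default_rng([seed, 77])
    truth, _ = _random_rigid(rng, max_rot_deg=15.0)
    art = UsArtifactSpec(transform=truth, shadow_half_angle_deg=half_angle,
                         seed=int(rng.integers(0, 2**31 - 1)))
    us, _ = simulate_us(pseudo, art, out_grid=us_grid)
    us_sm, _ = preprocess_us(us)
    t1, _ = register(pseudo, us_sm)
    remapped = EchogenicityTable().remapped(lambda v: v**gamma)
    pseudo2 = assign_pseudo_intensities(smap, remapped)
    t2, _ = register(pseudo2, us_sm)
    return {
        "corner_displacement_mm": max_corner_displacement(t1, t2, smap.grid),
        "error_default_mm": _mean_displacement(t1, truth, brain, smap.grid),
        "error_remapped_mm": _mean_displacement(t2, truth, brain, smap.grid),
    }
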