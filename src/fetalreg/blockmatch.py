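"""Robust block-matching registration with least-trimmed-squares estimation.

The alignment between a pseudo-ultrasound source and a real (or simulated)
ultrasound target is estimated by alternating two steps at each resolution
level:

1. *matching* — for every source block with non-zero variance, exhaustively
   search integer-voxel offsets within a cubic neighbourhood around the
   current-transform-mapped centroid in the target, scoring candidates by NCC
   (or its square, equivalent to the correlation ratio under a local affine
   intensity model).  Target blocks whose variance falls below a threshold
   (a fraction of the target intensity range) are skipped — they carry no
   feature to match;
2. *estimation* — fit a rigid or affine update to the displacement field by
   least trimmed squares (LTS): iterate fitting on the current inlier set and
   re-selecting the ``ceil(h * n)`` correspondences with the smallest squared
   residuals (C-steps), which discards displacements from blocks whose true
   counterpart is missing (shadowed or attenuated away in the ultrasound).

Matching is run at a coarse-to-fine pyramid (default 2 mm then 1 mm isotropic)
with a rigid stage followed by an affine stage at each level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from numba import njit

from .imagecore import (
    AffineTransform,
    ScalarVolume,
    VolumeGrid,
    gaussian_smooth,
    max_corner_displacement,
    resample_volume,
)


class MatchFailure(RuntimeError):
    """No usable block correspondences could be produced."""


@dataclass
class MatchSettings:
    block_radius: int = 1                 # 3x3x3 blocks
    search_radius: int = 7                # voxels, per direction
    block_step: int = 2
    variance_threshold_factor: float = 0.04   # fraction of target intensity range
    source_variance_floor: float = 1e-3       # "non-zero variance" for float data:
                                              # var > floor * (source range)^2
    lts_fraction: float = 0.75
    levels: tuple[float, ...] = (2.0, 1.0)    # isotropic mm, strictly decreasing
    models: tuple[str, ...] = ("rigid", "affine")
    similarity: str = "ncc"               # "ncc" or "cr"
    max_iterations: int = 20              # outer iterations per level/stage
    tolerance_mm: float = 0.5             # corner-displacement convergence

    def __post_init__(self) -> None:
        if self.block_radius < 1:
            raise ValueError("block_radius must be >= 1")
        if self.search_radius < 0:
            raise ValueError("search_radius must be >= 0")
        if not (0.0 < self.lts_fraction <= 1.0):
            raise ValueError("lts_fraction must lie in (0, 1]")
        if any(b >= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly decreasing")
        if self.similarity not in ("ncc", "cr"):
            raise ValueError("similarity must be 'ncc' or 'cr'")
        for m in self.models:
            if m not in ("rigid", "affine"):
                raise ValueError(f"unknown model {m!r}")


@dataclass
class DisplacementField:
    """Correspondences feeding the LTS estimator.

    ``points`` are source-block centroids mapped through the current transform
    (world mm, target space); ``displacements`` take them to the matched
    target-block centroids; ``similarities`` are the winning NCC (or CR).
    """

    points: np.ndarray         # (N, 3)
    displacements: np.ndarray  # (N, 3)
    similarities: np.ndarray   # (N,)

    def __len__(self) -> int:
        return len(self.points)


def ncc_similarity(a: np.ndarray, b: np.ndarray, similarity: str = "ncc") -> float:
    """Pearson correlation of two flattened blocks; ``cr`` returns its square."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("blocks must have equal size")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero-variance block passed to ncc_similarity; filter blocks first")
    r = float(da @ db) / math.sqrt(va * vb)
    return r * r if similarity == "cr" else r


def _block_lattice(shape: tuple[int, int, int], radius: int, step: int) -> np.ndarray:
    """Regular lattice of block-centre indices with blocks fully inside."""
    axes = []
    for n in shape:
        if n < 2 * radius + 1:
            return np.empty((0, 3), dtype=np.int64)
        axes.append(np.arange(radius, n - radius, step))
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1).astype(np.int64)


def select_source_blocks(
    img: ScalarVolume, settings: MatchSettings, side: str = "source"
) -> tuple[np.ndarray, float]:
    """Block centres surviving the variance rule for one side.

    Returns (centres, variance_threshold).  The source (pseudo-US) side keeps
    blocks with non-zero variance — read for floating-point data as variance
    above ``source_variance_floor * range^2``, so that blocks carrying only
    interpolation tails of the piecewise-constant image do not qualify as
    features.  The target side uses ``variance_threshold_factor * intensity
    range`` (variance, not sd, scaled by the range, matching the block
    exclusion rule used on clinical ultrasound).
    """
    if side not in ("source", "target_threshold"):
        raise ValueError("side must be 'source' or 'target_threshold'")
    r = settings.block_radius
    centres = _block_lattice(img.grid.shape, r, settings.block_step)
    if centres.size == 0:
        raise MatchFailure("image too small for the requested block size")
    rng = float(np.ptp(img.values))
    if side == "target_threshold":
        thresh = settings.variance_threshold_factor * rng
    else:
        thresh = settings.source_variance_floor * rng * rng
    nvox = (2 * r + 1) ** 3
    s1, s2 = _box_sums(img.values, r)
    var = (s2 - s1 * s1 / nvox) / nvox
    keep = var[tuple(centres.T)] > thresh
    centres = centres[keep]
    if len(centres) == 0:
        raise MatchFailure("no blocks survive the variance rule")
    return centres, thresh


def _sorted_offsets(radius: int) -> np.ndarray:
    """Search offsets ordered so that first-strictly-better wins implements the
    tie rule: smaller Euclidean offset first, then lexicographic."""
    rng = np.arange(-radius, radius + 1)
    offs = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], (offs**2).sum(axis=1)))
    return offs[order].astype(np.int64)


def _box_sums(vol: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum and sum-of-squares of the (2r+1)^3 block around every voxel.

    Values are exact for all centres at least ``radius`` from the border (the
    only ones the search visits)."""
    from scipy.ndimage import uniform_filter

    w = 2 * radius + 1
    n = w**3
    s1 = uniform_filter(vol, w, mode="constant") * n
    s2 = uniform_filter(vol * vol, w, mode="constant") * n
    return s1, s2


@njit(cache=True, fastmath=True)
def _match_kernel(src, tgt, tsum, tsumsq, src_centres, tgt_bases, offsets, radius, var_thresh, use_cr):  # pragma: no cover
    n = src_centres.shape[0]
    m = offsets.shape[0]
    w = 2 * radius + 1
    nvox = w * w * w
    best_idx = np.full(n, -1, dtype=np.int64)
    best_sim = np.full(n, -2.0)
    sx, sy, sz = tgt.shape
    max_off = 0
    for o in range(m):
        for a in range(3):
            if abs(offsets[o, a]) > max_off:
                max_off = abs(offsets[o, a])
    pw = 2 * (radius + max_off) + 1
    patch = np.empty(pw * pw * pw, dtype=np.float32)
    sblk = np.empty(nvox, dtype=np.float32)
    # flat within-patch strides of the w^3 block footprint
    stencil = np.empty(nvox, dtype=np.int64)
    q = 0
    for di in range(w):
        for dj in range(w):
            for dk in range(w):
                stencil[q] = di * pw * pw + dj * pw + dk
                q += 1
    for b in range(n):
        ci, cj, ck = src_centres[b, 0], src_centres[b, 1], src_centres[b, 2]
        # hoist the source block; its statistics are shared by all offsets
        ssum = 0.0
        ssum2 = 0.0
        q = 0
        for di in range(w):
            for dj in range(w):
                for dk in range(w):
                    v = src[ci + di - radius, cj + dj - radius, ck + dk - radius]
                    sblk[q] = v
                    q += 1
                    ssum += v
                    ssum2 += v * v
        svar = ssum2 - ssum * ssum / nvox
        if svar <= 0.0:
            continue
        bi, bj, bk = tgt_bases[b, 0], tgt_bases[b, 1], tgt_bases[b, 2]
        # copy the search patch into a contiguous local buffer (cache friendly)
        lo_i = bi - radius - max_off
        lo_j = bj - radius - max_off
        lo_k = bk - radius - max_off
        q = 0
        for pi in range(pw):
            gi = lo_i + pi
            inside_i = 0 <= gi < sx
            for pj in range(pw):
                gj = lo_j + pj
                inside_ij = inside_i and 0 <= gj < sy
                for pk in range(pw):
                    gk = lo_k + pk
                    patch[q] = tgt[gi, gj, gk] if (inside_ij and 0 <= gk < sz) else 0.0
                    q += 1
        for o in range(m):
            ti = bi + offsets[o, 0]
            tj = bj + offsets[o, 1]
            tk = bk + offsets[o, 2]
            if ti - radius < 0 or tj - radius < 0 or tk - radius < 0:
                continue
            if ti + radius >= sx or tj + radius >= sy or tk + radius >= sz:
                continue
            ts = tsum[ti, tj, tk]
            tvar = tsumsq[ti, tj, tk] - ts * ts / nvox
            if tvar / nvox <= var_thresh or tvar <= 0.0:
                continue
            base = (
                (ti - lo_i - radius) * pw * pw
                + (tj - lo_j - radius) * pw
                + (tk - lo_k - radius)
            )
            cross = 0.0
            for q in range(nvox):
                cross += sblk[q] * patch[base + stencil[q]]
            num = cross - ssum * ts / nvox
            ncc = num / math.sqrt(svar * tvar)
            sim = ncc * ncc if use_cr else ncc
            if sim > best_sim[b]:
                best_sim[b] = sim
                best_idx[b] = o
    return best_idx, best_sim


def match_blocks(
    source: ScalarVolume,
    target: ScalarVolume,
    current_t: AffineTransform,
    settings: MatchSettings,
    target_var_threshold: float | None = None,
) -> DisplacementField:
    """Exhaustive integer-offset block search around the mapped centroids.

    The source is warped through the current transform onto the target grid
    first, so block contents are compared in a common orientation; each
    non-zero-variance warped block then searches its cubic neighbourhood in
    the target.  Field points are the mapped centroids in target-space world
    coordinates.
    """
    if target_var_threshold is None:
        target_var_threshold = settings.variance_threshold_factor * float(np.ptp(target.values))
    warped = resample_volume(source, current_t.inverse(), target.grid, "linear")
    centres, _ = select_source_blocks(warped, settings, "source")
    offsets = _sorted_offsets(settings.search_radius)
    tgt64 = np.ascontiguousarray(target.values)
    tsum, tsumsq = _box_sums(tgt64, settings.block_radius)
    best_idx, best_sim = _match_kernel(
        np.ascontiguousarray(warped.values, dtype=np.float32),
        np.ascontiguousarray(tgt64, dtype=np.float32),
        tsum,
        tsumsq,
        centres,
        centres,
        offsets,
        settings.block_radius,
        float(target_var_threshold),
        settings.similarity == "cr",
    )
    ok = best_idx >= 0
    if not ok.any():
        raise MatchFailure("no block found a valid match in its search neighbourhood")
    pts = target.grid.index_to_world(centres[ok])
    matched = target.grid.index_to_world(centres[ok] + offsets[best_idx[ok]])
    return DisplacementField(
        points=pts,
        displacements=matched - pts,
        similarities=best_sim[ok],
    )


# ---------------------------------------------------------------------------
# LTS estimation


def _fit_affine(p: np.ndarray, q: np.ndarray) -> AffineTransform:
    pc = p - p.mean(axis=0)
    if np.linalg.matrix_rank(pc, tol=1e-9 * max(1.0, float(np.abs(pc).max()))) < 3:
        raise ValueError("degenerate geometry: source points are coplanar (rank < 3); affine fit impossible")
    a = np.hstack([p, np.ones((len(p), 1))])
    sol, *_ = np.linalg.lstsq(a, q, rcond=None)
    m = np.eye(4)
    m[:3, :3] = sol[:3].T
    m[:3, 3] = sol[3]
    return AffineTransform(m)


def _fit_rigid(p: np.ndarray, q: np.ndarray) -> AffineTransform:
    pc_mean = p.mean(axis=0)
    qc_mean = q.mean(axis=0)
    pc = p - pc_mean
    qc = q - qc_mean
    if np.linalg.matrix_rank(pc, tol=1e-9 * max(1.0, float(np.abs(pc).max()))) < 2:
        raise ValueError("degenerate geometry: source points are collinear (rank < 2); rigid fit impossible")
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = qc_mean - rot @ pc_mean
    return AffineTransform(m)


def _c_steps(p, q, fit, k, start_inliers, max_iter):
    """Iterated concentration steps from one starting inlier set.

    Returns (transform, trimmed objective); the objective is non-increasing
    across C-steps by construction (each refit minimises over the set it was
    given, each re-selection picks the smallest residuals).
    """
    inliers = np.asarray(start_inliers)
    best_obj = np.inf
    best_t = None
    for _ in range(max_iter):
        try:
            t = fit(p[inliers], q[inliers])
        except ValueError:
            break
        res2 = np.sum((q - t.apply(p)) ** 2, axis=1)
        new_inliers = np.argsort(res2, kind="stable")[:k]
        new_inliers.sort()
        obj = float(res2[new_inliers].sum())
        if obj <= best_obj + 1e-12:
            best_obj = obj
            best_t = t
        if len(new_inliers) == len(inliers) and np.array_equal(new_inliers, inliers):
            break
        if obj > best_obj + 1e-9 * max(best_obj, 1.0):
            break  # numerically stalled; keep the best state seen
        inliers = new_inliers
    return best_t, best_obj


def lts_estimate(
    field: DisplacementField,
    model: str = "rigid",
    h: float = 0.75,
    max_iter: int = 100,
    n_starts: int = 10,
) -> AffineTransform:
    """Least-trimmed-squares fit of a transform to the displacement field.

    The trimmed objective (sum of the ``ceil(h*n)`` smallest squared
    residuals) is minimised by concentration steps: fit on the current inlier
    set, rank squared residuals, keep the smallest (ties broken by index),
    refit, until the inlier set repeats.  Because the objective is non-convex,
    C-steps are run from the full-set least-squares start plus ``n_starts``
    random elemental subsets (the classic FAST-LTS strategy, seeded
    deterministically), and the lowest-objective solution wins.  ``h=1``
    reduces to ordinary least squares.
    """
    if model not in ("rigid", "affine"):
        raise ValueError("model must be 'rigid' or 'affine'")
    if not (0.0 < h <= 1.0):
        raise ValueError("h must lie in (0, 1]")
    fit = _fit_rigid if model == "rigid" else _fit_affine
    min_pts = 3 if model == "rigid" else 4
    p = np.asarray(field.points, dtype=float)
    q = p + np.asarray(field.displacements, dtype=float)
    n = len(p)
    if n < min_pts:
        raise ValueError(f"{model} fit needs at least {min_pts} correspondences, got {n}")
    k = max(min_pts, int(math.ceil(h * n)))
    best_t, best_obj = _c_steps(p, q, fit, k, np.arange(n), max_iter)
    if best_t is None:
        # propagate the degeneracy diagnostics from the full-set fit
        fit(p, q)
        raise ValueError("degenerate geometry: LTS could not fit any model")
    if h < 1.0 and n > 4 * min_pts:
        # a random start only displaces the full-set solution when clearly
        # better (2% hysteresis): near-ties would otherwise flip between
        # local minima under tiny input perturbations
        rng = np.random.default_rng(12345)
        m_sub = min(n, 3 * min_pts)
        for _ in range(n_starts):
            sub = rng.choice(n, size=m_sub, replace=False)
            sub.sort()
            t, obj = _c_steps(p, q, fit, k, sub, max_iter)
            if t is not None and obj < 0.98 * best_obj:
                best_t, best_obj = t, obj
    return best_t


# ---------------------------------------------------------------------------
# multi-resolution registration


def _resample_to_level(vol: ScalarVolume, spacing_mm: float) -> ScalarVolume:
    """Isotropic resampling for a pyramid level, with anti-alias smoothing."""
    old = np.asarray(vol.grid.spacing)
    sm = vol
    if spacing_mm > float(old.max()):
        # sigma chosen so the effective blur roughly matches the new Nyquist
        sigma = 0.5 * math.sqrt(max(spacing_mm**2 - float(old.max()) ** 2, 0.0))
        if sigma > 0.1 * float(old.min()):
            sm = gaussian_smooth(vol, sigma)
    extent = (np.asarray(vol.grid.shape) - 1) * old
    shape = np.maximum(np.floor(extent / spacing_mm).astype(int) + 1, 1)
    out_grid = VolumeGrid(tuple(shape), (spacing_mm,) * 3, vol.grid.origin)
    return resample_volume(sm, AffineTransform.identity(), out_grid, "linear")


def register(
    source_pseudo: ScalarVolume,
    target_us: ScalarVolume,
    init: AffineTransform | None = None,
    settings: MatchSettings | None = None,
    initial_scale: float = 1.0,
) -> tuple[AffineTransform, dict]:
    """Multi-level rigid-then-affine block-matching registration.

    The returned transform maps source (pseudo-US / MR template) world
    coordinates to target (US) world coordinates.  ``initial_scale`` applies
    an extra isotropic scaling about the source centre before matching (a
    stand-in for size normalisation from gestational age).
    """
    settings = settings or MatchSettings()
    t = init if init is not None else AffineTransform.identity()
    if initial_scale != 1.0:
        centre = source_pseudo.grid.index_to_world((np.asarray(source_pseudo.grid.shape) - 1) / 2.0)
        t = t @ AffineTransform.from_scaling(initial_scale, centre)
    diagnostics: dict = {"levels": [], "failed": False}
    for level in settings.levels:
        src_l = _resample_to_level(source_pseudo, level)
        tgt_l = _resample_to_level(target_us, level)
        thresh = settings.variance_threshold_factor * float(np.ptp(tgt_l.values))
        level_diag = {"spacing_mm": level, "stages": []}
        for model in settings.models:
            n_field = 0
            rms = float("nan")
            n_iter = 0
            for n_iter in range(1, settings.max_iterations + 1):
                try:
                    field = match_blocks(src_l, tgt_l, t, settings, thresh)
                    update = lts_estimate(field, model, settings.lts_fraction)
                except (MatchFailure, ValueError) as exc:
                    diagnostics["failed"] = True
                    diagnostics["failure"] = f"{model}@{level}mm iteration {n_iter}: {exc}"
                    level_diag["stages"].append(
                        {"model": model, "iterations": n_iter, "field_size": n_field, "trimmed_rms_mm": rms}
                    )
                    diagnostics["levels"].append(level_diag)
                    return t, diagnostics
                n_field = len(field)
                new_t = update @ t
                res = np.linalg.norm(
                    field.points + field.displacements - update.apply(field.points), axis=1
                )
                k = max(1, int(math.ceil(settings.lts_fraction * len(res))))
                rms = float(np.sqrt(np.mean(np.sort(res)[:k] ** 2)))
                moved = max_corner_displacement(t, new_t, src_l.grid)
                t = new_t
                if moved < settings.tolerance_mm:
                    break
            level_diag["stages"].append(
                {"model": model, "iterations": n_iter, "field_size": n_field, "trimmed_rms_mm": rms}
            )
        diagnostics["levels"].append(level_diag)
    return t, diagnostics


def exhaustive_match_oracle(
    source: ScalarVolume,
    target: ScalarVolume,
    current_t: AffineTransform,
    settings: MatchSettings,
    target_var_threshold: float | None = None,
) -> DisplacementField:
    """Plain-python reference implementation of the block search.

    Independent of the compiled kernel; used to validate it on small inputs.
    """
    r = settings.block_radius
    if target_var_threshold is None:
        target_var_threshold = settings.variance_threshold_factor * float(np.ptp(target.values))
    warped = resample_volume(source, current_t.inverse(), target.grid, "linear")
    centres, _ = select_source_blocks(warped, settings, "source")
    offsets = _sorted_offsets(settings.search_radius)
    pts, disps, sims = [], [], []
    tv = target.values
    for c in centres:
        base = c
        mp = target.grid.index_to_world(c)
        sblk = warped.values[c[0] - r:c[0] + r + 1, c[1] - r:c[1] + r + 1, c[2] - r:c[2] + r + 1]
        best = None
        best_sim = -2.0
        for off in offsets:
            ti, tj, tk = base + off
            if ti - r < 0 or tj - r < 0 or tk - r < 0:
                continue
            if ti + r >= tv.shape[0] or tj + r >= tv.shape[1] or tk + r >= tv.shape[2]:
                continue
            tblk = tv[ti - r:ti + r + 1, tj - r:tj + r + 1, tk - r:tk + r + 1]
            if tblk.var() <= target_var_threshold or tblk.var() == 0.0:
                continue
            try:
                sim = ncc_similarity(sblk, tblk, settings.similarity)
            except ValueError:
                continue
            if sim > best_sim:
                best_sim = sim
                best = off
        if best is not None:
            pts.append(mp)
            disps.append(target.grid.index_to_world(base + best) - mp)
            sims.append(best_sim)
    if not pts:
        raise MatchFailure("oracle: no valid matches")
    return DisplacementField(np.array(pts), np.array(disps), np.array(sims))
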