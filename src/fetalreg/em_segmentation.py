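"""EM tissue classification with atlas priors and multiplicative bias correction.

The MR volume is classified into K classes (class 0 is background, the rest
are tissues such as WM, cortex, deep grey matter, brainstem, cerebellum and
CSF) by iterating three steps:

1. posteriors  p_ik ∝ P(x_i* | mu_k, sigma_k) * p_ik^atlas, normalised per
   voxel, with the background likelihood modelled as a mixture of two
   Gaussians (amniotic fluid is much brighter than the dark air background);
2. class parameter updates: posterior-weighted mean and variance per class;
3. bias estimation: the bias-free image estimate is the inverse-variance
   posterior-weighted mean e_i = (sum_k p_ik mu_k / sigma_k^2) /
   (sum_k p_ik / sigma_k^2); the log residual r_i = log(x_i*/e_i) is smoothed
   with a wide Gaussian using weights x_i* sum_k p_ik / sigma_k^2, and the
   multiplicative field exp(-b) is applied directly to the intensities (no
   global log transform of the image).

The bias field is re-centred to zero mean over the brain mask each iteration,
removing the inherent global-scale ambiguity between the class means and the
multiplicative field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imagecore import ScalarVolume, LabelVolume, VolumeGrid, GridMismatchError

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class ClassParams:
    """Gaussian intensity model per class; class 0 is a two-Gaussian background."""

    means: np.ndarray          # (K,) class means; means[0] is the bg mixture mean
    sds: np.ndarray            # (K,) class sds
    bg_means: np.ndarray       # (2,) background sub-component means
    bg_sds: np.ndarray         # (2,)
    bg_weights: np.ndarray     # (2,), positive, sum 1

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.bg_means = np.asarray(self.bg_means, dtype=float)
        self.bg_sds = np.asarray(self.bg_sds, dtype=float)
        self.bg_weights = np.asarray(self.bg_weights, dtype=float)
        if np.any(self.sds <= 0) or np.any(self.bg_sds <= 0):
            raise ValueError("class standard deviations must be positive")
        if not np.isclose(self.bg_weights.sum(), 1.0) or np.any(self.bg_weights <= 0):
            raise ValueError("background mixing weights must be positive and sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.means)


@dataclass
class AtlasPriors:
    """Per-class prior probability volumes, normalised per voxel."""

    grid: VolumeGrid
    probs: np.ndarray  # (K, *shape)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape[1:] != self.grid.shape:
            raise ValueError("prior volumes do not match grid shape")
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise ValueError("priors must lie in [0, 1]")
        tot = self.probs.sum(axis=0)
        if np.any(np.abs(tot - 1.0) > 1e-3):
            raise ValueError("priors must sum to 1 (within 1e-3) at every voxel")
        self.probs = self.probs / tot  # exact normalisation

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]

    def brain_mask(self) -> np.ndarray:
        """Voxels where tissue (non-background) prior mass dominates."""
        return self.probs[1:].sum(axis=0) > 0.5


@dataclass
class PosteriorField:
    grid: VolumeGrid
    probs: np.ndarray  # (K, *shape), rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        tot = self.probs.sum(axis=0)
        if np.any(np.abs(tot - 1.0) > 1e-6):
            raise ValueError("posteriors must sum to 1 per voxel")

    def hard_labels(self, scheme: dict[int, str] | None = None) -> LabelVolume:
        lab = np.argmax(self.probs, axis=0).astype(np.int32)
        if scheme is None:
            scheme = {0: "background"} | {k: f"class_{k}" for k in range(1, self.probs.shape[0])}
        return LabelVolume(self.grid, lab, scheme)


@dataclass
class BiasState:
    log_bias: np.ndarray       # b, accumulated log field (smooth)
    corrected: ScalarVolume    # x* after applying exp(-b)
    residual: np.ndarray       # last log residual r_i


@dataclass
class EmSettings:
    sigma_bias_mm: float = 20.0
    max_iter: int = 50
    tol_frac: float = 1e-3      # on max |delta mu| relative to intensity range
    estimate_bias_field: bool = True
    bg_init_percentiles: tuple[float, float] = (10.0, 60.0)


def _likelihoods(x: np.ndarray, params: ClassParams) -> np.ndarray:
    """(K, *shape) Gaussian likelihoods; class 0 uses the background mixture."""
    k = params.n_classes
    out = np.empty((k,) + x.shape)
    bg = np.zeros_like(x)
    for w, m, s in zip(params.bg_weights, params.bg_means, params.bg_sds):
        bg += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * _SQRT2PI)
    out[0] = bg
    for j in range(1, k):
        s = params.sds[j]
        out[j] = np.exp(-0.5 * ((x - params.means[j]) / s) ** 2) / (s * _SQRT2PI)
    return out


def em_posteriors(x_star: ScalarVolume, params: ClassParams, priors: AtlasPriors) -> PosteriorField:
    """Posterior class probabilities given intensities, class params and priors."""
    if priors.grid.shape != x_star.grid.shape:
        raise GridMismatchError("intensities and priors are on different grids")
    if params.n_classes != priors.n_classes:
        raise ValueError("params and priors disagree on number of classes")
    num = _likelihoods(x_star.values, params) * priors.probs
    tot = num.sum(axis=0)
    dead = tot <= 0.0
    if dead.any():
        # no class explains these voxels at all: assign to background
        num[0, dead] = 1.0
        tot = num.sum(axis=0)
    return PosteriorField(x_star.grid, num / tot)


def update_class_params(x_star: ScalarVolume, post: PosteriorField, prev: ClassParams) -> ClassParams:
    """Posterior-weighted mean/variance updates; empty classes stay frozen."""
    x = x_star.values
    k = post.probs.shape[0]
    means = prev.means.copy()
    sds = prev.sds.copy()
    for j in range(1, k):
        p = post.probs[j]
        tot = p.sum()
        if tot <= 0:
            warnings.warn(f"class {j} has zero posterior mass; parameters frozen")
            continue
        mu = float((x * p).sum() / tot)
        var = float((((x - mu) ** 2) * p).sum() / tot)
        means[j] = mu
        sds[j] = max(np.sqrt(var), 1e-12)
    # background sub-components: mixture responsibilities within the bg posterior
    p_bg = post.probs[0]
    bg_means = prev.bg_means.copy()
    bg_sds = prev.bg_sds.copy()
    bg_weights = prev.bg_weights.copy()
    comp = np.empty((2,) + x.shape)
    for c in range(2):
        s = prev.bg_sds[c]
        comp[c] = prev.bg_weights[c] * np.exp(-0.5 * ((x - prev.bg_means[c]) / s) ** 2) / (s * _SQRT2PI)
    denom = comp.sum(axis=0)
    ok = denom > 0
    if p_bg[ok].sum() > 0:
        for c in range(2):
            resp = np.zeros_like(x)
            resp[ok] = p_bg[ok] * comp[c][ok] / denom[ok]
            tot = resp.sum()
            if tot > 0:
                mu = float((x * resp).sum() / tot)
                var = float((((x - mu) ** 2) * resp).sum() / tot)
                bg_means[c] = mu
                bg_sds[c] = max(np.sqrt(var), 1e-12)
                bg_weights[c] = tot / p_bg[ok].sum()
        bg_weights = np.clip(bg_weights, 1e-6, None)
        bg_weights = bg_weights / bg_weights.sum()
    means[0] = float(bg_weights @ bg_means)
    sds[0] = max(float(np.sqrt(bg_weights @ (bg_sds**2 + bg_means**2) - means[0] ** 2)), 1e-12)
    return ClassParams(means, sds, bg_means, bg_sds, bg_weights)


def estimate_bias(
    x_star: ScalarVolume,
    post: PosteriorField,
    params: ClassParams,
    sigma_bias_mm: float = 20.0,
    mask: np.ndarray | None = None,
) -> BiasState:
    """One multiplicative bias update from the current classification.

    Returns the smoothed log-bias field still present at this iteration
    (re-centred to zero mean over the mask) and the corrected intensities
    ``x* exp(-b)``.
    """
    x = x_star.values
    if mask is None:
        mask = post.probs[1:].sum(axis=0) > 0.5
    n_bad = int(np.count_nonzero((x <= 0) & mask))
    if n_bad:
        raise ValueError(f"bias estimation requires positive intensities inside the mask; {n_bad} voxels are <= 0")

    inv_var = 1.0 / params.sds[1:] ** 2
    num = np.tensordot(params.means[1:] * inv_var, post.probs[1:], axes=(0, 0))
    den = np.tensordot(inv_var, post.probs[1:], axes=(0, 0))
    r = np.zeros_like(x)
    valid = mask & (den > 0) & (num > 0)
    e = np.ones_like(x)
    e[valid] = num[valid] / den[valid]
    r[valid] = np.log(x[valid] / e[valid])

    w = np.zeros_like(x)
    w[valid] = x[valid] * den[valid]
    sigma_vox = [sigma_bias_mm / s for s in x_star.grid.spacing]
    sm_wr = ndimage.gaussian_filter(w * r, sigma_vox, mode="constant")
    sm_w = ndimage.gaussian_filter(w, sigma_vox, mode="constant")
    b = np.zeros_like(x)
    ok = sm_w > 1e-12 * max(sm_w.max(), 1e-300)
    b[ok] = sm_wr[ok] / sm_w[ok]
    b -= b[mask].mean()
    corrected = ScalarVolume(x_star.grid, x * np.exp(-np.where(mask, b, 0.0)))
    return BiasState(log_bias=b, corrected=corrected, residual=r)


def initial_params(x_star: ScalarVolume, priors: AtlasPriors, settings: EmSettings) -> ClassParams:
    """Prior-weighted intensity statistics as the EM starting point."""
    x = x_star.values
    k = priors.n_classes
    means = np.empty(k)
    sds = np.empty(k)
    for j in range(k):
        p = priors.probs[j]
        tot = p.sum()
        if tot <= 0:
            means[j] = x.mean()
            sds[j] = x.std() + 1e-6
            continue
        means[j] = (x * p).sum() / tot
        sds[j] = max(np.sqrt((((x - means[j]) ** 2) * p).sum() / tot), 1e-6)
    bg_vox = x[priors.probs[0] > 0.5]
    if bg_vox.size < 2:
        bg_vox = x.ravel()
    lo, hi = np.percentile(bg_vox, settings.bg_init_percentiles)
    spread = max(bg_vox.std(), 1e-6)
    return ClassParams(means, sds, np.array([lo, hi]), np.array([spread, spread]), np.array([0.5, 0.5]))


@dataclass
class EmResult:
    labels: LabelVolume
    posteriors: PosteriorField
    params: ClassParams
    bias: BiasState
    converged: bool
    n_iter: int
    history: list = field(default_factory=list)


def segment_em(
    mri: ScalarVolume,
    priors: AtlasPriors,
    settings: EmSettings | None = None,
    init: ClassParams | None = None,
    scheme: dict[int, str] | None = None,
) -> EmResult:
    """Full EM segmentation loop with interleaved bias correction."""
    settings = settings or EmSettings()
    if priors.grid.shape != mri.grid.shape:
        raise GridMismatchError("MR volume and atlas priors must share a grid (resample the priors first)")
    params = init if init is not None else initial_params(mri, priors, settings)
    x_star = mri.copy()
    rng_range = float(np.ptp(mri.values)) or 1.0
    mask = priors.brain_mask()
    log_bias = np.zeros(mri.grid.shape)
    post = em_posteriors(x_star, params, priors)
    converged = False
    history = []
    n_done = 0
    for it in range(settings.max_iter):
        new_params = update_class_params(x_star, post, params)
        if settings.estimate_bias_field:
            bias = estimate_bias(x_star, post, new_params, settings.sigma_bias_mm, mask)
            log_bias += bias.log_bias
            x_star = bias.corrected
        delta = float(np.max(np.abs(new_params.means - params.means)))
        params = new_params
        post = em_posteriors(x_star, params, priors)
        history.append({"iter": it, "delta_mu": delta, "means": params.means.tolist()})
        n_done = it + 1
        if delta < settings.tol_frac * rng_range:
            converged = True
            break
    bias_state = BiasState(log_bias=log_bias, corrected=x_star, residual=np.zeros_like(log_bias))
    labels = post.hard_labels(scheme)
    return EmResult(labels, post, params, bias_state, converged, n_done, history)
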