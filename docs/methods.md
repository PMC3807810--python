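# Methods

`fetalreg` aligns a reconstructed T2-weighted fetal-brain MR volume with 3D
fetal neurosonography. Because MR and B-mode ultrasound depict largely
complementary features (the WM–GM boundary is invisible in US; the skull,
falx and choroid plexus are poorly defined in MR), the MR volume is not
registered directly. Instead it is segmented into the structures a
sonographer actually sees, those structures are rendered as an artefact-free
*pseudo-ultrasound* image, and that image is registered to the real US
volume with a block-matching algorithm that is robust to shadows,
attenuation and missing features. This note records the models, the
parameters that matter, and the numerical choices, in the order the pipeline
runs them.

## Conventions

World coordinates are millimetres; grids are axis-aligned with 0-based voxel
indices and voxel centre `origin + index * spacing`. Transforms are 4×4
homogeneous maps of world coordinates; resampling is pull-back (the output
value at point *p* is the input interpolated at *T(p)*), with fill value 0
outside the support — both MR background and US background are dark. Euler
angles are intrinsic z–y–x, reported in degrees in (−180°, 180°], and are
used only for reporting (e.g. the largest rotation a registration had to
recover); internally rotations stay matrices. Oblique NIfTI grids are not
represented internally; volumes are reoriented to the closest canonical axes
on load and must be resampled upstream if truly oblique.

## Super-resolution reconstruction (`superres`)

Clinical fetal MR arrives as stacks of thick 2D slices. A single isotropic
volume x is estimated by minimising

    Σ_j w_j (y*_j − y^s_j)² + λ Σ_i sqrt(ε² + |∇x|²),

where `y^s_j = Σ_i m_ij x_i` simulates acquired voxel j from the current
volume through the acquisition PSF, and `y*_j` are the acquired intensities
after per-stack scaling. The PSF is an anisotropic Gaussian in the slice
frame: FWHM equal to the slice thickness through-plane (slice-selection
profile) and 1.2× the in-plane resolution in plane (main lobe of the
sinc sampling kernel), truncated at 3σ and renormalised so the discrete
coefficients of each acquired voxel sum to 1 (constant volumes are then
reproduced exactly). Slice poses are inputs; slice-to-volume motion
registration is deliberately out of scope.

The weights `w_j` make the fit robust to motion-corrupted data: a voxel-level
EM classifies residuals into a zero-mean Gaussian inlier class and a uniform
outlier class, a slice-level EM does the same on each slice's median absolute
residual, and `w_j` is the product of the two posteriors. The inlier/outlier
densities are not canonical; Gaussian + uniform is our choice and is the
standard one for this construction.

Numerical choices:

* Edge-preserving penalty: isotropic Charbonnier with λ = 0.02·range and
  ε = 0.01·range of the acquired data. The data term and regulariser are
  minimised by preconditioned gradient descent (Jacobi preconditioner =
  weighted slice coverage per voxel) with a backtracking line search, so the
  objective is non-increasing at fixed weights; 10 outer iterations
  (weights + scales re-estimated) × 3 descent steps by default.
* Per-stack intensity scales are estimated by weighted least squares each
  outer iteration and then normalised to mean 1: only relative scales are
  identifiable, and without the gauge fix the scales and the volume drift
  jointly toward zero because a dimmer volume has a smaller smoothness
  penalty.
* The starting volume is the PSF-weighted average of the acquired data; when
  the first weight estimate flags outlier slices (slice posterior < 0.5) the
  start is recomputed with those slices down-weighted, since a corrupted
  unweighted average otherwise poisons the first residuals.
* Voxels covered by no slice keep their initial value and are counted in the
  returned state.

## EM segmentation with bias correction (`em_segmentation`)

The MR volume is classified into K classes with a probabilistic atlas as
spatial prior, iterating three steps:

1. posteriors `p_ik ∝ N(x*_i; μ_k, σ_k) p_ik^atlas`, normalised per voxel.
   The background class is a mixture of two Gaussians — dark air and bright
   amniotic fluid both surround the head. Voxels where every prior-weighted
   likelihood underflows are assigned to background.
2. class updates: posterior-weighted mean and variance; the two background
   components are updated from mixture responsibilities within the
   background posterior. Empty classes freeze with a warning.
3. bias update, multiplicative throughout (no global log transform): the
   bias-free estimate is the inverse-variance weighted posterior mean
   `e_i = Σ_k p_ik μ_k/σ_k² / Σ_k p_ik/σ_k²`; the log residual
   `r_i = log(x*_i / e_i)` is smoothed with a wide Gaussian using weights
   `x*_i Σ_k p_ik/σ_k²`, and the image is corrected by `exp(−b)`. Whether the
   posterior weighting uses σ² or 1/σ² is ambiguous in the source
   formulation; we use inverse-variance weighting, consistent with the
   bias-correction literature this construction comes from (confident voxels
   of tight classes should dominate the field estimate).

The log-bias is re-centred to zero mean over the brain mask each iteration:
class means and a multiplicative field are only jointly identifiable up to
one global scale, and the gauge must be fixed somewhere. Consequences: any
recovered mean must be compared to ground truth in that gauge (multiply true
means by exp(mean g over the mask)).

Defaults: bias smoothing σ = 20 mm (the field is an RF inhomogeneity, smooth
at the scale of the head; configurable), convergence when max |Δμ_k| <
0.1% of the intensity range, at most 50 iterations. Initialisation:
prior-weighted intensity statistics; background components at the 10th/60th
percentile of background-dominant voxels, which lands one component on air
and one near fluid.

## Structure map (`structures`)

The tissue segmentation is converted into the US-visible inventory:

* **Hemisphere split / falx.** The WM mask is eroded by removing voxels
  closer than 1.5 mm to the WM surface; the two largest 26-connected
  remnants are the left/right cores (left = smaller centroid x, for
  determinism). Euclidean distance maps from each core are regularised with
  a Gaussian (σ = 10 mm) and every brain voxel goes to the nearer side.
  Voxels where the two regularised distances differ by at most one voxel
  size form the midline, are removed from the tissue labels, and are
  labelled as the falx along the whole midline — in fetal US the
  inter-hemispheric fissure reads as one bright membrane.
* **Skull.** A shell of voxels outside the brain+CSF mask within 2 mm of it.
  The fetal skull is thin, dark on T2w MR, and hugs the brain mask, so a
  distance-based shell is the practical estimate.
* **Brain surface.** The echogenic pial/subarachnoid layer: brain-tissue
  voxels within two voxels of the tissue boundary (0.66 mm on the reference
  0.33 mm grid; the default scales with the grid).
* **Merging.** WM and cortex merge into per-side cortical hemispheres (their
  boundary is invisible in US). The cerebellum stays homogeneous for older
  fetuses (`ga_mode="old"`); for younger ones a separately provided
  cerebellar-WM label is kept as its own darker class. Choroid plexus and
  septum pellucidum are input masks — they are manually delineated in
  practice. On overlap a fixed precedence applies (skull > choroid/septum >
  falx > surface > cerebellum/cerebellar WM > DGM/brainstem > hemispheres >
  CSF); the inventory itself carries no overlap semantics, so the order is
  ours: thin bright landmarks win over the broad classes they are embedded
  in.

## Pseudo-ultrasound (`pseudous`)

Each structure receives one uniform intensity, ordered from brightest to
darkest: skull (1.00); choroid plexus, septum pellucidum, falx (0.80); brain
surface (0.65); cerebellum (0.50); DGM and brainstem (0.35); cerebral
hemispheres, cerebellar WM and CSF (0.20); background 0. Because the
matching similarity (local NCC) is invariant to affine intensity changes,
only the *ordering* of these values carries information; the exact numbers
are a convenience and the table is fully configurable. No speckle is
simulated — speckle cannot be predicted from MR, so it can only mislead
matching; instead the real US volume is lightly smoothed (Gaussian,
σ = 0.5 mm by default) before registration. Cerebellar WM is placed in the
darkest tier: it appears hypoechogenic against the bright cerebellar cortex.

## Block-matching registration (`blockmatch`)

At each resolution level (isotropic 2 mm then 1 mm by default) and for each
model stage (rigid, then affine), two steps alternate:

1. **Matching.** The pseudo image is warped through the current transform
   onto the target grid, so blocks are compared in a common orientation.
   Every warped block of 3×3×3 voxels (centres every 2 voxels) with
   non-zero variance searches integer offsets within ±7 voxels in the
   target for the highest NCC (or squared NCC, the correlation-ratio variant
   appropriate when a local affine intensity model holds). Target candidates
   whose variance is below 0.04× the target intensity range are skipped —
   featureless ultrasound blocks cannot be matched. Ties are broken toward
   the smaller Euclidean offset, then lexicographically.

   "Non-zero variance" on the warped pseudo side is interpreted with a
   floating-point floor (variance > 1e-3 × range²): after trilinear
   resampling the nominally piecewise-constant image carries interpolation
   tails of variance ~1e-6 everywhere, and blocks with only such tails match
   speckle essentially at random — worse, they match *inward*, because
   candidates outside the brain fail the target variance rule, and the
   resulting coherent inward field biases the affine stage toward a global
   shrink. The floor keeps only blocks carrying a real tier boundary.

2. **Estimation.** A rigid (Procrustes with determinant correction) or
   affine (linear least squares) update is fitted by least trimmed squares:
   minimise the sum of the `ceil(h·n)` smallest squared residuals, with
   h = 0.75. The trimmed objective is minimised by concentration steps from
   the full-set least-squares start plus 10 random elemental starts
   (FAST-LTS; deterministic seeding), keeping a candidate only when it beats
   the incumbent by >2% — near-ties would otherwise flip between equivalent
   local minima under tiny input perturbations. h = 1 reduces exactly to
   least squares.

Stages run up to 20 iterations and stop early when the update moves the
volume corners by less than 0.5 mm. Both caps are ours: the integer-voxel
search makes successive transforms jitter by roughly a third of a
millimetre, so a tighter tolerance simply never fires, and recovering
rotations near 30° at the coarse level needs more than ten iterations. The
variance threshold is computed once per level on the resampled target.
Levels are built by Gaussian anti-alias smoothing followed by linear
resampling. Initialisation is a user transform (default identity) plus an
optional isotropic scale about the source centre, standing in for the
age-derived size normalisation used with clinical data.

The output of this algorithm is quantised: two runs on slightly perturbed
inputs agree to ~0.3–0.8 mm at the volume corners, not better, even when
both land within 0.2–0.4 mm of ground truth. Downstream consumers should
treat sub-half-millimetre differences between recovered transforms as noise.

## Synthetic data (`synthetic`)

The phantom is a nested-ellipsoid head at 20-week proportions on a 0.75 mm
grid (113×97×89 voxels): head (brain+CSF) semi-axes 27/23/21 mm, a 2 mm
skull shell, a 2.5 mm cortical rind over two WM lobes separated by a
one-voxel gap, DGM, brainstem, cerebellum (with an inner cerebellar-WM
ellipsoid in the young preset), two choroid blobs and a septum slab. The
structure map is derived through the same hemisphere-split/skull/surface
operators as a segmented MR volume, so phantom studies exercise the real
code path. Generators are bitwise-reproducible per seed and return their
ground truth.

MR appearance: per-class Gaussian intensities (T2w-like means — CSF 100,
WM 62, DGM 52, brainstem 48, cerebellum 47, cortex 45; amniotic fluid 85 in
a 6 mm layer hugging the head, air 5) times a smooth random second-order
polynomial field exp(g) with max |g| set by the bias amplitude.

US appearance, applied to the pseudo image after resampling through the
ground-truth transform: exponential depth attenuation (0.008/mm along the
beam from a virtual probe 55 mm above the head), a probe shadow cone (apex,
axis, half-angle, multiplicative factor 0.25; a bisection helper finds the
half-angle occluding a requested fraction of the brain), voxel-wise
log-normal multiplicative speckle (σ = 0.2, mean-one), additive Gaussian
noise (sd 2 on an 8-bit-like scale, gain 180). Speckle is modelled as white
multiplicative noise, *not* coherent interference: its role here is purely
disruptive, and white noise at the voxel scale is in fact harsher for NCC
matching than physically correlated speckle, so passing under it is the
conservative direction. Not modelled at all: reverberation artefacts,
refraction, anisotropic PSF of the US probe, anatomically realistic cortical
folding and gestational-age-dependent growth. Phantom results therefore
demonstrate algorithmic correctness and robustness to the modelled artefact
classes; they do not certify clinical accuracy.

The standard transform-recovery study simulates the US on a grid padded by
9 mm per side so that rotations up to 30° never clip the skull at the
volume border; clinical US volumes likewise extend beyond the brain.

## Evaluation (`evaluation`)

Dice overlap 2|A∩B|/(|A|+|B|) (0, with a warning, when both masks are
empty); barycentre distance between voxel-count-weighted world centroids
(computed in mm, so anisotropic grids are safe); mean target registration
error over named landmark pairs; maximum absolute Euler angle of the
polar-decomposed rotation factor (scale/shear removed first, so pure
scalings report 0°).

## Pipeline (`cli_pipeline`)

`fetalreg` exposes `simulate`, `segment`, `pseudous`, `register`, `evaluate`
and `run`. `run_pipeline` chains segmentation → structure map → pseudo US →
registration (→ metrics when reference labels exist), writing each
intermediate plus a JSON manifest with content hashes of the inputs; a rerun
with identical inputs and settings reuses the cached segmentation — the
template only needs segmenting once — and reproduces outputs bitwise.

## Problem sizes

The standard studies are sized for a single CPU: the registration phantom at
0.75 mm (~1M voxels, registered at 2 mm and 1 mm levels; one registration
runs in roughly 15–60 s), segmentation and super-resolution studies at 64³,
oracle comparisons at 28³. These sizes are the package's study conditions;
all of them are parameters, not limits.

## Known limitations

* Recovered transforms carry the ~0.3 mm quantisation noise described above;
  the algorithm returns no sub-voxel polish stage.
* The EM background model assumes exactly two background populations; more
  complex maternal anatomy in the field of view would need a richer mixture.
* The skull shell derived from an EM brain mask sits wherever the mask
  boundary sits; partial-volume CSF/fluid voxels can displace it by about a
  voxel relative to the anatomical skull.
* `h` values near 1 degrade under the standard artefact levels — the
  simulated shadow and speckle produce roughly 30% outlier matches, more
  than h = 0.9 trims. The default 0.75 holds.
* Slice-to-volume motion registration, non-rigid template propagation and
  locally-affine extensions are out of scope; hooks exist where a caller
  would plug them in (slice poses, aligned priors, initial transforms).
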