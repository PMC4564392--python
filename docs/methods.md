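# Methods

`lesionmorph` implements a lesion-aware grey-matter morphometry pipeline for
cerebral small vessel disease (SVD) and the synthetic phantom machinery
needed to validate every stage against known ground truth. This note
documents the models, the parameter choices, the numerical decisions, and
what the phantom experiments do and do not demonstrate about real data.

## The problem

SVD produces white matter hyperintensities (WMH; FLAIR-bright ischaemic
lesions) and lacunar infarcts (LI; small cavities with CSF-like gliotic
cores). Both corrupt conventional T1-driven tissue segmentation: WMH has a
T1 intensity close to grey matter and is classed as GM, and gliosis is
classed as CSF. Because segmentations drive spatial normalisation and
cortical thickness, these errors propagate into every downstream analysis,
precisely in the cohorts where lesion load is the variable of interest. The
pipeline therefore (1) segments WMH explicitly with a two-channel
(T1 + FLAIR) mixture model, (2) repairs the tissue maps before any
morphometry, and (3) quantifies the association between lesion load and
grey matter by voxel-based morphometry (VBM), voxel-based cortical
thickness (VBCT) and kernel Gaussian-process regression (GPR).

## Phantoms: the study conditions

No patient imaging ships with the package; every claim is tested on
phantoms with analytically known truth.

* **Anatomy.** A WM sphere (default radius 16 mm) wrapped in a GM shell
  (default 3 mm — the true cortical thickness) inside a CSF rim, on a 48^3
  grid of 1 mm isotropic voxels; a flat-slab variant gives axis-aligned
  oracle geometry. The intracranial envelope follows the *base* outer
  radius, so atrophy widens the CSF rim rather than shrinking the head, and
  total intracranial volume (TIV) varies only through the per-subject
  warps — keeping TIV from being collinear with lesion load.
* **Lesions.** WMH and LI are spheres carved into WM (radii 2–5 mm and
  2–4 mm), placed uniformly at random at centres deep enough to fit; the
  inner 70 % of each LI radius is rendered with a gliotic, CSF-like
  intensity. WMH and LI masks are disjoint and the recorded WMHV/LIV are
  voxel-exact.
* **Intensities.** Each class has a bivariate (T1, FLAIR) Gaussian. The
  defaults (T1/FLAIR means — CSF 30/20, GM 80/100, WM 110/90, WMH 84/140,
  gliosis 35/28; SD 5 per channel) are free parameters chosen so that WMH
  is nearest GM on T1 but is the FLAIR-brightest class, and gliosis is
  CSF-like — reproducing both misclassification modes. An optional
  multiplicative smooth bias field is available and defaults to off.
* **Cohorts.** Per-subject lesion load is drawn uniformly from
  500–12,000 mm^3 (what the phantom's WM core can host), and the GM shell
  is thinned by `0.5 mm per 10,000 mm^3` of WMH — the effect size the
  analyses must recover. Each subject receives a smooth random
  diffeomorphic warp (1 mm peak displacement, 12 mm correlation length)
  generated as a tapered, Gaussian-filtered random velocity field and
  exponentiated with the registration module, so invertibility is
  guaranteed. Ages are Normal(70, 9.5) years; sex is Bernoulli(0.64),
  coded 0/1. All randomness descends from one master seed through
  `numpy.random.SeedSequence`, so cohorts are bit-reproducible.

What the phantoms deliberately lack: MR physics (no sequences, k-space, or
partial-volume mixing in the rendered voxels), skull and dura, microbleeds,
anatomically realistic cortical folding, and spatially structured lesion
distributions. Passing tests therefore demonstrate the *algorithmic*
correctness and calibration of each stage under controlled conditions, not
clinical performance on patient MRI.

## Segmentation

Tissue classes are modelled as a multivariate mixture of Gaussians over the
input channels, fitted by EM over in-mask voxels. Population tissue
probability maps (TPMs), when supplied, act as per-voxel mixing weights in
both the E-step and the log-likelihood. Covariances carry a `1e-6 * mean
channel variance` ridge; convergence is declared at a relative
log-likelihood change below 1e-6 (cap 200 iterations) and monotonicity is
asserted every iteration.

Initialisation matters more than usual here. Without priors, k-means seeds
the classes. With priors, the class *means* cannot be seeded from
prior-weighted moments: the population WMH prior is spatially diffuse
inside WM (every subject's lesions are somewhere else), so its weighted
mean sits on the WM intensity mode. The fit therefore first runs the
intensity-only EM and then names its clusters by maximising the overlap
between cluster responsibilities and the prior probabilities (Hungarian
assignment) before the prior-weighted EM refines. Anonymous fits are
identified by intensity signature: CSF darkest and WM brightest on T1, WMH
brightest on FLAIR.

Population TPMs are the voxelwise cross-subject mean of per-subject
posteriors, smoothed at 4 mm FWHM, floored at 1e-3 inside the brain
support (no class ever has a strictly zero prior) and renormalised where
the floored sum exceeds 1.

WMH maps are binarised at probability 0.5 by default (configurable
per subject). Lacune masks can be grown from seed points by 6-connected,
intensity-windowed region growing (default window 350–500, 500 iterations).
Skull stripping thresholds the summed tissue probability at 0.1 and keeps
the largest connected component. Bias-field estimation is not implemented;
the phantom's bias amplitude defaults to zero.

## Tissue repair

Inside the binary WMH mask the full GM probability mass moves to WM
(`wm' = wm + gm, gm' = 0`); the WMH posterior mass itself also joins WM,
because the class is white matter pathology. Lacune voxels are reassigned
to the tissue class most often dominant at that location across the cohort
in group space: each subject's (WMH-repaired) maps vote with their argmax
class, ties break by the precedence WM > GM > CSF (lacunes live in WM), and
a voxel where the consensus is silent falls back to the subject's own
argmax (counted and reported). Every repair operation conserves total
tissue probability mass to better than 1e-6 and provably touches no voxel
outside the lesion masks. TIV counts voxels with summed GM+WM+CSF
probability >= 0.2 (inclusive); WMHV/LIV are mask voxel counts times the
voxel volume.

Reliability metrics for repeated volume measurements: mean variability is
the mean of `|a-b| / mean(a,b) * 100` over pairs, the standard error of
measurement is `sd(differences)/sqrt(2)`, and agreement is the two-way
single-measure intraclass correlation ICC(A,1); zero-volume pairs are
excluded and counted. ICC is computed from the ANOVA mean squares directly
so degenerate inputs (identical lists) return exactly 1.

## Registration and templates

Warps are parameterised by stationary velocity fields and exponentiated by
scaling-and-squaring (cubic-spline compositions, per-step displacement
capped at 0.25 voxels), which guarantees a diffeomorphism and gives the
inverse for free (negate the velocity). This is a deliberate, documented
substitution for geodesic shooting: far simpler, while preserving the
properties the analysis needs — invertibility, positive Jacobians, and
volume-preserving Jacobian modulation. Pairwise registration minimises the
multi-class SSD between warped and fixed probability maps by
Gaussian-regularised gradient descent (updates smoothed at 4 voxels FWHM)
with backtracking, coarse-to-fine over downsampling factors (4, 2, 1);
the objective is non-increasing across accepted iterations by
construction. During optimisation the exponential runs in a cheap
(linear-interpolation) mode; public results use the accurate settings.
Cohort-scale template building stops at the half-resolution scale — the
warped maps are smoothed at 6 mm afterwards, so the full-resolution
refinement adds little at several times the cost.

Templates iterate register-all / recentre velocities to zero mean /
average the warped maps (default one outer iteration at cohort scale).
Jacobians come from central differences of the deformation; modulation is
the voxelwise product. Warped-weighted smoothing computes
`smooth(w * t) / smooth(w)` with the weight `w` = warped GM x Jacobian,
defined where the smoothed weight exceeds 1e-3 — averaging thickness within
cortex without bleeding across tissue boundaries. All Gaussian smoothing
uses a renormalised truncated kernel (no mass loss at the brain edge).

## Voxel-based cortical thickness

Thickness is computed in native space on the repaired maps by the
Laplace-equation layer method: resample to the sampling grid (default
0.5 mm), label tissue by argmax, solve the Laplace equation on the GM
compartment with the WM shell at potential 0 and the CSF shell at 1, and
integrate a streamline from every GM voxel both ways along the normalised
potential gradient (RK4, step = sampling/5); the summed arc length, capped
at 10 mm, is the thickness. The four classic tuning knobs keep their
conventional names with these semantics: *CSF smoothness* (3 mm) and *CSF
thinness* (0.65) reconstruct buried sulcal CSF — wherever the smoothed CSF
probability reaches the threshold the voxel is forced to CSF before the
argmax; *dilations* (1) lets the GM compartment grow into unlabeled
support voxels only (never into WM or CSF, so thickness is not inflated).

Two numerical choices are worth knowing. First, the Dirichlet conditions
are imposed at sub-voxel interface positions: the probability-difference
level sets locate where the tissue interface crosses each voxel edge, and
a ghost-value (non-uniform) stencil places the boundary there rather than
at the neighbouring voxel centre. This removes the half-voxel staircase
bias of the naive voxelised boundary — with exactly specified interfaces
the spherical-shell potential matches the closed form to better than 1e-2
pointwise, where the voxel-centre condition plateaus around 5e-2. Second,
streamlines terminate when their nearest voxel leaves the GM compartment,
with the crossing placed half a step back; the potential is continued
outside the compartment by nearest-neighbour fill so the interpolated
gradient cannot reverse just inside the boundary. Voxels with a vanishing
gradient inherit their nearest valid neighbour's value. The relaxation is
red-black SOR (omega = 1.7, converged when the largest update falls below
1e-5); both the SOR sweeps and the streamline integration run as compiled
(numba) kernels with a pure-numpy fallback.

## Voxelwise statistics

Smoothed (6 mm FWHM) Jacobian-modulated warped GM maps, or warped-weighted
VBCT maps, are regressed voxelwise on WMHV with age, sex, LIV and TIV as
covariates (all mean-centred; intercept included). The analysis mask is
the mean *unsmoothed* warped GM support at probability 0.1 — a smoothed
mask would pull deep WM and CSF into the analysis. t contrasts use the
standard OLS form. Residual smoothness is estimated from forward
differences of the standardised residual fields, inverted through the
Gaussian-autocorrelation relation `E[d^2] = 2(1 - exp(-lambda h^2/2))/h^2`
(raw differences are kept for near-white fields where the inversion is
undefined); resel counts use the lattice (voxel/edge/face/cube) formula.
Peak family-wise-error p values are the expected Euler characteristic of
the t-field excursion set (Worsley densities, orders 0–3), floored at the
voxelwise uncorrected p — the EC expansion is a tail approximation and
must not undercut the single-voxel probability — and clipped to [0, 1].
A max-statistic permutation scheme with Freedman–Lane nuisance handling
provides the nonparametric cross-check; on smooth null cohorts the RFT
threshold sits within a few percent of the permutation threshold, and the
realised family-wise error rate is near (in practice slightly below — the
known lattice conservativeness of peak-level random field theory) the
nominal 0.05.

## GPR prediction of lesion load

Subject feature vectors are all in-mask voxels of the smoothed modulated
GM maps (or the warped-weighted thickness maps), mean-centred across
subjects and reduced to a linear kernel `K = F F'/D` — the natural
representation when voxels vastly outnumber subjects. Confounds (age, sex,
TIV, LIV, plus an intercept) are projected out of the kernel,
`K' = R K R`; inside cross-validation the projection is estimated on the
training subjects only and applied to all rows, so nothing leaks from the
held-out target. The GP covariance is `theta_s K + theta_n I`; the two
hyperparameters maximise the log marginal likelihood, found by profiling
out the overall scale (closed form) and searching the noise-to-signal
ratio on a log grid with local refinement — a deterministic, exact
reformulation of the two-parameter evidence optimisation. Leave-one-out
cross-validation refits hyperparameters in every fold; quality is Pearson
r between predicted and observed WMHV, r^2, and RMSE in mm^3. Significance
permutes the targets and reruns the full LOO procedure,
`p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`. The dual weights map back
to a voxel weight image `w = F' alpha / D` satisfying the dual–primal
identity `prediction = theta_s <f, w> + offset`; individual voxel weights
are not interpretable in isolation — only the full pattern defines the
predictor.

A caveat worth stating: when the kernel carries no usable signal, LOO
predictions collapse towards the leave-one-out training mean, which is
itself weakly (negatively) coupled to the held-out target, so null LOO
correlations can take extreme values. The permutation test is unaffected
(the same procedure is applied to every permuted target), and null
calibration is verified empirically (uniform permutation p values).

## Problem sizes used by the test suite and acceptance script

Oracle geometry runs on 24–48 voxel grids at the 0.5 mm sampling
resolution. The detection experiment uses the standard cohort conditions
at n = 20 (48^3 grid); null specificity uses ten cohorts of n = 12 on a
32^3 phantom with the thinning coefficient set to zero. The prediction
experiment uses n = 60 under the standard conditions with 199 target
permutations; permutation-test calibration uses 200 null datasets at 99
permutations each. GLM/FWE calibration uses 50 null cohorts of n = 24 maps
(28^3 grid, 4 mm smoothing, spherical mask of radius 12). These sizes are
the package's validation conditions; all are regenerated programmatically
from seeds.

## Known limitations

* The "modified" mixture-of-Gaussians segmentation is interpreted as
  prior-weighted EM with ridge-regularised covariances; bias-field
  correction and deformable priors (unified segmentation) are out of scope.
* The stationary-velocity registration is the largest methodological
  substitution (for geodesic shooting) and is validated for the properties
  the analyses need, not for matching any particular implementation's
  numerics. An affine pre-alignment step is absent: phantoms share a grid.
* VBCT parameter semantics for CSF smoothness/thinness/dilations are this
  package's definitions of conventionally named knobs.
* Peak-level RFT on discretely sampled fields is mildly conservative; the
  permutation route is provided for exact control.
* Phantom realism limits (above) apply to every empirical claim.
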