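# Methods

`tensorxfer` implements zero-shot subject-transfer decoding of task fMRI:
a target subject's trials are classified by decoders trained purely on
*other* subjects' functional data, with only anatomical (diffusion-tensor)
imaging used to bring the subjects into correspondence.  This note records
the models, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## The deviatoric tensor metric

Diffusion tensors are symmetric 3x3 matrices D (units mm^2/s) stored as
six components `(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)`.  Registration similarity
uses the anisotropy-only ("deviatoric") norm

    ||D1 - D2||_D = sqrt(8*pi/15) * ||dev(D1) - dev(D2)||_F,
    dev(D) = D - (tr D / 3) * I,

equivalently `sqrt(8*pi/15 * (||D1-D2||_F^2 - tr^2(D1-D2)/3))`.  Isotropic
differences are invisible to the metric: it drives alignment by white-matter
fiber structure, not by mean diffusivity.  The deviatoric diagonal is
evaluated as `(2a - b - c)/3`, which cancels exactly for isotropic tensors
in floating point.  Fractional anisotropy is computed by the Frobenius
formula `FA = sqrt(3/2)*||dev(D)||_F / ||D||_F` (no eigen-decomposition, so
slightly negative fitted eigenvalues need no clipping; a zero tensor has
FA = 0 by convention).

Tensor fitting is unweighted log-linear least squares of
`log S = log S0 - b g^T D g` per voxel.  Voxels with any non-positive
signal inside the mask are zeroed and flagged.  When two DWI acquisitions
are available they are averaged in signal space before fitting.

## Registration

A transform phi maps the template (output) grid into the subject volume in
world millimetres — pull-back resampling: `warped(x) = subject(phi(x))`.
phi is piecewise affine: a regular grid of blocks tiles the template
domain, each block carries an affine about its centre, and block maps are
blended with trilinear weights over the block centres, so phi is
continuous and differentiable almost everywhere.  A 1x1x1 grid is a global
affine.

The objective is the masked sum of squared deviatoric tensor distances
(sum of squared intensity differences for the scalar, T1-style baseline).
Optimization is multi-resolution coordinate search: at each pyramid level
(default factors 4, 2, 1, Gaussian-smoothed and strided, never below 8
voxels per axis) the 12 pose parameters per block (translation, rotation,
log-scale, shear) are probed with +/- steps, an accepted step is repeated
while it keeps improving, and steps are halved when a sweep stalls.  A
candidate block update is accepted only if the *full* blended objective
decreases (evaluated incrementally over the block's support), so objective
trajectories are non-increasing by construction.  Convergence: relative
decrease below 1e-4 over three sweeps, step exhaustion, or the sweep cap
(50).  Block determinants are kept within [0.25, 4], a prior on plausible
inter-subject volume change that also blocks degenerate collapses on small
grids.

Warped tensors are reoriented by the finite-strain rotation — the
orthogonal polar factor of the local linear part of phi.  During
optimization, the rotation of the block containing each voxel is used
(exact for global affines; the approximation error is second order in the
inter-block rotation differences); final resampling uses the exact
per-voxel rotation of the blended map, obtained by batch SVD.

Common coordinates follow the two-pass scheme: register every subject to a
designated template subject, average the warped volumes component-wise
(Euclidean averaging, matching the L2 objective), then re-register each
*original* subject volume to the mean; the second-pass transforms phi_s
project that subject's functional data into the common space.  The default
common grid for real data is 128 x 128 x 64 at 1.75 x 1.75 x 2.5 mm;
synthetic experiments run at 32^3 with 2 mm isotropic voxels.

`RegistrationConfig.fast()` (two pyramid levels, global affine, 12 sweeps)
is the schedule used for the 32^3 synthetic cohorts, where the ground-truth
deformations are dominated by their global-affine component; the full
default schedule adds 2x2x2 and 4x4x4 block refinements.

## Functional preprocessing and decoding

Runs are TR = 2 s, with trials Rest (8-16 s), Control (4 s), Attention
(8 s); the attention side is the label (+1 left / -1 right).  Pipeline per
run: drop the first 5 volumes; shift phase windows by the hemodynamic
delay (2 TRs = 4 s, configurable); per-voxel linear detrend; winsorize
samples beyond 4 MAD of the voxel median; average volumes within each
Attention phase; subtract the same trial's Control-phase mean; z-score
each voxel across the run's trials (a relative tolerance treats
machine-precision residue as zero variance).  Patterns are projected onto
the common grid through phi_s (trilinear) and restricted to an ROI, with
feature order the ascending voxel index so features align across subjects.
Optional supervised voxel selection ranks ROI voxels by the sum over
*reference* subjects of absolute Welch t statistics (left vs right trials);
the target subject's data never enters the ranking.

Decoders are soft-margin linear SVMs (C = 1, tol 1e-6, no class weights,
no rescaling beyond the per-run z-scores).  Conjunction: one SVM on all
reference subjects' trials pooled, tested on the held-out target
(leave-one-subject-out).  Naive voting: one SVM per reference subject;
majority vote, with an exact tie always scored as an error.  Self: within-
subject leave-one-run-out, accuracy averaged over folds.

## Discordance analysis

Each subject's native FA map is warped to the common grid through the
tensor route and through the scalar baseline route; the discordance map is
the voxel-wise mean over subjects of the absolute difference (signed
per-subject maps are retained).  Tissue classes are FA-threshold based on
the template: WM is FA >= 0.25 inside the brain mask, the edge of gray
matter is the GM shell 6-adjacent to WM, and the reported GM class
excludes that edge so the three classes are disjoint.  The "edge" rule is
this package's operationalization (threshold and connectivity are
configurable).  The upper tail of the discordance distribution in each
class is summarized by the exponential maximum-likelihood rate of the
exceedances over the class median, `a = 1/mean(x - threshold)`, with a
seeded bootstrap standard error; the median threshold is a package choice.

## Statistics

* Paired Wilcoxon signed-rank on per-subject accuracies; zero differences
  dropped, exact null distribution up to n = 25, normal approximation
  above.
* Jackknife area test: leave one subject out, fit OLS transfer-vs-self
  lines to both methods' retained points, integrate each line over its
  retained self-accuracy range, record the signed area difference.  The
  p-value is a one-sided t test on the jackknife pseudovalues (df n-1) —
  the pseudovalue construction is this package's choice; the raw
  leave-one-out differences are always returned so other summaries can be
  applied.  The integration range is the observed x-range per replicate.
* Surrogate distance test: observed statistic is the mean pairwise
  Euclidean distance among the selected subjects in the original feature
  space; surrogates redraw subsets of the same size uniformly without
  replacement (the observed subset may recur — the simplest exchangeable
  null); `p = (1 + #{surrogate <= observed}) / (1 + n_surrogates)`, which
  is super-uniform under the null by construction.
* PCA embedding of subject-by-parcel Jacobian features: mean-centred,
  components ordered by variance, each signed so its largest-magnitude
  loading is positive.

Deformation features are per-parcel means of the Jacobian determinant of
phi_s, computed from the analytic local linear part of the blended map
(weights are piecewise-linear, so the analytic Jacobian matches central
finite differences away from block boundaries).

## The synthetic cohort

The generator emulates the statistical structure the method assumes, not
brain anatomy: an ellipsoidal head holding a curved white-matter tract
(eigenvalues (1.7, 0.3, 0.3)e-3 mm^2/s, principal axis along the tract
tangent) that thins and thickens along its course so position along the
tract is anatomically identifiable; a weakly anisotropic gray-matter band
((0.9, 0.7, 0.7)e-3, radial axis); isotropic interior (2.5e-3).  Each
subject is a piecewise-affine deformation of the template (global
translation up to 2 voxels per axis, rotation up to 5 degrees, scaling
within 5%, plus 1 mm per-block jitter on a 2x2x2 grid; folding draws are
rejected), with tensor reorientation.  DWI: 30 directions at b = 1000
s/mm^2 on a golden-spiral lattice, S0 = 100, two acquisitions with
Gaussian noise (SD 2, Rician available) averaged in signal space.  A
pseudo-T1 volume (tissue intensities WM 1.0 / GM 0.7 / CSF 0.3, smooth
bias field, noise) drives the scalar baseline route.

Informative voxels sit in the gray-matter shell face-adjacent to the white
matter — the edge of gray matter.  Their side preference is a fixed
fine-grained pattern (the sign of a unit-smoothness Gaussian random field)
defined in template space and carried along by each subject's deformation:
functional elements occupy corresponding anatomical positions but form an
idiosyncratic spatial pattern, so voxel-level correspondence — i.e.
registration quality — determines whether the pattern transfers across
subjects.  During Attention, informative voxels gain +/- effect (1.0
z-units against noise SD 1.0, per-voxel drift SD 0.01/TR) according to
their preference and the attended side; Control adds the same symmetric
signal for both sides and carries no label information.  Subject 0 is the
undeformed template subject and is excluded from decoding.

Paper-scale runs are 25 trials x 5 runs; the desk-scale configuration used
by the tests and the acceptance script (`PhantomSpec.desk()`) uses 10
trials x 3 runs per subject, 6-8 subjects per cohort, and 32^3 grids —
sizes chosen so a full multi-cohort experiment runs on a laptop.

What passing synthetic tests shows: the geometry-handling, metric,
optimizer, decoders and statistics behave as specified, and the causal
chain the method posits (anatomy-locked functional patterns + anatomical
registration -> transferable decoders) holds end to end.  What it does not
show: performance on real brains — the phantom has no cortical folding,
physiological noise, motion, susceptibility distortion, or EPI-anatomy
misalignment, and its deformations are far smoother than real
inter-subject variability.

At the default effect size the synthetic decoders sit at ceiling (100%);
the acceptance script therefore also runs a low-SNR condition (effect
0.1 z, identical anatomy and registrations) so that transfer-vs-self
scatters have variance for the Wilcoxon, jackknife and surrogate
statistics.

## Known limitations

* The optimizer is a local pattern search; very large rotations or
  translations beyond the pyramid's capture range will not be recovered.
* Piecewise-affine blending is not diffeomorphic; invertibility is only
  monitored through the Jacobian sign.
* FA histograms change slightly under warping on coarse grids because
  trilinear interpolation smooths the sharp phantom boundaries; at 32^3
  this dominates the histogram-preservation error.
* The scalar baseline is a same-framework SSD registration, not a
  reimplementation of any specific neuroimaging package.
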