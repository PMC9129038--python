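# Methods

This note records the measurement conventions, model definitions,
generator assumptions and open design choices of `nucleofish`.

## Coordinate and distance conventions

Arrays are indexed `(z, y, x)`; physical coordinates are voxel-centre
based with the centre of voxel `(i, j, k)` at `(i·dz, j·dy, k·dx)` µm.
Default spacing is 0.15 µm in z and 0.1 µm in x/y — the z step of a
typical 100-plane acquisition, and a typical pixel size for a 63×/1.25
objective.  Bounding boxes are 0-based, half-open.  Distances are
reported to 3 decimals in µm.

**Signed border distance.**  The chromatin border lies between the last
mask voxel and the first background voxel, so a sub-voxel point inside
the mask measures to the nearest *background* voxel centre touching the
mask, and a point outside measures (negatively) to the nearest *mask*
voxel centre — the signed-EDT convention.  Measuring to the far side of
the interface keeps the error of the minimum one-sided: the documented
tolerance of all voxel-grid metrics is half a voxel diagonal (0.103 µm
at default spacing).  Sub-voxel surface interpolation is deliberately
not attempted; on simulated data the realised RMSE is about 0.02 µm,
an order of magnitude below the tolerance.  Negative distances are kept,
not discarded: peripheral signals just outside the thresholded chromatin
are real observations and removing them would bias against the
periphery.

**Local radius and relative distance.**  The local radius is the length
of the ray from the mask centroid through the spot centre to its first
exit from the mask, found by marching in steps of ¼ of the smallest
voxel spacing and reporting the midpoint of the bracketing samples.  A
spot coincident with the centroid has no ray; the equivalent-sphere
radius `(3V/4π)^(1/3)` is used by convention.  Relative distance is
`d / r` with the sign of `d` preserved.

**Equal-volume shells.**  Mask voxels are ranked by interior depth
(anisotropic EDT, array edges count as background) and split at the 1/3
and 2/3 rank boundaries, giving exact volume thirds on any shape; depth
ties at a boundary are broken by voxel index, deterministically.  The
reported thresholds `t1 < t2` sit midway between the flanking depths.
For a sphere of radius R the analytic values are `(1−(2/3)^{1/3})R ≈
0.126R` and `(1−(1/3)^{1/3})R ≈ 0.307R`.  A spot's shell comes from its
signed distance; negative distances are "outer".

**Ellipsoid fallback.**  When binarisation carves a bay-like background
region around a peripheral signal, raw border distances mislead.  The
fallback replaces the mask by the solid ellipsoid sharing its centroid
and principal axes (second central moments; a solid ellipsoid has
coordinate covariance `diag(a²,b²,c²)/5`), rescaled isotropically to the
mask volume.  It is applied per nucleus on request, or automatically
below a configurable solidity threshold (suggested 0.85, off by
default — in practice such nuclei are rare and best flagged by eye).

**Replication doublets.**  A locus replicated in S phase shows two DNA
signals.  When more signals than probe targets are found, signals within
the pairing radius (default 1.5 µm, configurable; no canonical value
exists) are paired by exhaustive minimisation of total within-pair
distance.  Distances and local radii are measured per member first and
averaged into one allele record, in that order.  Groups still exceeding
the expected allele count are flagged `excess`, excluded, and logged;
the brightest groups are kept.

## Segmentation and expression calls

Nucleus binarisation is Gaussian smoothing (1 voxel), Otsu threshold
within the ROI, 3D hole filling, largest connected component.  The
threshold is relative, so masks are invariant under intensity rescaling;
the known failure mode — low-density chromatin classified as background
— is what produces the negative-distance tail, and is reported in QC
rather than hidden.  A second component at ≥ 0.5× the largest raises an
ambiguity error asking for a tighter ROI.

Spot detection thresholds at median + k·(1.4826·MAD) (default k = 5)
and keeps 3D components of ≥ 4 voxels; each yields a
background-subtracted intensity-weighted centroid — more robust to noise
than the peak voxel.

Expression calling compares the maximum of the matched-filtered RNA
channel (Gaussian, 1 voxel) within 0.5 µm of the allele position against
the filtered nuclear background mean + k·SD (default k = 3).  Without
the matched filter the maximum of pure noise over a ~300-voxel
neighbourhood would routinely exceed 3 SD; filtering at the
diffraction-limited spot scale suppresses the noise maximum while
preserving a true transcription focus.  All three parameters are
exposed; none has a canonical published value.

## Statistical models

All models adjust for nuclear volume as a covariate.  The categorical
reference level is the paternal-pattern group (`matrepKO`,
`matIGDMRKO`) or the `near` allele, so a positive slope always means
"further from the border".  No multiple-testing correction is applied;
p-values are reported unadjusted.

- **DistanceModel** — OLS `distance ~ C(group) + volume` via
  statsmodels; rank-deficient designs and single-level predictors raise.
- **MixedDistanceModel** — REML linear mixed model with a per-cell
  random intercept (statsmodels MixedLM), fixed effects the per-cell
  expressed-allele count (0/1/2, reference 0) plus volume.  Degrees of
  freedom for the t tests use a containment-style approximation,
  `n_obs − n_cells − rank + 1`; this is an approximation and small
  drift in t/p relative to other software's df conventions is expected
  (estimates and SEs come straight from the REML fit, and are
  cross-checked against the R lme4 reference in the test suite).  With
  only singleton cells the model degenerates; an OLS fit is returned
  with a warning.  With zero between-cell variance the fixed effects
  reproduce OLS.
- **ExpressionModel** — ML logistic regression; the repeated-alleles
  option uses cluster-robust (by cell) standard errors on the
  fixed-effects fit — the package's chosen treatment of within-nucleus
  correlation for a binary outcome, in place of a full binomial GLMM.
  Complete separation raises with a diagnostic.
- **fisher_near_far** — two-sided Fisher exact test; the odds ratio is
  the conditional MLE, reported as log₂(OR), ±∞ on a zero cell.
- **shell_chisq** — Pearson chi-squared without continuity correction,
  df = (r−1)(c−1); zero margins raise.

## The synthetic-data generator

The generator defines the study conditions the tests run under.

**Image stacks** are ROI-sized (64×96×96 voxels ≈ 9.6 µm cubed, one
nucleus each) rather than full multi-position acquisitions — the
geometry is identical per nucleus and the smaller canvas keeps the whole
validation suite fast.  The nucleus is an ellipsoid (default semi-axes
2.6/3.2/3.6 µm) with a low-order spherical-harmonic radial perturbation
(degrees 2–3, peak amplitude 4%) standing in for the bay-like
irregularities of real chromatin outlines, without modelling texture.
Noise is Poisson shot noise plus additive Gaussian read noise (SD 3);
SNR is defined as (spot peak − background mean) / background SD and
defaults to 10 — no acquisition noise statistics were available, so the
default is a choice, not a derivation.  Spots are per-axis Gaussians
(σ 0.12 µm); no PSF anisotropy or deconvolution artefacts are modelled.
Spots are placed at voxel centres whose signed EDT is closest to each
requested true distance (within half a voxel diagonal), and the recorded
truth is the exact signed distance of the chosen voxel; negative
requests place the spot just outside the mask.

**Allele tables** draw, per cell: a log-normal nuclear volume
(log-mean 6.1 ≈ 446 µm³, log-SD 0.2 — a typical ES-cell nucleus), an
equivalent-sphere local radius, a shared N(0, 0.3 µm) cell intercept,
and per-allele distances N(group mean, group SD) truncated by rejection
to [−0.3 µm, local radius].  Default group means/SDs place maternal
alleles at 1.81 ± 1.00 µm and paternal at 1.58 ± 0.954 µm, with the
epigenotype-switch lines inheriting the localisation of their expressed
pattern and WT lines at the midpoint.  Expression is Bernoulli with
logit `−0.034 + 0.5·d`, i.e. ≈ 70.5% expressed at the maternal mean.
Deletion lines carry one allele, all other lines two; three replicate
lines per genotype, cells assigned round-robin.

The truncation matters when interpreting recovery tests: it shifts the
realised group means upward by a few hundredths of a µm and attenuates
the realised between-cell SD (≈ 0.43 µm realised for 0.5 µm configured).
Recovery is therefore always judged against the generator's *realised*
parameters, computed by an independent oracle (Gauss–Hermite integration
of the truncated-normal mean over the volume and intercept
distributions, or large-n allele-pair covariance), never by loosening
tolerances.

**What the generator does not emulate:** chromatin texture and
intensity inhomogeneity, neighbouring/touching nuclei, optical PSF
tails, deconvolution artefacts, z-dependent attenuation, or cell-cycle
structure beyond the volume distribution.  Passing tests demonstrate
that the measurement chain is correct on data satisfying the model's
assumptions; they do not certify segmentation quality on hard real
images.

## Problem sizes and numerical choices

The validation suite uses 200 random masks ≤ 40³ voxels for exhaustive
border-scan equivalence, 50 rendered nuclei for end-to-end recovery,
600 cells/group for effect recovery, 1 000 replicates for type-I error
calibration, and full enumeration of all 2×2 tables with margins ≤ 30
for the Fisher oracle.  The acceptance script mirrors these at 50
nuclei / 600 cells / 500 replicates.  These sizes are the package's
choices for tight, fast, statistically meaningful checks.

Ties in near/far ranking are broken by allele id and flagged; mixed
model optimisation falls back from the default optimiser to Powell on
numerical failure; all simulation randomness flows from a single seed
through `numpy.random.default_rng`, and identical configs with identical
seeds are bit-reproducible.

## Known limitations

- Sub-voxel surface interpolation is not performed; all grid metrics
  carry the half-voxel-diagonal tolerance.
- The mixed-model df approximation is containment-style, not
  Satterthwaite; t/p values can drift slightly from lme4/lmerTest.
- The binary GLMM is approximated by cluster-robust logistic SEs.
- Expression calling is automated and threshold-based where a human
  scorer would integrate context; k is exposed for calibration.
- 2D analysis, nucleolus/speckle sub-compartments, deconvolution and
  manual nucleus curation are out of scope.
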