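# Methods

This note records the models, the parameter choices that matter, what the
synthetic data do and do not emulate, and the numerical decisions a
maintainer would want to know.

## The problem

Automated MS/CIS monitoring needs two quantities per scan session: total
white-matter-lesion volume and per-class brain tissue volumes (CSF, GM, WM;
TIV = their sum).  Conventional pipelines take a 3-D T1 plus a T2-FLAIR;
clinical protocols often provide only the FLAIR.  The package implements a
FLAIR-only stream for both quantities and the statistics used to compare it
against the conventional stream.

## Lesion segmentation (mixture model)

**Model.**  Brain-voxel intensities (1 channel FLAIR, or 2 channels
FLAIR+T1) follow a finite Gaussian mixture in which every component belongs
to a tissue class.  An anatomical parcellation enters twice: it initialises
per-class means/covariances (no k-means, fully deterministic), and it
supplies a per-voxel spatial prior — a relaxed one-hot with relaxation
ρ = 0.1, i.e. 90 % of the prior mass on the parcellation label and 10 %
spread by global class frequency.  The relaxation absorbs parcellation
errors; it must stay small for model selection to behave, because prior
mass spread across classes acts as model misspecification that the forward
search would otherwise fit with spurious components.

**Model selection.**  Greedy forward search starting from one component per
class: split the highest-variance inlier component of a class along its
principal axis, refit by EM, accept the best split if BIC decreases, stop
when nothing improves or at 3 components/class.  BIC uses the number of fitted
voxels; parameters counted as (K_c − 1) weights plus K_c·(d + d(d+1)/2) per
class.

**Abnormality (lesion candidates).**  The WM class carries one candidate
outlier component, seeded at the mean of WM-labelled voxels whose FLAIR
intensity exceeds the WM mean by 2 SD.  The seed is a tail *mean* rather
than a per-channel mean shift so that it stays on the joint-intensity
manifold with two channels (a shifted seed lies off the data cloud and
starves).  Two safeguards make the outlier identifiable:

* *Justification*: after model selection the model is refitted without the
  candidate; the candidate survives only if BIC prefers keeping it.  On
  lesion-free data the outlier therefore vanishes entirely.
* *Role re-derivation*: after fitting, a non-dominant WM component is marked
  abnormal only if its FLAIR mean lies above the dominant component of
  *every* class by 2 of that component's FLAIR SDs.  GM/WM partial-volume
  components (which model selection legitimately adds) thus remain inliers.

**Post-processing.**  The outlier posterior map is binarised at 0.5;
26-connected components are kept if their volume is at least that of a 3 mm
sphere ((4/3)π·1.5³ ≈ 14.14 mm³ — enforced in mm³ so anisotropic spacings
behave), their centroid lies within WM or its one-voxel boundary band, and
their mean FLAIR intensity exceeds the WM mean.  Surviving components are
then grown by hysteresis into 26-adjacent voxels with posterior ≥ 0.1 inside
the WM band.  The growth step recovers the partial-volume lesion rim, whose
posterior falls below the 0.5 cut and whose omission biases the segmented
volume low, most visibly at the noisier 1.5T preset.  The 0.1 cut sits well
above the near-zero posterior level immediately *outside* lesions, so growth
terminates at the true boundary rather than leaking.

**Numerics.**  EM stops when the relative log-likelihood change is < 1e-6 or
at 200 iterations; the log-likelihood trajectory is stored and is
non-decreasing.  Covariances are floored at (0.01·channel SD)² — this also
keeps the duplicated-channel (rank-deficient) case well-posed.  Components
starved below d+1 effective voxels are pruned with a warning.  Beyond 25 000
brain voxels the EM fits a deterministic stride subsample (statistically
indistinguishable at these SNRs); candidate posteriors are always evaluated
at full resolution.  Ties in posterior argmax resolve to the lowest class
index.

## Tissue segmentation (multi-atlas)

Affine-family registration → nearest-neighbour label propagation →
locally-weighted voting.  The vote of atlas *a* at voxel *v* is
exp(−MSD_patch(a, v)/h²), with MSD the mean squared intensity difference
over a 3³ patch.  The bandwidth h is global and noise-scaled:
h² = 2·σ̂², with σ̂ the median 3³-patch SD over brain-intensity voxels.  A
*local* patch-SD bandwidth (the more obvious choice) is structure-dominated
exactly at tissue boundaries, where it flattens the weights and lets
misaligned atlases erode thin structures such as the CSF shell; the global
noise scale keeps boundary votes sharp.
Posteriors are the normalised weighted votes; labels their argmax (ties to
the lowest class index); volumes are reported from the posterior sums
("soft" counting) by default, with hard-label counting available.

Registration modes: full affine (SimpleITK multi-resolution, Mattes mutual
information across modalities, correlation within, full sampling so runs are
deterministic), "moments" (closed-form: intensity centre-of-mass translation
plus per-axis scaling from second moments), "translation", "identity".  The
pipeline default is "moments": the synthetic atlases and targets are
generated rigidly aligned up to a global head-size factor, which moments
capture at negligible cost; full affine adds little accuracy on these
phantoms at many times the runtime and remains available per config.

The FLAIR-capable database is built by registering each atlas subject's
FLAIR to its own T1 and propagating the T1 labels onto the FLAIR grid;
entries then support either input modality.

This fusion scheme is a deliberately simple, affine-only stand-in for
geodesic label-propagation pipelines; it preserves the tested contract
(multi-atlas, dual-modality database, FLAIR-only capability) at desk scale.

## Inpainting

Onion-peel patch matching: lesion voxels are filled boundary-inward, each
taking the centre value of the minimum-mean-squared-difference patch (3³
patch, 15³ search window) among originally non-lesion candidates; filled
voxels become patch support for deeper layers; ties resolve to the smallest
window-linear index, so the operation is deterministic.  The one-voxel
perilesional rim is never modified but is excluded from patch *evidence*:
its partial-volume-brightened intensities would otherwise drag the fill
bright from the first layer inward; with the rim excluded the fill is
distribution-matched to the surrounding WM (asserted by a two-sample
Kolmogorov–Smirnov test in the suite).  Masks covering more than half the WM
are refused.  Fallbacks when a window holds no candidate: double the window
once, then copy the nearest non-lesion voxel with a warning.

## Synthetic phantoms (what they emulate, what they do not)

A phantom subject is a nested set of smoothed ellipsoid compartments
(background, CSF shell, GM ribbon, WM core, ellipsoidal ventricles) on a 64³
grid at 1 mm isotropic spacing, with focal ellipsoidal WM lesions
(default 3 lesions, diameters uniform in 5–10 mm with ±15 % axis jitter,
placed fully inside WM, non-overlapping, ≤ 100 placement attempts each — the
rasterised component always exceeds the 14.14 mm³ sphere-volume bound).
Intensity presets (arbitrary units): FLAIR CSF 30 / WM 55 / GM 70 /
lesion 95; T1 CSF 30 / GM 60 / WM 85 / lesion 60 (T1-isointense to GM).
Noise SDs: FLAIR 8 (1.5T) vs 5 (3T); T1 6 vs 4 — the 3T presets model the
higher SNR of the higher field.  The noise-free image is smoothed with a
σ = 0.6 voxel Gaussian (a crude partial-volume/PSF surrogate) before white
Gaussian noise and a smooth multiplicative quadratic bias field (amplitude
5 %) are applied.

Atlas databases are lesion-free phantoms whose anatomy is deformed by a
smooth random displacement field (Gaussian-filtered white noise, σ = 8
voxels, RMS amplitude 2 mm by default); fields that fold space (non-positive
Jacobian determinant) are rejected as compartment inversion.

Cohorts inject biology: age uniform in 18–59 years; target GM volume
500 ml − 1.5 ml/yr·(age − 38.5) + N(0, 5 ml); a per-subject head-size factor
(±3 % SD on all compartments) gives TIV its own variance so it is a
meaningful covariate.  Since 500 ml of GM cannot fit in 64³ mm³, the cohort
voxel size is derived once from the target mean (≈ 2.7 mm isotropic) and the
GM outer semi-axes are solved analytically per subject.  Paired 1.5T/3T
cases share anatomy and lesions (only the contrast preset differs), like a
same-week rescan; consequently their *ground-truth* volumes are identical,
and GLM calibration uses one field row per subject to avoid double-counting.

What passing tests on these phantoms do **not** show: robustness to real MR
artefacts (motion, ghosting, strong bias fields, partial-volume mixing
beyond the σ = 0.6 surrogate), to real anatomical variability (the anatomy
is ellipsoidal, deformations smooth and small), to non-focal or
juxtacortical pathology, or to acquisition heterogeneity across scanners.
The field-strength presets differ only in noise level, not in contrast or
resolution.

## High-lesion-load conditions

The phantom brain holds ~25 ml of WM, so absolute lesion loads of the
"radiologically advanced" kind (≈ 15 ml in an adult brain, about 3 % of WM)
cannot be reproduced literally.  The package's high-load condition instead
plants ~4 ml (8 lesions of 8–12 mm), i.e. ~15 % of the phantom's WM —
proportionally several times harsher than an adult 15 ml load.  Under it the
two *filled* inpainting modes agree on GM volume to well under 1 %, and the
joint pipeline's GM error stays under 5 %; segmenting entirely uncorrected
images at that extreme load begins to bias GM measurably, which is why
inpainting is on by default.

## Statistics

Conventions, each chosen once: Dice of two empty masks is 1.0 (flagged);
through-origin regression uses β = Σxy/Σx², SE² = (RSS/(n−1))/Σx², uncentred
R² = 1 − RSS/Σy², and Gaussian AIC = n·ln(RSS/n) + 2k (k = 1 without, 2 with
intercept; an exact fit replaces AIC by a −1e12 sentinel and sets a flag).
The Wilcoxon signed-rank test drops zero differences, mid-ranks ties, returns
W = min(W⁺, W⁻), and computes the two-sided p by full sign-pattern
enumeration for n ≤ 12 (also under ties, which scipy's exact method refuses)
and by a normal approximation with tie and continuity correction beyond.
Cohen's f uses full- vs reduced-model R² (the reduced model drops age).  No
multiple-testing correction is applied; p-values are reported raw.  IQRs use
linear-interpolation (type-7) quantiles.  The "top decile of lesion load"
subset takes ⌈0.1·n⌉ subjects, at least one.

## Problem sizes

Defaults were sized for a single-CPU desk run: 64³ phantoms, 10-atlas
databases, 20-seed ensembles per field preset for lesion recovery, a
20-subject cohort for the method-agreement regression, 2000 null simulations
for test calibration, and 20 repeats of n = 60 cohorts for GLM power.  The
acceptance script uses 10-seed ensembles and a 12-subject cohort and
completes in a few minutes.

## Known limitations

* The lesion segmenter assumes lesions are FLAIR-hyperintense relative to
  every tissue class; subtle or T1-black-hole-only lesions are out of reach.
* Components dominated by lesion (more than ~half of WM) break the
  dominant-component heuristic and the inpainting guard refuses first.
* Affine-family registration only; anatomies requiring non-linear alignment
  will degrade fusion accuracy gracefully but measurably.
* The 2-channel path assumes the T1 is already resampled onto the FLAIR
  grid; the package provides the registration tools but does not second-guess
  the caller's resampling.
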