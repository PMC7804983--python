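# flairvol

Joint volumetric analysis of white-matter lesions and brain tissue from a
single T2-FLAIR image.

In multiple sclerosis and its precursor, clinically isolated syndrome (CIS),
two MRI quantities matter for monitoring: the total volume of white-matter
lesions, and brain tissue volumes (grey matter atrophy in particular).
Conventional automated pipelines need both a 3-D T1-weighted scan (for tissue
volumetry) and a T2-FLAIR scan (for lesions), but clinical MS protocols often
omit the 3-D T1.  `flairvol` implements and evaluates a FLAIR-only
alternative: unsupervised Gaussian-mixture lesion segmentation, multi-atlas
tissue segmentation driven by a FLAIR-capable atlas database, patch-based
lesion inpainting in between, and the comparison statistics needed to judge
the FLAIR-only stream against the conventional T1 / T1+FLAIR one.

Because no study images ship with the package, everything is exercised on a
built-in synthetic brain phantom generator with exact ground truth (paired
T1/FLAIR volumes at 1.5T and 3T contrast presets, 4-class anatomy, focal WM
lesions ≥ 3 mm diameter).

## Methods at a glance

* **Lesion segmentation** (`flairvol.mixture`) — a finite Gaussian mixture
  over brain voxels with components tagged per tissue class (CSF/GM/WM),
  a relaxed spatial prior from an anatomical parcellation, and greedy forward
  model selection: a class's highest-variance component is split and the
  refit kept only if BIC = −2 log L + k ln n decreases.  The WM class carries
  a candidate *outlier* component seeded on the hyperintense FLAIR tail; its
  posterior is thresholded (0.5), filtered by a minimum-diameter rule
  (volume ≥ (4/3)π(d/2)³ with d = 3 mm), parcellation location and intensity
  rules, and grown by hysteresis to recover partial-volume lesion rims.
  Works FLAIR-only (1 channel) or FLAIR+T1 (2 channels).
* **Tissue segmentation** (`flairvol.atlas`) — affine registration of each
  atlas subject to the target, nearest-neighbour label propagation, and
  locally-weighted fusion: atlas *a*'s vote at voxel *v* is
  exp(−MSD_patch(a, v)/h²).  A FLAIR-capable database is built by propagating
  each atlas subject's T1 labels onto its co-registered FLAIR.
* **Inpainting** (`flairvol.inpaint`) — deterministic onion-peel patch-match
  filling of lesion voxels (modes: uncorrected / manual-filled /
  outlier-filled), so lesion hyperintensity does not bias tissue volumes.
* **Statistics** (`flairvol.stats`) — Dice 2TP/(2TP+FP+FN), directional and
  symmetric volume-difference measures, through-origin regression
  (β = Σxy/Σx², uncentred R², Gaussian AIC), Wilcoxon signed-rank (exact
  enumeration for n ≤ 12), paired t, Cohen's f, and a GM-volume ~ age + TIV +
  field GLM.
* **Pipeline** (`flairvol.pipeline`) — the joint FLAIR-only run
  (parcellate → segment lesions → inpaint → re-parcellate) and the full
  method-comparison experiment over a paired 1.5T/3T cohort.

## Worked example

```python
import flairvol as fv

# a 3T phantom subject with WM lesions, plus a 10-subject atlas database
case = fv.generate_phantom(fv.PhantomSpec(seed=5, lesion_count=4))
db = fv.generate_atlas_database(10, fv.PhantomSpec(seed=42, lesion_count=0))

result = fv.run_joint_flair(case.flair, db, fv.PipelineConfig(seed=1))
print(f"lesions: {result.lesions.volume_ml:.2f} ml "
      f"(truth {case.truth_lesions.volume_ml:.2f} ml, "
      f"dice {fv.dice(result.lesions, case.truth_lesions):.3f})")
v, t = result.volumes, fv.compute_tissue_volumes(case.truth_tissue)
print(f"GM {v.gm_ml:.1f} ml (truth {t.gm_ml:.1f}), TIV {v.tiv_ml:.1f} ml")
```

prints

```
lesions: 1.49 ml (truth 1.50 ml, dice 0.976)
GM 25.4 ml (truth 25.7), TIV 74.5 ml
```

i.e. from the FLAIR image alone the pipeline recovers the planted lesion
volume within ~1 % with voxel overlap 0.98, and the grey-matter volume within
~1.5 % of the phantom ground truth (volumes are on the 64³·1 mm phantom scale).

The same objects drive the command line:

```bash
flairvol make-atlas --n 10 --seed 42 --out db/
flairvol phantom --n 1 --lesions 4 --seed 5 --out case/
flairvol joint --flair case/case000_flair.nii.gz --db db/ --out out/
```

## Layout

```
src/flairvol/
  core.py      image/label/mask data model, NIfTI I/O, volume accounting
  phantom.py   synthetic subjects, atlas databases, cohorts with an age effect
  mixture.py   GMM lesion segmentation with BIC model selection
  inpaint.py   patch-based lesion filling
  atlas.py     registration, label propagation, locally-weighted fusion
  stats.py     agreement statistics, regressions, tests, effect sizes
  pipeline.py  joint FLAIR-only run and the comparison experiment
  cli.py       `flairvol` command-line interface
docs/methods.md  model assumptions, parameter choices, limitations
```
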