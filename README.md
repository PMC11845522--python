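# labnorm

Geometry-preserving spatial normalization of multisubject inner-ear MRI.

The bony labyrinth is tiny (a few hundred mm³) compared with everything
else in a head scan, and its anatomy — the diameters and orientations of
the semicircular canals in particular — varies widely between subjects.
Whole-image rigid registration therefore tends to align the large, bright
structures (brainstem, petrous bone) at the expense of the inner ear, and
any transform with more degrees of freedom (affine, nonlinear) would
destroy exactly the geometric information that morphometric studies of
the labyrinth need.  `labnorm` implements and compares four *rigid-only*
ways of bringing subject volumes into an inner-ear atlas space, together
with the evaluation machinery used to decide between them:

* **3P** — semi-manual three-point registration: the closed-form
  least-squares rigid transform (Kabsch/SVD with determinant correction,
  no scaling term) fitted to three anatomical fiducials — the lateral
  pole of the posterior semicircular canal, the superior apex of the
  superior canal, and the cochlear apex — with the fiducial registration
  error (FRE) reported per fit.
* **TIE** (thick inner ear) — rigid Mattes mutual-information
  registration whose metric is sampled only inside a volumetrically
  dilated, atlas-derived inner-ear mask.
* **ANTs-like / Elastix-like** — the same engine unmasked, as baselines
  for what unaided automatic registration does.
* **Evaluation** — method-wise voxelwise median volumes; ROI-masked
  colocalization against the atlas (Costes auto-threshold, thresholded
  Manders split tM1/tM2, Pearson/Spearman correlation, OLS regression);
  and the statistics battery for Likert rating tables (per-method
  summaries, insufficiency rates, one-way ANOVA with Bonferroni post-hoc
  comparisons and pooled-SD Cohen's *d*, Welch's t, Spearman/Kendall
  inter-rater agreement).

Because patient data cannot ship with the package, all end-to-end
behaviour is exercised on a **synthetic labyrinth phantom**: an analytic
union of three near-orthogonal canal tori, a vestibular ellipsoid and a
conical cochlear spiral, rasterized by signed distance with a soft edge,
posed rigidly, blurred and noised — with exact ground-truth landmarks,
mask and pose.  An optional bright brainstem-like distractor reproduces
the failure mode that motivates masking.

## Worked example

```python
from labnorm import (RegistrationConfig, RigidTransform, make_tie_mask,
                     register_rigid, target_registration_error)
from labnorm.phantom import default_spec, generate_phantom, make_atlas

atlas, atlas_truth = make_atlas()                    # noise-free reference
mask = make_tie_mask(atlas, "otsu", 5)               # dilated inner-ear mask

pose = RigidTransform.from_euler((8, -5, 12), (3, -2, 1.5))
subject, truth = generate_phantom(default_spec(pose=pose, seed=11))

cfg = RegistrationConfig.preset("tie", fixed_mask=mask, random_seed=17)
res = register_rigid(subject, atlas, cfg)
tre = target_registration_error(res.transform, truth.landmarks,
                                atlas_truth.landmarks)
print(f"converged={res.converged}  landmark TRE {tre:.3f} mm")
```

prints

```
converged=True  landmark TRE 0.006 mm
```

i.e. the mask-aided registration recovers the 8–12° / few-mm pose to a
small fraction of the 0.5 mm voxel size, measured at the three anatomical
fiducials.  The `examples/` directory walks through every capability
(phantoms and preprocessing, 3P, masked vs. unmasked registration with a
distractor, group medians and colocalization, rating statistics), and the
same machinery is available from the shell:

```sh
labnorm phantom --n 12 --seed 7 --out-dir cohort/
labnorm register --method tie --moving cohort/sub000.nii.gz \
    --atlas cohort/atlas.nii.gz --mask tie_mask.nii.gz --seed 17 \
    --out sub000_tie.nii.gz
labnorm run --n 12 --seed 1 --out-dir demo/     # full pipeline
```

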