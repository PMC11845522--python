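# Methods

This note documents the models, conventions and numerical choices behind
`labnorm`, and what the synthetic phantom does and does not show about
real data.

## Coordinate and transform conventions

Physical space is a right-handed, RAS-like millimetre frame.  A voxel
with 0-based index (i, j, k) has its *center* at
`origin + direction · (spacing ⊙ (i, j, k))`, with `direction`
orthonormal.  The first physical axis is left–right, so "the sagittal
plane" is a plane of constant first coordinate.  Source images may use
either scanner or viewer conventions; we fix this one convention for
everything in the package rather than guessing what any particular
acquisition used, and the NIfTI reader simply trusts the header.

A `RigidTransform` is `p' = R(p − c) + c + t` with `RᵀR = I` and
`det R = +1` enforced at construction and re-checked after every
composition/inversion, so scaling, shear and reflection are excluded *by
type*.  Transforms map moving-space points into fixed (atlas) space;
resampling onto the atlas grid uses the inverse mapping, as is standard.

Mirroring a left ear to right-ear orientation is an index flip along the
left–right axis with unchanged grid geometry (not a negative-determinant
direction matrix), which keeps every volume right-handed and makes the
operation an exact involution.

## Preprocessing

Two-fold upsampling uses separable tricubic Catmull–Rom interpolation
(a = −0.5) on all three axes.  The slice-based tools this emulates call
this "bicubic", but on isotropic 3D data a 2D kernel would leave one
axis nearest-neighbour, so the 3D separable form is the faithful
reading.  Output convention: exactly 2n voxels per axis at half spacing,
voxel centers at quarter-spacing offsets covering the same field of
view (origin shifts by −spacing/4).  Boundaries are padded by linear
extrapolation, so polynomials up to degree 1 are reproduced exactly up
to the edge — that property, not smoothness, is what the tests pin down.
Cropping keeps the physical position of every retained voxel by moving
the origin.

## Three-point registration (3P)

With exactly three non-collinear point pairs the least-squares rigid
problem has a closed-form solution: align centroids, SVD the 3×3
cross-covariance, and flip the sign of the smallest singular direction
if the best orthogonal map would be a reflection.  No iterative
optimiser, hence no ties or tolerance knobs.  Note that three centered
points give a rank-2 cross-covariance, so the sign of the null
direction is numerical noise; the implementation applies the correction
silently in that case and only logs a reflection warning when the
smallest singular value is genuinely nonzero.  No scaling term is
fitted even though three points would admit one: geometry preservation
is the premise of the whole pipeline.

The fiducial registration error (RMS residual at the fitted landmarks)
is always computed; fits with FRE above a configurable threshold
(default 2 mm, roughly four working-resolution voxels) are *flagged*
rather than rejected, since a bad FRE usually means a mis-clicked
landmark that a human should re-inspect.

## Intensity registration and the TIE mask

One engine (SimpleITK's registration framework) serves three presets —
`tie`, `ants-like`, `elastix-like` — that differ only in the
fixed-image mask and in optimizer step constants.  This reflects the
design position that the accuracy difference between masked and
unmasked registration comes from *where* the similarity metric is
sampled, not from optimizer details.  Common settings: Mattes mutual
information with 32 bins; rigid (Euler) transform initialised by
aligning the geometric centers of the two image domains; 3-level
pyramid (shrink 4/2/1, Gaussian smoothing 2/1/0 mm); regular-step
gradient descent with physical-shift parameter scaling.  By default the
metric is evaluated *densely* at every (masked) fixed voxel center:
random off-lattice sampling biases the sampled-metric optimum by about
0.1°, which is the same order as the accuracy the whole pipeline is
after, and on a small masked problem dense evaluation costs almost
nothing.  Fractional random sampling remains available
(`sampling_fraction < 1`), seeded for reproducibility and with the
per-level fraction scaled by the shrink factor cubed so the *number* of
samples stays roughly constant across pyramid levels — without this, a
masked metric at shrink 4 is estimated from a few dozen samples and the
coarse level loses its basin-finding purpose.  The engine runs
single-threaded, so results are bit-reproducible per seed.
A full-grid mask is detected and dropped, making masked and unmasked
runs identical in that limit by construction.

The TIE mask is built by thresholding the atlas (Otsu by default),
then dilating with an exact Euclidean ball (computed via a distance
transform, so the result equals lattice-point enumeration).  The
default dilation is 2.5 mm of physical thickness — 10 voxels on a
0.25 mm upsampled grid, 5 on the 0.5 mm phantom grid used in tests;
the radius is expressed in voxels and configurable.

"Non-convergence" is not defined by the optimizer alone: a run counts
as non-converged when the iteration cap is hit at the finest level *or*
the final transform leaves sanity bounds (rotation > 45°, or
displacement beyond half the fixed field of view relative to the
center-aligning initialisation).  Failures are reported in the result
object, never raised, because group pipelines must continue past
individual failures.  No hyper-parameter search was run for any preset;
the point of the comparison is the masking, and tuned optimizers would
blur that.

## Median volumes and colocalization

The group result of a method is the voxelwise median of its registered
volumes (even counts: mean of the central pair — the rule must be total
even though the motivating cohorts are odd-sized).  Agreement with the
atlas is quantified inside a mandatory ROI mask; without it the
abundant background voxels dominate and manufacture false-positive
colocalization.

Costes auto-threshold: orthogonal (total-least-squares) regression
ch2 ≈ a·ch1 + b over ROI voxels, then a sweep of T downward through the
distinct observed ch1 intensities (data-adaptive rather than a fixed
step, hence exact and reproducible), stopping at the largest T for
which the Pearson correlation of voxels with ch1 < T and ch2 < a·T + b
is ≤ 0.  Membership is evaluated as `max(ch1, (ch2−b)/a) < T`, which
lets the whole sweep run on prefix sums after one sort (O(n log n)
instead of O(n²)); the two membership formulations differ only on exact
floating-point boundary ties.  A whole-ROI correlation ≤ 0 (or a
non-positive regression slope) short-circuits to a flagged
"no positive colocalization" result at the channel maxima; if the
below-threshold correlation never reaches 0 the threshold descends to
the minimum observed intensity.

Manders split coefficients follow the thresholded definition
(tM1 = fraction of ch1 intensity where ch2 exceeds its threshold, and
symmetrically), with negative intensities clipped to zero (count
logged) so the coefficients stay in [0, 1].  Spearman rho is computed
over the full ROI (not only above-threshold voxels — the alternative
exists in the literature but is not what we do), alongside Pearson and
an OLS line of image on atlas.

## Rating statistics

Grades live on the 6-point Likert scale with half-steps (1 best, 6 =
no alignment/non-convergence).  "Insufficient" means grade ≥ 5.0, which
includes the half-step 5.5; the cutoff is configurable.  The default
ANOVA observation is the per-dataset mean grade across raters — for a
4-method, 153-dataset, 3-rater table this gives 612 observations and
within-groups df 608 — with fully pooled per-rating observations as a
documented alternative.  Cohen's d divides a pairwise mean difference
by the *all-groups* pooled SD (the root of the ANOVA within-group mean
square; for equal group sizes the root of the average group variance).
This is the convention that makes effect sizes reproducible from
published per-group moments alone.  Post-hoc p-values are classical
pooled-variance t tests Bonferroni-multiplied by the number of pairwise
comparisons (6 for four methods), capped at 1.  Inter-rater agreement
is pairwise Spearman rho (rank baseline differences between raters make
kappa-style chance correction misleading here) plus Kendall tau-b for
sensitivity to the heavy ties a half-step Likert scale produces.
Grades are treated as interval data throughout; an ordinal-regression
treatment would be defensible but is deliberately out of scope.

## The phantom

The phantom is the package's stand-in for patient MRI: three partial
canal tori with near-orthogonal plane normals (pairwise plane angles
within 90° ± 20° enforced), ring radii 3.2–3.6 mm, tube radius 0.9 mm;
a vestibular ellipsoid (2.5 × 1.8 × 1.5 mm semi-axes); a conical
cochlear spiral (2.5 turns, 3 mm base radius, 4.5 mm height, 0.8 mm
tube).  Fluid intensity 100 on background 10, Gaussian blur σ = 0.4 mm,
additive Gaussian noise SD 5 (Gaussian rather than Rician: high-SNR
magnitude MRI is near-Gaussian).  The default grid is 64³ at 0.5 mm —
the acquisition resolution of the motivating data and a size at which
the full registration battery runs in minutes on one CPU; the geometry
is resolution-independent, so finer grids are a spec change away.
Rasterization evaluates the exact union signed distance at voxel
centers and maps it to occupancy over a one-voxel soft edge; hard
binary voxelization would alias canal tubes of ~2-voxel diameter and
make mutual information both artificially easy (stair-step texture) and
unstable.

Ground truth comes with every phantom: the three fiducials are computed
analytically (in-plane extreme of the posterior torus along +x, of the
superior torus along +z, clamped into the arc; spiral endpoint for the
cochlear apex) and transformed by the generating pose, so landmark
truth is exact to machine precision and moves exactly with the pose.
Left-ear phantoms are generated by analytically mirroring the geometry,
which makes `mirror_sagittal(left) == right` hold to float precision on
the symmetric default grid.

Cohorts jitter pose (uniform ±10° / ±4 mm by default — plausible
inter-subject crop variation, chosen once, not fitted to anything),
canal ring radii (5 % relative SD) and canal plane normals (4° SD),
with independent per-member noise streams.  The optional distractor is
a 6 mm-radius bright sphere, present in atlas and subjects but offset
by up to ±3 mm per axis in each subject, so its best alignment
*conflicts* with the labyrinth's — the mechanism by which unmasked
registration fails on real crops.  The demo pipeline includes it by
default.

What passing phantom tests shows: the geometry of the machinery —
metric masking helps when a dominant structure disagrees with the
target structure, landmark fits are exact, the evaluation statistics
are correct.  What it does not show: performance under real tissue
contrast, bias fields, partial voluming, pathology, or human landmark
placement error; the phantom's intensity model is far simpler than
T2-SPACE anatomy, and its "manual" landmarks are exact unless noise is
explicitly added.

## Experiment sizes

The packaged studies use 100 poses for landmark exactness, 20 poses for
mask-aided recovery (±15° / ±5 mm), 10 distractor phantoms for the
masked-vs-unmasked comparison, and a 12-subject demo cohort — sizes at
which every conclusion they support is stable across seeds while the
whole battery stays in the minutes range on a single CPU.

## Known limitations

* The intensity-registration presets are named "ants-like" and
  "elastix-like" as descriptions of configuration style, not claims of
  binary fidelity to those toolboxes.
* The Costes sweep's prefix-sum formulation can, in principle, disagree
  with the direct-membership formulation on exact floating-point
  boundary ties; this is unobservable in practice and the tests compare
  against the direct oracle.
* Rating statistics treat Likert grades as interval data.
* The phantom cannot validate landmark *selection*, only landmark
  *fitting*; inter-observer click variability is supported via an
  optional noise parameter but not modelled from data.
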