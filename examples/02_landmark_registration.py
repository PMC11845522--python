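"""Three-point (3P) landmark registration of a posed phantom to the atlas.

The semi-manual workflow: pick the three fiducials on the subject scan,
fit the closed-form rigid transform to the atlas fiducials, resample.
Here the phantom's analytic ground-truth landmarks play the role of the
manual clicks, optionally with added localisation noise.
"""

import numpy as np

from labnorm import (
    LandmarkTriplet,
    RigidTransform,
    fit_rigid_from_landmarks,
    resample_linear,
)
from labnorm.phantom import default_spec, generate_phantom, make_atlas

atlas, atlas_truth = make_atlas()

pose = RigidTransform.from_euler((8.0, -5.0, 12.0), (3.0, -2.0, 1.5))
subject, truth = generate_phantom(default_spec(pose=pose, seed=11))

# noiseless clicks: exact recovery of the inverse pose
fit = fit_rigid_from_landmarks(truth.landmarks, atlas_truth.landmarks)
resid = fit.transform.compose(pose)
print(f"noiseless fit:  FRE {fit.fre_mm:.2e} mm, "
      f"pose residual {resid.rotation_angle_deg():.2e} deg / "
      f"{resid.translation_magnitude():.2e} mm")

# 0.5 mm click jitter: FRE and residual grow accordingly
rng = np.random.default_rng(0)
noisy = LandmarkTriplet.from_array(truth.landmarks.as_array() + rng.normal(0, 0.5, (3, 3)))
fit_n = fit_rigid_from_landmarks(noisy, atlas_truth.landmarks)
resid_n = fit_n.transform.compose(pose)
print(f"0.5 mm jitter:  FRE {fit_n.fre_mm:.3f} mm, "
      f"pose residual {resid_n.rotation_angle_deg():.2f} deg / "
      f"{resid_n.translation_magnitude():.2f} mm, suspect={fit_n.suspect}")

registered = resample_linear(subject, fit.transform, atlas)
sel = atlas_truth.labyrinth_mask.voxels
r = np.corrcoef(registered.voxels[sel], atlas.voxels[sel])[0, 1]
print(f"registered-vs-atlas correlation inside the labyrinth: {r:.4f}")
# FRE is the residual at the fitted fiducials; the pose residual is the
# actual alignment error, which stays small while clicks are accurate.
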