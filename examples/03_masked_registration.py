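"""Mask-aided (TIE) vs. unmasked rigid mutual-information registration.

Shows the central effect: with a large bright brainstem-like structure in
the field of view whose position varies relative to the labyrinth, an
unmasked metric aligns the big structure and drags the inner ear out of
place; evaluating the metric only inside the dilated inner-ear mask fixes
this.
"""

from dataclasses import replace

import numpy as np

from labnorm import (
    RegistrationConfig,
    RigidTransform,
    make_tie_mask,
    register_rigid,
    target_registration_error,
)
from labnorm.phantom import Distractor, default_spec, generate_phantom, make_atlas

base = default_spec(distractor=Distractor())
atlas, atlas_truth = make_atlas(base)

# the atlas-derived mask is built from the labyrinth alone, then dilated
labyrinth_only, _ = make_atlas(replace(base, distractor=None))
mask = make_tie_mask(labyrinth_only, "otsu", dilation_radius_voxels=5)
print(f"TIE mask: {mask.n_true} voxels "
      f"({100 * mask.n_true / mask.voxels.size:.1f}% of the grid)")

pose = RigidTransform.from_euler((6.0, -4.0, 9.0), (2.0, 3.0, -1.0))
spec = replace(base, pose=pose, seed=5,
               distractor=Distractor(center=(-7.0, 2.0, -6.5)))  # displaced brainstem
subject, truth = generate_phantom(spec)

for label, preset, m in (("TIE (masked)", "tie", mask), ("unmasked", "elastix-like", None)):
    cfg = RegistrationConfig.preset(preset, fixed_mask=m, random_seed=17)
    res = register_rigid(subject, atlas, cfg)
    tre = target_registration_error(res.transform, truth.landmarks, atlas_truth.landmarks)
    print(f"{label:14s} converged={res.converged}  "
          f"landmark TRE {tre:.3f} mm  ({res.notes})")
# The TRE is the alignment error at the three anatomical fiducials: the
# masked run lands well under a voxel (0.5 mm), the unmasked run is pulled
# toward the displaced distractor by a few millimetres.
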