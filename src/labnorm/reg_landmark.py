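"""Semi-manual three-point (3P) registration.

A rigid transform is fitted in closed form to the three anatomical
fiducial pairs (lateral pole of the posterior semicircular canal, superior
apex of the superior canal, cochlear apex) by centroid alignment and SVD
of the 3x3 cross-covariance, with the determinant-sign correction that
forbids reflection.  With exactly three non-collinear points the
least-squares problem has a unique proper-rigid minimiser, so no iterative
optimisation is involved.  The fiducial registration error (FRE, the RMS
residual at the fitted landmarks, in mm) is always reported; sets whose
FRE exceeds a configurable threshold are flagged as suspect rather than
rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .core import LandmarkTriplet, RigidTransform, Volume

__all__ = ["LandmarkFit", "fit_rigid_from_landmarks", "resample_linear", "target_registration_error"]

log = logging.getLogger(__name__)

#: default FRE (mm) above which a landmark set is flagged as suspect
DEFAULT_FRE_THRESHOLD_MM = 2.0


@dataclass(frozen=True)
class LandmarkFit:
    """Result of a three-point rigid fit."""

    transform: RigidTransform
    fre_mm: float
    suspect: bool
    reflection_corrected: bool


def fit_rigid_from_landmarks(
    moving: LandmarkTriplet,
    fixed: LandmarkTriplet,
    fre_threshold_mm: float = DEFAULT_FRE_THRESHOLD_MM,
) -> LandmarkFit:
    """Least-squares rigid transform taking ``moving`` fiducials onto ``fixed``.

    Closed form (Kabsch/Umeyama without scaling): center both triplets on
    their centroids, take the SVD of the cross-covariance, and correct the
    sign of the smallest singular direction if the best orthogonal map
    would be a reflection.
    """
    X = moving.as_array()
    Y = fixed.as_array()
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    # three centered points give a rank-2 cross-covariance, so the sign of
    # the null direction is numerical noise; only a correction on a clearly
    # nonzero smallest singular value marks a truly reflective correspondence
    reflection_corrected = bool(d < 0 and S[2] > 1e-9 * max(S[0], 1.0))
    if reflection_corrected:
        log.warning("landmark correspondence is reflection-dominated; det correction applied")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    transform = RigidTransform(R, t)
    residuals = transform.apply(X) - Y
    fre = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    suspect = fre > fre_threshold_mm
    if suspect:
        log.warning("fiducial registration error %.3f mm exceeds threshold %.3f mm", fre, fre_threshold_mm)
    return LandmarkFit(transform, fre, suspect, bool(reflection_corrected))


def resample_linear(
    moving: Volume,
    transform: RigidTransform,
    reference: Volume,
    background: float = 0.0,
) -> Volume:
    """Resample ``moving`` onto the ``reference`` grid under a rigid transform.

    ``transform`` maps moving-space physical points into reference (fixed)
    space; each output voxel takes the trilinear interpolation of the
    moving image at the inverse-mapped point, with out-of-domain points
    filled with ``background``.
    """
    resampled = sitk.Resample(
        moving.to_sitk(),
        reference.to_sitk(),
        transform.inverse().to_sitk(),
        sitk.sitkLinear,
        float(background),
        sitk.sitkFloat64,
    )
    return Volume.from_sitk(resampled)


def target_registration_error(
    transform: RigidTransform,
    moving_targets: LandmarkTriplet | np.ndarray,
    fixed_targets: LandmarkTriplet | np.ndarray,
) -> float:
    """RMS distance (mm) between mapped moving targets and fixed targets.

    Evaluated at points *not* used to fit the transform, this is the
    target registration error (TRE).
    """
    mv = moving_targets.as_array() if isinstance(moving_targets, LandmarkTriplet) else np.asarray(moving_targets, float)
    fx = fixed_targets.as_array() if isinstance(fixed_targets, LandmarkTriplet) else np.asarray(fixed_targets, float)
    diff = transform.apply(mv) - fx
    return float(np.sqrt(np.mean(np.sum(np.atleast_2d(diff) ** 2, axis=1))))
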