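"""Core domain types and geometry conventions.

Physical space is a right-handed RAS-like coordinate system measured in
millimetres.  A voxel with 0-based index ``(i, j, k)`` has its *center* at

    origin + direction @ (spacing * (i, j, k))

where ``direction`` is a 3x3 orthonormal matrix whose columns are the
physical directions of the three index axes.  The first physical axis is
the left-right axis (the sagittal plane is a plane of constant first
coordinate).

Rigid transforms map *moving*-space physical points into *fixed*
(atlas)-space physical points; resampling a moving image onto a fixed grid
uses the inverse mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "METHODS",
    "LANDMARK_NAMES",
    "Volume",
    "BinaryMask",
    "RigidTransform",
    "LandmarkTriplet",
    "RatingRecord",
    "GRADE_MIN",
    "GRADE_MAX",
]

#: Registration method labels used throughout (semi-manual three-point,
#: mask-aided thick-inner-ear, unmasked Elastix-like, unmasked ANTs-like).
METHODS = ("3P", "TIE", "EL", "ANTS")

#: Canonical anatomical fiducial names, in storage order.
LANDMARK_NAMES = ("posterior_scc_lateral", "superior_scc_apex", "cochlea_apex")

GRADE_MIN = 1.0
GRADE_MAX = 6.0

_ORTHO_TOL = 1e-9


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {np.shape(x)}")
    return v


def _check_direction(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise ValueError(f"direction must be 3x3, got {d.shape}")
    if not np.allclose(d.T @ d, np.eye(3), atol=1e-9):
        raise ValueError("direction matrix is not orthonormal (D^T D != I within 1e-9)")
    return d


@dataclass
class Volume:
    """A 3D scalar image with physical grid geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units, indexed ``[i, j, k]``.
    spacing : 3-vector, mm
    origin : 3-vector, mm — physical position of the center of voxel (0,0,0).
    direction : 3x3 orthonormal matrix (columns = index axis directions).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D voxel grid, got {self.voxels.ndim}D")
        if self.voxels.size == 0:
            raise ValueError("voxel grid is empty")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = _check_direction(self.direction)

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_physical(self, indices) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers for index triples.

        ``indices`` may be a single (i,j,k) or an (N,3) array; fractional
        indices are allowed.
        """
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        pts = self.origin + (self.direction @ (self.spacing * idx).T).T
        return pts[0] if np.asarray(indices).ndim == 1 else pts

    def physical_to_index(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (self.direction.T @ (pts - self.origin).T).T / self.spacing
        return idx[0] if np.asarray(points).ndim == 1 else idx

    def physical_center(self) -> np.ndarray:
        """Center of the image domain (midpoint of the voxel-center grid)."""
        mid = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.index_to_physical(mid)

    def same_grid(self, other: "Volume | BinaryMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        return replace(self, voxels=voxels)

    # -- SimpleITK bridge ---------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.T))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        if img.GetDimension() != 3:
            raise ValueError(f"expected a 3D image, got {img.GetDimension()}D")
        arr = sitk.GetArrayFromImage(img).T  # -> index order (i, j, k)
        return cls(
            voxels=arr,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
        )


@dataclass
class BinaryMask:
    """A boolean grid sharing the Volume geometry convention."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("mask must be a non-empty 3D grid")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be > 0")
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = _check_direction(self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_true(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def same_grid(self, other: "Volume | BinaryMask", tol: float = 1e-6) -> bool:
        return Volume.same_grid(self, other, tol)  # type: ignore[arg-type]

    def require_nonempty(self, what: str = "mask") -> None:
        if self.n_true == 0:
            raise ValueError(f"{what} has no true voxels")

    @classmethod
    def from_volume(cls, vol: Volume, threshold: float = 0.5) -> "BinaryMask":
        return cls(vol.voxels > threshold, vol.spacing, vol.origin, vol.direction)

    def to_volume(self, dtype=np.uint8) -> Volume:
        return Volume(self.voxels.astype(dtype), self.spacing, self.origin, self.direction)

    def to_sitk(self) -> sitk.Image:
        return self.to_volume().to_sitk()


class RigidTransform:
    """Rotation + translation about a center: ``p' = R (p - c) + c + t``.

    Maps moving-space physical points (mm) into fixed-space physical
    points.  The rotation must be proper (det = +1, orthonormal); scaling,
    shearing and reflection are forbidden by construction.
    """

    __slots__ = ("rotation", "translation", "center")

    def __init__(self, rotation=None, translation=None, center=None):
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det = -1 (reflection); rigid transforms must preserve handedness")
        self.rotation = R
        self.translation = np.zeros(3) if translation is None else _as_vec3(translation, "translation")
        self.center = np.zeros(3) if center is None else _as_vec3(center, "center")

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(cls, angles_deg: Sequence[float], translation=(0.0, 0.0, 0.0), center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Intrinsic rotations about fixed x, y, z axes (applied z.y.x order)."""
        ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(Rz @ Ry @ Rx, translation, center)

    # -- algebra ------------------------------------------------------------
    @property
    def offset(self) -> np.ndarray:
        """The effective translation with center folded in: p' = R p + offset."""
        return self.translation + self.center - self.rotation @ self.center

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (self.rotation @ pts.T).T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self . other`` (apply ``other`` first)."""
        R = self.rotation @ other.rotation
        t = self.rotation @ other.offset + self.offset
        return RigidTransform(R, t, np.zeros(3))

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -(Rinv @ self.offset), np.zeros(3))

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees.

        Uses a quaternion extraction rather than acos of the trace, whose
        derivative singularity at the identity floors the measurable angle
        at ~1e-8 rad.
        """
        from scipy.spatial.transform import Rotation

        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    def translation_magnitude(self) -> float:
        """Norm of the effective translation (center folded in), mm."""
        return float(np.linalg.norm(self.offset))

    def is_identity(self, rot_tol_deg: float = 1e-9, trans_tol_mm: float = 1e-9) -> bool:
        return self.rotation_angle_deg() <= rot_tol_deg and self.translation_magnitude() <= trans_tol_mm

    # -- SimpleITK bridge ---------------------------------------------------
    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(self.rotation.flatten()))
        t.SetCenter(tuple(self.center))
        t.SetTranslation(tuple(self.translation))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "RigidTransform":
        if isinstance(t, sitk.CompositeTransform):
            out = cls.identity()
            # Composite applies the *last added* transform first.
            for i in range(t.GetNumberOfTransforms()):
                out = out.compose(cls.from_sitk(t.GetNthTransform(i)))
            return out
        R = np.array(t.GetMatrix()).reshape(3, 3)
        return cls(R, np.array(t.GetTranslation()), np.array(t.GetCenter()))

    def __repr__(self) -> str:
        return (
            f"RigidTransform(angle={self.rotation_angle_deg():.3f} deg, "
            f"offset={np.round(self.offset, 4).tolist()} mm)"
        )


@dataclass
class LandmarkTriplet:
    """The three anatomical fiducials, in physical mm.

    The points are the most lateral pole of the posterior semicircular
    canal, the most superior apex of the superior semicircular canal, and
    the cochlear apex.  A rigid fit from three points is well-posed only
    when they are non-collinear, which is enforced on construction.
    """

    posterior_scc_lateral: np.ndarray
    superior_scc_apex: np.ndarray
    cochlea_apex: np.ndarray

    #: minimum triangle area (mm^2) before the triplet counts as degenerate
    AREA_TOL = 1e-6

    def __post_init__(self) -> None:
        self.posterior_scc_lateral = _as_vec3(self.posterior_scc_lateral, LANDMARK_NAMES[0])
        self.superior_scc_apex = _as_vec3(self.superior_scc_apex, LANDMARK_NAMES[1])
        self.cochlea_apex = _as_vec3(self.cochlea_apex, LANDMARK_NAMES[2])
        pts = self.as_array()
        if len({tuple(p) for p in pts}) < 3:
            raise ValueError("landmarks must be pairwise distinct")
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        if area <= self.AREA_TOL:
            raise ValueError(
                f"landmarks are collinear (triangle area {area:.3g} mm^2); a rigid fit is underdetermined"
            )

    def as_array(self) -> np.ndarray:
        return np.stack(
            [self.posterior_scc_lateral, self.superior_scc_apex, self.cochlea_apex]
        )

    @classmethod
    def from_array(cls, pts) -> "LandmarkTriplet":
        pts = np.asarray(pts, dtype=float)
        if pts.shape != (3, 3):
            raise ValueError(f"expected 3x3 points, got {pts.shape}")
        return cls(pts[0], pts[1], pts[2])

    def transformed(self, transform: RigidTransform) -> "LandmarkTriplet":
        return LandmarkTriplet.from_array(transform.apply(self.as_array()))


_VALID_GRADES = frozenset(np.arange(2, 13) / 2.0)  # 1.0, 1.5, ..., 6.0


@dataclass(frozen=True)
class RatingRecord:
    """One Likert grade for one (dataset, method, rater) triple.

    Grades follow the 6-point scale (1 = best possible alignment, 6 = no
    alignment / non-convergence) with intermittent half-steps allowed.
    """

    dataset_id: str
    method: str
    rater_id: str
    grade: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        g = float(self.grade)
        if not (GRADE_MIN <= g <= GRADE_MAX):
            raise ValueError(f"grade {g} outside [{GRADE_MIN}, {GRADE_MAX}]")
        if g not in _VALID_GRADES:
            raise ValueError(f"grade {g} is not on the half-step lattice 1.0, 1.5, ..., 6.0")
        object.__setattr__(self, "grade", g)
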