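"""Synthetic labyrinth phantom and cohort generator.

The phantom emulates what the registration pipeline sees in a cropped,
T2-weighted inner-ear volume: a bright fluid-filled membranous labyrinth —
three near-orthogonal semicircular-canal arcs, a vestibular ellipsoid and
a conical cochlear spiral — on a darker tissue background, optionally with
a large bright brainstem-like distractor structure that dominates the
voxel mass and misleads unmasked intensity registration.

Geometry is analytic solid geometry rasterized by evaluating signed
distances at voxel centers with a half-voxel soft edge (hard binary
voxelization would alias and make mutual-information registration
artificially brittle).  Every phantom carries its ground truth: the three
anatomical fiducials (lateral pole of the posterior canal, superior apex
of the superior canal, cochlear apex) computed analytically on the posed
geometry, the labyrinth mask, and the generating pose.  Generation is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BinaryMask, LandmarkTriplet, RigidTransform, Volume

__all__ = [
    "CanalSpec",
    "CochleaSpec",
    "Distractor",
    "PhantomSpec",
    "PhantomTruth",
    "CohortVariability",
    "CohortMember",
    "generate_phantom",
    "generate_cohort",
    "default_spec",
    "make_atlas",
]

_MIRROR = np.diag([-1.0, 1.0, 1.0])  # reflection across the sagittal plane


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class CanalSpec:
    """One semicircular canal: a partial torus.

    ``center``/``normal`` define the ring plane, ``ring_radius`` the torus
    major radius, ``arc_deg`` the angular extent of the canal (the gap
    faces the vestibule at the frame origin).
    """

    center: tuple
    normal: tuple
    ring_radius: float
    arc_deg: float = 300.0


@dataclass(frozen=True)
class CochleaSpec:
    """Conical spiral tube: ``turns`` revolutions shrinking from
    ``base_radius`` while advancing ``height`` along ``axis``."""

    base_center: tuple = (-1.0, 4.0, -2.0)
    axis: tuple = (0.25, 0.55, -0.8)
    turns: float = 2.5
    base_radius: float = 3.0
    height: float = 4.5
    tube_radius: float = 0.8
    taper: float = 0.75


@dataclass(frozen=True)
class Distractor:
    """Large bright sphere (brainstem-like) off the labyrinth."""

    center: tuple = (-9.0, 0.0, -5.0)
    radius: float = 6.0
    intensity: float = 90.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic inner-ear volume."""

    grid_size: tuple = (64, 64, 64)
    spacing_mm: tuple = (0.5, 0.5, 0.5)
    canals: tuple = (
        # lateral (horizontal) canal
        CanalSpec(center=(1.5, 0.5, 1.0), normal=(0.17, 0.05, 0.98), ring_radius=3.2),
        # superior (anterior) canal
        CanalSpec(center=(0.0, 1.0, 3.2), normal=(0.7, 0.7, 0.12), ring_radius=3.4),
        # posterior canal
        CanalSpec(center=(-0.5, -2.0, 1.2), normal=(0.7, -0.7, 0.12), ring_radius=3.6),
    )
    canal_tube_radius_mm: float = 0.9
    vestibule_center: tuple = (0.0, 0.0, 0.0)
    vestibule_semi_axes_mm: tuple = (2.5, 1.8, 1.5)
    cochlea: CochleaSpec = field(default_factory=CochleaSpec)
    fluid_intensity: float = 100.0
    background_intensity: float = 10.0
    smoothing_sigma_mm: float = 0.4
    noise_sd: float = 5.0
    chirality: str = "right"
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    distractor: Optional[Distractor] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chirality not in ("left", "right"):
            raise ValueError(f"chirality must be 'left' or 'right', got {self.chirality!r}")
        if self.fluid_intensity <= self.background_intensity:
            raise ValueError("fluid intensity must exceed background intensity")
        if self.canal_tube_radius_mm <= 0 or self.cochlea.tube_radius <= 0:
            raise ValueError("tube radii must be positive")
        if any(c.ring_radius <= 0 for c in self.canals):
            raise ValueError("canal ring radii must be positive")
        if any(a <= 0 for a in self.vestibule_semi_axes_mm):
            raise ValueError("vestibule semi-axes must be positive")
        normals = [_unit(c.normal) for c in self.canals]
        for i in range(len(normals)):
            for j in range(i + 1, len(normals)):
                # angle between planes, folded into [0, 90]
                ang = np.degrees(np.arccos(np.clip(abs(normals[i] @ normals[j]), 0, 1)))
                if ang < 70.0:
                    raise ValueError(
                        f"canal planes {i} and {j} are {ang:.1f} deg apart; "
                        "need near-orthogonal (90 +/- 20 deg)"
                    )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    landmarks: LandmarkTriplet
    labyrinth_mask: BinaryMask
    pose: RigidTransform


def default_spec(**overrides) -> PhantomSpec:
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------

def _plane_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(n, helper))
    v = np.cross(n, u)
    return u, v


def _canal_frame(canal: CanalSpec, vestibule_center: np.ndarray):
    c = np.asarray(canal.center, dtype=float)
    n = _unit(canal.normal)
    u, v = _plane_basis(n)
    # gap faces the vestibule: arc is centered on the angle pointing away
    gap_dir = vestibule_center - c
    gap_in_plane = gap_dir - (gap_dir @ n) * n
    if np.linalg.norm(gap_in_plane) < 1e-9:
        theta_gap = 0.0
    else:
        g = _unit(gap_in_plane)
        theta_gap = np.arctan2(g @ v, g @ u)
    theta_center = theta_gap + np.pi
    return c, n, u, v, theta_center


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _canal_sdf(points: np.ndarray, canal: CanalSpec, tube_radius: float, vestibule_center: np.ndarray) -> np.ndarray:
    c, n, u, v, theta_center = _canal_frame(canal, vestibule_center)
    half_span = np.deg2rad(canal.arc_deg) / 2.0
    w = points - c
    z = w @ n
    pu = w @ u
    pv = w @ v
    theta = np.arctan2(pv, pu)
    inside = np.abs(_wrap_angle(theta - theta_center)) <= half_span
    # distance to the full ring where the angle is inside the arc
    rho = np.hypot(pu, pv)
    d_ring = np.hypot(rho - canal.ring_radius, z)
    # otherwise distance to the nearest arc endpoint
    ends = []
    for s in (-1.0, 1.0):
        te = theta_center + s * half_span
        ends.append(c + canal.ring_radius * (np.cos(te) * u + np.sin(te) * v))
    d_end = np.minimum(
        np.linalg.norm(points - ends[0], axis=-1),
        np.linalg.norm(points - ends[1], axis=-1),
    )
    return np.where(inside, d_ring, d_end) - tube_radius


def _canal_extreme_point(canal: CanalSpec, direction: np.ndarray, vestibule_center: np.ndarray) -> np.ndarray:
    """Centerline point of the canal arc extremal along ``direction``.

    The unconstrained extreme of the ring is the in-plane projection of
    the direction; if that angle falls in the gap, the nearest arc
    endpoint is used instead.
    """
    c, n, u, v, theta_center = _canal_frame(canal, vestibule_center)
    half_span = np.deg2rad(canal.arc_deg) / 2.0
    e = np.asarray(direction, dtype=float)
    e_plane = e - (e @ n) * n
    if np.linalg.norm(e_plane) < 1e-12:
        theta = theta_center
    else:
        ep = _unit(e_plane)
        theta = np.arctan2(ep @ v, ep @ u)
    delta = float(_wrap_angle(np.asarray(theta - theta_center)))
    delta = np.clip(delta, -half_span, half_span)
    theta = theta_center + delta
    return c + canal.ring_radius * (np.cos(theta) * u + np.sin(theta) * v)


def _cochlea_curve(cochlea: CochleaSpec, n_samples_per_turn: int = 200) -> np.ndarray:
    axis = _unit(cochlea.axis)
    e1, e2 = _plane_basis(axis)
    n = max(16, int(np.ceil(n_samples_per_turn * cochlea.turns)))
    t = np.linspace(0.0, 1.0, n)
    phi = 2.0 * np.pi * cochlea.turns * t
    rho = cochlea.base_radius * (1.0 - cochlea.taper * t)
    base = np.asarray(cochlea.base_center, dtype=float)
    return (
        base
        + rho[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        + (cochlea.height * t)[:, None] * axis
    )


def _ellipsoid_sdf(points: np.ndarray, center: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    # standard bound-preserving approximation to the ellipsoid distance
    p = (points - center) / semi_axes
    k0 = np.linalg.norm(p, axis=-1)
    k1 = np.linalg.norm(p / semi_axes, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(k1 > 0, k0 * (k0 - 1.0) / k1, -np.min(semi_axes))
    return d


class _Geometry:
    """Posed, chirality-resolved analytic geometry of one phantom."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        mirror = spec.chirality == "left"
        M = _MIRROR if mirror else np.eye(3)
        self.vestibule_center = M @ np.asarray(spec.vestibule_center, dtype=float)
        self.vestibule_semi = np.asarray(spec.vestibule_semi_axes_mm, dtype=float)
        self.canals = [
            CanalSpec(
                center=tuple(M @ np.asarray(c.center, float)),
                normal=tuple(M @ _unit(c.normal)),
                ring_radius=c.ring_radius,
                arc_deg=c.arc_deg,
            )
            for c in spec.canals
        ]
        self.cochlea_points = _cochlea_curve(spec.cochlea) @ M.T
        self.cochlea_tube = spec.cochlea.tube_radius
        self._tree = cKDTree(self.cochlea_points)
        if spec.distractor is not None:
            self.distractor_center = M @ np.asarray(spec.distractor.center, float)
        lm = self._local_landmarks(M)
        self.landmarks = LandmarkTriplet.from_array(spec.pose.apply(lm))

    def _local_landmarks(self, M: np.ndarray) -> np.ndarray:
        lateral = M @ np.array([1.0, 0.0, 0.0])
        superior = np.array([0.0, 0.0, 1.0])
        # canals are stored (lateral, superior, posterior)
        post = self.canals[2]
        sup = self.canals[1]
        p1 = _canal_extreme_point(post, lateral, self.vestibule_center)
        p2 = _canal_extreme_point(sup, superior, self.vestibule_center)
        p3 = self.cochlea_points[-1]
        return np.stack([p1, p2, p3])

    # -- signed distances in *unposed* (atlas-like) space -------------------
    def labyrinth_sdf(self, points: np.ndarray) -> np.ndarray:
        d = _ellipsoid_sdf(points, self.vestibule_center, self.vestibule_semi)
        for canal in self.canals:
            d = np.minimum(
                d,
                _canal_sdf(points, canal, self.spec.canal_tube_radius_mm, self.vestibule_center),
            )
        d_coch = self._tree.query(points, workers=1)[0] - self.cochlea_tube
        return np.minimum(d, d_coch)

    def distractor_sdf(self, points: np.ndarray) -> np.ndarray:
        ds = self.spec.distractor
        return np.linalg.norm(points - self.distractor_center, axis=-1) - ds.radius

    def support_points(self) -> dict[str, np.ndarray]:
        """Key surface points per structure, for bounds checking."""
        out: dict[str, np.ndarray] = {}
        for name, canal in zip(("lateral_scc", "superior_scc", "posterior_scc"), self.canals):
            c, n, u, v, _ = _canal_frame(canal, self.vestibule_center)
            th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
            ring = c + canal.ring_radius * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)
            out[name] = ring
        out["vestibule"] = self.vestibule_center + np.diag(self.vestibule_semi)
        out["cochlea"] = self.cochlea_points[:: max(1, len(self.cochlea_points) // 16)]
        return out


def _voxel_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    shape = np.asarray(spec.grid_size, dtype=int)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    origin = -(shape - 1) / 2.0 * spacing  # grid centered on the frame origin
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return grid.reshape(-1, 3), origin, spacing


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Rasterize one phantom; returns the volume and its ground truth.

    The analytic union (three canal tori + vestibular ellipsoid + cochlear
    spiral tube) is evaluated as a signed distance at every voxel center
    of the posed grid, converted to occupancy with a half-voxel soft edge,
    scaled to the fluid/background intensities, Gaussian-blurred and
    corrupted by seeded additive Gaussian noise.
    """
    geo = _Geometry(spec)
    points, origin, spacing = _voxel_centers(spec)
    shape = tuple(int(s) for s in spec.grid_size)

    _check_bounds(geo, spec, points, origin, spacing)

    inv = spec.pose.inverse()
    local = inv.apply(points)
    edge = float(np.mean(spacing))
    sdf_lab = geo.labyrinth_sdf(local)
    occ_lab = np.clip(0.5 - sdf_lab / edge, 0.0, 1.0)
    contrast = spec.fluid_intensity - spec.background_intensity
    signal = contrast * occ_lab
    if spec.distractor is not None:
        occ_d = np.clip(0.5 - geo.distractor_sdf(local) / edge, 0.0, 1.0)
        signal = np.maximum(signal, (spec.distractor.intensity - spec.background_intensity) * occ_d)
    vox = (spec.background_intensity + signal).reshape(shape)

    if spec.smoothing_sigma_mm > 0:
        vox = ndimage.gaussian_filter(vox, sigma=spec.smoothing_sigma_mm / spacing)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sd, size=vox.shape)

    volume = Volume(vox, spacing, origin)
    mask = BinaryMask((sdf_lab <= 0).reshape(shape), spacing, origin)
    mask.require_nonempty("labyrinth mask")
    truth = PhantomTruth(landmarks=geo.landmarks, labyrinth_mask=mask, pose=spec.pose)
    return volume, truth


def _check_bounds(geo, spec, points, origin, spacing) -> None:
    lo = points.min(axis=0) - spacing / 2.0
    hi = points.max(axis=0) + spacing / 2.0
    margin = spec.canal_tube_radius_mm
    for name, pts in geo.support_points().items():
        posed = spec.pose.apply(np.atleast_2d(pts))
        if np.any(posed < lo - margin) or np.any(posed > hi + margin):
            raise ValueError(
                f"structure {name!r} exceeds the grid after posing "
                f"(extent {posed.min(axis=0).round(1)}..{posed.max(axis=0).round(1)} mm, "
                f"grid {lo.round(1)}..{hi.round(1)} mm)"
            )


def make_atlas(spec: Optional[PhantomSpec] = None) -> tuple[Volume, PhantomTruth]:
    """The fixed reference: noise-free, identity-pose phantom of the base spec."""
    base = spec if spec is not None else default_spec()
    atlas_spec = replace(base, noise_sd=0.0, pose=RigidTransform.identity(), chirality="right")
    return generate_phantom(atlas_spec)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortVariability:
    """Per-parameter jitter magnitudes for a synthetic cohort.

    Poses are drawn uniformly within ``+/- rotation_deg`` per axis and
    ``+/- translation_mm`` per axis; canal ring radii get multiplicative
    Gaussian jitter, canal plane normals a random small rotation, and the
    distractor (when present) an independent positional offset that
    decouples its best alignment from the labyrinth's.
    """

    rotation_deg: float = 10.0
    translation_mm: float = 4.0
    canal_radius_rel_sd: float = 0.05
    canal_orientation_deg: float = 4.0
    distractor_offset_mm: float = 0.0


@dataclass
class CohortMember:
    dataset_id: str
    volume: Volume
    truth: PhantomTruth
    spec: PhantomSpec


def _jitter_spec(base: PhantomSpec, var: CohortVariability, rng: np.random.Generator, seed: int) -> PhantomSpec:
    angles = rng.uniform(-var.rotation_deg, var.rotation_deg, size=3)
    trans = rng.uniform(-var.translation_mm, var.translation_mm, size=3)
    pose = RigidTransform.from_euler(angles, trans)
    canals = []
    for c in base.canals:
        radius = c.ring_radius * (1.0 + rng.normal(0.0, var.canal_radius_rel_sd)) if var.canal_radius_rel_sd > 0 else c.ring_radius
        normal = np.asarray(_unit(c.normal))
        if var.canal_orientation_deg > 0:
            axis = _unit(rng.normal(size=3))
            ang = np.deg2rad(rng.normal(0.0, var.canal_orientation_deg))
            k = axis
            normal = (
                normal * np.cos(ang)
                + np.cross(k, normal) * np.sin(ang)
                + k * (k @ normal) * (1 - np.cos(ang))
            )
        canals.append(CanalSpec(c.center, tuple(normal), float(radius), c.arc_deg))
    distractor = base.distractor
    if distractor is not None and var.distractor_offset_mm > 0:
        offset = rng.uniform(-var.distractor_offset_mm, var.distractor_offset_mm, size=3)
        distractor = replace(distractor, center=tuple(np.asarray(distractor.center) + offset))
    return replace(base, canals=tuple(canals), pose=pose, distractor=distractor, seed=seed)


def generate_cohort(
    n: int,
    variability: CohortVariability,
    base_spec: Optional[PhantomSpec] = None,
    seed: int = 0,
    max_retries: int = 50,
) -> list[CohortMember]:
    """Generate ``n`` phantoms with independently jittered geometry and pose.

    Jitters that produce an invalid spec (geometry out of bounds or a
    broken invariant) are resampled up to ``max_retries`` times before
    raising.  Reproducible for a given seed; members get independent
    noise streams.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_spec if base_spec is not None else default_spec()
    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    for i in range(n):
        member_noise_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(max_retries + 1):
            try:
                spec = _jitter_spec(base, variability, rng, member_noise_seed)
                volume, truth = generate_phantom(spec)
                break
            except ValueError:
                if attempt == max_retries:
                    raise
        members.append(CohortMember(f"sub{i:03d}", volume, truth, spec))
    return members
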