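"""Parametric scene geometry for an ultrasound eye-tracking bench.

The scene models a benchtop gaze-estimation rig: a sphere-on-sphere model
eye (a scleral sphere with a smaller, offset corneal sphere whose protruding
cap makes echo timing gaze-dependent) mounted on a goniometer, an optional
parametric occluder (a reflective shell with an elliptical aperture plus a
nose-side wedge, standing in for eyelids/nose), and a ring of small
directional transducers facing the eye.

Coordinate convention (used everywhere in the package): right-handed, origin
at the sclera center, +z toward the transducer ring, +x temporal-to-nasal,
+y up.  The horizontal gaze angle theta rotates about +y (positive toward
+x, i.e. nasally), the vertical gaze angle phi about +x (positive up).
Gaze (0, 0) points at the ring center.  Distances are millimetres, angles
degrees.

Ray-surface intersection is analytic (ray-quadric / ray-plane); there is no
fixed-step ray marching.  The relative geometry tolerance is 1e-9; tangent
hits resolve to "hit".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "EyeModel",
    "OccluderSpec",
    "RingSpec",
    "Transducer",
    "Hit",
    "Scene",
    "gaze_rotation",
    "make_scene",
    "specular_reflect",
    "unit",
]

GEOM_RTOL = 1e-9


class InvalidGeometryError(ValueError):
    """Raised for scene parameters that do not describe a valid bench."""


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalised to unit length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise the zero vector")
    return v / n


def gaze_rotation(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Rotation matrix taking the rest gaze axis (+z) to gaze (theta, phi).

    theta rotates about +y (positive nasal, +x); phi about +x (positive up,
    +y).  The composition is R = Ry(theta) @ Rx(-phi), so at theta = 0 the
    gaze direction is (0, sin(phi), cos(phi)).
    """
    t = math.radians(theta_deg)
    p = math.radians(phi_deg)
    ry = np.array(
        [[math.cos(t), 0.0, math.sin(t)], [0.0, 1.0, 0.0], [-math.sin(t), 0.0, math.cos(t)]]
    )
    rx = np.array(
        [[1.0, 0.0, 0.0], [0.0, math.cos(p), math.sin(p)], [0.0, -math.sin(p), math.cos(p)]]
    )
    return ry @ rx


def specular_reflect(incident: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Mirror-law reflection r = d - 2 (d.n) n of a unit incident direction."""
    d = np.asarray(incident, dtype=float)
    n = np.asarray(normal, dtype=float)
    return d - 2.0 * np.dot(d, n) * n


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EyeModel:
    """Sphere-on-sphere model eye.

    The corneal sphere (radius ``cornea_radius``) is centred
    ``cornea_offset`` millimetres from the sclera center along the gaze
    axis; the part of it protruding beyond the scleral sphere (radius
    ``sclera_radius``) is the corneal cap.  With the defaults the corneal
    apex protrudes 5.6 + 7.8 - 11.925 = 1.475 mm beyond the scleral surface.
    Rotating gaze never changes ``sclera_center`` or any radius.
    """

    sclera_radius: float = 11.925
    cornea_radius: float = 7.8
    cornea_offset: float = 5.6
    sclera_center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sclera_radius <= 0 or self.cornea_radius <= 0 or self.cornea_offset <= 0:
            raise InvalidGeometryError("eye radii and offset must be positive")
        if self.apex_protrusion <= 0:
            raise InvalidGeometryError(
                "cornea does not protrude: offset + cornea_radius "
                f"({self.cornea_offset + self.cornea_radius:g}) <= sclera_radius "
                f"({self.sclera_radius:g})"
            )

    @property
    def apex_protrusion(self) -> float:
        """Protrusion of the corneal apex beyond the scleral sphere (mm)."""
        return self.cornea_offset + self.cornea_radius - self.sclera_radius

    def gaze_axis(self, theta_deg: float, phi_deg: float) -> np.ndarray:
        return gaze_rotation(theta_deg, phi_deg) @ np.array([0.0, 0.0, 1.0])

    def cornea_center(self, theta_deg: float, phi_deg: float) -> np.ndarray:
        return np.asarray(self.sclera_center) + self.cornea_offset * self.gaze_axis(
            theta_deg, phi_deg
        )

    def corneal_apex(self, theta_deg: float, phi_deg: float) -> np.ndarray:
        axis = self.gaze_axis(theta_deg, phi_deg)
        return np.asarray(self.sclera_center) + (self.cornea_offset + self.cornea_radius) * axis


@dataclass(frozen=True)
class OccluderSpec:
    """Parametric occluder: reflective shell with an aperture plus nose wedge.

    A stand-in for the printed face scan of a physical bench: a plane shell
    ``standoff_mm`` in front of the corneal apex with an elliptical aperture
    (half-width a, half-height b, center shifted ``aperture_center_y_mm``
    upward, emulating the palpebral fissure sitting slightly above the
    optical axis) and a small tilted "nose-pad" patch near ring azimuth
    ``wedge_azimuth_deg`` that reflects energy between nasal transmitter
    positions and the receiver.
    """

    standoff_mm: float = 2.0
    aperture_half_width_mm: float = 5.5
    aperture_half_height_mm: float = 4.5
    aperture_center_y_mm: float = 1.0
    outer_radius_mm: float = 40.0
    wedge_azimuth_deg: float = 20.0
    wedge_extent_deg: float = 30.0
    wedge_radial_mm: float = 4.0
    wedge_protrusion_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.standoff_mm <= 0:
            raise InvalidGeometryError("occluder shell must stand off the corneal apex")
        if self.aperture_half_width_mm <= 0 or self.aperture_half_height_mm <= 0:
            raise InvalidGeometryError("aperture half-axes must be positive")


@dataclass(frozen=True)
class Transducer:
    """A small circular-aperture directional transducer."""

    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    mode: str  # "transmit" | "receive"
    aperture_radius: float = 0.5
    acceptance_half_angle: float = 15.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise InvalidGeometryError("transducer direction must be unit-norm")
        if self.mode not in ("transmit", "receive"):
            raise InvalidGeometryError(f"unknown transducer mode {self.mode!r}")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def dir(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class RingSpec:
    """Transducer ring facing the eye.

    Transducers sit on a circle of ``radius_mm`` in a plane ``standoff_mm``
    beyond the rest corneal apex, at the listed angular positions (degrees,
    measured from +x nasal, counter-clockwise seen from the ring).  All
    transducers aim at the rest corneal apex on the axis.  The receiver of
    the gaze protocol sits at ``receiver_deg``.
    """

    radius_mm: float = 20.0
    standoff_mm: float = 25.0
    positions_deg: tuple[float, ...] = tuple(range(-90, 91, 10))
    receiver_deg: float = 180.0
    aperture_radius_mm: float = 0.5
    acceptance_half_angle_deg: float = 15.0

    def __post_init__(self) -> None:
        pos = [p % 360.0 for p in self.positions_deg]
        if len(set(pos)) != len(pos):
            raise InvalidGeometryError("ring positions must be unique modulo 360")

    def plane_z(self, eye: EyeModel) -> float:
        apex = eye.corneal_apex(0.0, 0.0)
        return float(apex[2] + self.standoff_mm)

    def aim_point(self, eye: EyeModel) -> np.ndarray:
        """Eye-side axis point all transducers aim at (the rest apex)."""
        return eye.corneal_apex(0.0, 0.0)

    def transducer(self, eye: EyeModel, angle_deg: float, mode: str) -> Transducer:
        a = math.radians(angle_deg)
        p = np.array(
            [self.radius_mm * math.cos(a), self.radius_mm * math.sin(a), self.plane_z(eye)]
        )
        d = unit(self.aim_point(eye) - p)
        return Transducer(
            position=tuple(p),
            direction=tuple(d),
            mode=mode,
            aperture_radius=self.aperture_radius_mm,
            acceptance_half_angle=self.acceptance_half_angle_deg,
        )


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------


class Surface:
    """Base class for analytic reflective surfaces.

    ``intersect_batch`` returns the parameter t (mm along the unit ray
    direction) of the nearest valid intersection for each ray, or +inf when
    the ray misses.
    """

    surface_id: str

    def intersect_batch(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def normals(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SphereSurface(Surface):
    """Sphere, optionally clipped to the region outside another ball.

    Used both for plain spheres and for the two lobes of the eye: the
    corneal cap is the portion of the corneal sphere outside the scleral
    ball and vice versa, so the boundary of the union is exactly the set of
    clipped sphere points.
    """

    def __init__(
        self,
        center: np.ndarray,
        radius: float,
        surface_id: str,
        exclude_center: Optional[np.ndarray] = None,
        exclude_radius: float = 0.0,
    ) -> None:
        if radius <= 0:
            raise InvalidGeometryError("sphere radius must be positive")
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)
        self.surface_id = surface_id
        self.exclude_center = (
            None if exclude_center is None else np.asarray(exclude_center, dtype=float)
        )
        self.exclude_radius = float(exclude_radius)

    def contains_point(self, p: np.ndarray) -> bool:
        """Whether p lies on this (possibly clipped) surface, within tolerance."""
        p = np.asarray(p, dtype=float)
        tol = self.radius * 1e-6
        if abs(np.linalg.norm(p - self.center) - self.radius) > tol:
            return False
        if self.exclude_center is not None:
            return bool(
                np.linalg.norm(p - self.exclude_center)
                >= self.exclude_radius * (1.0 - GEOM_RTOL) - tol
            )
        return True

    def intersect_batch(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        o = origins - self.center
        b = np.einsum("ij,ij->i", o, directions)
        c = np.einsum("ij,ij->i", o, o) - self.radius**2
        disc = b * b - c
        # tangent hits (disc == 0 within tolerance) resolve to "hit"
        hit = disc >= -GEOM_RTOL * self.radius**2
        sq = np.sqrt(np.clip(disc, 0.0, None))
        eps = self.radius * 1e-7
        t_out = np.full(origins.shape[0], np.inf)
        for root in (-b - sq, -b + sq):
            valid = hit & (root > eps)
            if self.exclude_center is not None:
                pts = origins + root[:, None] * directions
                dist = np.linalg.norm(pts - self.exclude_center, axis=1)
                valid &= dist >= self.exclude_radius * (1.0 - GEOM_RTOL)
            t_out = np.where(valid & (root < t_out), root, t_out)
        return t_out

    def normals(self, points: np.ndarray) -> np.ndarray:
        n = points - self.center
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


class ShellSurface(Surface):
    """Plane shell z = z0 with an elliptical aperture and finite outer radius."""

    surface_id = "occluder"

    def __init__(
        self,
        z0: float,
        half_width: float,
        half_height: float,
        center_y: float,
        outer_radius: float,
    ) -> None:
        self.z0 = float(z0)
        self.half_width = float(half_width)
        self.half_height = float(half_height)
        self.center_y = float(center_y)
        self.outer_radius = float(outer_radius)

    def in_aperture(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x / self.half_width) ** 2 + ((y - self.center_y) / self.half_height) ** 2 < 1.0

    def on_surface(self, p: np.ndarray, tol: float = 1e-6) -> bool:
        p = np.asarray(p, dtype=float)
        if abs(p[2] - self.z0) > tol:
            return False
        if p[0] ** 2 + p[1] ** 2 > self.outer_radius**2:
            return False
        return not bool(self.in_aperture(np.asarray(p[0]), np.asarray(p[1])))

    def intersect_batch(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        dz = directions[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self.z0 - origins[:, 2]) / dz
        eps = 1e-7
        pts_x = origins[:, 0] + t * directions[:, 0]
        pts_y = origins[:, 1] + t * directions[:, 1]
        r2 = pts_x**2 + pts_y**2
        valid = (
            np.isfinite(t)
            & (t > eps)
            & (r2 <= self.outer_radius**2)
            & ~self.in_aperture(pts_x, pts_y)
        )
        return np.where(valid, t, np.inf)

    def normals(self, points: np.ndarray) -> np.ndarray:
        n = np.zeros_like(points)
        n[..., 2] = 1.0
        return n


class PatchSurface(Surface):
    """Finite rectangular plane patch with its own frame (the nose wedge)."""

    def __init__(
        self,
        center: np.ndarray,
        normal: np.ndarray,
        u_axis: np.ndarray,
        half_u: float,
        half_v: float,
        surface_id: str = "wedge",
    ) -> None:
        self.center = np.asarray(center, dtype=float)
        self.n = unit(normal)
        self.u = unit(np.asarray(u_axis, dtype=float) - np.dot(u_axis, self.n) * self.n)
        self.v = np.cross(self.n, self.u)
        self.half_u = float(half_u)
        self.half_v = float(half_v)
        self.surface_id = surface_id

    def on_surface(self, p: np.ndarray, tol: float = 1e-6) -> bool:
        rel = np.asarray(p, dtype=float) - self.center
        if abs(rel @ self.n) > tol:
            return False
        return bool(abs(rel @ self.u) <= self.half_u and abs(rel @ self.v) <= self.half_v)

    def intersect_batch(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        denom = directions @ self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((self.center - origins) @ self.n) / denom
        eps = 1e-7
        pts = origins + t[:, None] * directions
        rel = pts - self.center
        uu = rel @ self.u
        vv = rel @ self.v
        valid = (
            np.isfinite(t)
            & (t > eps)
            & (np.abs(uu) <= self.half_u)
            & (np.abs(vv) <= self.half_v)
        )
        return np.where(valid, t, np.inf)

    def normals(self, points: np.ndarray) -> np.ndarray:
        return np.broadcast_to(self.n, points.shape).copy()


class PlateSurface(Surface):
    """Infinite plane (flat target of the attenuation bench)."""

    def __init__(self, point: np.ndarray, normal: np.ndarray, surface_id: str = "plate") -> None:
        self.point = np.asarray(point, dtype=float)
        self.n = unit(normal)
        self.surface_id = surface_id

    def on_surface(self, p: np.ndarray, tol: float = 1e-6) -> bool:
        return bool(abs((np.asarray(p, dtype=float) - self.point) @ self.n) <= tol)

    def intersect_batch(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        denom = directions @ self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((self.point - origins) @ self.n) / denom
        valid = np.isfinite(t) & (t > 1e-7)
        return np.where(valid, t, np.inf)

    def normals(self, points: np.ndarray) -> np.ndarray:
        return np.broadcast_to(self.n, points.shape).copy()


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hit:
    t: float
    point: np.ndarray
    normal: np.ndarray
    surface_id: str


@dataclass
class Scene:
    """A collection of reflective surfaces supporting intersection queries."""

    surfaces: list = field(default_factory=list)
    eye: Optional[EyeModel] = None
    gaze: tuple[float, float] = (0.0, 0.0)
    occluder: Optional[OccluderSpec] = None
    ring: Optional[RingSpec] = None

    @property
    def surface_ids(self) -> list[str]:
        return [s.surface_id for s in self.surfaces]

    def surface(self, surface_id: str) -> Surface:
        for s in self.surfaces:
            if s.surface_id == surface_id:
                return s
        raise KeyError(surface_id)

    def intersect_batch(
        self, origins: np.ndarray, directions: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Nearest intersection per ray: (t, surface index; -1 for a miss)."""
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        n = origins.shape[0]
        best_t = np.full(n, np.inf)
        best_i = np.full(n, -1, dtype=int)
        for i, s in enumerate(self.surfaces):
            t = s.intersect_batch(origins, directions)
            closer = t < best_t
            best_t = np.where(closer, t, best_t)
            best_i = np.where(closer, i, best_i)
        return best_t, best_i

    def intersect(self, ray_origin: np.ndarray, ray_direction: np.ndarray) -> Optional[Hit]:
        """Nearest intersection strictly ahead of the origin, or None.

        The returned normal is unit-length and faces the incoming ray.
        """
        d = np.asarray(ray_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("ray direction must be unit-norm")
        o = np.asarray(ray_origin, dtype=float)
        t, idx = self.intersect_batch(o[None, :], d[None, :])
        if idx[0] < 0:
            return None
        surf = self.surfaces[idx[0]]
        p = o + t[0] * d
        n = surf.normals(p[None, :])[0]
        if np.dot(n, d) > 0:  # orient toward the incoming ray
            n = -n
        return Hit(t=float(t[0]), point=p, normal=n, surface_id=surf.surface_id)


def intersect(ray_origin, ray_direction, scene: Scene) -> Optional[Hit]:
    """Functional alias for :meth:`Scene.intersect`."""
    return scene.intersect(ray_origin, ray_direction)


def _build_wedge(eye: EyeModel, occ: OccluderSpec, ring: RingSpec) -> PatchSurface:
    """Nose-pad patch aimed to couple nasal transmitter positions to the receiver.

    The patch normal bisects the directions from the patch center to the
    ring position at ``wedge_azimuth_deg`` and to the receiver, which is how
    a pad surface angled against the nose redirects energy across the frame.
    """
    z0 = eye.corneal_apex(0.0, 0.0)[2] + occ.standoff_mm
    az = math.radians(occ.wedge_azimuth_deg)
    center = np.array(
        [
            occ.wedge_radial_mm * math.cos(az),
            occ.wedge_radial_mm * math.sin(az),
            z0 + occ.wedge_protrusion_mm,  # the nose pad protrudes out of the face
        ]
    )
    tx = ring.transducer(eye, occ.wedge_azimuth_deg, "transmit").pos
    rx = ring.transducer(eye, ring.receiver_deg, "receive").pos
    normal = unit(unit(tx - center) + unit(rx - center))
    half_u = occ.wedge_radial_mm * math.tan(math.radians(occ.wedge_extent_deg) / 2.0)
    u_axis = np.array([-math.sin(az), math.cos(az), 0.0])  # azimuthal direction
    return PatchSurface(center, normal, u_axis, half_u=half_u, half_v=2.5)


def make_scene(
    eye: EyeModel | None = None,
    gaze: tuple[float, float] = (0.0, 0.0),
    occluder: Optional[OccluderSpec] = None,
    ring: Optional[RingSpec] = None,
    gaze_range_deg: float = 35.0,
) -> Scene:
    """Build the bench scene for one gaze pose.

    The eye contributes two clipped spheres ("sclera", "cornea"); the
    optional occluder a shell with elliptical aperture ("occluder") and the
    nose-pad patch ("wedge").  ``gaze_range_deg`` is the mechanical range of
    the goniometer stage; poses beyond it are refused.
    """
    eye = eye or EyeModel()
    theta, phi = gaze
    if abs(theta) > gaze_range_deg or abs(phi) > gaze_range_deg:
        raise InvalidGeometryError(
            f"gaze ({theta:g}, {phi:g}) outside mechanical range +/-{gaze_range_deg:g} deg"
        )
    ring = ring or RingSpec()
    c_sclera = np.asarray(eye.sclera_center, dtype=float)
    c_cornea = eye.cornea_center(theta, phi)
    surfaces: list[Surface] = [
        SphereSurface(
            c_sclera,
            eye.sclera_radius,
            "sclera",
            exclude_center=c_cornea,
            exclude_radius=eye.cornea_radius,
        ),
        SphereSurface(
            c_cornea,
            eye.cornea_radius,
            "cornea",
            exclude_center=c_sclera,
            exclude_radius=eye.sclera_radius,
        ),
    ]
    if occluder is not None:
        z0 = eye.corneal_apex(0.0, 0.0)[2] + occluder.standoff_mm
        if z0 <= eye.sclera_radius:
            raise InvalidGeometryError("occluder shell must lie strictly outside the sclera")
        surfaces.append(
            ShellSurface(
                z0,
                occluder.aperture_half_width_mm,
                occluder.aperture_half_height_mm,
                occluder.aperture_center_y_mm,
                occluder.outer_radius_mm,
            )
        )
        surfaces.append(_build_wedge(eye, occluder, ring))
    return Scene(surfaces=surfaces, eye=eye, gaze=(theta, phi), occluder=occluder, ring=ring)
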