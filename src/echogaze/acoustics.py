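"""Directional acoustic ray physics and Monte-Carlo tracing.

Physics of the airborne ultrasound link at 1.7 MHz:

* Pressure reflection at a media boundary uses the impedance-mismatch power
  fraction R = ((Z2 - Z1) / (Z2 + Z1))**2 with Z = rho * c.  The air/tissue
  mismatch puts R above 99.8%, so traced rays reflect with unit reflectance
  by default (configurable).
* Absorption in air at this frequency is severe; the amplitude factor over a
  path d is 10**(-A d / 20) with A = 470 dB/m.
* Transducers are directional.  The angular weight applied at emission and at
  reception is w(alpha) = cos(min(alpha * 90/15, 90 deg)): unity on axis,
  zero at and beyond the 15-degree cutoff.  A ray detected by a receiver
  carries the product of its emission weight, its reception weight and the
  attenuation over the full path.

Speed of sound in air is fixed at 343 m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Scene, Transducer, unit

__all__ = [
    "SOUND_SPEED_M_S",
    "MM_PER_US",
    "MediumProperties",
    "DirectivityModel",
    "AttenuationModel",
    "ArrivalRecord",
    "RayBundle",
    "reflection_fraction",
    "directional_weight",
    "attenuation_factor",
    "emit_rays",
    "trace",
    "receiver_histogram",
    "arrivals_to_frame",
]

SOUND_SPEED_M_S = 343.0
#: millimetres of path per microsecond of flight
MM_PER_US = SOUND_SPEED_M_S * 1e-3


@dataclass(frozen=True)
class MediumProperties:
    """Acoustic medium: density (kg/m^3) and sound speed (m/s)."""

    density: float
    speed: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.speed <= 0:
            raise ValueError("density and speed must be positive")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance Z = rho * c (kg / m^2 s)."""
        return self.density * self.speed


AIR = MediumProperties(density=1.0, speed=SOUND_SPEED_M_S)


def reflection_fraction(medium1: MediumProperties, medium2: MediumProperties) -> float:
    """Fraction of incident sound power reflected at the boundary.

    R = ((Z2 - Z1) / (Z2 + Z1))**2; symmetric in its arguments, zero for
    matched impedances and approaching one as the mismatch grows.
    """
    z1, z2 = medium1.impedance, medium2.impedance
    if z1 <= 0 or z2 <= 0:
        raise ValueError("impedances must be positive")
    return float(((z2 - z1) / (z2 + z1)) ** 2)


@dataclass(frozen=True)
class DirectivityModel:
    """Angular sensitivity w(alpha) = cos(min(alpha * 90/cutoff, 90 deg))."""

    cutoff_deg: float = 15.0

    def weight(self, alpha_deg):
        alpha = np.asarray(alpha_deg, dtype=float)
        if np.any(alpha < 0):
            raise ValueError("angle alpha must be non-negative")
        scaled = np.minimum(alpha * (90.0 / self.cutoff_deg), 90.0)
        w = np.cos(np.radians(scaled))
        # cos(90 deg) is not exactly zero in floats; the cutoff is exact
        w = np.where(alpha >= self.cutoff_deg, 0.0, w)
        return w if w.shape else float(w)


@dataclass(frozen=True)
class AttenuationModel:
    """Absorption in air: amplitude factor 10**(-A d / 20) with A in dB/m."""

    absorption_db_per_m: float = 470.0
    sound_speed_m_s: float = SOUND_SPEED_M_S

    def factor(self, distance_mm):
        d = np.asarray(distance_mm, dtype=float)
        if np.any(d < 0):
            raise ValueError("distance must be non-negative")
        f = 10.0 ** (-self.absorption_db_per_m * (d / 1000.0) / 20.0)
        return f if f.shape else float(f)


def directional_weight(alpha_deg, model: DirectivityModel | None = None):
    """Directivity weight of a ray at angle ``alpha_deg`` off the axis."""
    return (model or DirectivityModel()).weight(alpha_deg)


def attenuation_factor(distance_mm, model: AttenuationModel | None = None):
    """Amplitude attenuation over a path of ``distance_mm`` millimetres."""
    return (model or AttenuationModel()).factor(distance_mm)


# ---------------------------------------------------------------------------
# Ray emission
# ---------------------------------------------------------------------------


@dataclass
class RayBundle:
    """A batch of rays sharing an origin, with per-ray emission weights."""

    origin: np.ndarray
    directions: np.ndarray  # (n, 3) unit vectors
    weights: np.ndarray  # (n,) emission weights in [0, 1]
    mode: str  # "directional" | "omnidirectional"

    def __len__(self) -> int:
        return self.directions.shape[0]


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = unit(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(a, helper))
    v = np.cross(a, u)
    return u, v


def emit_rays(
    n: int,
    mode: str,
    transducer: Transducer,
    seed: int,
    directivity: DirectivityModel | None = None,
) -> RayBundle:
    """Release ``n`` rays uniformly over the emission hemisphere.

    Directions are uniform on the hemisphere centred on the transducer axis
    (deterministic given ``seed``; counter-based Philox generator).  In
    directional mode each ray carries the emission weight w(alpha); in
    omnidirectional mode all weights are one.
    """
    if n < 1:
        raise ValueError("need at least one ray")
    if mode not in ("directional", "omnidirectional"):
        raise ValueError(f"unknown emission mode {mode!r}")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    z = rng.uniform(0.0, 1.0, size=n)  # cos(alpha), uniform area on hemisphere
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    s = np.sqrt(1.0 - z**2)
    axis = transducer.dir
    u, v = _orthonormal_frame(axis)
    dirs = (
        s[:, None] * np.cos(phi)[:, None] * u
        + s[:, None] * np.sin(phi)[:, None] * v
        + z[:, None] * axis
    )
    if mode == "directional":
        model = directivity or DirectivityModel(cutoff_deg=transducer.acceptance_half_angle)
        alpha = np.degrees(np.arccos(np.clip(z, -1.0, 1.0)))
        weights = np.asarray(model.weight(alpha))
    else:
        weights = np.ones(n)
    return RayBundle(origin=transducer.pos.copy(), directions=dirs, weights=weights, mode=mode)


# ---------------------------------------------------------------------------
# Tracing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrivalRecord:
    """One detected acoustic path at a receiver.

    ``weight`` is emission weight x reception weight x attenuation over the
    full path (x reflectance per bounce when reflectance < 1).  The extra
    geometric fields support oracle checks and rendering and are not part of
    the CSV schema.
    """

    receiver_id: int
    path_mm: float
    time_us: float
    n_bounces: int
    weight: float
    arrival_point: Optional[tuple[float, float, float]] = None
    emit_direction: Optional[tuple[float, float, float]] = None
    last_bounce_point: Optional[tuple[float, float, float]] = None
    surface_ids: tuple[str, ...] = ()


def arrivals_to_frame(arrivals: Sequence[ArrivalRecord]) -> pd.DataFrame:
    """Arrival records as a DataFrame with the CSV export schema."""
    return pd.DataFrame(
        [
            {
                "receiver_id": a.receiver_id,
                "path_mm": a.path_mm,
                "time_us": a.time_us,
                "n_bounces": a.n_bounces,
                "weight": a.weight,
            }
            for a in arrivals
        ],
        columns=["receiver_id", "path_mm", "time_us", "n_bounces", "weight"],
    )


def _disc_crossings(
    origins: np.ndarray,
    dirs: np.ndarray,
    t_limit: np.ndarray,
    receiver: Transducer,
) -> tuple[np.ndarray, np.ndarray]:
    """Parameter t at which each ray crosses the receiver's aperture disc.

    Returns (t, mask); t is only meaningful where mask is True.  A crossing
    counts when it happens strictly before the ray's next surface hit.
    """
    n = receiver.dir
    denom = dirs @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = ((receiver.pos - origins) @ n) / denom
    pts = origins + t[:, None] * dirs
    r2 = np.einsum("ij,ij->i", pts - receiver.pos, pts - receiver.pos)
    mask = (
        np.isfinite(t)
        & (t > 1e-7)
        & (t < t_limit)
        & (r2 <= receiver.aperture_radius**2)
    )
    return t, mask


def trace(
    rays: RayBundle,
    scene: Scene,
    receivers: Sequence[Transducer],
    max_bounces: int = 3,
    directivity: DirectivityModel | None = None,
    attenuation: AttenuationModel | None = None,
    reflectance: float = 1.0,
) -> list[ArrivalRecord]:
    """Propagate rays through the scene and collect receiver arrivals.

    Rays reflect specularly (unit reflectance by default) until they cross a
    receiver aperture disc, exceed ``max_bounces`` reflections, or escape.
    A detected ray yields one ArrivalRecord weighted by emission weight,
    reception weight w(arrival alpha) and attenuation over the full path; in
    directional reception mode rays arriving at alpha >= cutoff are rejected
    before they are counted.  Rays crossing an aperture terminate there
    (the sensor face blocks them) whether or not they are accepted.
    """
    if max_bounces < 1:
        raise ValueError("max_bounces must be >= 1")
    attn = attenuation or AttenuationModel()
    n_rays = len(rays)
    origins = np.broadcast_to(rays.origin, (n_rays, 3)).copy()
    dirs = rays.directions.copy()
    path = np.zeros(n_rays)
    weights = rays.weights.copy()
    active = np.ones(n_rays, dtype=bool)
    bounces = np.zeros(n_rays, dtype=int)
    first_dirs = rays.directions
    last_bounce = np.full((n_rays, 3), np.nan)
    trail: list[list[str]] = [[] for _ in range(n_rays)]
    arrivals: list[ArrivalRecord] = []

    directional_rx = rays.mode == "directional"

    for bounce_round in range(max_bounces + 1):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        o, d = origins[idx], dirs[idx]
        t_hit, surf_i = scene.intersect_batch(o, d)

        # receiver detection along the segment, nearest crossing first
        seg_cross_t = np.full(len(idx), np.inf)
        seg_cross_r = np.full(len(idx), -1, dtype=int)
        for r_id, rx in enumerate(receivers):
            t_c, m = _disc_crossings(o, d, t_hit, rx)
            closer = m & (t_c < seg_cross_t)
            seg_cross_t = np.where(closer, t_c, seg_cross_t)
            seg_cross_r = np.where(closer, r_id, seg_cross_r)

        detected = seg_cross_r >= 0
        for j in np.flatnonzero(detected):
            gi = idx[j]
            rx = receivers[seg_cross_r[j]]
            total_path = path[gi] + seg_cross_t[j]
            cos_a = float(np.clip(-d[j] @ rx.dir, -1.0, 1.0))
            alpha = math.degrees(math.acos(cos_a))
            if directional_rx:
                model = directivity or DirectivityModel(cutoff_deg=rx.acceptance_half_angle)
                w_rx = float(model.weight(alpha)) if alpha < model.cutoff_deg else 0.0
                if w_rx <= 0.0:
                    active[gi] = False  # rejected before it is counted
                    continue
            else:
                w_rx = 1.0
            w = weights[gi] * w_rx * float(attn.factor(total_path))
            point = o[j] + seg_cross_t[j] * d[j]
            arrivals.append(
                ArrivalRecord(
                    receiver_id=int(seg_cross_r[j]),
                    path_mm=float(total_path),
                    time_us=float(total_path / MM_PER_US),
                    n_bounces=int(bounces[gi]),
                    weight=float(w),
                    arrival_point=tuple(point),
                    emit_direction=tuple(first_dirs[gi]),
                    last_bounce_point=(
                        tuple(last_bounce[gi]) if bounces[gi] > 0 else None
                    ),
                    surface_ids=tuple(trail[gi]),
                )
            )
            active[gi] = False

        if bounce_round == max_bounces:
            break

        # reflect the remaining rays at their nearest surface
        for j in range(len(idx)):
            gi = idx[j]
            if not active[gi]:
                continue
            if not np.isfinite(t_hit[j]) or surf_i[j] < 0:
                active[gi] = False  # escaped
                continue
            surf = scene.surfaces[surf_i[j]]
            p = o[j] + t_hit[j] * d[j]
            nrm = surf.normals(p[None, :])[0]
            if nrm @ d[j] > 0:
                nrm = -nrm
            origins[gi] = p
            dirs[gi] = d[j] - 2.0 * (d[j] @ nrm) * nrm
            path[gi] += t_hit[j]
            bounces[gi] += 1
            weights[gi] *= reflectance
            last_bounce[gi] = p
            trail[gi].append(surf.surface_id)

    return arrivals


def receiver_histogram(
    arrivals: Sequence[ArrivalRecord],
    bin_width_us: float,
    t_max_us: Optional[float] = None,
    normalize: bool = False,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-receiver weighted arrival-time histogram.

    Returns a mapping receiver_id -> (bin_edges_us, mass).  The histogram
    mass sums to the total arrival weight of that receiver (or to one when
    ``normalize``); an empty arrival list yields an empty dict.
    """
    if bin_width_us <= 0:
        raise ValueError("bin width must be positive")
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if not arrivals:
        return out
    if t_max_us is None:
        t_max_us = max(a.time_us for a in arrivals)
    n_bins = max(1, int(math.ceil(t_max_us / bin_width_us)))
    edges = np.arange(n_bins + 1) * bin_width_us
    by_receiver: dict[int, list[ArrivalRecord]] = {}
    for a in arrivals:
        by_receiver.setdefault(a.receiver_id, []).append(a)
    for r_id, recs in sorted(by_receiver.items()):
        times = np.array([a.time_us for a in recs])
        w = np.array([a.weight for a in recs])
        mass, _ = np.histogram(times, bins=edges, weights=w)
        if normalize and mass.sum() > 0:
            mass = mass / mass.sum()
        out[r_id] = (edges, mass)
    return out
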