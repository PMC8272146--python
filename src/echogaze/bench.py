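"""Synthetic test-bench emulation: tone bursts, digitized traces, protocols.

Emulates three benchtop protocols around the model eye:

1. an attenuation sweep against a flat plate on a translation stage,
2. a directivity sweep of a rotating transmitter against a fixed receiver,
3. the gaze protocol: a model eye on a goniometer stepped over a grid of
   gaze poses, a fixed receiver, and a transmitter stepped over arc
   positions; at each combination a 7-cycle 1.74 MHz tone burst is fired
   repeatedly and the receiver trace digitized at 80 MHz.

Traces are synthesised from the deterministic specular arrivals of the
scene (each arrival contributes a delayed, weighted copy of the burst) plus
additive Gaussian noise; sessions carry multiplicative gain jitter and a
timing offset to emulate day-to-day environmental drift.  The full dataset
is exposed lazily: the manifest and arrival tables are computed eagerly,
individual traces are rendered on demand from counter-based seeds, so the
same configuration and seed always reproduce the same bytes.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .acoustics import (
    ArrivalRecord,
    AttenuationModel,
    DirectivityModel,
    MM_PER_US,
    attenuation_factor,
    directional_weight,
)
from .geometry import EyeModel, OccluderSpec, RingSpec, Scene, Transducer, make_scene
from .specular import specular_arrivals

__all__ = [
    "ConfigError",
    "BurstSpec",
    "NoiseSpec",
    "ProtocolSpec",
    "RawTrace",
    "BenchDataset",
    "default_gaze_grid",
    "synth_burst",
    "received_wavelet",
    "render_trace",
    "bench_scene_factory",
    "run_protocol",
    "bench1_attenuation_sweep",
    "bench2_directivity_sweep",
]

#: scales dimensionless arrival weights into trace amplitude units so that
#: the strongest default-scene corneal echo sits near unity
AMPLITUDE_GAIN = 2.0e7


class ConfigError(ValueError):
    """Raised for physically or numerically inconsistent bench settings."""


@dataclass(frozen=True)
class BurstSpec:
    """Transmit tone burst and digitizer settings."""

    carrier_hz: float = 1.74e6
    n_cycles: int = 7
    repetition_hz: float = 2000.0
    sample_rate_hz: float = 80e6
    duration_us: float = 300.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 2.0 * self.carrier_hz:
            raise ConfigError(
                f"sample rate {self.sample_rate_hz:g} Hz is sub-Nyquist for "
                f"{self.carrier_hz:g} Hz carrier"
            )
        if self.n_cycles < 1 or self.duration_us <= 0:
            raise ConfigError("burst needs >= 1 cycle and positive duration")

    @property
    def burst_duration_us(self) -> float:
        return self.n_cycles / self.carrier_hz * 1e6

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_us * 1e-6 * self.sample_rate_hz))


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model.

    ``additive_std`` is the per-sample Gaussian noise of a single raw trace
    (in trace amplitude units; the default puts the strongest corneal echo
    at roughly 6 dB peak SNR).  Sessions carry a multiplicative gain factor
    1 + N(0, session_gain_std) and a timing offset N(0, session_jitter_us).
    """

    additive_std: float = 0.35
    session_gain_std: float = 0.05
    session_jitter_us: float = 0.2

    def __post_init__(self) -> None:
        if min(self.additive_std, self.session_gain_std, self.session_jitter_us) < 0:
            raise ConfigError("noise magnitudes must be non-negative")


def default_gaze_grid() -> tuple[tuple[float, float], ...]:
    """The 36-pose gaze grid: {-5,-3,-1,+1,+3,+5} degrees in theta and phi."""
    vals = (-5.0, -3.0, -1.0, 1.0, 3.0, 5.0)
    return tuple((t, p) for t in vals for p in vals)


@dataclass(frozen=True)
class ProtocolSpec:
    """Gaze-protocol bookkeeping: poses, arc positions, repeats, sessions."""

    gaze_grid_deg: tuple[tuple[float, float], ...] = field(default_factory=default_gaze_grid)
    tx_positions_deg: tuple[float, ...] = tuple(range(-90, 91, 10))
    repeats: int = 50
    sessions: int = 9
    group_size: int = 10
    receiver_deg: float = 180.0

    def __post_init__(self) -> None:
        if self.repeats % self.group_size:
            raise ConfigError(
                f"repeats ({self.repeats}) not divisible by group size ({self.group_size})"
            )
        if self.sessions < 1:
            raise ConfigError("need at least one session")

    @property
    def n_groups(self) -> int:
        return self.repeats // self.group_size

    @property
    def n_traces(self) -> int:
        return len(self.gaze_grid_deg) * len(self.tx_positions_deg) * self.repeats * self.sessions

    def effective_rate_hz(self, burst: BurstSpec) -> float:
        """Feature rate after group averaging (2 kHz / 10 = 200 Hz default)."""
        return burst.repetition_hz / self.group_size


@dataclass
class RawTrace:
    """One digitized receiver waveform with its acquisition indices."""

    samples: np.ndarray
    sample_rate_hz: float
    tx_pos_deg: float
    repeat: int
    session: int
    gaze: tuple[float, float]


def synth_burst(spec: BurstSpec) -> np.ndarray:
    """Sampled n-cycle sinusoidal tone burst (unit amplitude).

    This is the electrical drive: a rectangular-envelope train of
    ``n_cycles`` oscillations at the carrier.
    """
    n = int(round(spec.n_cycles / spec.carrier_hz * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    return np.sin(2.0 * math.pi * spec.carrier_hz * t)


def received_wavelet(spec: BurstSpec) -> np.ndarray:
    """The echo wave packet as seen by the receiver.

    The transducer pair is band-limited and rings up and down over the
    burst, so the received packet is the drive shaped by a raised-cosine
    envelope.  This gives echoes a dominant central crest, as on a real
    bench, instead of the n-way amplitude tie of an ideal rectangular
    burst.
    """
    wave = synth_burst(spec)
    n = wave.size
    envelope = np.sin(np.pi * (np.arange(n) + 0.5) / n) ** 2
    return wave * envelope


def render_trace(
    arrivals: Sequence[ArrivalRecord],
    burst: BurstSpec,
    noise: NoiseSpec,
    rng: np.random.Generator,
    session_gain: float = 1.0,
    session_jitter_us: float = 0.0,
    additive_std: Optional[float] = None,
    amplitude_gain: float = AMPLITUDE_GAIN,
) -> np.ndarray:
    """Render one digitized trace from a set of arrivals.

    trace = session_gain * sum_k weight_k * burst(t - time_k - jitter)
            + N(0, additive_std) per sample.

    ``additive_std`` overrides the NoiseSpec value (the group-averaged fast
    path passes std / sqrt(group size)).
    """
    n = burst.n_samples
    wave = received_wavelet(burst)
    out = np.zeros(n)
    fs_us = burst.sample_rate_hz * 1e-6  # samples per microsecond
    for a in arrivals:
        if a.time_us > burst.duration_us:
            raise ConfigError(
                f"arrival at {a.time_us:.1f} us exceeds trace duration "
                f"{burst.duration_us:.1f} us"
            )
        start = int(round((a.time_us + session_jitter_us) * fs_us))
        if start < 0 or start >= n:
            continue
        stop = min(n, start + wave.size)
        out[start:stop] += a.weight * amplitude_gain * wave[: stop - start]
    out *= session_gain
    std = noise.additive_std if additive_std is None else additive_std
    if std > 0:
        out += rng.normal(0.0, std, size=n)
    return out


def bench_scene_factory(
    eye: EyeModel | None = None,
    ring: RingSpec | None = None,
    occluder: Optional[OccluderSpec] = OccluderSpec(),
    gaze_range_deg: float = 35.0,
) -> Callable[[tuple[float, float]], Scene]:
    """Scene factory for the gaze protocol: one posed scene per gaze."""
    eye = eye or EyeModel()
    ring = ring or RingSpec()

    def factory(gaze: tuple[float, float]) -> Scene:
        return make_scene(eye, gaze, occluder, ring, gaze_range_deg=gaze_range_deg)

    return factory


class BenchDataset:
    """Lazy gaze-protocol dataset: eager arrivals + manifest, on-demand traces.

    Ray solving runs once per (pose, transmitter position) and is reused
    across repeats and sessions; per-session gain/timing perturbations and
    per-trace noise come from counter-based seeds, so any trace can be
    re-rendered independently and the whole dataset is bitwise reproducible
    from (config, seed).
    """

    def __init__(
        self,
        protocol: ProtocolSpec,
        scene_factory: Callable[[tuple[float, float]], Scene],
        burst: BurstSpec,
        noise: NoiseSpec,
        seed: int,
        fast: bool = True,
    ) -> None:
        self.protocol = protocol
        self.burst = burst
        self.noise = noise
        self.seed = int(seed)
        self.fast = bool(fast)
        self.scene_factory = scene_factory

        first_scene = scene_factory(protocol.gaze_grid_deg[0])
        if first_scene.ring is None or first_scene.eye is None:
            raise ConfigError("protocol scenes must carry an eye and a ring")
        self._eye = first_scene.eye
        self._ring = first_scene.ring

        self.arrivals: dict[tuple[int, int], list[ArrivalRecord]] = {}
        rx = self._ring.transducer(self._eye, protocol.receiver_deg, "receive")
        for pi, gaze in enumerate(protocol.gaze_grid_deg):
            scene = scene_factory(gaze) if pi else first_scene
            for ti, tx_pos in enumerate(protocol.tx_positions_deg):
                tx = self._ring.transducer(self._eye, tx_pos, "transmit")
                self.arrivals[(pi, ti)] = specular_arrivals(scene, tx, rx)

    # -- session perturbations ------------------------------------------------

    def session_params(self, session: int) -> tuple[float, float]:
        """(gain, timing jitter in us) of one session."""
        rng = np.random.Generator(
            np.random.Philox(np.random.SeedSequence((self.seed, 101, session)))
        )
        gain = 1.0 + rng.normal(0.0, self.noise.session_gain_std)
        jitter = rng.normal(0.0, self.noise.session_jitter_us)
        return float(gain), float(jitter)

    # -- trace rendering ------------------------------------------------------

    def _trace_rng(self, session: int, pose: int, tx: int, k: int) -> np.random.Generator:
        return np.random.Generator(
            np.random.Philox(np.random.SeedSequence((self.seed, session, pose, tx, k)))
        )

    def raw_trace(self, session: int, pose: int, tx: int, repeat: int) -> RawTrace:
        """One single-shot trace (full-protocol mode indexing)."""
        gain, jitter = self.session_params(session)
        samples = render_trace(
            self.arrivals[(pose, tx)],
            self.burst,
            self.noise,
            self._trace_rng(session, pose, tx, 1000 + repeat),
            session_gain=gain,
            session_jitter_us=jitter,
        )
        return RawTrace(
            samples=samples,
            sample_rate_hz=self.burst.sample_rate_hz,
            tx_pos_deg=self.protocol.tx_positions_deg[tx],
            repeat=repeat,
            session=session,
            gaze=self.protocol.gaze_grid_deg[pose],
        )

    def averaged_trace(self, session: int, pose: int, tx: int, k: int) -> np.ndarray:
        """The k-th 10-trace group average.

        In fast mode the average is synthesised directly (one render with
        additive noise std reduced by sqrt(group size) -- statistically
        identical for i.i.d. Gaussian noise); otherwise the group's raw
        traces are rendered and averaged samplewise.
        """
        g = self.protocol.group_size
        if self.fast:
            gain, jitter = self.session_params(session)
            return render_trace(
                self.arrivals[(pose, tx)],
                self.burst,
                self.noise,
                self._trace_rng(session, pose, tx, k),
                session_gain=gain,
                session_jitter_us=jitter,
                additive_std=self.noise.additive_std / math.sqrt(g),
            )
        traces = [
            self.raw_trace(session, pose, tx, k * g + j).samples for j in range(g)
        ]
        return np.mean(traces, axis=0)

    # -- bookkeeping ----------------------------------------------------------

    @property
    def manifest(self) -> pd.DataFrame:
        """One row per trace: full mode lists repeats, fast mode group averages."""
        p = self.protocol
        reps = range(p.n_groups) if self.fast else range(p.repeats)
        col = "k" if self.fast else "repeat"
        rows = [
            {
                "session": s,
                "theta_deg": p.gaze_grid_deg[pi][0],
                "phi_deg": p.gaze_grid_deg[pi][1],
                "tx_pos_deg": p.tx_positions_deg[ti],
                col: r,
            }
            for s in range(p.sessions)
            for pi in range(len(p.gaze_grid_deg))
            for ti in range(len(p.tx_positions_deg))
            for r in reps
        ]
        return pd.DataFrame(rows)

    @property
    def n_traces(self) -> int:
        p = self.protocol
        per = p.n_groups if self.fast else p.repeats
        return len(p.gaze_grid_deg) * len(p.tx_positions_deg) * per * p.sessions

    def iter_groups(self) -> Iterator[tuple[int, int, int, int]]:
        """Yield (session, pose, tx, k) over every averaged-trace slot."""
        p = self.protocol
        yield from itertools.product(
            range(p.sessions),
            range(len(p.gaze_grid_deg)),
            range(len(p.tx_positions_deg)),
            range(p.n_groups),
        )

    def sidecar(self) -> dict:
        """JSON-serialisable provenance record."""
        return {
            "sample_rate_hz": self.burst.sample_rate_hz,
            "seed": self.seed,
            "fast": self.fast,
            "n_traces": self.n_traces,
            "poses": len(self.protocol.gaze_grid_deg),
            "tx_positions": list(self.protocol.tx_positions_deg),
            "sessions": self.protocol.sessions,
        }


def run_protocol(
    protocol: ProtocolSpec,
    scene_factory: Callable[[tuple[float, float]], Scene],
    burst: BurstSpec,
    noise: NoiseSpec,
    seed: int,
    fast: bool = True,
) -> BenchDataset:
    """Emulate the gaze protocol; see :class:`BenchDataset`."""
    return BenchDataset(protocol, scene_factory, burst, noise, seed, fast=fast)


# ---------------------------------------------------------------------------
# Characterisation benches
# ---------------------------------------------------------------------------


def bench1_attenuation_sweep(
    distances_mm: Sequence[float],
    attenuation: AttenuationModel | None = None,
    geometry_factor: float = 1.0,
) -> pd.DataFrame:
    """Attenuation bench: facing pair against a flat plate on a stage.

    The echo travels twice the stage distance, so the received peak
    amplitude decays as 10**(-2 A d / 20); returned in arbitrary units.
    """
    d = np.asarray(list(distances_mm), dtype=float)
    if np.any(d <= 0):
        raise ConfigError("plate distances must be positive")
    attn = attenuation or AttenuationModel()
    amp = geometry_factor * attn.factor(2.0 * d)
    return pd.DataFrame({"distance_mm": d, "amplitude": amp})


def bench2_directivity_sweep(
    angles_deg: Sequence[float],
    directivity: DirectivityModel | None = None,
    geometry_factor: float = 1.0,
) -> pd.DataFrame:
    """Directivity bench: rotating transmitter against a fixed facing receiver.

    Received amplitude follows the native curve w(|angle|), zero at and
    beyond the cutoff.
    """
    a = np.asarray(list(angles_deg), dtype=float)
    model = directivity or DirectivityModel()
    amp = geometry_factor * np.asarray(model.weight(np.abs(a)))
    return pd.DataFrame({"angle_deg": a, "amplitude": amp})
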