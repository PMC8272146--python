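"""Feature engineering: group averaging, band-pass filtering, peak picking.

The raw single-shot traces are too noisy for direct peak measurements, so
each block of ten consecutive traces is averaged (k = 0..4 groups out of 50
repeats), band-pass filtered around the carrier ([1.6, 1.9] MHz Butterworth,
order 4), and the squared filtered trace locates the echo: a 45 us window is
centred on its global maximum and the time and value of the first occurrence
of the maximum of the *averaged raw* trace inside that window become the
time-of-flight tau (us) and amplitude a features.  One feature vector per
(pose, session, k) stacks tau_r and a_r over the transmitter positions r.

Filtering is zero-phase (forward-backward) by default so that the group
delay of the filter does not bias tau; a single-pass mode is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .bench import BenchDataset, ConfigError

__all__ = [
    "DegenerateTraceError",
    "IncompleteDatasetError",
    "FeatureSpec",
    "average_groups",
    "bandpass",
    "extract_peak_features",
    "feature_columns",
    "build_feature_matrix",
    "write_feature_csv",
]


class DegenerateTraceError(ValueError):
    """Raised when a trace carries no usable signal (identically zero window)."""


class IncompleteDatasetError(ValueError):
    """Raised when the dataset is missing (pose, transmitter, session) cells."""


@dataclass(frozen=True)
class FeatureSpec:
    """Filter and window settings of the extraction pipeline."""

    band_low_hz: float = 1.6e6
    band_high_hz: float = 1.9e6
    filter_order: int = 4
    window_us: float = 45.0
    group_size: int = 10
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigError("need 0 < band_low < band_high")


def average_groups(traces: np.ndarray, group_size: int = 10) -> np.ndarray:
    """Average consecutive disjoint blocks of ``group_size`` traces.

    ``traces`` is (n_traces, n_samples) in acquisition order; returns
    (n_traces // group_size, n_samples).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("expected a (n_traces, n_samples) array")
    n = traces.shape[0]
    if n % group_size:
        raise ValueError(
            f"{n} traces not divisible by group size {group_size} "
            f"(remainder {n % group_size})"
        )
    return traces.reshape(n // group_size, group_size, -1).mean(axis=1)


def _design_bandpass(spec: FeatureSpec, sample_rate_hz: float) -> np.ndarray:
    if not spec.band_high_hz < sample_rate_hz / 2.0:
        raise ConfigError(
            f"band edge {spec.band_high_hz:g} Hz not below Nyquist "
            f"({sample_rate_hz / 2:g} Hz)"
        )
    return signal.butter(
        spec.filter_order,
        [spec.band_low_hz, spec.band_high_hz],
        btype="bandpass",
        fs=sample_rate_hz,
        output="sos",
    )


def bandpass(
    trace: np.ndarray,
    sample_rate_hz: float,
    spec: FeatureSpec | None = None,
    sos: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Band-pass filter a trace with the order-4 Butterworth design.

    Zero-phase (forward-backward) by default; pass a precomputed ``sos`` to
    amortise the design over many traces.
    """
    spec = spec or FeatureSpec()
    if sos is None:
        sos = _design_bandpass(spec, sample_rate_hz)
    x = np.asarray(trace, dtype=float)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def extract_peak_features(
    raw_avg: np.ndarray,
    filtered: np.ndarray,
    sample_rate_hz: float,
    window_us: float = 45.0,
) -> tuple[float, float]:
    """Time-of-flight and amplitude of the dominant echo.

    Squares the filtered trace, centres a ``window_us`` window on its global
    maximum (clipped at the trace edges), and returns (tau_us, a): the time
    of the first occurrence of the maximum of the averaged raw trace inside
    the window, and that maximum value.
    """
    raw_avg = np.asarray(raw_avg, dtype=float)
    filtered = np.asarray(filtered, dtype=float)
    if raw_avg.shape != filtered.shape:
        raise ValueError("raw and filtered traces must have equal length")
    power = filtered**2
    if not np.any(power > 0):
        raise DegenerateTraceError("filtered trace is identically zero")
    center = int(np.argmax(power))
    half = int(round(window_us * 1e-6 * sample_rate_hz / 2.0))
    lo = max(0, center - half)
    hi = min(raw_avg.size, center + half + 1)
    window = raw_avg[lo:hi]
    if not np.any(window != 0):
        raise DegenerateTraceError("analysis window is identically zero")
    first_peak = int(np.argmax(window))  # argmax returns the first maximum
    tau_us = (lo + first_peak) / sample_rate_hz * 1e6
    return float(tau_us), float(window[first_peak])


def _pos_label(r: float) -> str:
    r_int = int(round(r))
    if r_int < 0:
        return f"m{-r_int}"
    if r_int > 0:
        return f"p{r_int}"
    return "0"


def feature_columns(tx_positions_deg: Sequence[float]) -> list[str]:
    """Canonical feature-column order: all tau then all a, by position."""
    return [f"tof_us_{_pos_label(r)}" for r in tx_positions_deg] + [
        f"amp_{_pos_label(r)}" for r in tx_positions_deg
    ]


def build_feature_matrix(
    dataset: BenchDataset,
    spec: FeatureSpec | None = None,
) -> pd.DataFrame:
    """Extract the full feature table from an emulated protocol dataset.

    Returns one row per (pose, session, k) with columns theta_deg, phi_deg,
    session, k, then tau and amplitude for each transmitter position
    (2 x positions features).  Rows appear in (session, pose, k) order;
    missing dataset cells raise IncompleteDatasetError.
    """
    spec = spec or FeatureSpec()
    p = dataset.protocol
    sos = _design_bandpass(spec, dataset.burst.sample_rate_hz)
    n_pos = len(p.tx_positions_deg)
    cols = feature_columns(p.tx_positions_deg)
    missing = [
        (pi, ti)
        for pi in range(len(p.gaze_grid_deg))
        for ti in range(n_pos)
        if (pi, ti) not in dataset.arrivals
    ]
    if missing:
        raise IncompleteDatasetError(f"missing (pose, transmitter) cells: {missing[:5]}")
    rows = []
    for s in range(p.sessions):
        for pi, (theta, phi) in enumerate(p.gaze_grid_deg):
            for k in range(p.n_groups):
                taus = np.empty(n_pos)
                amps = np.empty(n_pos)
                for ti in range(n_pos):
                    avg = dataset.averaged_trace(s, pi, ti, k)
                    filt = bandpass(avg, dataset.burst.sample_rate_hz, spec, sos=sos)
                    taus[ti], amps[ti] = extract_peak_features(
                        avg, filt, dataset.burst.sample_rate_hz, spec.window_us
                    )
                rows.append(
                    dict(
                        zip(
                            ["theta_deg", "phi_deg", "session", "k"] + cols,
                            [theta, phi, s, k, *taus, *amps],
                        )
                    )
                )
    return pd.DataFrame(rows)


def write_feature_csv(
    features: pd.DataFrame,
    path: str | Path,
    sidecar: Optional[dict] = None,
) -> Path:
    """Write the feature table as CSV with a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, index=False, lineterminator="\n")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path
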