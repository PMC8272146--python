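"""Tone bursts, trace rendering, protocol bookkeeping, bench sweeps."""

import math

import numpy as np
import pandas as pd
import pytest

from echogaze.acoustics import MM_PER_US, ArrivalRecord
from echogaze.bench import (
    AMPLITUDE_GAIN,
    BenchDataset,
    BurstSpec,
    ConfigError,
    NoiseSpec,
    ProtocolSpec,
    bench1_attenuation_sweep,
    bench2_directivity_sweep,
    bench_scene_factory,
    default_gaze_grid,
    received_wavelet,
    render_trace,
    run_protocol,
    synth_burst,
)


def _arrival(t_us, weight=1.0 / AMPLITUDE_GAIN):
    return ArrivalRecord(
        receiver_id=0, path_mm=t_us * MM_PER_US, time_us=t_us, n_bounces=1, weight=weight
    )


QUIET = NoiseSpec(additive_std=0.0, session_gain_std=0.0, session_jitter_us=0.0)


class TestSynthBurst:
    def test_seven_cycles_at_80_mhz_is_322_samples(self):
        wave = synth_burst(BurstSpec())
        assert wave.size == 322  # 7 / 1.74e6 * 80e6, rounded

    def test_dominant_frequency_is_the_carrier(self):
        spec = BurstSpec()
        wave = synth_burst(spec)
        freqs = np.fft.rfftfreq(wave.size, 1.0 / spec.sample_rate_hz)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(wave)))]
        bin_width = spec.sample_rate_hz / wave.size
        assert abs(peak - spec.carrier_hz) <= bin_width

    def test_single_cycle_is_one_sine_period(self):
        spec = BurstSpec(n_cycles=1)
        wave = synth_burst(spec)
        t = np.arange(wave.size) / spec.sample_rate_hz
        assert np.allclose(wave, np.sin(2 * np.pi * spec.carrier_hz * t))
        # one full period: starts at zero and wraps back near zero
        assert abs(wave[0]) < 1e-12 and abs(wave[-1]) < 2 * np.pi / wave.size

    def test_sub_nyquist_sampling_rejected(self):
        with pytest.raises(ConfigError, match="Nyquist"):
            BurstSpec(sample_rate_hz=3e6)

    def test_received_wavelet_peaks_centrally(self):
        wave = received_wavelet(BurstSpec())
        peak = np.argmax(np.abs(wave))
        assert 0.3 * wave.size < peak < 0.7 * wave.size


class TestRenderTrace:
    def test_single_echo_lands_at_arrival_time(self):
        """Cross-correlation with the wavelet peaks at the arrival time."""
        spec = BurstSpec()
        rng = np.random.default_rng(0)
        trace = render_trace([_arrival(120.0)], spec, QUIET, rng)
        wave = received_wavelet(spec)
        xc = np.correlate(trace, wave, mode="valid")
        lag_us = np.argmax(xc) / spec.sample_rate_hz * 1e6
        assert lag_us == pytest.approx(120.0, abs=0.5 / spec.sample_rate_hz * 1e6)

    def test_no_arrivals_no_noise_is_silent(self):
        trace = render_trace([], BurstSpec(), QUIET, np.random.default_rng(0))
        assert not trace.any()

    def test_two_separated_echoes_have_disjoint_support(self):
        spec = BurstSpec()
        trace = render_trace([_arrival(50.0), _arrival(100.0)], spec, QUIET,
                             np.random.default_rng(0))
        fs_us = spec.sample_rate_hz * 1e-6
        gap = trace[int(60 * fs_us): int(90 * fs_us)]
        assert not gap.any()
        assert trace[int(50 * fs_us): int(55 * fs_us)].any()
        assert trace[int(100 * fs_us): int(105 * fs_us)].any()

    def test_arrival_beyond_duration_is_an_error(self):
        with pytest.raises(ConfigError, match="305"):
            render_trace([_arrival(305.0)], BurstSpec(), QUIET, np.random.default_rng(0))

    def test_session_gain_scales_signal(self):
        spec = BurstSpec()
        base = render_trace([_arrival(100.0)], spec, QUIET, np.random.default_rng(0))
        scaled = render_trace([_arrival(100.0)], spec, QUIET, np.random.default_rng(0),
                              session_gain=1.3)
        assert np.allclose(scaled, 1.3 * base)

    def test_noise_averaging_law(self):
        """The std of a 10-trace average of pure noise is std/sqrt(10)."""
        spec = BurstSpec(duration_us=12.5)  # 1000 samples
        noise = NoiseSpec(additive_std=1.0, session_gain_std=0.0, session_jitter_us=0.0)
        rng = np.random.default_rng(42)
        traces = np.array([render_trace([], spec, noise, rng) for _ in range(100)])
        avg = traces.reshape(10, 10, -1).mean(axis=1)
        assert avg.std() == pytest.approx(1.0 / math.sqrt(10), rel=0.05)


TINY = ProtocolSpec(
    gaze_grid_deg=((-5.0, -5.0), (5.0, 5.0), (1.0, -3.0)),
    sessions=2,
)


@pytest.fixture(scope="module")
def tiny_dataset():
    return run_protocol(TINY, bench_scene_factory(), BurstSpec(), NoiseSpec(), seed=21)


class TestProtocol:
    def test_default_counts_multiply_out(self):
        p = ProtocolSpec()
        assert len(p.gaze_grid_deg) == 36
        assert len(p.tx_positions_deg) == 19
        assert p.n_traces == 36 * 19 * 50 * 9 == 307_800

    def test_effective_rate_is_200_hz(self):
        assert ProtocolSpec().effective_rate_hz(BurstSpec()) == pytest.approx(200.0)

    def test_default_grid_spans_pm5_degrees(self):
        grid = np.array(default_gaze_grid())
        assert grid.min() == -5.0 and grid.max() == 5.0
        assert len(grid) == 36

    def test_repeats_must_divide_into_groups(self):
        with pytest.raises(ConfigError, match="group size"):
            ProtocolSpec(repeats=45)

    def test_manifest_counts(self, tiny_dataset):
        m = tiny_dataset.manifest
        p = tiny_dataset.protocol
        assert len(m) == len(p.gaze_grid_deg) * 19 * p.n_groups * p.sessions
        # every trace's gaze label matches its pose
        assert set(zip(m.theta_deg, m.phi_deg)) == set(p.gaze_grid_deg)

    def test_full_mode_manifest_lists_every_repeat(self):
        ds = run_protocol(TINY, bench_scene_factory(), BurstSpec(), NoiseSpec(),
                          seed=21, fast=False)
        assert len(ds.manifest) == 3 * 19 * 50 * 2

    def test_same_seed_reproduces_traces_bitwise(self, tiny_dataset):
        other = run_protocol(TINY, bench_scene_factory(), BurstSpec(), NoiseSpec(), seed=21)
        a = tiny_dataset.averaged_trace(1, 2, 7, 3)
        b = other.averaged_trace(1, 2, 7, 3)
        assert np.array_equal(a, b)
        c = other.averaged_trace(1, 2, 7, 4)
        assert not np.array_equal(a, c)

    def test_fast_and_full_group_averages_share_arrivals(self):
        """Fast mode renders the same deterministic signal as the mean of
        the full mode's ten raw traces (noise-free check)."""
        ds_fast = run_protocol(TINY, bench_scene_factory(), BurstSpec(), QUIET,
                               seed=21, fast=True)
        ds_full = run_protocol(TINY, bench_scene_factory(), BurstSpec(), QUIET,
                               seed=21, fast=False)
        a = ds_fast.averaged_trace(0, 1, 9, 2)
        b = ds_full.averaged_trace(0, 1, 9, 2)
        assert np.allclose(a, b)

    def test_session_perturbations_differ_between_sessions(self, tiny_dataset):
        g0, j0 = tiny_dataset.session_params(0)
        g1, j1 = tiny_dataset.session_params(1)
        assert (g0, j0) != (g1, j1)


class TestBench1:
    def test_round_trip_ratio_law(self):
        table = bench1_attenuation_sweep([10.0, 20.0, 35.0])
        a = table.amplitude.to_numpy()
        d = table.distance_mm.to_numpy()
        expected = 10 ** (-2 * 470.0 * (d[1:] - d[:-1]) / 1000.0 / 20.0)
        assert np.allclose(a[1:] / a[:-1], expected)

    def test_log_amplitude_is_affine_in_distance(self):
        d = np.linspace(5, 60, 12)
        table = bench1_attenuation_sweep(d)
        slope = np.polyfit(d, np.log10(table.amplitude), 1)[0]
        assert slope == pytest.approx(-2 * 470.0 / 1000.0 / 20.0, rel=1e-9)

    def test_amplitude_decays_toward_zero(self):
        table = bench1_attenuation_sweep(np.linspace(1, 500, 50))
        amp = table.amplitude.to_numpy()
        assert np.all(np.diff(amp) < 0)
        assert amp[-1] < 1e-20

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ConfigError):
            bench1_attenuation_sweep([0.0, 10.0])


class TestBench2:
    def test_peak_on_axis_and_symmetric(self):
        table = bench2_directivity_sweep(np.arange(-20, 21, 1))
        amp = table.amplitude.to_numpy()
        assert amp.max() == amp[20] == 1.0
        assert np.allclose(amp, amp[::-1])

    def test_zero_at_and_beyond_cutoff(self):
        table = bench2_directivity_sweep([-20, -15, 15, 16, 30])
        assert not table.amplitude.to_numpy().any()

    def test_half_power_angle_matches_cutoff(self):
        """Received power w(a)^2 crosses one half at cutoff/2 = 7.5 deg."""
        table = bench2_directivity_sweep([7.5])
        assert table.amplitude.iloc[0] ** 2 == pytest.approx(0.5)
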