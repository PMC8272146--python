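"""Reflection, directivity, attenuation, ray emission and tracing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from echogaze.acoustics import (
    MM_PER_US,
    ArrivalRecord,
    AttenuationModel,
    DirectivityModel,
    MediumProperties,
    attenuation_factor,
    directional_weight,
    emit_rays,
    receiver_histogram,
    reflection_fraction,
    trace,
)
from echogaze.geometry import (
    EyeModel,
    OccluderSpec,
    PlateSurface,
    RingSpec,
    Scene,
    SphereSurface,
    Transducer,
    make_scene,
    unit,
)
from echogaze.specular import specular_point_sphere

AIR = MediumProperties(density=1.0, speed=343.0)


class TestReflectionFraction:
    def test_air_to_glass_reflects_nearly_everything(self):
        glass = MediumProperties(density=2580.0, speed=4500.0)
        assert reflection_fraction(AIR, glass) == pytest.approx(0.9999, abs=5e-5)

    def test_matched_impedance_reflects_nothing(self):
        m = MediumProperties(density=1051.0, speed=1550.0)
        assert reflection_fraction(m, m) == 0.0

    def test_three_to_one_ratio(self):
        m1 = MediumProperties(density=1.0, speed=100.0)
        m2 = MediumProperties(density=3.0, speed=100.0)
        assert reflection_fraction(m1, m2) == pytest.approx(0.25)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        r1=st.floats(0.5, 5000, allow_nan=False),
        c1=st.floats(100, 6000, allow_nan=False),
        r2=st.floats(0.5, 5000, allow_nan=False),
        c2=st.floats(100, 6000, allow_nan=False),
    )
    def test_symmetric_and_bounded(self, r1, c1, r2, c2):
        a = MediumProperties(r1, c1)
        b = MediumProperties(r2, c2)
        f = reflection_fraction(a, b)
        assert 0.0 <= f <= 1.0
        assert f == pytest.approx(reflection_fraction(b, a), rel=1e-12)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            MediumProperties(density=0.0, speed=343.0)


class TestDirectivity:
    def test_on_axis_weight_is_exactly_one(self):
        assert directional_weight(0.0) == 1.0

    @pytest.mark.parametrize("alpha", [15.0, 16.0, 45.0, 90.0])
    def test_zero_at_and_beyond_cutoff(self, alpha):
        assert directional_weight(alpha) == 0.0

    def test_midpoint_value(self):
        assert directional_weight(7.5) == pytest.approx(math.cos(math.radians(45.0)))

    def test_monotone_nonincreasing_within_cone(self):
        alphas = np.linspace(0.0, 15.0, 301)
        w = directional_weight(alphas)
        assert np.all(np.diff(w) <= 1e-12)

    def test_negative_angle_rejected(self):
        with pytest.raises(ValueError):
            directional_weight(-1.0)

    def test_configurable_cutoff(self):
        model = DirectivityModel(cutoff_deg=10.0)
        assert model.weight(5.0) == pytest.approx(math.cos(math.radians(45.0)))
        assert model.weight(10.0) == 0.0


class TestAttenuation:
    def test_zero_distance_is_unity(self):
        assert attenuation_factor(0.0) == 1.0

    def test_one_metre_is_470_db(self):
        assert attenuation_factor(1000.0) == pytest.approx(10.0 ** (-470.0 / 20.0))

    def test_60_mm_round_trip_value(self):
        # 470 dB/m x 0.06 m = 28.2 dB
        assert attenuation_factor(60.0) == pytest.approx(10.0 ** (-28.2 / 20.0), rel=1e-12)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 200, 100)
        f = attenuation_factor(d)
        assert np.all(np.diff(f) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            attenuation_factor(-1.0)


class TestEmitRays:
    TX = Transducer(position=(0, 0, 0.0), direction=(0, 0, 1.0), mode="transmit")

    def test_same_seed_reproduces_rays(self):
        a = emit_rays(1000, "directional", self.TX, seed=3)
        b = emit_rays(1000, "directional", self.TX, seed=3)
        assert np.array_equal(a.directions, b.directions)
        assert np.array_equal(a.weights, b.weights)

    def test_hemisphere_monte_carlo_matches_quadrature(self):
        """Mean of a smooth function over emitted directions approximates
        its uniform-hemisphere average."""
        rays = emit_rays(100_000, "omnidirectional", self.TX, seed=9)
        f = lambda z: 1.0 + z**2 + 0.5 * z  # depends on polar angle only
        mc = f(rays.directions[:, 2]).mean()
        exact, _ = integrate.quad(f, 0.0, 1.0)  # z uniform on [0, 1]
        assert mc == pytest.approx(exact, rel=5e-3)

    def test_directional_weights_follow_native_curve(self):
        rays = emit_rays(50_000, "directional", self.TX, seed=4)
        alpha = np.degrees(np.arccos(np.clip(rays.directions[:, 2], -1, 1)))
        assert np.all(rays.weights[alpha >= 15.0] == 0.0)
        inside = alpha < 15.0
        expected = np.cos(np.radians(np.minimum(alpha[inside] * 6.0, 90.0)))
        assert np.allclose(rays.weights[inside], expected, atol=1e-12)

    def test_omnidirectional_weights_are_one(self):
        rays = emit_rays(100, "omnidirectional", self.TX, seed=1)
        assert np.all(rays.weights == 1.0)


def _mirror_pair(d_mm: float):
    scene = Scene(surfaces=[PlateSurface(np.array([0, 0, 0.0]), np.array([0, 0, 1.0]))])
    tx = Transducer(position=(0, 0, d_mm), direction=(0, 0, -1.0), mode="transmit")
    rx = Transducer(
        position=(0, 0, d_mm), direction=(0, 0, -1.0), mode="receive", aperture_radius=2.0
    )
    return scene, tx, rx


class TestTrace:
    def test_mirror_geometry_round_trip(self):
        """Collocated pair facing a plate at d: arrivals at path 2d, t=2d/c."""
        scene, tx, rx = _mirror_pair(50.0)
        rays = emit_rays(50_000, "directional", tx, seed=5)
        arrivals = trace(rays, scene, [rx], max_bounces=3)
        assert arrivals
        for a in arrivals:
            assert a.n_bounces == 1
            assert a.path_mm == pytest.approx(100.0, abs=0.1)
            assert a.time_us == pytest.approx(100.0 / MM_PER_US, abs=0.1 / MM_PER_US)

    def test_path_time_consistency_and_energy_bookkeeping(self):
        scene, tx, rx = _mirror_pair(30.0)
        rays = emit_rays(30_000, "directional", tx, seed=6)
        arrivals = trace(rays, scene, [rx], max_bounces=3)
        for a in arrivals:
            assert a.time_us * MM_PER_US == pytest.approx(a.path_mm, rel=1e-9)
            assert 0.0 <= a.weight <= 1.0
        assert sum(a.weight for a in arrivals) <= rays.weights.sum()

    def test_one_bounce_paths_match_specular_oracle(self):
        """Traced 1-bounce paths on a sphere equal the analytic
        stationary-path length to the crossing point, < 1e-6 mm."""
        scene = Scene(surfaces=[SphereSurface(np.zeros(3), 10.0, "sphere")])
        tx = Transducer(
            position=(0, 8, 40.0), direction=tuple(unit([0, -8, -40.0])), mode="transmit"
        )
        rx = Transducer(
            position=(12, 0, 40.0),
            direction=tuple(unit([-12, 0, -40.0])),
            mode="receive",
            aperture_radius=6.0,
        )
        rays = emit_rays(120_000, "omnidirectional", tx, seed=7)
        arrivals = [a for a in trace(rays, scene, [rx], max_bounces=1) if a.n_bounces == 1]
        assert len(arrivals) >= 5
        for a in arrivals:
            b = np.array(a.arrival_point)
            p = specular_point_sphere(tx.pos, b, np.zeros(3), 10.0)
            oracle = np.linalg.norm(p - tx.pos) + np.linalg.norm(b - p)
            assert abs(oracle - a.path_mm) < 1e-6

    def test_occluder_shadowing_blocks_corneal_echo(self):
        """With the corneal apex covered, the axial receiver sees no
        1-bounce corneal arrivals."""
        eye = EyeModel()
        # aperture shifted far upward: the apex sits behind the shell
        occ = OccluderSpec(aperture_center_y_mm=15.0)
        tx = Transducer(position=(0, 0, 38.4), direction=(0, 0, -1.0), mode="transmit")
        rx = Transducer(
            position=(0.5, 0, 38.4),
            direction=(0, 0, -1.0),
            mode="receive",
            aperture_radius=3.0,
        )
        rays = emit_rays(30_000, "directional", tx, seed=8)
        blocked = trace(rays, make_scene(eye, (0, 0), occ), [rx], max_bounces=1)
        assert not any("cornea" in a.surface_ids for a in blocked)
        open_eye = trace(rays, make_scene(eye, (0, 0), None), [rx], max_bounces=1)
        assert any("cornea" in a.surface_ids for a in open_eye)

    def test_gaze_rotation_monotonically_lengthens_axial_echo(self):
        """Monostatic axial corneal echo time grows as gaze rotates away."""
        from echogaze.specular import specular_arrivals

        eye = EyeModel()
        tx = Transducer(position=(0, 0, 38.4), direction=(0, 0, -1.0), mode="transmit")
        rx = Transducer(position=(0, 0, 38.4), direction=(0, 0, -1.0), mode="receive")
        times = []
        for theta in range(0, 6):
            scene = make_scene(eye, (theta, 0), None)
            arr = [
                a
                for a in specular_arrivals(scene, tx, rx)
                if a.surface_ids == ("cornea",)
            ]
            times.append(min(a.time_us for a in arr))
        assert np.all(np.diff(times) > 0)


class TestReceiverHistogram:
    def _arrival(self, t_us, w, rid=0):
        return ArrivalRecord(receiver_id=rid, path_mm=t_us * MM_PER_US, time_us=t_us,
                             n_bounces=1, weight=w)

    def test_single_arrival_single_bin(self):
        h = receiver_histogram([self._arrival(12.3, 0.5)], bin_width_us=1.0, t_max_us=20)
        edges, mass = h[0]
        assert mass.sum() == pytest.approx(0.5)
        assert np.count_nonzero(mass) == 1
        assert mass[12] == pytest.approx(0.5)

    def test_mass_equals_total_weight(self):
        arr = [self._arrival(t, w) for t, w in [(5, 0.1), (5.2, 0.2), (30, 0.3)]]
        _, mass = receiver_histogram(arr, 2.0)[0]
        assert mass.sum() == pytest.approx(0.6)

    def test_empty_arrivals_is_valid_empty_histogram(self):
        assert receiver_histogram([], 1.0) == {}

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ValueError):
            receiver_histogram([self._arrival(1, 1)], 0.0)

    def test_histogram_shape_converges_with_ray_count(self):
        """Doubling the ray count shrinks the total-variation distance to a
        high-count reference histogram."""
        scene = Scene(surfaces=[PlateSurface(np.array([0, 0, 0.0]), np.array([0, 0, 1.0]))])
        tx = Transducer(position=(0, 0, 30.0), direction=(0, 0, -1.0), mode="transmit")
        rx = Transducer(
            position=(0, 0, 30.0),
            direction=(0, 0, -1.0),
            mode="receive",
            aperture_radius=8.0,
        )

        def norm_hist(n, seed):
            rays = emit_rays(n, "omnidirectional", tx, seed=seed)
            arr = trace(rays, scene, [rx], max_bounces=2)
            _, mass = receiver_histogram(arr, 0.5, t_max_us=200.0, normalize=True)[0]
            return mass

        ref = norm_hist(500_000, 100)
        tv_small = 0.5 * np.abs(norm_hist(4_000, 101) - ref).sum()
        tv_large = 0.5 * np.abs(norm_hist(64_000, 102) - ref).sum()
        assert tv_large < tv_small
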