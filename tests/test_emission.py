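"""Emission analysis: kinematics, peak rules, impulse and energy measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lithocav.emission import (
    TorusState,
    acoustic_emission_energy,
    bubble_energetics,
    collision_speed,
    compression_ratio,
    detect_significant_peaks,
    emission_metrics,
    equivalent_radius,
    mach_number,
    pressure_impulse,
    scale_to_1mm,
    torus_volume,
)
from lithocav.synth import (
    HydrophoneTrace,
    make_hydrophone_trace,
    make_radius_time,
    make_silhouette,
)

MM = 1e-3
US = 1e-6


def test_shock_mach_number_from_measured_speeds():
    assert mach_number(1820.0, 1480.0) == pytest.approx(1.23, abs=0.005)


def test_collision_speed_sums_contributions():
    assert collision_speed(0.0, 12.0) == 12.0
    assert collision_speed(29.0, 39.0) == 68.0
    assert collision_speed(5.0, 7.0) == collision_speed(7.0, 5.0)


class TestEquivalentRadius:
    def _profile_sphere(self, a, n=401):
        z = np.linspace(0, 2 * a, n)
        return z, np.sqrt(np.clip(a**2 - (z - a) ** 2, 0, None))

    def test_sphere_identity(self):
        a = 0.5 * MM
        z, prof = self._profile_sphere(a)
        sil = make_silhouette(prof, z[1] - z[0], pixel_pitch=5e-6)
        assert equivalent_radius(sil) == pytest.approx(a, rel=0.02)

    def test_prolate_spheroid_closed_form(self):
        a, b = 0.8 * MM, 0.4 * MM  # axial, radial semi-axes
        z = np.linspace(0, 2 * a, 501)
        prof = b * np.sqrt(np.clip(1 - ((z - a) / a) ** 2, 0, None))
        sil = make_silhouette(prof, z[1] - z[0], pixel_pitch=5e-6)
        assert equivalent_radius(sil) == pytest.approx((a * b * b) ** (1 / 3), rel=0.02)

    def test_robust_to_pixel_noise(self):
        a = 0.5 * MM
        z, prof = self._profile_sphere(a)
        base = equivalent_radius(make_silhouette(prof, z[1] - z[0], pixel_pitch=5e-6))
        for seed in range(10):
            noisy = make_silhouette(
                prof, z[1] - z[0], pixel_pitch=5e-6, noise=0.01, seed=seed
            )
            assert equivalent_radius(noisy) == pytest.approx(base, rel=0.01)

    def test_empty_silhouette_warns_and_returns_zero(self):
        from lithocav.synth import SilhouetteImage

        sil = SilhouetteImage(np.zeros((41, 41)), 5e-6, 20)
        with pytest.warns(UserWarning):
            assert equivalent_radius(sil) == 0.0


class TestEnergetics:
    def test_potential_energy_formula(self, water):
        s = make_radius_time(1.0 * MM, 150 * US, 1.5, 0.3)
        en = bubble_energetics(s, 0.5 * MM, water)
        # (4 pi / 3) * 98,986 Pa * (1 mm)^3 = 4.15e-4 J
        assert en.EB == pytest.approx(4.15e-4, rel=0.01)

    def test_gamma_definition(self, water):
        s = make_radius_time(1.6 * MM, 250 * US, 1.0, 0.3)
        en = bubble_energetics(s, 0.5 * MM, water)
        assert en.gamma == pytest.approx(0.3125, rel=0.01)

    def test_k1_recovered_from_generated_series(self, water):
        for k1 in (1.0, 1.3, 1.8):
            s = make_radius_time(1.6 * MM, 250 * US, k1, 0.3)
            en = bubble_energetics(s, 0.5 * MM, water)
            assert en.k1 == pytest.approx(k1, rel=0.02)

    def test_rebound_loss_fraction_recovered(self, water):
        s = make_radius_time(1.6 * MM, 250 * US, 1.0, 0.3)
        en = bubble_energetics(s, 0.5 * MM, water)
        assert en.dEB / en.EB == pytest.approx(0.7, rel=0.02)
        assert en.dEB >= 0

    def test_missing_events_rejected(self, water):
        s = make_radius_time(1.6 * MM, 250 * US, 1.0, 0.3)
        s.events.pop("rebound_maximum")
        with pytest.raises(ValueError, match="rebound_maximum"):
            bubble_energetics(s, 0.5 * MM, water)


class TestPeaks:
    def _trace_with(self, amps, spacing=20 * US):
        peaks = [((i + 1) * spacing, a) for i, a in enumerate(amps)]
        return make_hydrophone_trace(peaks, sensor_distance=1 * MM, noise_rms=0.0)

    def test_thirty_percent_rule(self):
        pk = detect_significant_peaks(self._trace_with([10e5, 4e5, 3.5e5, 2e5, 1e5]))
        assert pk.n_significant == 3

    def test_single_peak_is_significant(self):
        pk = detect_significant_peaks(self._trace_with([5e5]))
        assert pk.n_significant == 1

    def test_exactly_thirty_percent_is_not_significant(self):
        t = np.arange(0, 100e-6, 0.2e-6)
        p = np.zeros_like(t)
        p[100] = 1e6
        p[300] = 0.3e6  # exactly the threshold
        tr = HydrophoneTrace(t, p, 1 * MM, 0.0)
        pk = detect_significant_peaks(tr)
        sig_amps = pk.pressures[pk.significant]
        assert 0.3e6 not in sig_amps
        assert pk.n_significant == 1

    def test_all_zero_trace_has_no_peaks(self):
        tr = HydrophoneTrace(np.arange(0, 1e-4, 2e-7), np.zeros(500), 1 * MM, 0.0)
        assert detect_significant_peaks(tr).times.size == 0

    def test_noise_floor_suppresses_spurious_peaks(self):
        tr = make_hydrophone_trace([(20 * US, 10e5)], sensor_distance=1 * MM,
                                   noise_rms=0.02e5, seed=1)
        pk = detect_significant_peaks(tr)
        assert pk.n_significant == 1


class TestScaling:
    def test_identity_at_1mm(self):
        assert scale_to_1mm(12345.0, 1 * MM) == pytest.approx(12345.0)

    def test_3bar_at_10mm_is_30bar(self):
        assert scale_to_1mm(3e5, 10 * MM) == pytest.approx(30e5)

    @given(p=st.floats(1.0, 1e8), d=st.floats(1e-4, 0.1))
    @settings(max_examples=30, deadline=None)
    def test_round_trip(self, p, d):
        assert scale_to_1mm(p, d) * (MM / d) == pytest.approx(p, rel=1e-12)


class TestImpulseAndEnergy:
    def _rect_trace(self, amp, width, distance=10 * MM, dt=0.01 * US):
        t = np.arange(0, 5 * width, dt)
        p = np.where((t >= width) & (t < 2 * width), amp, 0.0)
        return HydrophoneTrace(t, p, distance, 0.0)

    def test_rectangular_impulse(self):
        tr = self._rect_trace(5e5, 2 * US)
        assert pressure_impulse(tr, (0, 1e-5)) == pytest.approx(1.0, rel=0.02)

    def test_zero_trace_zero_impulse(self):
        t = np.linspace(0, 1e-5, 1000)
        tr = HydrophoneTrace(t, np.zeros_like(t), 1 * MM)
        assert pressure_impulse(tr) == 0.0

    def test_empty_window_warns(self):
        tr = self._rect_trace(1e5, 1 * US)
        with pytest.warns(UserWarning):
            assert pressure_impulse(tr, (5e-6, 1e-6)) == 0.0

    def test_rectangular_burst_energy_closed_form(self, water):
        # 4 pi r^2 p^2 tau / (rho c) at r = 10 mm: 8.5e-6 J
        tr = self._rect_trace(1e5, 1 * US)
        assert acoustic_emission_energy(tr, water) == pytest.approx(8.5e-6, rel=0.02)

    def test_energy_independent_of_sensor_distance(self, water):
        # amplitudes follow 1/r: the 4 pi r^2 factor cancels
        e = []
        for d in (5 * MM, 10 * MM, 20 * MM):
            tr = self._rect_trace(1e5 * (10 * MM / d), 1 * US, distance=d)
            e.append(acoustic_emission_energy(tr, water))
        assert e[0] == pytest.approx(e[1], rel=1e-6)
        assert e[1] == pytest.approx(e[2], rel=1e-6)

    def test_two_burst_metrics_recover_generator_ratio(self, water):
        tr = make_hydrophone_trace(
            [(100 * US, 30e5), (300 * US, 10e5)], sensor_distance=10 * MM
        )
        m = emission_metrics(tr, split_time=200 * US, fluid=water)
        assert m.p1 == pytest.approx(30e5, rel=0.01)
        assert m.p2 == pytest.approx(10e5, rel=0.01)
        assert m.p1_over_p2 == pytest.approx(3.0, rel=0.02)


class TestTorus:
    def test_degenerate_cross_section(self):
        assert torus_volume(TorusState(1 * MM, 0.0, 30e-6)) == 0.0

    def test_formula_matches_revolution_integral(self):
        rc, rt = 0.56 * MM, 0.1 * MM
        # numerically revolve the circular cross-section
        y = np.linspace(-rt, rt, 4001)
        half_w = np.sqrt(np.clip(rt**2 - y**2, 0, None))
        V_num = np.trapezoid(2 * np.pi * rc * 2 * half_w, y)
        assert torus_volume(TorusState(rc, rt, 30e-6)) == pytest.approx(V_num, rel=5e-3)

    def test_compression_ratio_quadratic_in_cross_section(self):
        big = TorusState(0.6 * MM, 0.2 * MM, 50e-6)
        small = TorusState(0.6 * MM, 0.1 * MM, 50e-6)
        assert compression_ratio(big, small) == pytest.approx(4.0)

    def test_invalid_torus_rejected(self):
        with pytest.raises(ValueError):
            TorusState(0.1 * MM, 0.2 * MM, 30e-6)
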