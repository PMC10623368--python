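"""Synthetic generators: normalization, closure with analyzers, determinism."""

import numpy as np
import pytest

from lithocav.synth import (
    GridSpec,
    make_bubble_geometry_sequence,
    make_hydrophone_trace,
    make_power_profile,
    make_radius_time,
    make_silhouette,
    rayleigh_collapse_time,
)

MM = 1e-3
US = 1e-6


class TestPowerProfile:
    @pytest.mark.parametrize("shape", ["flat", "trapezoid", "ramped"])
    def test_integral_equals_pulse_energy(self, shape):
        p = make_power_profile(0.2, 70 * US, shape, 0.5 * US)
        assert np.trapezoid(p.power, p.times) == pytest.approx(0.2, rel=1e-3)
        assert (p.power >= 0).all()

    @pytest.mark.parametrize("shape", ["flat", "trapezoid", "ramped"])
    def test_fwhm_matches_request(self, shape):
        p = make_power_profile(0.2, 70 * US, shape, 0.5 * US)
        assert p.measured_fwhm() == pytest.approx(70 * US, rel=0.02)

    def test_flat_top_peak_is_energy_over_fwhm(self):
        p = make_power_profile(0.2, 70 * US, "flat", 0.5 * US)
        assert p.power.max() == pytest.approx(0.2 / 70e-6, rel=1e-6)

    def test_segment_energies_partition_the_pulse(self):
        p = make_power_profile(0.2, 70 * US, "trapezoid", 0.5 * US)
        seg = p.segment_energies(30)
        assert seg.sum() == pytest.approx(0.2, rel=1e-9)
        assert (seg >= 0).all()

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            make_power_profile(Ep=-1)
        with pytest.raises(ValueError):
            make_power_profile(dt=20 * US)  # does not resolve the pulse


@pytest.fixture(scope="module")
def geom():
    return make_bubble_geometry_sequence(SD=0.5 * MM, Re_max=1.6 * MM, n_seg=30)


class TestBubbleGeometry:
    def test_segment_zero_is_empty(self, geom):
        assert not geom.masks[0].any()

    def test_final_volume_matches_re_max(self, geom):
        Re = geom.equivalent_radii()[-1]
        assert Re == pytest.approx(1.6 * MM, rel=0.02)

    def test_default_contact_segment_is_5_at_half_mm(self, geom):
        assert geom.contact_segment == 5
        # before contact the vapor never touches the boundary row ...
        pre = geom.masks[geom.contact_segment - 1]
        assert not pre[:, 0].any()
        # ... and after contact it does
        post = geom.masks[geom.contact_segment + 1]
        assert post[:, 0].any()

    def test_area_monotone_during_growth(self, geom):
        areas = geom.masks.sum(axis=(1, 2))
        assert (np.diff(areas) >= 0).all()

    def test_coarse_grid_rejected(self):
        bad = GridSpec(nr=4, nz=64, dr=0.6 * MM, dz=0.05 * MM)
        with pytest.raises(ValueError, match="resolve"):
            make_bubble_geometry_sequence(grid=bad)


class TestRadiusTime:
    def test_growth_monotone_to_maximum(self):
        s = make_radius_time(1.6 * MM, 250 * US, 1.0, 0.3)
        m = s.times <= s.event_time("maximum")
        assert (np.diff(s.Re[m]) >= -1e-15).all()
        i_max = np.argmax(s.Re)
        assert s.times[i_max] == pytest.approx(250 * US, abs=s.times[1])

    def test_collapse_at_k1_times_2Tc(self, water):
        k1 = 1.2
        s = make_radius_time(1.6 * MM, 250 * US, k1, 0.3)
        Tc = rayleigh_collapse_time(1.6 * MM, water)
        assert s.event_time("primary_collapse") == pytest.approx(k1 * 2 * Tc, rel=1e-9)

    def test_rebound_energy_fraction(self):
        # EB ~ Re^3: with rebound_fraction 0.3 the recovered dEB/EB is 0.7
        s = make_radius_time(1.6 * MM, 250 * US, 1.0, 0.3)
        Re_max = s.Re.max()
        t_reb = s.event_time("rebound_maximum")
        Re_reb = np.interp(t_reb, s.times, s.Re)
        assert 1.0 - (Re_reb / Re_max) ** 3 == pytest.approx(0.7, rel=0.02)

    def test_events_ordered(self):
        s = make_radius_time(1.6 * MM, 250 * US, 1.3, 0.25)
        order = ["inception", "maximum", "primary_collapse", "rebound_maximum", "secondary_collapse"]
        times = [s.event_time(e) for e in order]
        assert times == sorted(times)

    def test_infeasible_collapse_before_maximum_rejected(self):
        # 2 Tc for a 1 mm bubble is ~184 us < 250 us: k1 = 1 is impossible
        with pytest.raises(ValueError, match="infeasible"):
            make_radius_time(1.0 * MM, 250 * US, 1.0, 0.3)


class TestHydrophone:
    def test_one_over_r_scaling(self):
        tr = make_hydrophone_trace(
            [(20 * US, 30e5)], sensor_distance=10 * MM, noise_rms=0.0, dt=0.02 * US
        )
        assert tr.pressure.max() == pytest.approx(3.0e5, rel=1e-3)

    def test_noiseless_peak_time_round_trip(self):
        tr = make_hydrophone_trace([(20 * US, 30e5)], sensor_distance=10 * MM, noise_rms=0.0)
        assert abs(tr.times[np.argmax(tr.pressure)] - 20 * US) <= 2 * tr.dt

    def test_seed_determinism(self):
        a = make_hydrophone_trace([(20 * US, 30e5)], noise_rms=100.0, seed=7)
        b = make_hydrophone_trace([(20 * US, 30e5)], noise_rms=100.0, seed=7)
        assert np.array_equal(a.pressure, b.pressure)

    def test_overlapping_peaks_warn_and_superpose(self):
        with pytest.warns(UserWarning, match="superpose"):
            tr = make_hydrophone_trace(
                [(20 * US, 10e5), (20.2 * US, 10e5)], sensor_distance=1 * MM
            )
        assert tr.pressure.max() > 10e5  # amplitudes added


class TestSilhouette:
    def test_sphere_renders_with_requested_area(self):
        a = 0.5 * MM
        z = np.linspace(0, 2 * a, 201)
        prof = np.sqrt(np.clip(a**2 - (z - a) ** 2, 0, None))
        sil = make_silhouette(prof, z[1] - z[0], pixel_pitch=10e-6)
        area_px = sil.binary.sum() * sil.pixel_pitch**2
        assert area_px == pytest.approx(np.pi * a**2, rel=0.02)

    def test_blurred_image_deterministic(self):
        z = np.linspace(0, 1 * MM, 101)
        prof = np.full_like(z, 0.3 * MM)
        s1 = make_silhouette(prof, z[1] - z[0], blur=2.0, noise=0.05, seed=3)
        s2 = make_silhouette(prof, z[1] - z[0], blur=2.0, noise=0.05, seed=3)
        assert np.array_equal(s1.image, s2.image)

    def test_unresolved_bubble_rejected(self):
        z = np.linspace(0, 0.1 * MM, 11)
        prof = np.full_like(z, 0.02 * MM)
        with pytest.raises(ValueError, match="20 px"):
            make_silhouette(prof, z[1] - z[0], pixel_pitch=20e-6)
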