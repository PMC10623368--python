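"""Monte Carlo transport: analytic oracles, conservation, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lithocav.photon_mc import (
    STONE,
    VAPOR,
    WATER,
    beer_lambert_transmission,
    media_from_mask,
    run_dynamic_simulation,
    trace_segment,
)
from lithocav.materials import OpticalMedium, get_material
from lithocav.synth import GridSpec, make_bubble_geometry_sequence, make_power_profile

MM = 1e-3


class TestBeerLambert:
    def test_zero_path_transmits_everything(self):
        assert beer_lambert_transmission(0.0, 12345.0) == 1.0

    def test_half_mm_of_water(self):
        # exp(-2.42/mm * 0.5 mm) = exp(-1.21)
        assert beer_lambert_transmission(0.5 * MM, 2420.0) == pytest.approx(
            0.2982, abs=1e-4
        )

    @given(
        a=st.floats(0, 2e-3),
        b=st.floats(0, 2e-3),
        mu=st.floats(0, 5000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_multiplicative_in_path_length(self, a, b, mu):
        t_ab = beer_lambert_transmission(a + b, mu)
        t_a = beer_lambert_transmission(a, mu)
        t_b = beer_lambert_transmission(b, mu)
        assert t_ab == pytest.approx(t_a * t_b, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            beer_lambert_transmission(-1.0, 10.0)


def _water_grid(nz=125):
    return GridSpec(nr=125, nz=nz, dr=0.01 * MM, dz=0.004 * MM, z0=0.0)


class TestTraceSegment:
    def test_collimated_transmission_matches_beer_lambert(self):
        grid = _water_grid()
        media = media_from_mask(None, grid)
        dep = trace_segment(
            1.0, media, n_photons=20_000, seed=2, launch_z=0.5 * MM,
            target_plane_z=0.0, numerical_aperture=0.0,
        )
        assert dep.transmitted == pytest.approx(
            beer_lambert_transmission(0.5 * MM, 2420.0), rel=1e-3
        )

    def test_vapor_channel_transmits_over_80_percent(self):
        grid = _water_grid()
        mask = np.zeros((grid.nr, grid.nz), bool)
        mask[grid.r_centers <= 0.3 * MM, :] = True
        media = media_from_mask(mask, grid)
        dep = trace_segment(1.0, media, n_photons=20_000, seed=1,
                            launch_z=0.5 * MM, target_plane_z=0.0)
        assert dep.transmitted >= 0.80

    def test_transparent_medium_conserves_without_absorption(self):
        grid = _water_grid()
        clear = OpticalMedium("clear", 0.0, 0.0, 0.0, 1.33)
        media = media_from_mask(None, grid, optics={WATER: clear, STONE: clear, VAPOR: clear})
        dep = trace_segment(1.0, media, n_photons=5_000, seed=3, launch_z=0.5 * MM)
        assert dep.absorbed.sum() == pytest.approx(0.0, abs=1e-12)
        assert dep.transmitted + dep.escaped == pytest.approx(1.0, rel=1e-9)

    def test_energy_ledger_closes_with_scattering(self):
        grid = GridSpec(nr=64, nz=96, dr=0.02 * MM, dz=0.02 * MM, z0=-1.0 * MM)
        media = media_from_mask(np.zeros((64, 46), bool), grid)
        dep = trace_segment(0.0066, media, n_photons=5_000, seed=4, launch_z=0.9 * MM)
        assert dep.conservation_residual() < 1e-6

    def test_seed_determinism(self):
        grid = _water_grid()
        media = media_from_mask(None, grid)
        d1 = trace_segment(1.0, media, n_photons=2_000, seed=9, launch_z=0.5 * MM)
        d2 = trace_segment(1.0, media, n_photons=2_000, seed=9, launch_z=0.5 * MM)
        assert np.array_equal(d1.absorbed, d2.absorbed)
        assert d1.escaped == d2.escaped

    def test_zero_scattering_attenuation_on_random_paths(self, rng):
        # property: ballistic MC equals the exponential law for any depth
        for depth_cells in rng.integers(20, 120, size=3):
            grid = GridSpec(nr=60, nz=int(depth_cells), dr=0.01 * MM, dz=0.004 * MM)
            media = media_from_mask(None, grid)
            L = grid.nz * grid.dz
            dep = trace_segment(
                1.0, media, n_photons=2_000, seed=int(depth_cells),
                launch_z=L, target_plane_z=0.0, numerical_aperture=0.0,
            )
            assert dep.transmitted == pytest.approx(
                beer_lambert_transmission(L, 2420.0), rel=1e-3
            )

    def test_unlabeled_voxels_rejected(self):
        grid = _water_grid()
        labels = np.full((grid.nr, grid.nz), 7, dtype=np.int8)
        from lithocav.photon_mc import MediaMap

        with pytest.raises(ValueError, match="unlabeled"):
            MediaMap(grid, labels, {WATER: get_material("water", "optical")})

    def test_too_few_photons_rejected(self):
        media = media_from_mask(None, _water_grid())
        with pytest.raises(ValueError, match="photons"):
            trace_segment(1.0, media, n_photons=10)


@pytest.fixture(scope="module")
def small_setup():
    pulse = make_power_profile()
    geom = make_bubble_geometry_sequence(
        SD=0.5 * MM, Re_max=1.6 * MM, n_seg=10,
        grid=GridSpec(nr=64, nz=64, dr=3.75e-05, dz=6.6e-05),
        segment_duration=15e-6,
    )
    return pulse, geom


class TestDynamicRun:
    def test_budget_fractions_sum_to_one(self, small_setup):
        pulse, geom = small_setup
        budget, maps = run_dynamic_simulation(
            pulse, geom, n_photons_per_segment=2_000, seed=0
        )
        total = budget.fraction_fluid + budget.fraction_solid + budget.fraction_escaped
        assert total == pytest.approx(1.0, abs=1e-9)
        for dep in maps:
            assert dep.conservation_residual() < 1e-6

    def test_no_bubble_fluid_fraction_matches_beer_lambert(self):
        # frozen "no bubble" geometry, collimated: water absorbs 1 - exp(-mu_a SD)
        pulse = make_power_profile(numerical_aperture=0.0)
        grid = GridSpec(nr=64, nz=50, dr=0.02 * MM, dz=0.01 * MM)
        geom_masks = np.zeros((4, 64, 50), bool)
        from lithocav.synth import BubbleGeometrySequence

        geom = BubbleGeometrySequence(
            segment_duration=37.5e-6, masks=geom_masks, grid=grid,
            SD=0.5 * MM, contact_segment=1,
        )
        budget, _ = run_dynamic_simulation(
            pulse, geom, n_photons_per_segment=4_000, seed=5
        )
        absorbed_water = 1.0 - beer_lambert_transmission(0.5 * MM, 2420.0)
        # stone scatters some light back into the water, so allow an upward bias
        assert budget.fraction_fluid == pytest.approx(absorbed_water, rel=0.15)

    def test_segment_mismatch_rejected(self, small_setup):
        pulse, geom = small_setup
        # geometry with a different segment count than requested energies
        seg_E = pulse.segment_energies(geom.n_segments)
        assert len(seg_E) == geom.n_segments  # consistency of the helper itself
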