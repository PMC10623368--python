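"""Wave solver: free-field law, interface physics, principal stresses."""

import numpy as np
import pytest

from lithocav.materials import ElasticMaterial, get_material
from lithocav.waves import (
    WaveDomain,
    _run,
    build_source,
    head_wave_angle_analytic,
    principal_stresses,
    rayleigh_wave_speed,
    simulate,
)

MM = 1e-3


class TestPrincipalStresses:
    def test_uniaxial_tension(self):
        s1, s3 = principal_stresses(0.0, 0.0, 1e6, 0.0)
        assert s1 == pytest.approx(1e6)
        assert s3 == pytest.approx(0.0)

    def test_pure_shear(self):
        s1, s3 = principal_stresses(0.0, 0.0, 0.0, 2e5)
        assert s1 == pytest.approx(2e5)
        assert s3 == pytest.approx(-2e5)

    def test_random_tensors_match_eigendecomposition(self, rng):
        for _ in range(100):
            rr, tt, zz, rz = rng.normal(0, 1e6, 4)
            s1, s3 = principal_stresses(rr, tt, zz, rz)
            T = np.array([[rr, 0, rz], [0, tt, 0], [rz, 0, zz]])
            ev = np.linalg.eigvalsh(T)
            assert s1 == pytest.approx(ev[-1], rel=1e-12, abs=1e-3)
            assert s3 == pytest.approx(ev[0], rel=1e-12, abs=1e-3)


class TestRayleighSpeed:
    def test_viktorov_approximation(self, quartz):
        # (0.87 + 1.12 nu) / (1 + nu) * c_T is accurate to well under 1%
        nu = quartz.poisson
        approx = (0.87 + 1.12 * nu) / (1 + nu) * quartz.c_T
        assert rayleigh_wave_speed(quartz) == pytest.approx(approx, rel=0.005)

    def test_analytic_head_wave_angle_near_25_degrees(self):
        nu = 0.17
        cT = 3780.0
        cL = cT * np.sqrt(2 * (1 - nu) / (1 - 2 * nu))
        qz = ElasticMaterial("qz", 2200.0, cL, cT)
        angle = head_wave_angle_analytic(1480.0, qz)
        assert angle == pytest.approx(25.6, abs=0.3)


@pytest.fixture(scope="module")
def free_field(water):
    dom = WaveDomain(r_max=2.3 * MM, z_min=-2.3 * MM, z_max=2.3 * MM, h=12e-6,
                     sponge_cells=24)
    return _run(
        water, None, dom, duration=3.2e-6, src_amplitude=1.0, src_width=0.4e-6,
        src_z=0.0, point_probes=((0.5 * MM, 0.0), (1.0 * MM, 0.0), (2.0 * MM, 0.0)),
        record_energy_every=40,
    )


class TestFreeField:
    def test_peak_follows_one_over_r(self, free_field):
        p = {r: s.max() for (r, _), s in free_field.point_records.items()}
        assert p[1.0 * MM] / p[0.5 * MM] == pytest.approx(0.5, rel=0.03)
        assert p[2.0 * MM] / p[1.0 * MM] == pytest.approx(0.5, rel=0.03)

    def test_radiated_energy_independent_of_radius(self, free_field, water):
        # 4 pi r^2 / (rho c) * int p^2 dt evaluated at two radii
        dt = free_field.dt
        es = []
        for r in (0.5 * MM, 1.0 * MM):
            s = free_field.point_records[(r, 0.0)]
            es.append(4 * np.pi * r**2 / (water.rho * water.c) * np.sum(s**2) * dt)
        assert es[1] == pytest.approx(es[0], rel=0.03)

    def test_energy_non_increasing_after_source_off(self, free_field):
        eh = free_field.energy_history
        t_off = 8 * 0.4e-6 / np.sqrt(2 * np.log(2))
        late = eh[eh[:, 0] > t_off + 0.1e-6]
        assert late.shape[0] >= 3
        assert (np.diff(late[:, 1]) <= 1e-3 * late[0, 1]).all()


class TestSourceCalibration:
    def test_requested_peak_at_1mm(self, water):
        src = build_source(30e5, 0.4e-6, 30e-6, water, h=12e-6)
        dom = WaveDomain(r_max=1.4 * MM, z_min=-1.4 * MM, z_max=1.4 * MM, h=12e-6,
                         sponge_cells=24)
        res = _run(water, None, dom, duration=3.2e-6, src_amplitude=src.amplitude,
                   src_width=src.pulse_width, src_z=0.0,
                   point_probes=((1.0 * MM, 0.0),))
        assert res.point_records[(1.0 * MM, 0.0)].max() == pytest.approx(30e5, rel=0.02)

    def test_unresolvable_pulse_rejected(self, water):
        with pytest.raises(ValueError, match="unresolvable"):
            build_source(30e5, 1e-9, 30e-6, water, h=12e-6)


@pytest.fixture(scope="module")
def plane_setup(water):
    qz = get_material("quartz", "elastic")
    dom = WaveDomain(r_max=0.4 * MM, z_min=-0.6 * MM, z_max=1.2 * MM, h=10e-6,
                     sponge_cells=28)

    def run(solid):
        return _run(
            water, solid, dom, duration=1.6e-6, src_amplitude=1e15,
            src_width=0.1e-6, src_z=0.8 * MM,
            point_probes=((0.05 * MM, 0.4 * MM), (0.05 * MM, 0.008 * MM)),
            plane_source=True,
        )

    return qz, run


class TestInterface:
    def test_normal_incidence_reflection_coefficient(self, plane_setup, water):
        qz, run = plane_setup
        res = run(qz)
        t = res.times
        s = res.point_records[(0.05 * MM, 0.4 * MM)]
        inc = np.abs(s[(t > 0.3e-6) & (t < 0.9e-6)]).max()
        refl = np.abs(s[(t > 0.95e-6) & (t < 1.5e-6)]).max()
        Z1 = water.rho * water.c
        Z2 = qz.rho * qz.c_L
        expected = (Z2 - Z1) / (Z2 + Z1)  # ~0.80 water -> fused quartz
        assert refl / inc == pytest.approx(expected, rel=0.03)

    def test_rigid_limit_pressure_doubling(self, plane_setup, water):
        qz, run = plane_setup
        rigid = ElasticMaterial("rigid", qz.rho * 1e3, qz.c_L, qz.c_T)
        res_free = run(qz)
        res_rigid = run(rigid)
        t = res_free.times
        s_inc = res_free.point_records[(0.05 * MM, 0.4 * MM)]
        inc = np.abs(s_inc[(t > 0.3e-6) & (t < 0.9e-6)]).max()
        boundary = np.abs(res_rigid.point_records[(0.05 * MM, 0.008 * MM)]).max()
        assert boundary / inc == pytest.approx(2.0, rel=0.03)


class TestSolidCoupling:
    def test_boundary_traces_have_ordered_principals(self, water, quartz):
        src = build_source(30e5, 0.15e-6, 40e-6, water, h=12e-6, shape="compressive")
        dom = WaveDomain(r_max=1.0 * MM, z_min=-0.5 * MM, z_max=0.5 * MM, h=12e-6)
        res = simulate(src, water, quartz, dom, duration=0.8e-6,
                       stations=np.arange(0.05, 0.9, 0.1) * MM)
        assert len(res.traces) == 9
        for tr in res.traces:
            assert (tr.sigma1 >= tr.sigma3 - 1e-6).all()
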