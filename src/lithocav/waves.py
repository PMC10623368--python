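"""Axisymmetric linear fluid-solid wave propagation from a monopole source.

An explicit velocity-stress staggered-grid finite-difference scheme on
(r, z), with the fluid treated as the mu = 0 limit of the same isotropic
elastic update — one unified rule for both half-spaces, coupling the
acoustic field in the water to longitudinal, shear and (leaky) Rayleigh
waves in the solid.  The staggering places no field on the symmetry axis's
singular 1/r terms:

* sigma_rr, sigma_tt, sigma_zz (and material lambda, mu) at (i+1/2, j)
* v_r at (i, j) with v_r = 0 on the axis
* sigma_rz at (i, j+1/2) with sigma_rz = 0 on the axis
* v_z at (i+1/2, j+1/2)

The monopole source injects an isotropic stress-rate into a small blob of
fluid cells at height h_c above the interface; its amplitude is calibrated
by a free-field run so the radiated pulse matches a requested peak
pressure at 1 mm (free field obeys p = s(t - r/c) / r).  Outer boundaries
are Cerjan-style exponential sponges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .materials import AmbientFluid, ElasticMaterial, get_material

__all__ = [
    "SourceModel",
    "WaveDomain",
    "WaveResult",
    "BoundaryStressTrace",
    "build_source",
    "simulate",
    "head_wave_angle",
    "head_wave_angle_analytic",
    "rayleigh_wave_speed",
    "principal_stresses",
]

MM = 1e-3


def rayleigh_wave_speed(solid: ElasticMaterial) -> float:
    """Free-surface Rayleigh wave speed from the characteristic equation.

    Solves (2 - x^2)^2 = 4 sqrt(1 - x^2 cT^2/cL^2) sqrt(1 - x^2) for
    x = c_R / c_T in (0, 1).  The fluid-loaded (leaky) Rayleigh speed of a
    stiff solid under water differs only marginally.
    """
    k = (solid.c_T / solid.c_L) ** 2

    def f(x):
        return (2.0 - x * x) ** 2 - 4.0 * np.sqrt(1.0 - k * x * x) * np.sqrt(1.0 - x * x)

    x = brentq(f, 0.3, 1.0 - 1e-12)
    return x * solid.c_T


def head_wave_angle_analytic(fluid_c: float, solid: ElasticMaterial) -> float:
    """Schmidt head-wave angle from the surface normal: arcsin(c / c_R), deg."""
    c_R = rayleigh_wave_speed(solid)
    return float(np.degrees(np.arcsin(fluid_c / c_R)))


def principal_stresses(
    sigma_rr: np.ndarray,
    sigma_tt: np.ndarray,
    sigma_zz: np.ndarray,
    sigma_rz: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """First and third principal stresses of the axisymmetric tensor.

    The hoop direction decouples, so the eigenvalues are sigma_tt together
    with the two eigenvalues of the in-plane [[rr, rz], [rz, zz]] block.
    Inputs broadcast elementwise (e.g. time series per station).
    """
    mean = 0.5 * (sigma_rr + sigma_zz)
    radius = np.sqrt(0.25 * (sigma_rr - sigma_zz) ** 2 + sigma_rz**2)
    e1, e2 = mean + radius, mean - radius
    s1 = np.maximum(np.maximum(e1, e2), sigma_tt)
    s3 = np.minimum(np.minimum(e1, e2), sigma_tt)
    return s1, s3


def _bipolar(t: np.ndarray | float, width: float) -> np.ndarray:
    """Single-cycle bipolar pulse (derivative of a Gaussian), unit peak.

    Leading compression lobe first; ``width`` sets the lobe time scale
    (sigma = width / sqrt(2 ln 2)).
    """
    sigma = width / np.sqrt(2.0 * np.log(2.0))
    u = (np.asarray(t) - 4.0 * sigma) / sigma
    return -u * np.exp(0.5 * (1.0 - u * u))


def _gaussian_rate(t: np.ndarray | float, width: float) -> np.ndarray:
    """Injection rate whose radiated far field is the bipolar pulse above.

    The radiated pressure of a monopole is proportional to the time
    derivative of the injected stress rate, so injecting a smooth Gaussian
    yields the clean single-cycle bipolar wave with no switch-on step.
    """
    sigma = width / np.sqrt(2.0 * np.log(2.0))
    u = (np.asarray(t) - 4.0 * sigma) / sigma
    return np.exp(-0.5 * u * u)


def _sigmoid_rate(t: np.ndarray | float, width: float) -> np.ndarray:
    """Injection rate whose radiated far field is a monopolar Gaussian.

    A smooth step (cumulative Gaussian) of volume injection radiates a
    purely compressive pulse — the standard model for the shock emitted by
    a collapsing bubble, with no rarefaction tail.
    """
    sigma = width / np.sqrt(2.0 * np.log(2.0))
    u = (np.asarray(t) - 4.0 * sigma) / sigma
    return 0.5 * (1.0 + erf(u / np.sqrt(2.0)))


@dataclass(frozen=True)
class SourceModel:
    """Calibrated monopole source.

    ``amplitude`` is the stress-rate injection scale for the grid spacing
    ``h`` it was calibrated on; ``peak_p_at_1mm`` is the resulting
    free-field peak pressure at 1 mm from the source.
    """

    peak_p_at_1mm: float  # Pa
    pulse_width: float  # s
    h_c: float  # m, source height above the interface
    amplitude: float
    h: float  # m, grid spacing of the calibration
    shape: str = "bipolar"  # "bipolar" or "compressive"

    def waveform(self, t: np.ndarray | float) -> np.ndarray:
        """Radiated free-field pulse shape (unit peak)."""
        if self.shape == "compressive":
            sigma = self.pulse_width / np.sqrt(2.0 * np.log(2.0))
            u = (np.asarray(t) - 4.0 * sigma) / sigma
            return np.exp(-0.5 * u * u)
        return _bipolar(t, self.pulse_width)

    @property
    def duration(self) -> float:
        sigma = self.pulse_width / np.sqrt(2.0 * np.log(2.0))
        return 8.0 * sigma


@dataclass(frozen=True)
class WaveDomain:
    """Physical extents and resolution of the simulation box (metres)."""

    r_max: float
    z_min: float
    z_max: float
    h: float
    sponge_cells: int = 30

    def __post_init__(self):
        if self.z_min >= 0 and self.z_max <= 0:
            raise ValueError("domain must have extent")


@dataclass
class BoundaryStressTrace:
    """sigma_1 / sigma_3 histories at one radial station on the interface."""

    R: float
    times: np.ndarray
    sigma1: np.ndarray
    sigma3: np.ndarray
    sigma_rr: np.ndarray = None
    sigma_tt: np.ndarray = None
    sigma_zz: np.ndarray = None
    sigma_rz: np.ndarray = None


@dataclass
class WaveResult:
    """Output bundle of a wave run."""

    domain: WaveDomain
    dt: float
    snapshot_times: list
    snapshots: list  # fluid-pressure (and total-field) arrays, (Nr, Nz+1)
    traces: list
    r_stress: np.ndarray  # radial coordinates of stress columns
    z_levels: np.ndarray
    energy_history: np.ndarray = None
    point_records: dict = field(default_factory=dict)  # (r, z) -> pressure series
    times: np.ndarray = None


def _material_arrays(
    r_s: np.ndarray,
    z_levels: np.ndarray,
    fluid: AmbientFluid,
    solid: ElasticMaterial | None,
    layered: tuple[ElasticMaterial, float] | None = None,
):
    """lambda, mu, rho at the normal-stress points (Nr, Nz+1)."""
    Nr, Nzp = r_s.size, z_levels.size
    lam = np.full((Nr, Nzp), fluid.rho * fluid.c**2)
    mu = np.zeros((Nr, Nzp))
    rho = np.full((Nr, Nzp), fluid.rho)
    if solid is not None:
        in_solid = z_levels < 0.0
        lam[:, in_solid] = solid.lam
        mu[:, in_solid] = solid.mu
        rho[:, in_solid] = solid.rho
        if layered is not None:
            base, thickness = layered
            deep = z_levels < -thickness
            lam[:, deep] = base.lam
            mu[:, deep] = base.mu
            rho[:, deep] = base.rho
    return lam, mu, rho


def _sponge_profile(n: int, width: int, alpha: float = 0.010) -> np.ndarray:
    """Cerjan damping multiplier along one axis (1 in the interior)."""
    g = np.ones(n)
    for k in range(width):
        g[n - 1 - k] = np.exp(-((alpha * (width - k)) ** 2))
    return g


def _run(
    fluid: AmbientFluid,
    solid: ElasticMaterial | None,
    domain: WaveDomain,
    duration: float,
    src_amplitude: float,
    src_width: float,
    src_z: float,
    stations: np.ndarray | None = None,
    snapshot_times: tuple = (),
    point_probes: tuple = (),
    layered: tuple[ElasticMaterial, float] | None = None,
    cfl: float = 0.45,
    plane_source: bool = False,
    src_shape: str = "bipolar",
    record_energy_every: int = 0,
    record_traces: bool = True,
) -> WaveResult:
    h = domain.h
    sp = domain.sponge_cells
    Nr = int(round(domain.r_max / h)) + sp
    Nz = int(round((domain.z_max - domain.z_min) / h)) + 2 * sp
    z_min = domain.z_min - sp * h
    # shapes (see module docstring for staggering)
    Nzp = Nz + 1
    r_s = (np.arange(Nr) + 0.5) * h
    r_v = np.arange(Nr + 1) * h
    z_levels = z_min + np.arange(Nzp) * h

    lam, mu, rho = _material_arrays(r_s, z_levels, fluid, solid, layered)
    c_max = fluid.c if solid is None else max(fluid.c, solid.c_L)
    if layered is not None:
        c_max = max(c_max, layered[0].c_L)
    dt = cfl * h / (np.sqrt(2.0) * c_max)
    n_steps = int(np.ceil(duration / dt))

    # staggered material fields
    rho_vr = np.empty((Nr + 1, Nzp))
    rho_vr[1:-1, :] = 0.5 * (rho[1:, :] + rho[:-1, :])
    rho_vr[0, :] = rho[0, :]
    rho_vr[-1, :] = rho[-1, :]
    rho_vz = 0.5 * (rho[:, 1:] + rho[:, :-1])
    # harmonic mean keeps mu_rz = 0 at the fluid-solid interface (free slip)
    mu4 = np.zeros((Nr + 1, Nz))
    mu_pad = np.pad(mu, ((1, 1), (0, 0)), mode="edge")
    stack = np.stack(
        [mu_pad[:-1, 1:], mu_pad[:-1, :-1], mu_pad[1:, 1:], mu_pad[1:, :-1]]
    )
    with np.errstate(divide="ignore"):
        inv = np.where(stack > 0, 1.0 / np.where(stack > 0, stack, 1.0), np.inf)
    mu4 = np.where(np.isinf(inv).any(axis=0), 0.0, 4.0 / inv.sum(axis=0))

    srr = np.zeros((Nr, Nzp))
    stt = np.zeros((Nr, Nzp))
    szz = np.zeros((Nr, Nzp))
    srz = np.zeros((Nr + 1, Nz))
    vr = np.zeros((Nr + 1, Nzp))
    vz = np.zeros((Nr, Nz))

    # sponge masks per field shape (outer r, bottom, top)
    gr_s = _sponge_profile(Nr, sp)
    gz_lvl = _sponge_profile(Nzp, sp) * _sponge_profile(Nzp, sp)[::-1]
    gz_half = _sponge_profile(Nz, sp) * _sponge_profile(Nz, sp)[::-1]
    if plane_source:
        # a plane wave has no radial dependence; damping the rim would
        # diffract artificial signal inward, so only the z ends absorb
        gr_s = np.ones(Nr)
    gr_v = np.ones(Nr + 1)
    gr_v[1:] = gr_s
    damp_s = gr_s[:, None] * gz_lvl[None, :]
    damp_v_r = gr_v[:, None] * gz_lvl[None, :]
    damp_rz = gr_v[:, None] * gz_half[None, :]
    damp_vz = gr_s[:, None] * gz_half[None, :]

    # source footprint: small Gaussian blob of fluid cells around (0, src_z)
    if plane_source:
        j_src = int(round((src_z - z_min) / h))
        src_mask = np.zeros((Nr, Nzp))
        src_mask[:, j_src] = 1.0
    else:
        rr2 = r_s[:, None] ** 2 + (z_levels[None, :] - src_z) ** 2
        src_mask = np.exp(-rr2 / (2.0 * (1.0 * h) ** 2))
        src_mask[src_mask < 1e-3] = 0.0

    # station bookkeeping: record just below the interface (first solid level)
    trace_data = None
    if stations is not None and solid is not None and record_traces:
        j_int = int(round((0.0 - z_min) / h))
        j_rec = j_int - 1  # z = -h, first stress level in the solid
        st_cols = np.clip(np.round(stations / h - 0.5).astype(int), 0, Nr - 1)
        trace_data = {
            "cols": st_cols,
            "j": j_rec,
            "srr": np.zeros((len(st_cols), n_steps)),
            "stt": np.zeros((len(st_cols), n_steps)),
            "szz": np.zeros((len(st_cols), n_steps)),
            "srz": np.zeros((len(st_cols), n_steps)),
        }

    probe_series = {p: np.zeros(n_steps) for p in point_probes}
    probe_idx = {
        p: (min(int(p[0] / h), Nr - 1), int(round((p[1] - z_min) / h)))
        for p in point_probes
    }

    snap_steps = sorted({int(round(ts / dt)) for ts in snapshot_times})
    snapshots, snap_t = [], []
    energies = []
    sigma_w = src_width / np.sqrt(2.0 * np.log(2.0))
    # a compressive (step-rate) source keeps a constant injection rate after
    # the pulse, which radiates nothing; the others switch off cleanly
    t_off = np.inf if src_shape == "compressive" else 8.0 * sigma_w

    inv_rho_vr = dt / rho_vr
    inv_rho_vz = dt / rho_vz
    times = np.arange(n_steps) * dt

    for n in range(n_steps):
        t = n * dt
        # --- velocity updates
        dsrr_dr = (srr[1:, :] - srr[:-1, :]) / h
        mean_dev = 0.5 * ((srr[1:, :] + srr[:-1, :]) - (stt[1:, :] + stt[:-1, :]))
        vr[1:-1, 1:-1] += inv_rho_vr[1:-1, 1:-1] * (
            dsrr_dr[:, 1:-1]
            + (srz[1:-1, 1:] - srz[1:-1, :-1]) / h
            + mean_dev[:, 1:-1] / r_v[1:-1, None]
        )
        vr[0, :] = 0.0

        dszz_dz = (szz[:, 1:] - szz[:, :-1]) / h
        dsrz_dr = (srz[1:, :] - srz[:-1, :]) / h
        srz_mean = 0.5 * (srz[1:, :] + srz[:-1, :])
        vz += inv_rho_vz * (dszz_dz + dsrz_dr + srz_mean / r_s[:, None])

        vr *= damp_v_r
        vz *= damp_vz

        # --- stress updates
        dvr_dr = (vr[1:, :] - vr[:-1, :]) / h
        ett_full = 0.5 * (vr[1:, :] + vr[:-1, :]) / r_s[:, None]
        err = dvr_dr[:, 1:-1]
        ett = ett_full[:, 1:-1]
        ezz = (vz[:, 1:] - vz[:, :-1]) / h
        tr = err + ett + ezz
        lam_i = lam[:, 1:-1]
        mu_i = mu[:, 1:-1]
        srr[:, 1:-1] += dt * (2.0 * mu_i * err + lam_i * tr)
        stt[:, 1:-1] += dt * (2.0 * mu_i * ett + lam_i * tr)
        szz[:, 1:-1] += dt * (2.0 * mu_i * ezz + lam_i * tr)

        dvr_dz = (vr[1:-1, 1:] - vr[1:-1, :-1]) / h
        dvz_dr = (vz[1:, :] - vz[:-1, :]) / h
        srz[1:-1, :] += dt * mu4[1:-1, :] * (dvr_dz + dvz_dr)
        srz[0, :] = 0.0

        # --- monopole injection (isotropic stress rate in the fluid blob)
        if t < t_off and src_amplitude != 0.0:
            # point monopole: radiated p ~ d/dt(rate), so a Gaussian rate gives
            # a bipolar pulse and a step rate a compressive pulse; plane
            # sheet: radiated p ~ integral(rate), so a bipolar rate gives a
            # Gaussian pulse
            if plane_source:
                rate = _bipolar(t, src_width)
            elif src_shape == "compressive":
                rate = _sigmoid_rate(t, src_width)
            else:
                rate = _gaussian_rate(t, src_width)
            s_t = src_amplitude * rate * dt
            srr -= s_t * src_mask
            stt -= s_t * src_mask
            szz -= s_t * src_mask

        srr *= damp_s
        stt *= damp_s
        szz *= damp_s
        srz *= damp_rz

        # --- recording
        if trace_data is not None:
            j = trace_data["j"]
            cols = trace_data["cols"]
            trace_data["srr"][:, n] = srr[cols, j]
            trace_data["stt"][:, n] = stt[cols, j]
            trace_data["szz"][:, n] = szz[cols, j]
            # srz lives at (i, j+1/2); average to the stress point
            srz_c = 0.25 * (
                srz[cols, j - 1] + srz[cols, j] + srz[cols + 1, j - 1] + srz[cols + 1, j]
            )
            trace_data["srz"][:, n] = srz_c
        for p, (ic, jc) in probe_idx.items():
            probe_series[p][n] = -(srr[ic, jc] + stt[ic, jc] + szz[ic, jc]) / 3.0
        if n in snap_steps:
            snapshots.append(-(srr + stt + szz) / 3.0)
            snap_t.append(t)
        if record_energy_every and n % record_energy_every == 0:
            ke = 0.5 * rho_vz * vz**2
            ke2 = 0.5 * rho_vr[1:, 1:] * vr[1:, 1:] ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                # compliance-form strain energy; fluid (mu=0): p^2 / (2 lambda)
                trs = srr + stt + szz
                dev = srr**2 + stt**2 + szz**2
                u_solid = np.where(
                    mu > 0,
                    (dev - lam / (3 * lam + 2 * mu) * trs**2) / np.where(mu > 0, 4 * mu, 1),
                    trs**2 / (18.0 * lam),
                )
            srz_sq = np.zeros_like(u_solid)
            srz_sq[:, :-1] = 0.25 * (srz[1:, :] ** 2 + srz[:-1, :] ** 2) * 2
            u_shear = np.where(mu > 0, srz_sq / np.where(mu > 0, 2 * mu, 1), 0.0)
            vols = 2 * np.pi * r_s[:, None] * h * h
            E = float(
                (ke * vols[:, :Nz]).sum()
                + (ke2 * vols[:, :Nz]).sum()
                + ((u_solid + u_shear) * vols).sum()
            )
            energies.append((t, E))
            # sustained growth after switch-off signals numerical instability
            post = [e for tt, e in energies if tt > t_off]
            if len(post) > 2 and post[-1] > 2.0 * max(post[:-1]):
                raise RuntimeError("instability detected: discrete energy is growing")

    traces = []
    if trace_data is not None:
        for k, col in enumerate(trace_data["cols"]):
            s1, s3 = principal_stresses(
                trace_data["srr"][k],
                trace_data["stt"][k],
                trace_data["szz"][k],
                trace_data["srz"][k],
            )
            traces.append(
                BoundaryStressTrace(
                    R=r_s[col],
                    times=times,
                    sigma1=s1,
                    sigma3=s3,
                    sigma_rr=trace_data["srr"][k],
                    sigma_tt=trace_data["stt"][k],
                    sigma_zz=trace_data["szz"][k],
                    sigma_rz=trace_data["srz"][k],
                )
            )

    return WaveResult(
        domain=domain,
        dt=dt,
        snapshot_times=snap_t,
        snapshots=snapshots,
        traces=traces,
        r_stress=r_s,
        z_levels=z_levels,
        energy_history=np.array(energies) if energies else None,
        point_records=probe_series,
        times=times,
    )


def build_source(
    peak_p_at_1mm: float,
    pulse_width: float = 0.5e-6,
    h_c: float = 30e-6,
    fluid: AmbientFluid | None = None,
    h: float = 10e-6,
    calib_r: float = 1.0 * MM,
    shape: str = "bipolar",
) -> SourceModel:
    """Calibrate a monopole source to a requested free-field peak at 1 mm.

    Runs a fluid-only simulation with unit injection amplitude, measures
    the radiated peak pressure at ``calib_r`` on the source level, applies
    the 1/r law to refer it to 1 mm and scales linearly.  The calibration
    is tied to the grid spacing ``h``; :func:`simulate` recalibrates
    automatically if run at a different resolution.
    """
    if min(peak_p_at_1mm, pulse_width, h_c) <= 0:
        raise ValueError("source parameters must be positive")
    if fluid is None:
        fluid = get_material("water", "fluid")
    if pulse_width < 4.0 * h / fluid.c:
        raise ValueError(
            f"pulse width {pulse_width:.2e}s unresolvable at h = {h:.2e} m"
        )
    extent = calib_r + 0.3 * MM
    dom = WaveDomain(r_max=extent, z_min=-extent, z_max=extent, h=h, sponge_cells=24)
    travel = calib_r / fluid.c
    res = _run(
        fluid,
        None,
        dom,
        duration=travel + 10.0 * pulse_width,
        src_amplitude=1.0,
        src_width=pulse_width,
        src_z=0.0,
        point_probes=((calib_r, 0.0),),
        src_shape=shape,
    )
    p_peak = res.point_records[(calib_r, 0.0)].max()
    if p_peak <= 0:
        raise RuntimeError("calibration run produced no signal at the probe")
    p_at_1mm = p_peak * (calib_r / MM)
    amp = peak_p_at_1mm / p_at_1mm
    return SourceModel(
        peak_p_at_1mm=peak_p_at_1mm,
        pulse_width=pulse_width,
        h_c=h_c,
        amplitude=amp,
        h=h,
        shape=shape,
    )


def simulate(
    source: SourceModel,
    fluid: AmbientFluid | None = None,
    solid: ElasticMaterial | None = None,
    domain: WaveDomain | None = None,
    duration: float = 1.0e-6,
    stations: np.ndarray | None = None,
    snapshot_times: tuple = (),
    point_probes: tuple = (),
    layered: tuple[ElasticMaterial, float] | None = None,
    record_energy_every: int = 0,
) -> WaveResult:
    """Propagate the calibrated monopole over a solid half-space.

    Returns snapshots of fluid pressure, sigma1/sigma3 boundary-stress
    traces at the requested radial ``stations`` (on the first stress level
    inside the solid), and optional point-pressure probes in the fluid.
    """
    if fluid is None:
        fluid = get_material("water", "fluid")
    if solid is None:
        solid = get_material("quartz", "elastic")
    if domain is None:
        domain = WaveDomain(r_max=1.6 * MM, z_min=-0.8 * MM, z_max=0.8 * MM, h=10e-6)
    src = source
    if abs(source.h - domain.h) > 1e-15:
        src = build_source(
            source.peak_p_at_1mm,
            source.pulse_width,
            source.h_c,
            fluid,
            h=domain.h,
            shape=source.shape,
        )
    return _run(
        fluid,
        solid,
        domain,
        duration,
        src_amplitude=src.amplitude,
        src_width=src.pulse_width,
        src_z=src.h_c,
        stations=stations,
        snapshot_times=snapshot_times,
        point_probes=point_probes,
        layered=layered,
        record_energy_every=record_energy_every,
        src_shape=src.shape,
    )


def head_wave_angle(
    result: WaveResult,
    fluid: AmbientFluid,
    solid: ElasticMaterial | None = None,
    h_c: float | None = None,
) -> float:
    """Extract the Schmidt head-wave angle from a fluid probe line.

    Ahead of the direct water arrival (any path through the fluid is
    bounded below by hypot(r, z - h_c) / c), the only disturbance at a
    probe is the head wave launched by the leaky Rayleigh wave running
    along the interface.  Its pulse-peak arrival time along a horizontal
    probe line advances as dt/dr = 1 / c_LRW, so a linear fit of peak time
    vs radius yields the apparent interface speed and the angle from the
    surface normal follows from Snell's construction,
    theta = arcsin(c / c_LRW).

    The ``result`` must have been run with ``point_probes`` on a single
    horizontal line in the fluid (see :func:`head_wave_experiment`).
    """
    probes = [(p, s) for p, s in result.point_records.items()]
    if len(probes) < 4:
        raise ValueError("need a probe line (>= 4 points) to fit the head wave")
    z_vals = {round(p[1], 12) for p, _ in probes}
    if len(z_vals) != 1:
        raise ValueError("probes must share a single height z")
    z_p = probes[0][0][1]
    if h_c is None:
        h_c = 0.0
    t = result.times
    duration = t[-1]
    c = fluid.c
    pts_r, pts_t = [], []
    amps = []
    for (r_p, _), s in sorted(probes):
        onset = np.hypot(r_p, z_p - h_c) / c - 0.03e-6
        m = t < min(onset, duration)
        w = np.abs(s[m])
        if w.size < 8 or w.max() <= 0:
            continue
        i = int(np.argmax(w))
        if i >= w.size - 5:  # peak truncated by the recording window
            continue
        tp = t[i]
        if 0 < i < w.size - 1:  # parabolic sub-sample refinement
            denom = w[i - 1] - 2 * w[i] + w[i + 1]
            if denom != 0:
                tp += 0.5 * (w[i - 1] - w[i + 1]) / denom * (t[1] - t[0])
        pts_r.append(r_p)
        pts_t.append(tp)
        amps.append(w.max())
    amps = np.asarray(amps)
    keep = amps > 0.02 * amps.max() if amps.size else amps
    pts_r = np.asarray(pts_r)[keep]
    pts_t = np.asarray(pts_t)[keep]
    if pts_r.size < 4:
        raise RuntimeError("head wave not detected on enough probes")
    slope = np.polyfit(pts_r, pts_t, 1)[0]
    if slope <= 0 or 1.0 / slope <= c:
        raise RuntimeError("fitted front is not supersonic: no head wave separated")
    return float(np.degrees(np.arcsin(c * slope)))


def head_wave_experiment(
    fluid: AmbientFluid | None = None,
    solid: ElasticMaterial | None = None,
    h: float = 6e-6,
    h_c: float = 50e-6,
    pulse_width: float = 0.08e-6,
    probe_z: float = 0.35 * MM,
    probe_r: np.ndarray | None = None,
    duration: float = 1.05e-6,
) -> tuple[float, WaveResult]:
    """Run the fluid-solid head-wave measurement and return (angle, result).

    Defaults reproduce the water-on-quartz configuration: a short monopole
    pulse just above the interface, a horizontal probe line at 0.35 mm
    height, and a duration long enough for the head wave (but not the
    direct wave) to sweep the line.
    """
    if fluid is None:
        fluid = get_material("water", "fluid")
    if solid is None:
        solid = get_material("quartz", "elastic")
    if probe_r is None:
        probe_r = np.arange(1.3, 2.0, 0.1) * MM
    src = build_source(30e5, pulse_width, h_c, fluid, h=h)
    r_max = probe_r.max() + 0.6 * MM
    dom = WaveDomain(r_max=r_max, z_min=-0.6 * MM, z_max=probe_z + 0.5 * MM, h=h)
    res = simulate(
        src,
        fluid,
        solid,
        dom,
        duration=duration,
        point_probes=tuple((rq, probe_z) for rq in probe_r),
    )
    angle = head_wave_angle(res, fluid, solid, h_c=h_c)
    return angle, res
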