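"""Synthetic generators for every input the lithotripsy rig would produce.

The experiments behind this package (high-speed shadowgraphs, hydrophone
traces, measured fiber power profiles) are not deposited anywhere, so each
downstream stage is driven by a controllable synthetic stand-in:

* :func:`make_power_profile` — temporal laser power profile (default 0.2 J,
  70 us FWHM over a 150 us support, matching the dusting setting).
* :func:`make_bubble_geometry_sequence` — pear-shaped axisymmetric vapor
  masks on an (r, z) grid, segmented in time for dynamic photon transport.
* :func:`make_radius_time` — equivalent-radius history with labeled
  inception / maximum / collapse / rebound events.
* :func:`make_hydrophone_trace` — multi-peak shock burst as seen by a
  needle hydrophone at a known distance, with 1/r spherical spreading.
* :func:`make_silhouette` — binary side-view silhouette image of an
  axisymmetric bubble (stands in for a shadowgraph frame).

All stochastic generators are deterministic under a fixed seed.
Coordinates follow the package convention: axisymmetric (r, z), z = 0 at
the solid boundary, z increasing toward the fiber, cell-centered voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .materials import AmbientFluid, get_material

__all__ = [
    "LaserPulse",
    "BubbleGeometrySequence",
    "RadiusTimeSeries",
    "HydrophoneTrace",
    "SilhouetteImage",
    "GridSpec",
    "make_power_profile",
    "make_bubble_geometry_sequence",
    "make_radius_time",
    "make_hydrophone_trace",
    "make_silhouette",
    "rayleigh_collapse_time",
]

MM = 1e-3
US = 1e-6


def rayleigh_collapse_time(Re_max: float, fluid: AmbientFluid | None = None) -> float:
    """Rayleigh collapse time Tc = 0.915 * Re_max * sqrt(rho / (p_stat - p_v))."""
    if fluid is None:
        fluid = get_material("water", "fluid")
    return 0.915 * Re_max * np.sqrt(fluid.rho / fluid.delta_p)


# ----------------------------------------------------------------- pulses


@dataclass(frozen=True)
class LaserPulse:
    """Temporal power profile of a single laser pulse.

    ``times`` in s, ``power`` in W; the trapezoidal integral of power
    equals ``Ep`` (J) by construction.
    """

    times: np.ndarray
    power: np.ndarray
    Ep: float
    fwhm: float
    fiber_core_diameter: float = 365e-6
    numerical_aperture: float = 0.26

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def measured_fwhm(self) -> float:
        """Full width at half of the maximum power, by linear interpolation."""
        p = self.power
        half = 0.5 * p.max()
        above = np.nonzero(p >= half)[0]
        i0, i1 = above[0], above[-1]
        t = self.times

        def cross(ia, ib):
            if p[ib] == p[ia]:
                return t[ia]
            return t[ia] + (half - p[ia]) * (t[ib] - t[ia]) / (p[ib] - p[ia])

        t_lo = cross(i0 - 1, i0) if i0 > 0 else t[0]
        t_hi = cross(i1 + 1, i1) if i1 < len(p) - 1 else t[-1]
        return float(t_hi - t_lo)

    def segment_energies(self, n_seg: int) -> np.ndarray:
        """Partition the pulse energy into n_seg equal-duration segments."""
        edges = np.linspace(self.times[0], self.times[-1], n_seg + 1)
        out = np.empty(n_seg)
        for i in range(n_seg):
            m = (self.times >= edges[i]) & (self.times <= edges[i + 1])
            tt = np.union1d(self.times[m], edges[i : i + 2])
            pp = np.interp(tt, self.times, self.power)
            out[i] = np.trapezoid(pp, tt)
        # distribute any residual quadrature error so the partition is exact
        out *= self.Ep / out.sum()
        return out


def make_power_profile(
    Ep: float = 0.2,
    fwhm: float = 70e-6,
    shape: str = "trapezoid",
    dt: float = 0.5e-6,
    support: float | None = None,
    fiber_core_diameter: float = 365e-6,
    numerical_aperture: float = 0.26,
) -> LaserPulse:
    """Build a synthetic laser power profile with exact energy normalization.

    ``shape``:

    * ``flat`` — rectangular flat-top of width ``fwhm`` (zero-padded tails).
    * ``trapezoid`` — linear 10 us ramp, flat top, linear tail arranged to
      give the requested FWHM over a 150 us support (default geometry of
      the measured dusting profile: 70 us FWHM, 150 us total duration).
    * ``ramped`` — triangular rise to a peak then linear decay.
    """
    if Ep <= 0 or fwhm <= 0 or dt <= 0:
        raise ValueError("Ep, fwhm and dt must be positive")
    if dt >= fwhm / 10:
        raise ValueError("dt must resolve the pulse: require dt < fwhm/10")

    if support is None:
        support = max(150e-6, 2.0 * fwhm)
    t = np.arange(0.0, support + 0.5 * dt, dt)

    if shape == "flat":
        pad = 0.5 * (support - fwhm)
        # half-value edge samples make the trapezoidal integral exactly
        # peak * fwhm, so normalization yields peak = Ep / fwhm
        p = ((t > pad) & (t < pad + fwhm)).astype(float)
        p[np.isclose(t, pad, atol=0.25 * dt) | np.isclose(t, pad + fwhm, atol=0.25 * dt)] = 0.5
    elif shape == "trapezoid":
        # linear ramp (10 us), flat top, linear tail; half-power points sit
        # mid-ramp and mid-tail, so the tail end follows from the FWHM.
        ramp = min(10e-6, 0.2 * fwhm)
        top = 0.43 * fwhm  # flat-top length; 30 us for the default 70 us FWHM
        t1 = ramp + top
        t_end = 2.0 * fwhm - top  # from FWHM = t1/2 + t_end/2 - ramp/2
        if t_end <= t1 or t_end > support:
            raise ValueError("fwhm incompatible with trapezoid shape on this support")
        p = np.where(
            t < ramp,
            t / ramp,
            np.where(t <= t1, 1.0, np.clip((t_end - t) / (t_end - t1), 0.0, 1.0)),
        )
    elif shape == "ramped":
        # triangle: FWHM of a rise-to-peak-then-fall profile is half the
        # footprint, so the fall ends at 2*fwhm (zero-padded afterwards)
        t_end = 2.0 * fwhm
        if t_end > support:
            raise ValueError("fwhm too long for ramped shape on this support")
        peak = 0.3 * t_end
        p = np.where(
            t <= peak, t / peak, np.clip((t_end - t) / (t_end - peak), 0.0, 1.0)
        )
    else:
        raise ValueError(f"unknown shape {shape!r}")

    p = np.clip(p, 0.0, None)
    integral = np.trapezoid(p, t)
    p *= Ep / integral
    pulse = LaserPulse(t, p, Ep, fwhm, fiber_core_diameter, numerical_aperture)
    got = pulse.measured_fwhm()
    if abs(got - fwhm) > 0.02 * fwhm:
        warnings.warn(
            f"profile FWHM {got:.3g}s deviates from requested {fwhm:.3g}s by >2%"
        )
    return pulse


# ----------------------------------------------------- geometry sequences


@dataclass(frozen=True)
class GridSpec:
    """Cell-centered (r, z) grid: nr x nz cells of size dr x dz (m).

    z runs from ``z0`` (usually negative: inside the solid) upward.
    """

    nr: int
    nz: int
    dr: float
    dz: float
    z0: float = 0.0

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return self.z0 + (np.arange(self.nz) + 0.5) * self.dz

    @property
    def cell_volumes(self) -> np.ndarray:
        """Volume of each annular cell, shape (nr, 1), m^3."""
        r = self.r_centers
        return (2.0 * np.pi * r * self.dr * self.dz)[:, None]


@dataclass(frozen=True)
class BubbleGeometrySequence:
    """Per-segment axisymmetric vapor-phase indicator masks.

    ``masks`` has shape (n_seg, nr, nz); True marks vapor.  The bubble
    grows from the fiber tip (z = SD) toward the solid boundary (z = 0),
    its apex reaching the boundary at segment ``contact_segment``.
    """

    segment_duration: float
    masks: np.ndarray
    grid: GridSpec
    SD: float
    contact_segment: int

    @property
    def n_segments(self) -> int:
        return self.masks.shape[0]

    @property
    def total_time(self) -> float:
        return self.n_segments * self.segment_duration

    def segment_volume(self, i: int) -> float:
        return float((self.masks[i] * self.grid.cell_volumes).sum())

    def equivalent_radii(self) -> np.ndarray:
        """Volume-equivalent radius per segment, m."""
        v = np.array([self.segment_volume(i) for i in range(self.n_segments)])
        return (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)


def _pear_profile(z: np.ndarray, z_apex: float, z_top: float, b: float) -> np.ndarray:
    """Radial half-width r(z) of a pear-shaped solid of revolution.

    Ellipse-like body, widest toward the fiber end (z_top) and tapering
    toward the advancing apex — the pear seen in side-view shadowgraphs.
    ``z_apex`` may be negative (virtual apex below the boundary), in which
    case the profile is clipped at z = 0 and the contact disc grows as the
    apex sinks.
    """
    a = 0.5 * (z_top - z_apex)
    zc = 0.5 * (z_top + z_apex)
    u = np.clip((z - zc) / max(a, 1e-12), -1.0, 1.0)
    taper = 1.0 - 0.3 * (1.0 - u) / 2.0  # 0.7 at the apex, 1 at the fiber end
    r = b * np.sqrt(np.clip(1.0 - u * u, 0.0, None)) * taper
    r[(z < z_apex) | (z > z_top)] = 0.0
    return r


def make_bubble_geometry_sequence(
    SD: float = 0.5 * MM,
    Re_max: float = 1.6 * MM,
    n_seg: int = 30,
    grid: GridSpec | None = None,
    segment_duration: float = 5e-6,
    contact_segment: int | None = None,
    inception_segment: int | None = None,
    fiber_core_diameter: float = 365e-6,
) -> BubbleGeometrySequence:
    """Generate a growing pear-shaped vapor bubble as per-segment voxel masks.

    The apex advances linearly from the fiber tip and reaches the solid
    boundary at ``contact_segment`` (default 5 for SD = 0.5 mm, scaled
    proportionally for other standoffs); afterwards the bubble keeps
    growing radially while pinned at the boundary.  Per-segment
    volume-equivalent radii follow a smooth growth law ending at
    ``Re_max``.
    """
    if SD < 0 or Re_max <= 0:
        raise ValueError("require SD >= 0 and Re_max > 0")
    if grid is None:
        extent_r = max(1.5 * Re_max, 1.25 * MM)
        extent_z = SD + 2.2 * Re_max
        grid = GridSpec(
            nr=128, nz=128, dr=extent_r / 128, dz=extent_z / 128, z0=0.0
        )
    if grid.dr > fiber_core_diameter / 2:
        raise ValueError(
            "grid too coarse: dr must resolve the fiber core radius "
            f"({fiber_core_diameter / 2:.2e} m)"
        )
    if contact_segment is None:
        contact_segment = max(1, round(5 * SD / (0.5 * MM))) if SD > 0 else 1
    if inception_segment is None:
        # superheating to nucleation takes ~17 us of the pulse (about 3.5 of
        # the default 5 us segments); no vapor exists before that
        inception_segment = min(max(1, round(0.7 * contact_segment)), n_seg - 2)

    z = grid.z_centers
    r = grid.r_centers
    masks = np.zeros((n_seg, grid.nr, grid.nz), dtype=bool)
    # growth law for the equivalent radius after inception: sin^(2/3) ramp
    # (volume ~ sin^2); segments before inception stay empty
    frac = np.zeros(n_seg)
    idx = np.arange(inception_segment, n_seg)
    frac[idx] = (
        np.sin(0.5 * np.pi * (idx - inception_segment + 1) / (n_seg - inception_segment))
        ** (2.0 / 3.0)
    )
    vol_cells = grid.cell_volumes

    for i in range(inception_segment, n_seg):
        target_Re = Re_max * frac[i]
        # virtual apex keeps sinking after contact: the contact disc widens
        z_apex = SD * (1.0 - i / contact_segment)
        z_apex = max(z_apex, -0.6 * target_Re)
        z_top = SD + 0.35 * target_Re  # bubble shoulders engulf the fiber tip
        b = target_Re  # initial radial scale, corrected below
        for _ in range(12):  # fixed-point: scale b so the voxel volume matches
            prof = _pear_profile(z, z_apex, z_top, b)
            mask = r[:, None] <= prof[None, :]
            vol = (mask * vol_cells).sum()
            if vol <= 0:
                b *= 1.5
                continue
            got_Re = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
            ratio = target_Re / got_Re
            b *= ratio
            if abs(ratio - 1.0) < 5e-4:
                break
        prof = _pear_profile(z, z_apex, z_top, b)
        masks[i] = r[:, None] <= prof[None, :]

    return BubbleGeometrySequence(
        segment_duration=segment_duration,
        masks=masks,
        grid=grid,
        SD=SD,
        contact_segment=contact_segment,
    )


# ------------------------------------------------------- radius histories


@dataclass(frozen=True)
class RadiusTimeSeries:
    """Equivalent bubble radius history with labeled events (times in s)."""

    times: np.ndarray
    Re: np.ndarray
    events: dict = field(default_factory=dict)

    def event_time(self, name: str) -> float:
        try:
            return self.events[name]
        except KeyError:
            raise KeyError(
                f"series lacks event {name!r}; has {sorted(self.events)}"
            ) from None


def make_radius_time(
    Re_max: float = 1.6 * MM,
    t_max: float = 250e-6,
    k1_target: float = 1.0,
    rebound_fraction: float = 0.3,
    dt: float = 0.1e-6,
    fluid: AmbientFluid | None = None,
) -> RadiusTimeSeries:
    """Synthesize an equivalent-radius history R_e(t).

    Growth rises monotonically to ``Re_max`` at ``t_max``; the primary
    collapse lands at ``k1_target * 2 Tc`` (inception at t = 0), so a
    downstream prolongation-factor estimate recovers ``k1_target``.  The
    rebound peaks at ``rebound_fraction**(1/3) * Re_max`` (volume-fraction
    convention: the rebounded bubble retains that fraction of the maximum
    volume, hence of the potential energy E_B).
    """
    if not 0.0 < rebound_fraction < 1.0:
        raise ValueError("rebound_fraction must lie in (0, 1)")
    if k1_target < 1.0:
        raise ValueError("k1_target must be >= 1")
    if fluid is None:
        fluid = get_material("water", "fluid")
    Tc = rayleigh_collapse_time(Re_max, fluid)
    t_col = k1_target * 2.0 * Tc
    if t_col <= 1.05 * t_max:
        raise ValueError(
            f"infeasible parameters: collapse at k1*2Tc = {t_col:.3g}s would not "
            f"follow the maximum at t_max = {t_max:.3g}s; increase Re_max or k1"
        )
    collapse_span = t_col - t_max
    if dt > collapse_span / 20:
        raise ValueError("dt too coarse to resolve the collapse phase")

    Re_reb = rebound_fraction ** (1.0 / 3.0) * Re_max
    t_reb = t_col + 0.8 * collapse_span * rebound_fraction ** (1.0 / 3.0)
    t_col2 = t_reb + (t_reb - t_col)
    t_end = t_col2 + 2 * dt

    t = np.arange(0.0, t_end, dt)
    Re = np.zeros_like(t)

    # growth: smooth monotone rise (Rayleigh-like R ~ t^(2/5) near inception)
    g = t <= t_max
    Re[g] = Re_max * np.sin(0.5 * np.pi * t[g] / t_max) ** (2.0 / 5.0)
    # primary collapse: R ~ (t_col - t)^(2/5)
    c = (t > t_max) & (t <= t_col)
    Re[c] = Re_max * np.clip((t_col - t[c]) / collapse_span, 0, 1) ** (2.0 / 5.0)
    # rebound and secondary collapse
    rb = (t > t_col) & (t <= t_col2)
    phase = np.pi * (t[rb] - t_col) / (t_col2 - t_col)
    Re[rb] = Re_reb * np.sin(phase) ** (2.0 / 5.0)

    events = {
        "inception": 0.0,
        "maximum": t_max,
        "primary_collapse": t_col,
        "rebound_maximum": t_reb,
        "secondary_collapse": t_col2,
    }
    return RadiusTimeSeries(times=t, Re=Re, events=events)


# ------------------------------------------------------ hydrophone traces


@dataclass(frozen=True)
class HydrophoneTrace:
    """Uniformly sampled pressure history at a known sensor distance."""

    times: np.ndarray
    pressure: np.ndarray
    sensor_distance: float
    noise_rms: float = 0.0

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def make_hydrophone_trace(
    peak_list: list[tuple[float, float]],
    sensor_distance: float = 10 * MM,
    noise_rms: float = 0.0,
    seed: int | None = 0,
    duration: float | None = None,
    dt: float = 0.2e-6,
    half_width: float = 0.5e-6,
) -> HydrophoneTrace:
    """Synthesize a shock-burst hydrophone trace.

    ``peak_list`` holds (time, amplitude-at-1mm) pairs; each peak becomes a
    short bipolar transient (leading compression) whose measured amplitude
    is scaled by (1 mm / sensor_distance), the spherical-spreading 1/r law.
    """
    if sensor_distance <= 0:
        raise ValueError("sensor_distance must be positive")
    if duration is None:
        t_last = max((tp for tp, _ in peak_list), default=0.0)
        duration = t_last + 20 * half_width
    t = np.arange(0.0, duration, dt)
    p = np.zeros_like(t)
    scale = (1.0 * MM) / sensor_distance

    # bipolar transient: derivative-of-Gaussian, positive lobe first,
    # normalized to unit peak amplitude and shifted so the compressive
    # maximum lands exactly at the requested peak time
    sigma = half_width / np.sqrt(2.0 * np.log(2.0))
    for tp, amp in peak_list:
        u = (t - tp) / sigma - 1.0
        w = -u * np.exp(0.5 * (1.0 - u * u))  # peak +1 at u = -1, i.e. t = tp
        contrib = amp * scale * w
        if np.any((np.abs(p) > 1e-12) & (np.abs(contrib) > 1e-12)):
            warnings.warn("overlapping peak supports; amplitudes superpose")
        p += contrib

    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_rms, size=p.shape)
    return HydrophoneTrace(times=t, pressure=p, sensor_distance=sensor_distance, noise_rms=noise_rms)


# ------------------------------------------------------------ silhouettes


@dataclass(frozen=True)
class SilhouetteImage:
    """Binary side-view image of an axisymmetric bubble.

    ``image`` is (nx, nz) with the symmetry axis along axis 1 at row index
    ``axis_row`` (x = 0).
    """

    image: np.ndarray
    pixel_pitch: float
    axis_row: int

    @property
    def binary(self) -> np.ndarray:
        return self.image >= 0.5


def make_silhouette(
    radial_profile: np.ndarray,
    z_pitch: float,
    pixel_pitch: float | None = None,
    blur: float = 0.0,
    noise: float = 0.0,
    seed: int | None = 0,
) -> SilhouetteImage:
    """Render an axisymmetric region (half-width profile r(z)) as a silhouette.

    ``radial_profile`` gives the bubble half-width at each axial sample,
    spaced ``z_pitch`` apart.  The image is the projection: pixel (x, z) is
    inside when \\|x\\| <= r(z).  Gaussian ``blur`` (px) and additive noise are
    applied before re-thresholding downstream.
    """
    rmax = float(np.max(radial_profile))
    if rmax <= 0:
        raise ValueError("empty radial profile")
    if pixel_pitch is None:
        pixel_pitch = z_pitch
    if 2.0 * rmax / pixel_pitch < 20:
        raise ValueError("pixel_pitch too coarse: need >= 20 px across the bubble")

    z_coords = np.arange(len(radial_profile)) * z_pitch
    nz = int(np.ceil(z_coords[-1] / pixel_pitch)) + 1
    half_nx = int(np.ceil(1.2 * rmax / pixel_pitch)) + 2
    nx = 2 * half_nx + 1
    x = (np.arange(nx) - half_nx) * pixel_pitch
    zc = np.arange(nz) * pixel_pitch
    prof = np.interp(zc, z_coords, radial_profile)
    img = (np.abs(x)[:, None] <= prof[None, :]).astype(float)
    if blur > 0:
        img = gaussian_filter(img, blur)
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise, img.shape)
    return SilhouetteImage(image=img, pixel_pitch=pixel_pitch, axis_row=half_nx)
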