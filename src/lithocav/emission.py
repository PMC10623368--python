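"""Bubble kinematics and acoustic-emission metrics.

Quantifies what the high-speed-imaging / hydrophone analysis chain
measures: equivalent bubble radius from silhouettes, the dimensionless
standoff gamma = SD / Re_max, Rayleigh-time normalization, the collapse
prolongation factor k1, bubble potential energy E_B and its loss dE_B over
the first rebound, significant shock peaks (the 30%-of-maximum rule),
1/r distance correction of peak pressures, pressure impulse, spherical-wave
acoustic emission energy, and toroidal-bubble volume/compression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .materials import AmbientFluid, get_material
from .synth import (
    HydrophoneTrace,
    RadiusTimeSeries,
    SilhouetteImage,
    rayleigh_collapse_time,
)

__all__ = [
    "BubbleEnergetics",
    "AcousticPeaks",
    "EmissionMetrics",
    "TorusState",
    "equivalent_radius",
    "bubble_energetics",
    "detect_significant_peaks",
    "scale_to_1mm",
    "pressure_impulse",
    "acoustic_emission_energy",
    "emission_metrics",
    "torus_volume",
    "compression_ratio",
    "collision_speed",
    "mach_number",
]

MM = 1e-3


def mach_number(speed: float, sound_speed: float = 1480.0) -> float:
    """Shock Mach number Ma = v / c."""
    if sound_speed <= 0:
        raise ValueError("sound_speed must be positive")
    return speed / sound_speed


def collision_speed(v_contraction: float, v_radial_jet: float) -> float:
    """Toroidal-bubble wall collision speed: contraction plus radial jet."""
    return v_contraction + v_radial_jet


# ----------------------------------------------------------- kinematics


def equivalent_radius(silhouette: SilhouetteImage) -> float:
    """Volume-equivalent radius from a binary silhouette, m.

    Solid-of-revolution row integration about the image's symmetry axis:
    each axial pixel column contributes pi * r(z)^2 * dz with r(z) the
    average of the two half-widths, then Re = (3V / 4 pi)^(1/3).
    """
    img = silhouette.binary
    if not img.any():
        warnings.warn("empty silhouette; returning 0")
        return 0.0
    pitch = silhouette.pixel_pitch
    ax = silhouette.axis_row
    upper = img[ax:, :]  # x >= 0 half, includes the axis row
    lower = img[ax::-1, :]  # x <= 0 half, axis row first
    # half-width in px: count of filled pixels outward from the axis
    w_up = upper.sum(axis=0)
    w_lo = lower.sum(axis=0)
    r_px = 0.5 * (w_up + w_lo) - 0.5  # center the axis pixel
    r_px = np.clip(r_px, 0.0, None)
    V = float(np.sum(np.pi * (r_px * pitch) ** 2 * pitch))
    return (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class BubbleEnergetics:
    """Energy bookkeeping of one growth-collapse-rebound cycle."""

    Re_max: float  # m
    gamma: float  # SD / Re_max
    Tc: float  # s, Rayleigh collapse time
    k1: float  # prolongation factor t1 / (2 Tc)
    EB: float  # J, maximum bubble potential energy
    EB1: float  # J, potential energy at first rebound maximum
    dEB: float  # J, EB - EB1


def bubble_potential_energy(Re: float, fluid: AmbientFluid) -> float:
    """E_B = (4 pi / 3) (p_stat - p_v) Re^3, the cavity potential energy."""
    return (4.0 * np.pi / 3.0) * fluid.delta_p * Re**3


def bubble_energetics(
    series: RadiusTimeSeries,
    SD: float,
    fluid: AmbientFluid | None = None,
) -> BubbleEnergetics:
    """Extract gamma, Tc, k1, EB and the rebound energy loss from a series.

    Requires labeled events ``inception``, ``maximum``, ``primary_collapse``
    and ``rebound_maximum``.  k1 is the inception-to-primary-collapse
    duration normalized by twice the Rayleigh collapse time of the
    equivalent maximum bubble.
    """
    if fluid is None:
        fluid = get_material("water", "fluid")
    for ev in ("inception", "maximum", "primary_collapse", "rebound_maximum"):
        if ev not in series.events:
            raise ValueError(f"series lacks required event label {ev!r}")
    t_inc = series.event_time("inception")
    t_max = series.event_time("maximum")
    t_col = series.event_time("primary_collapse")
    t_reb = series.event_time("rebound_maximum")

    Re_max = float(np.interp(t_max, series.times, series.Re))
    Re_reb = float(np.interp(t_reb, series.times, series.Re))
    Tc = rayleigh_collapse_time(Re_max, fluid)
    k1 = (t_col - t_inc) / (2.0 * Tc)
    EB = bubble_potential_energy(Re_max, fluid)
    EB1 = bubble_potential_energy(Re_reb, fluid)
    return BubbleEnergetics(
        Re_max=Re_max,
        gamma=SD / Re_max,
        Tc=Tc,
        k1=k1,
        EB=EB,
        EB1=EB1,
        dEB=EB - EB1,
    )


# ------------------------------------------------------------- acoustics


@dataclass(frozen=True)
class AcousticPeaks:
    """Detected pressure peaks with the 30%-of-maximum significance rule."""

    times: np.ndarray  # s
    pressures: np.ndarray  # Pa at the sensor
    pressures_1mm: np.ndarray  # Pa scaled to 1 mm
    significant: np.ndarray  # bool

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def scale_to_1mm(pressure: float | np.ndarray, sensor_distance: float) -> float | np.ndarray:
    """1/r spherical-spreading correction: p(1 mm) = p * (d / 1 mm)."""
    if sensor_distance <= 0:
        raise ValueError("sensor_distance must be positive")
    return pressure * (sensor_distance / MM)


def detect_significant_peaks(
    trace: HydrophoneTrace,
    prominence_noise_factor: float = 3.0,
) -> AcousticPeaks:
    """Local pressure maxima, flagged significant when strictly above 30% of
    the trace maximum.

    The peak search uses a prominence floor of ``prominence_noise_factor``
    times the trace's noise RMS so that baseline noise cannot enter the
    30% rule.  An all-zero trace yields an empty peak set.
    """
    p = np.asarray(trace.pressure, dtype=float)
    if p.size == 0 or not np.any(p > 0):
        z = np.array([])
        return AcousticPeaks(z, z, z, np.array([], dtype=bool))
    floor = prominence_noise_factor * trace.noise_rms if trace.noise_rms > 0 else 0.0
    idx, _ = find_peaks(p, prominence=max(floor, 1e-30))
    if idx.size == 0:
        # single-sample or monotone traces: fall back to the global maximum
        idx = np.array([int(np.argmax(p))])
    pk = p[idx]
    thresh = 0.3 * p.max()
    sig = pk > thresh  # strictly greater: exactly 30% is not significant
    return AcousticPeaks(
        times=trace.times[idx],
        pressures=pk,
        pressures_1mm=scale_to_1mm(pk, trace.sensor_distance),
        significant=sig,
    )


def pressure_impulse(
    trace: HydrophoneTrace,
    window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal integral of pressure over a time window, Pa s."""
    t, p = trace.times, trace.pressure
    if window is not None:
        t0, t1 = window
        if t1 <= t0:
            warnings.warn("empty integration window; returning 0")
            return 0.0
        m = (t >= t0) & (t <= t1)
        tt = np.union1d(t[m], [max(t0, t[0]), min(t1, t[-1])])
        pp = np.interp(tt, t, p)
        t, p = tt, pp
    return float(np.trapezoid(p, t))


def acoustic_emission_energy(
    trace: HydrophoneTrace,
    fluid: AmbientFluid | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Far-field spherical-wave emission energy Es = 4 pi r^2 / (rho c) * int p^2 dt.

    ``r`` is the sensor distance; with 1/r amplitude decay the result is
    independent of where the hydrophone sits.
    """
    if fluid is None:
        fluid = get_material("water", "fluid")
    t, p = trace.times, trace.pressure
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, p = t[m], p[m]
    integral = float(np.trapezoid(p**2, t)) if t.size > 1 else 0.0
    return 4.0 * np.pi * trace.sensor_distance**2 / (fluid.rho * fluid.c) * integral


@dataclass(frozen=True)
class EmissionMetrics:
    """Primary/secondary collapse peak pressures and integral measures."""

    p1: float  # Pa at 1 mm, primary-collapse burst maximum
    p2: float  # Pa at 1 mm, secondary-collapse burst maximum
    p1_over_p2: float
    PI: float  # Pa s, pressure impulse (primary burst window, at sensor)
    Es: float  # J, acoustic emission energy of the primary burst


def emission_metrics(
    trace: HydrophoneTrace,
    split_time: float,
    fluid: AmbientFluid | None = None,
) -> EmissionMetrics:
    """Reduce a two-burst trace to p1, p2, their ratio, PI and Es.

    ``split_time`` separates the primary from the secondary collapse burst
    (the rebound-maximum time when derived from a radius series).
    """
    peaks = detect_significant_peaks(trace)
    if peaks.times.size == 0:
        return EmissionMetrics(0.0, 0.0, float("nan"), 0.0, 0.0)
    primary = peaks.times <= split_time
    p1 = float(peaks.pressures_1mm[primary].max()) if primary.any() else 0.0
    p2 = float(peaks.pressures_1mm[~primary].max()) if (~primary).any() else 0.0
    PI = pressure_impulse(trace, (trace.times[0], split_time))
    Es = acoustic_emission_energy(trace, fluid, (trace.times[0], split_time))
    return EmissionMetrics(
        p1=p1,
        p2=p2,
        p1_over_p2=p1 / p2 if p2 > 0 else float("inf"),
        PI=PI,
        Es=Es,
    )


# ----------------------------------------------------------------- torus


@dataclass(frozen=True)
class TorusState:
    """Toroidal bubble: centerline radius, cross-section radius, height."""

    r_c: float  # m
    r_torus: float  # m
    h_c: float  # m, collapse height above the boundary

    def __post_init__(self):
        if self.r_torus > self.r_c:
            raise ValueError("require r_torus <= r_c for a proper torus")
        if min(self.r_c, self.h_c) <= 0 or self.r_torus < 0:
            raise ValueError("torus dimensions must be positive")


def torus_volume(state: TorusState) -> float:
    """V = 2 pi^2 r_c r_torus^2 (circular-cross-section torus)."""
    return 2.0 * np.pi**2 * state.r_c * state.r_torus**2


def compression_ratio(max_state: TorusState, min_state: TorusState) -> float:
    """Volumetric compression ratio V_max / V_min of the collapsing torus."""
    v_min = torus_volume(min_state)
    if v_min <= 0:
        raise ValueError("minimum-volume torus has zero volume")
    return torus_volume(max_state) / v_min
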