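"""Voxelized Monte Carlo photon transport for fiber-laser lithotripsy.

Photon packets are launched from the fiber face within the numerical
aperture cone and marched in small straight steps through an axisymmetric
labeled voxel grid (water / vapor bubble / stone).  Absorption is deposited
continuously along the path (weight attenuation, so energy conservation is
exact to round-off); scattering events are drawn per step and redirect the
packet by Henyey-Greenstein sampling.  Per-segment runs against a dynamic
bubble geometry yield the fluid/solid/escaped energy partition of the
pulse.

Packet positions and directions live in 3-D Cartesian space; the medium is
looked up through (r, z) = (hypot(x, y), z), which is exact for
axisymmetric scenes and keeps the deposition maps two-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import OpticalMedium, get_material
from .synth import BubbleGeometrySequence, GridSpec, LaserPulse

__all__ = [
    "MediaMap",
    "DepositionMap",
    "EnergyBudget",
    "beer_lambert_transmission",
    "trace_segment",
    "run_dynamic_simulation",
    "media_from_mask",
]

WATER, VAPOR, STONE = 0, 1, 2
FLUID_LABELS = (WATER, VAPOR)


def beer_lambert_transmission(path_length: float, mu_a: float) -> float:
    """Ballistic transmission exp(-mu_a * L) along a straight path (SI units)."""
    if path_length < 0 or mu_a < 0:
        raise ValueError("path_length and mu_a must be non-negative")
    return float(np.exp(-mu_a * path_length))


@dataclass(frozen=True)
class MediaMap:
    """Labeled axisymmetric voxel grid plus per-label optical properties."""

    grid: GridSpec
    labels: np.ndarray  # (nr, nz) int
    optics: dict[int, OpticalMedium]

    def __post_init__(self):
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.optics)
        if missing:
            raise ValueError(f"unlabeled media in map: {sorted(missing)}")


@dataclass
class DepositionMap:
    """Absorbed-energy map and the packet-energy ledger for one segment."""

    grid: GridSpec
    absorbed: np.ndarray  # (nr, nz), J
    absorbed_by_label: dict[int, float]
    transmitted: float  # J, absorbed at the target plane (if any)
    escaped: float  # J, left the domain
    launched: float  # J

    def conservation_residual(self) -> float:
        if self.launched == 0.0:
            return 0.0
        total = self.absorbed.sum() + self.transmitted + self.escaped
        return abs(total - self.launched) / self.launched


@dataclass(frozen=True)
class EnergyBudget:
    """Pulse-energy partition between fluid, solid and escaped light."""

    fraction_fluid: float
    fraction_solid: float
    fraction_escaped: float
    per_segment: np.ndarray = field(default=None)  # (n_seg, 3) fractions of Ep

    def __post_init__(self):
        s = self.fraction_fluid + self.fraction_solid + self.fraction_escaped
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"budget fractions sum to {s}, not 1")


def _rotate(d: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors ``d`` by polar angle theta about themselves."""
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    cp, sp = np.cos(phi), np.sin(phi)
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    near_pole = np.abs(dz) > 0.99999
    denom = np.sqrt(np.clip(1.0 - dz**2, 1e-24, None))
    out = np.empty_like(d)
    out[:, 0] = sin_t * (dx * dz * cp - dy * sp) / denom + dx * cos_t
    out[:, 1] = sin_t * (dy * dz * cp + dx * sp) / denom + dy * cos_t
    out[:, 2] = -sin_t * cp * denom + dz * cos_t
    # degenerate case: direction along +-z
    if np.any(near_pole):
        sgn = np.sign(dz[near_pole])
        out[near_pole, 0] = sin_t[near_pole] * cp[near_pole]
        out[near_pole, 1] = sin_t[near_pole] * sp[near_pole]
        out[near_pole, 2] = sgn * cos_t[near_pole]
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    return out / norm


def trace_segment(
    segment_energy: float,
    media: MediaMap,
    n_photons: int = 20_000,
    seed: int | np.random.SeedSequence = 0,
    fiber_core_diameter: float = 365e-6,
    numerical_aperture: float = 0.26,
    launch_z: float | None = None,
    target_plane_z: float | None = None,
    step: float | None = None,
    weight_cutoff: float = 1e-4,
    max_steps: int = 20_000,
) -> DepositionMap:
    """Transport one pulse segment's energy through the labeled voxel grid.

    Packets start uniformly over the fiber core at ``launch_z`` (default:
    top of the grid) heading downward within the NA cone
    (sin(theta_max) = NA / n_water).  ``numerical_aperture = 0`` gives a
    collimated beam.  If ``target_plane_z`` is set, packets crossing that
    plane are absorbed there and tallied as ``transmitted`` (attenuation is
    applied exactly up to the crossing point).  Packets below
    ``weight_cutoff`` deposit their residual weight locally, so the energy
    ledger closes exactly.
    """
    if n_photons < 1_000:
        raise ValueError("n_photons must be >= 1e3 for meaningful statistics")
    grid = media.grid
    if step is None:
        step = 0.5 * min(grid.dr, grid.dz)
    rng = np.random.default_rng(seed)

    labels = media.labels
    lab_ids = sorted(media.optics)
    mu_a_of = np.zeros(max(lab_ids) + 1)
    mu_s_of = np.zeros(max(lab_ids) + 1)
    g_of = np.zeros(max(lab_ids) + 1)
    for k, m in media.optics.items():
        mu_a_of[k], mu_s_of[k], g_of[k] = m.mu_a, m.mu_s, m.g

    w0 = segment_energy / n_photons
    # launch: uniform over the core disk
    rr = 0.5 * fiber_core_diameter * np.sqrt(rng.random(n_photons))
    th = 2.0 * np.pi * rng.random(n_photons)
    z_top = grid.z0 + grid.nz * grid.dz
    if launch_z is None:
        launch_z = z_top - 1e-9
    pos = np.column_stack([rr * np.cos(th), rr * np.sin(th), np.full(n_photons, launch_z)])
    # direction: uniform in solid angle within the NA cone, pointing down (-z)
    n_water = media.optics.get(WATER, get_material("water", "optical")).n
    sin_max = min(numerical_aperture / n_water, 1.0)
    cos_min = np.sqrt(1.0 - sin_max**2)
    cos_t = cos_min + (1.0 - cos_min) * rng.random(n_photons)
    phi = 2.0 * np.pi * rng.random(n_photons)
    sin_t = np.sqrt(1.0 - cos_t**2)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), -cos_t])
    w = np.full(n_photons, w0)

    absorbed = np.zeros((grid.nr, grid.nz))
    absorbed_lab = {k: 0.0 for k in lab_ids}
    transmitted = 0.0
    escaped = 0.0
    launched = segment_energy

    r_max = grid.nr * grid.dr
    z_lo = grid.z0

    active = np.arange(n_photons)
    for _ in range(max_steps):
        if active.size == 0:
            break
        p = pos[active]
        d = dirs[active]
        ww = w[active]

        ds = np.full(active.size, step)
        hit_target = np.zeros(active.size, dtype=bool)
        if target_plane_z is not None:
            going_down = d[:, 2] < -1e-12
            s_hit = np.full(active.size, np.inf)
            s_hit[going_down] = (p[going_down, 2] - target_plane_z) / (-d[going_down, 2])
            hit_target = s_hit <= ds
            ds = np.where(hit_target, np.clip(s_hit, 0.0, None), ds)

        # current voxel / medium
        r = np.hypot(p[:, 0], p[:, 1])
        ir = np.minimum((r / grid.dr).astype(int), grid.nr - 1)
        iz = ((p[:, 2] - grid.z0) / grid.dz).astype(int)
        iz = np.clip(iz, 0, grid.nz - 1)
        lab = labels[ir, iz]
        mu_a = mu_a_of[lab]
        mu_s = mu_s_of[lab]

        att = np.exp(-mu_a * ds)
        dep = ww * (1.0 - att)
        np.add.at(absorbed, (ir, iz), dep)
        for k in lab_ids:
            m = lab == k
            if m.any():
                absorbed_lab[k] += dep[m].sum()
        ww = ww * att
        p = p + d * ds[:, None]

        # target plane: remaining weight is transmitted
        if target_plane_z is not None and hit_target.any():
            transmitted += ww[hit_target].sum()
            ww[hit_target] = 0.0

        # domain exit
        r_new = np.hypot(p[:, 0], p[:, 1])
        out = (r_new >= r_max) | (p[:, 2] <= z_lo) | (p[:, 2] >= z_top + step)
        out &= ~hit_target
        if out.any():
            escaped += ww[out].sum()
            ww[out] = 0.0

        # scattering
        scatter = (rng.random(active.size) < (1.0 - np.exp(-mu_s * ds))) & ~out & ~hit_target
        if scatter.any():
            gs = g_of[lab[scatter]]
            u = rng.random(scatter.sum())
            ct = _hg_cos_array(gs, u)
            ph = 2.0 * np.pi * rng.random(scatter.sum())
            d[scatter] = _rotate(d[scatter], ct, ph)

        # weight cutoff: deposit residual locally
        dead = (ww < weight_cutoff * w0) & ~out & ~hit_target
        if dead.any():
            np.add.at(absorbed, (ir[dead], iz[dead]), ww[dead])
            for k in lab_ids:
                m = dead & (lab == k)
                if m.any():
                    absorbed_lab[k] += ww[m].sum()
            ww[dead] = 0.0

        pos[active] = p
        dirs[active] = d
        w[active] = ww
        active = active[ww > 0.0]

    # safety: any packet still alive after max_steps counts as escaped
    if active.size:
        escaped += w[active].sum()

    return DepositionMap(
        grid=grid,
        absorbed=absorbed,
        absorbed_by_label=absorbed_lab,
        transmitted=transmitted,
        escaped=escaped,
        launched=launched,
    )


def _hg_cos_array(g: np.ndarray, u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    iso = np.abs(g) < 1e-6
    out[iso] = 1.0 - 2.0 * u[iso]
    gg = g[~iso]
    s = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u[~iso])
    out[~iso] = np.clip((1.0 + gg * gg - s * s) / (2.0 * gg), -1.0, 1.0)
    return out


def media_from_mask(
    vapor_mask: np.ndarray | None,
    grid: GridSpec,
    optics: dict[int, OpticalMedium] | None = None,
    vacuum_bubble: bool = False,
) -> MediaMap:
    """Label a voxel grid: stone below z = 0, vapor where masked, water else.

    ``vacuum_bubble`` zeroes the vapor absorption (the bubble interior
    treated as transparent); the default keeps the weak vapor coefficient
    of 0.001 mm^-1.
    """
    if optics is None:
        vap = get_material("vapor", "optical")
        if vacuum_bubble:
            vap = OpticalMedium(vap.name, 0.0, 0.0, 0.0, vap.n)
        optics = {
            WATER: get_material("water", "optical"),
            VAPOR: vap,
            STONE: get_material("begostone", "optical"),
        }
    z = grid.z_centers
    labels = np.full((grid.nr, grid.nz), WATER, dtype=np.int8)
    labels[:, z < 0.0] = STONE
    if vapor_mask is not None:
        n_fluid = int((z >= 0.0).sum())
        if vapor_mask.shape != (grid.nr, n_fluid):
            raise ValueError(
                f"vapor mask shape {vapor_mask.shape} does not match the "
                f"grid's fluid region ({grid.nr}, {n_fluid})"
            )
        fluid_cols = np.nonzero(z >= 0.0)[0]
        sub = labels[:, fluid_cols]
        sub[vapor_mask] = VAPOR
        labels[:, fluid_cols] = sub
    return MediaMap(grid=grid, labels=labels, optics=optics)


def run_dynamic_simulation(
    pulse: LaserPulse,
    geometry: BubbleGeometrySequence,
    optics: dict[int, OpticalMedium] | None = None,
    n_photons_per_segment: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    stone_depth: float = 1.0e-3,
    vacuum_bubble: bool = False,
) -> tuple[EnergyBudget, list[DepositionMap]]:
    """Energy partition of a full pulse against a dynamic bubble geometry.

    The pulse is split into the geometry's segments; each segment's energy
    is transported through that segment's frozen vapor mask with the stone
    occupying ``z < 0`` down to ``stone_depth``.  Segment deposition maps
    are reduced to fluid/solid/escaped fractions weighted by segment
    energies.
    """
    n_seg = geometry.n_segments
    seg_E = pulse.segment_energies(n_seg)
    g0 = geometry.grid
    n_stone = int(round(stone_depth / g0.dz))
    grid = GridSpec(nr=g0.nr, nz=g0.nz + n_stone, dr=g0.dr, dz=g0.dz, z0=-n_stone * g0.dz)

    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    seeds = ss.spawn(n_seg)

    maps: list[DepositionMap] = []
    per_seg = np.zeros((n_seg, 3))
    for i in range(n_seg):
        media = media_from_mask(
            geometry.masks[i], grid, optics=optics, vacuum_bubble=vacuum_bubble
        )
        dep = trace_segment(
            seg_E[i],
            media,
            n_photons=n_photons_per_segment,
            seed=seeds[i],
            fiber_core_diameter=pulse.fiber_core_diameter,
            numerical_aperture=pulse.numerical_aperture,
            launch_z=geometry.SD,
        )
        maps.append(dep)
        fluid = sum(dep.absorbed_by_label.get(k, 0.0) for k in FLUID_LABELS)
        solid = dep.absorbed_by_label.get(STONE, 0.0) + dep.transmitted
        per_seg[i] = (fluid, solid, dep.escaped)

    tot = per_seg.sum(axis=0)
    Ep = seg_E.sum()
    frac = tot / Ep
    budget = EnergyBudget(
        fraction_fluid=float(frac[0]),
        fraction_solid=float(frac[1]),
        fraction_escaped=float(frac[2]),
        per_segment=per_seg / Ep,
    )
    return budget, maps
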