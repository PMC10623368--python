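"""Axisymmetric transient heat conduction with melting-threshold ablation.

Solves rho*cp dT/dt = div(k grad T) + f on a cell-centered (r, z)
finite-volume grid with homogeneous Neumann (insulated) boundaries, using
an unconditionally stable theta scheme (Crank-Nicolson by default) and a
sparse direct solve.  The finite-volume form conserves enthalpy exactly on
the insulated domain, which the multi-pulse crater model relies on for its
energy ledger.

Material is removed ("ablated") from the solid when a cell has both
reached the melting temperature and accumulated more volumetric laser
energy than the material's thermal resistance; ablated cells become
insulating voids and never revert.  Repeated pulses therefore carve a
crater whose front recedes from the fiber, which in turn lowers the
surface irradiance through beam-cone divergence — the mechanism behind the
observed saturation of crater growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import factorized

from .materials import ThermalMedium, get_material
from .synth import GridSpec, LaserPulse

__all__ = [
    "ThermalField",
    "CraterRecord",
    "HeatSolver",
    "step_heat",
    "apply_ablation",
    "surface_irradiance",
    "run_multi_pulse",
]

MM = 1e-3


@dataclass
class ThermalField:
    """Temperature state on an axisymmetric grid.

    ``acc_source`` accumulates deposited laser energy density (J m^-3) per
    cell, the quantity compared against the material's thermal resistance
    in the ablation rule.
    """

    grid: GridSpec
    temperature: np.ndarray  # (nr, nz), K
    ablated: np.ndarray  # (nr, nz) bool
    time: float = 0.0
    acc_source: np.ndarray = None
    injected_energy: float = 0.0
    ablation_debit: float = 0.0

    def __post_init__(self):
        if self.acc_source is None:
            self.acc_source = np.zeros_like(self.temperature)
        if np.any(self.temperature < 0):
            raise ValueError("temperature must be >= 0 K")

    @classmethod
    def uniform(cls, grid: GridSpec, T0: float = 293.15) -> "ThermalField":
        return cls(
            grid=grid,
            temperature=np.full((grid.nr, grid.nz), T0),
            ablated=np.zeros((grid.nr, grid.nz), dtype=bool),
        )

    def enthalpy(self, medium: ThermalMedium, T_ref: float = 293.15) -> float:
        """Sensible heat above T_ref in the remaining solid, J."""
        vol = self.grid.cell_volumes
        dT = np.where(self.ablated, 0.0, self.temperature - T_ref)
        return float((medium.rho * medium.cp * dT * vol).sum())


@dataclass(frozen=True)
class CraterRecord:
    pulse_index: int
    volume: float  # m^3
    max_depth: float  # m
    surface_profile_area: float  # m^2


class HeatSolver:
    """Theta-scheme finite-volume conduction solver on a fixed grid.

    The sparse operator is rebuilt whenever the ablated mask changes
    (ablated cells are decoupled by zeroing the conductance of their
    faces).  The factorization is cached so repeated equal-dt steps are a
    pair of triangular solves.
    """

    def __init__(self, medium: ThermalMedium, grid: GridSpec, theta: float = 0.5):
        self.medium = medium
        self.grid = grid
        self.theta = theta
        self._K = None
        self._mask_id = None
        self._solvers: dict = {}

    def _build_K(self, ablated: np.ndarray) -> sparse.csr_matrix:
        g = self.grid
        nr, nz, dr, dz = g.nr, g.nz, g.dr, g.dz
        k = self.medium.k_cond
        n = nr * nz
        idx = np.arange(n).reshape(nr, nz)
        rows, cols, vals = [], [], []
        open_cell = ~ablated

        # radial faces between (i, j) and (i+1, j): area 2*pi*(i+1)*dr*dz
        face_r = 2.0 * np.pi * (np.arange(1, nr) * dr) * dz
        cond = k * face_r / dr  # W/K per face, shape (nr-1,)
        conn = open_cell[:-1, :] & open_cell[1:, :]
        a, b = idx[:-1, :][conn], idx[1:, :][conn]
        c = np.broadcast_to(cond[:, None], (nr - 1, nz))[conn]
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [c, c, -c, -c]

        # axial faces between (i, j) and (i, j+1): area 2*pi*r_i*dr
        face_z = 2.0 * np.pi * g.r_centers * dr
        cond_z = k * face_z / dz  # shape (nr,)
        conn = open_cell[:, :-1] & open_cell[:, 1:]
        a, b = idx[:, :-1][conn], idx[:, 1:][conn]
        c = np.broadcast_to(cond_z[:, None], (nr, nz - 1))[conn]
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [c, c, -c, -c]

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def step(self, field: ThermalField, source: np.ndarray | None, dt: float) -> ThermalField:
        """Advance one time step.  ``source`` is volumetric power f, W m^-3."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        g = self.grid
        if self.theta < 0.5:
            # explicit-leaning scheme: enforce the diffusive stability bound
            alpha = self.medium.diffusivity
            dt_max = 0.5 * min(g.dr, g.dz) ** 2 / (alpha * (1.0 - 2.0 * self.theta))
            if dt > dt_max:
                raise ValueError(
                    f"dt = {dt:.3g}s unstable for theta = {self.theta}; "
                    f"use dt <= {dt_max:.3g}s or theta >= 0.5"
                )

        mask_id = hash(field.ablated.tobytes())
        if self._K is None or mask_id != self._mask_id:
            self._K = self._build_K(field.ablated)
            self._mask_id = mask_id
            self._solvers.clear()

        vol = np.broadcast_to(g.cell_volumes, field.temperature.shape).ravel()
        cap = self.medium.rho * self.medium.cp * vol  # J/K per cell
        T = field.temperature.ravel()
        f = np.zeros_like(T) if source is None else source.ravel()
        f = np.where(field.ablated.ravel(), 0.0, f)

        if dt not in self._solvers:
            M = sparse.diags(cap / dt)
            A = (M - self.theta * self._K).tocsc()
            self._solvers[dt] = factorized(A)
        rhs = cap / dt * T + (1.0 - self.theta) * (self._K @ T) + f * vol
        T_new = self._solvers[dt](rhs)

        acc = field.acc_source + np.where(field.ablated, 0.0, (source if source is not None else 0.0)) * dt
        injected = field.injected_energy + float((f * vol).sum() * dt)
        return replace(
            field,
            temperature=T_new.reshape(field.temperature.shape),
            time=field.time + dt,
            acc_source=acc,
            injected_energy=injected,
        )


def step_heat(
    field: ThermalField,
    source: np.ndarray | None,
    dt: float,
    medium: ThermalMedium | None = None,
    solver: HeatSolver | None = None,
    theta: float = 0.5,
) -> ThermalField:
    """One conduction step (convenience wrapper building a solver on demand)."""
    if solver is None:
        if medium is None:
            medium = get_material("begostone", "thermal")
        solver = HeatSolver(medium, field.grid, theta=theta)
    return solver.step(field, source, dt)


def apply_ablation(
    field: ThermalField,
    medium: ThermalMedium,
    thermal_resistance: float,
    acc_baseline: np.ndarray | None = None,
) -> tuple[ThermalField, float]:
    """Remove cells that satisfy both ablation conditions.

    A cell is ablated when its temperature has reached the melting point
    AND the laser energy density it received exceeds ``thermal_resistance``
    (J m^-3).  With ``acc_baseline`` (a snapshot of ``acc_source`` taken
    before the pulse) the comparison uses only the energy deposited since
    that snapshot — the per-pulse threshold through which crater growth
    saturates once the diverging beam dilutes the surface dose.  Returns
    the updated field and the volume removed this call.  Removed cells'
    enthalpy is charged to the field's ablation debit so the energy ledger
    stays closed.
    """
    if thermal_resistance <= 0:
        raise ValueError("thermal_resistance must be positive")
    dose = field.acc_source if acc_baseline is None else field.acc_source - acc_baseline
    new = (
        (field.temperature >= medium.melt_T)
        & (dose > thermal_resistance)
        & ~field.ablated
    )
    if not new.any():
        return field, 0.0
    vol = np.broadcast_to(field.grid.cell_volumes, new.shape)
    removed = float(vol[new].sum())
    debit = float(
        (medium.rho * medium.cp * (field.temperature[new] - 293.15) * vol[new]).sum()
    )
    ablated = field.ablated | new
    T = field.temperature.copy()
    T[new] = 293.15  # voids carry no heat
    return (
        replace(
            field,
            ablated=ablated,
            temperature=T,
            ablation_debit=field.ablation_debit + debit,
        ),
        removed,
    )


def crater_depth_profile(field: ThermalField) -> np.ndarray:
    """Depth of the ablation front below the original surface per r column, m.

    The original surface is the top of the grid (largest z).  Columns with
    no ablation have depth 0.
    """
    g = field.grid
    depth = np.zeros(g.nr)
    for i in range(g.nr):
        col = field.ablated[i]
        # front = topmost contiguous ablated run from the surface downward
        j = g.nz - 1
        d = 0
        while j >= 0 and col[j]:
            d += 1
            j -= 1
        depth[i] = d * g.dz
    return depth


def surface_irradiance(
    peak_power: float,
    SD: float,
    crater_depth: np.ndarray | float = 0.0,
    r: np.ndarray | None = None,
    fiber_core_diameter: float = 365e-6,
    numerical_aperture: float = 0.26,
    n_medium: float = 1.33,
) -> tuple[float, float]:
    """Mean irradiance on the (possibly cratered) illuminated surface.

    Cone-divergence model: the beam radius grows as
    a(d) = a_core + d * tan(theta_div) with sin(theta_div) = NA / n, where
    d is the fiber-to-surface distance (standoff plus local crater depth).
    Returns (mean irradiance in W m^-2, beam radius at the surface in m).
    The in-pulse peak power convention is used; divide by the duty factor
    externally for a PRF-averaged figure.
    """
    if SD < 0:
        raise ValueError("SD must be >= 0")
    a0 = 0.5 * fiber_core_diameter
    tan_div = np.tan(np.arcsin(min(numerical_aperture / n_medium, 1.0)))
    depth = np.atleast_1d(np.asarray(crater_depth, dtype=float))
    d_eff = SD + float(depth.mean())
    a = a0 + d_eff * tan_div
    if r is not None and depth.size == r.size and depth.size > 1:
        # actual sloped-surface area inside the illuminated radius
        dr = r[1] - r[0]
        slope = np.gradient(-depth, dr)
        inside = r <= a
        area = float((2.0 * np.pi * r[inside] * np.sqrt(1.0 + slope[inside] ** 2) * dr).sum())
        area = max(area, np.pi * a0**2)
    else:
        area = np.pi * a**2
    return peak_power / area, a


def run_multi_pulse(
    SD: float = 0.5 * MM,
    Ep: float = 0.2,
    absorbed_fraction: float = 0.01,
    n_pulses: int = 500,
    prf: float = 20.0,
    medium: ThermalMedium | None = None,
    thermal_resistance: float = 1.5e8,
    grid: GridSpec | None = None,
    pulse: LaserPulse | None = None,
    n_steps_pulse: int = 4,
    n_steps_cool: int = 4,
) -> tuple[list[CraterRecord], ThermalField]:
    """Multi-pulse crater evolution on a 0.5 x 0.5 mm solid domain.

    Each pulse deposits ``absorbed_fraction * Ep`` on the current crater
    front with Beer-Lambert decay into the solid, conducts heat during the
    pulse, ablates qualifying cells, then cools for the inter-pulse period
    set by ``prf``.  ``absorbed_fraction = 0`` produces all-zero records.
    """
    if not 0.0 <= absorbed_fraction <= 1.0:
        raise ValueError("absorbed_fraction must lie in [0, 1]")
    if medium is None:
        medium = get_material("begostone", "thermal")
    if grid is None:
        # solid occupies z in [-0.5 mm, 0]; surface at the top (z = 0)
        grid = GridSpec(nr=48, nz=48, dr=0.5 * MM / 48, dz=0.5 * MM / 48, z0=-0.5 * MM)
    pulse_duration = pulse.duration if pulse is not None else 150e-6
    peak_power = Ep / (0.7 * pulse_duration)  # effective in-pulse power
    mu_a_stone = get_material("begostone", "optical").mu_a

    field = ThermalField.uniform(grid)
    solver = HeatSolver(medium, grid, theta=0.5)
    records: list[CraterRecord] = []
    removed_total = 0.0
    E_abs = absorbed_fraction * Ep
    cool_dt = max((1.0 / prf - pulse_duration) / n_steps_cool, 1e-6)
    r = grid.r_centers
    z = grid.z_centers

    beam_a = 0.5 * 365e-6  # updated each pulse from the receding front
    for ip in range(n_pulses):
        if E_abs > 0.0:
            depth = crater_depth_profile(field)
            # beam spreads with the fiber-to-front distance averaged over the
            # currently illuminated spot (previous pulse's beam radius)
            in_spot = r <= beam_a
            d_spot = depth[in_spot] if in_spot.any() else depth[:1]
            irr, beam_a = surface_irradiance(peak_power, SD, d_spot)
            # volumetric source: Beer-Lambert decay below the local front
            source = np.zeros((grid.nr, grid.nz))
            inside = r <= beam_a
            for i in np.nonzero(inside)[0]:
                front_z = 0.0 - depth[i]
                below = z <= front_z
                below &= ~field.ablated[i]
                dz_below = front_z - z[below]
                source[i, below] = mu_a_stone * np.exp(-mu_a_stone * dz_below)
            # normalize: total absorbed power during the pulse = E_abs / tau
            norm = (source * np.broadcast_to(grid.cell_volumes, source.shape)).sum()
            if norm > 0:
                source *= (E_abs / pulse_duration) / norm
            acc_before = field.acc_source.copy()
            dtp = pulse_duration / n_steps_pulse
            for _ in range(n_steps_pulse):
                field = solver.step(field, source, dtp)
            field, removed = apply_ablation(
                field, medium, thermal_resistance, acc_baseline=acc_before
            )
            removed_total += removed
        for _ in range(n_steps_cool):
            field = solver.step(field, None, cool_dt)

        depth = crater_depth_profile(field)
        dr = grid.dr
        slope = np.gradient(-depth, dr) if grid.nr > 1 else np.zeros(1)
        opened = depth > 0
        area = float(
            (2.0 * np.pi * r[opened] * np.sqrt(1.0 + slope[opened] ** 2) * dr).sum()
        )
        records.append(
            CraterRecord(
                pulse_index=ip,
                volume=removed_total,
                max_depth=float(depth.max()),
                surface_profile_area=area,
            )
        )
        if depth.max() >= (grid.nz - 2) * grid.dz:
            raise RuntimeError(
                f"crater reached the domain boundary at pulse {ip}; enlarge the domain"
            )
    return records, field
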