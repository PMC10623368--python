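"""Central registry of optical, thermal, acoustic and elastic material properties.

All quantities are SI internally.  Optical attenuation coefficients are
accepted in the lithotripsy literature's conventional mm^-1 in the shipped
data file and converted to m^-1 exactly once, at load time.

Shared geometry convention used throughout the package: axisymmetric
cylindrical coordinates ``(r, z)`` with ``z = 0`` at the solid boundary and
``z`` increasing toward the fiber tip; voxels are cell-centered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "OpticalMedium",
    "ThermalMedium",
    "ElasticMaterial",
    "AmbientFluid",
    "MaterialLookupError",
    "MaterialRegistry",
    "get_material",
    "default_registry",
]

MM = 1e-3  # metres per millimetre


class MaterialLookupError(KeyError):
    """Raised when a material name or kind is not registered."""


@dataclass(frozen=True)
class OpticalMedium:
    """Optical properties at the Ho:YAG wavelength (2080 nm).

    mu_a, mu_s in m^-1; g is the Henyey-Greenstein anisotropy; n the
    refractive index.
    """

    name: str
    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("attenuation coefficients must be >= 0")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class ThermalMedium:
    """Bulk thermal properties used by the heat-conduction/ablation solver."""

    name: str
    rho: float  # kg m^-3
    cp: float  # J kg^-1 K^-1
    k_cond: float  # W m^-1 K^-1
    melt_T: float  # K
    latent_heat_vap: float  # J kg^-1

    def __post_init__(self) -> None:
        for field in ("rho", "cp", "k_cond", "melt_T"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be strictly positive")
        if self.latent_heat_vap < 0:
            raise ValueError("latent_heat_vap must be >= 0")
        if self.melt_T <= 293.15:
            raise ValueError("melt_T must exceed ambient temperature")

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity alpha = k / (rho cp), m^2 s^-1."""
        return self.k_cond / (self.rho * self.cp)


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic elastic solid described by density and wave speeds."""

    name: str
    rho: float  # kg m^-3
    c_L: float  # longitudinal speed, m s^-1
    c_T: float  # transverse (shear) speed, m s^-1

    def __post_init__(self) -> None:
        if min(self.rho, self.c_L, self.c_T) <= 0:
            raise ValueError("density and wave speeds must be positive")
        # positive-definite elasticity (lambda > -2mu/3) requires c_L > c_T*sqrt(4/3)
        if self.c_L <= self.c_T * math.sqrt(4.0 / 3.0):
            raise ValueError("c_L must exceed c_T*sqrt(4/3)")

    @property
    def mu(self) -> float:
        """Shear modulus, Pa."""
        return self.rho * self.c_T**2

    @property
    def lam(self) -> float:
        """First Lame parameter, Pa."""
        return self.rho * (self.c_L**2 - 2.0 * self.c_T**2)

    @property
    def poisson(self) -> float:
        """Poisson ratio."""
        a = (self.c_L / self.c_T) ** 2
        return (a - 2.0) / (2.0 * (a - 1.0))


@dataclass(frozen=True)
class AmbientFluid:
    """Ambient liquid state (water at 1 atm, 20 degC by default)."""

    name: str
    rho: float  # kg m^-3
    c: float  # sound speed, m s^-1
    p_stat: float  # static pressure, Pa
    p_v: float  # vapor pressure, Pa
    T0: float  # ambient temperature, K

    def __post_init__(self) -> None:
        if not self.p_stat > self.p_v > 0:
            raise ValueError("require p_stat > p_v > 0")
        if min(self.rho, self.c, self.T0) <= 0:
            raise ValueError("rho, c and T0 must be positive")

    @property
    def delta_p(self) -> float:
        """Collapse driving pressure p_stat - p_v, Pa."""
        return self.p_stat - self.p_v


_KINDS = ("optical", "thermal", "elastic", "fluid")


class MaterialRegistry:
    """Immutable lookup of material records loaded from a JSON data file."""

    def __init__(self, raw: dict):
        self._store: dict[tuple[str, str], object] = {}
        for name, d in raw.get("optical", {}).items():
            self._store[(name, "optical")] = OpticalMedium(
                name, d["mu_a_mm"] / MM, d["mu_s_mm"] / MM, d["g"], d["n"]
            )
        for name, d in raw.get("thermal", {}).items():
            self._store[(name, "thermal")] = ThermalMedium(
                name, d["rho"], d["cp"], d["k_cond"], d["melt_T"], d["latent_heat_vap"]
            )
        for name, d in raw.get("elastic", {}).items():
            self._store[(name, "elastic")] = ElasticMaterial(
                name, d["rho"], d["c_L"], d["c_T"]
            )
        for name, d in raw.get("fluid", {}).items():
            self._store[(name, "fluid")] = AmbientFluid(
                name, d["rho"], d["c"], d["p_stat"], d["p_v"], d["T0"]
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "MaterialRegistry":
        with open(path) as fh:
            return cls(json.load(fh))

    def get(self, name: str, kind: str):
        if kind not in _KINDS:
            raise MaterialLookupError(
                f"unknown kind {kind!r}; available kinds: {', '.join(_KINDS)}"
            )
        try:
            return self._store[(name, kind)]
        except KeyError:
            avail = sorted(n for (n, k) in self._store if k == kind)
            raise MaterialLookupError(
                f"no {kind} material named {name!r}; available: {', '.join(avail)}"
            ) from None

    def names(self, kind: str) -> list[str]:
        return sorted(n for (n, k) in self._store if k == kind)


def _load_default() -> MaterialRegistry:
    with resources.files("lithocav.data").joinpath("materials.json").open() as fh:
        return MaterialRegistry(json.load(fh))


_DEFAULT: MaterialRegistry | None = None


def default_registry() -> MaterialRegistry:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_default()
    return _DEFAULT


def get_material(name: str, kind: str, registry: MaterialRegistry | None = None):
    """Look up an immutable material property record.

    Parameters
    ----------
    name : registered material name, e.g. ``"water"``, ``"quartz"``.
    kind : one of ``optical``, ``thermal``, ``elastic``, ``fluid``.
    registry : optional override registry (e.g. loaded from a user file).
    """
    reg = registry if registry is not None else default_registry()
    return reg.get(name, kind)
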