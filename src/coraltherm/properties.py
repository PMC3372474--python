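"""Material-property closures for seawater and porous coral zones.

The coral tissue and skeleton are treated as isotropic porous media in local
thermal equilibrium with the pore water.  This module provides:

* porosity from bulk and true (aragonite) density, phi = 1 - rho_b/rho_t;
* volume-weighted effective density, heat capacity and conductivity, and the
  effective thermal diffusivity alpha_eff = k_eff / (rho*Cp)_eff;
* Darcy (viscous) and Forchheimer (inertial) resistance coefficients from
  the Blake-Kozeny and Burke-Plummer packed-bed closures, with the coral
  sample diameter as the characteristic length;
* the Prandtl number Pr = nu / alpha, the ratio of momentum to thermal
  boundary-layer thickness.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Fluid:
    """Incompressible fluid constants (SI)."""

    rho: float  # kg/m^3
    cp: float  # J/(kg K)
    k: float  # W/(m K)
    mu: float  # Pa s

    def __post_init__(self) -> None:
        if min(self.rho, self.cp, self.k, self.mu) <= 0:
            raise ValueError("fluid properties must be strictly positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity (m^2/s)."""
        return self.mu / self.rho

    @property
    def rho_cp(self) -> float:
        return self.rho * self.cp

    @property
    def alpha(self) -> float:
        """Thermal diffusivity (m^2/s)."""
        return self.k / (self.rho * self.cp)


@dataclass(frozen=True)
class Solid:
    """Coral skeletal constituent (aragonite) constants (SI)."""

    rho: float
    cp: float
    k: float

    def __post_init__(self) -> None:
        if min(self.rho, self.cp, self.k) <= 0:
            raise ValueError("solid properties must be strictly positive")

    @property
    def rho_cp(self) -> float:
        return self.rho * self.cp


#: seawater at 26 C
WATER_26C = Fluid(rho=996.8, cp=4179.0, k=0.61, mu=8.7e-4)

#: aragonite; density from the mineral literature, Cp and k from standard
#: mineral tables (coral-specific values are not tabulated anywhere)
ARAGONITE = Solid(rho=2940.0, cp=880.0, k=2.2)

#: aragonite true density in g/cm^3, for porosity-from-density conversions
TRUE_DENSITY_ARAGONITE = 2.94


@dataclass(frozen=True)
class MaterialSet:
    """Fluid + coral-solid constituents and the skeletal true density (g/cm^3)."""

    fluid: Fluid = WATER_26C
    solid: Solid = ARAGONITE
    true_density: float = TRUE_DENSITY_ARAGONITE

    def __post_init__(self) -> None:
        if self.true_density <= 0:
            raise ValueError("true density must be positive")


def porosity_from_density(rho_b: float, rho_t: float = TRUE_DENSITY_ARAGONITE) -> float:
    """Porosity phi = 1 - rho_b/rho_t from bulk and true density (same units)."""
    if rho_t <= 0:
        raise ValueError("true density must be positive")
    if rho_b < 0 or rho_b > rho_t:
        raise ValueError("bulk density must lie in [0, true density]")
    return 1.0 - rho_b / rho_t


def bulk_density_from_porosity(phi: float, rho_t: float = TRUE_DENSITY_ARAGONITE) -> float:
    """Inverse of :func:`porosity_from_density`: rho_b = (1 - phi) * rho_t."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("porosity must lie in [0, 1]")
    return (1.0 - phi) * rho_t


@dataclass(frozen=True)
class EffectiveProps:
    """Porosity-averaged properties of a porous zone."""

    rho: float  # kg/m^3
    rho_cp: float  # J/(m^3 K)
    k: float  # W/(m K)

    @property
    def cp(self) -> float:
        return self.rho_cp / self.rho

    @property
    def alpha(self) -> float:
        """Effective thermal diffusivity k_eff / (rho*Cp)_eff (m^2/s)."""
        return self.k / self.rho_cp


def effective_props(phi: float, mat: MaterialSet, k_mean: str = "arithmetic") -> EffectiveProps:
    """Volume-weighted effective properties of a zone with porosity ``phi``.

    rho_eff   = phi*rho_f + (1-phi)*rho_c
    (rhoCp)_eff = phi*rho_f*Cp_f + (1-phi)*rho_c*Cp_c
    k_eff     = phi*k_f + (1-phi)*k_c          (parallel / arithmetic mean)

    ``k_mean="harmonic"`` selects the series (harmonic) conductivity mean
    instead; the arithmetic mean is the default local-thermal-equilibrium
    closure.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("porosity must lie in [0, 1]")
    f, s = mat.fluid, mat.solid
    rho = phi * f.rho + (1.0 - phi) * s.rho
    rho_cp = phi * f.rho_cp + (1.0 - phi) * s.rho_cp
    if k_mean == "arithmetic":
        k = phi * f.k + (1.0 - phi) * s.k
    elif k_mean == "harmonic":
        k = 1.0 / (phi / f.k + (1.0 - phi) / s.k)
    else:
        raise ValueError(f"unknown conductivity mean {k_mean!r}")
    return EffectiveProps(rho=rho, rho_cp=rho_cp, k=k)


def darcy_coefficient(phi: float, d: float) -> float:
    """Blake-Kozeny viscous resistance D = 150*(1-phi)^2 / (phi^3 * d^2) (m^-2).

    Enters the momentum equation as the sink -nu*D*U per unit volume.  ``d``
    is the diameter of the coral sample.  phi = 0 is rejected (an
    impermeable zone should be excluded from the flow instead).
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError("porosity must lie in (0, 1] for a porous zone")
    if d <= 0:
        raise ValueError("characteristic diameter must be positive")
    return 150.0 * (1.0 - phi) ** 2 / (phi**3 * d * d)


def forchheimer_coefficient(phi: float, d: float) -> float:
    """Burke-Plummer inertial resistance F = 3.5*(1-phi) / (phi^3 * d) (m^-1).

    Enters the momentum sink as -(F/2)*|U|*U.  At the millimetre-per-second
    velocities of the validation chamber this quadratic term is negligible
    and is disabled by default in the solver.
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError("porosity must lie in (0, 1] for a porous zone")
    if d <= 0:
        raise ValueError("characteristic diameter must be positive")
    return 3.5 * (1.0 - phi) / (phi**3 * d)


def prandtl_number(nu: float, alpha: float) -> float:
    """Prandtl number Pr = nu / alpha (dimensionless)."""
    if alpha <= 0:
        raise ValueError("thermal diffusivity must be positive")
    return nu / alpha


@dataclass(frozen=True)
class PorousZoneSpec:
    """Resistance coefficients and porosity of one porous zone."""

    phi: float
    d: float
    D: float  # viscous resistance, m^-2
    F: float  # inertial resistance, m^-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("porosity must lie in [0, 1]")
        if self.D < 0 or self.F < 0:
            raise ValueError("resistances must be non-negative")

    @classmethod
    def from_porosity(cls, phi: float, d: float, inertial: bool = False) -> "PorousZoneSpec":
        """Build a zone spec from porosity and sample diameter.

        The Forchheimer term is omitted unless ``inertial`` is set, because
        the viscous term dominates the pressure drop at low velocity.
        """
        return cls(
            phi=phi,
            d=d,
            D=darcy_coefficient(phi, d),
            F=forchheimer_coefficient(phi, d) if inertial else 0.0,
        )


#: default tissue percolation porosity ("5-10%" range; intact tissue barely
#: percolates, cut faces do)
TISSUE_POROSITY = 0.05
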