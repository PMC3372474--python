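"""Lumped-parameter heat balance for a coral in flowing water.

At steady state the shortwave power absorbed by the tissue equals the
convective loss to the water (Newton cooling):

    alpha * I * A_p = h * A * dT_ss    =>    dT_ss = alpha*I*A_p / (h*A)

where ``alpha`` is the tissue absorptivity, ``I`` the downwelling irradiance,
``A_p`` the horizontally projected (irradiated) area, ``A`` the total
convective surface area and ``h`` the convective heat-transfer coefficient.
Treating the coral as internally well mixed, the warm-up after a dark-light
shift is a single exponential with time constant

    tau = (rho*Cp)_eff / (h * S),      S = A/V,

so the surface-to-volume ratio S is the shape parameter separating branching
corals (large S, fast, cool) from massive corals (small S, slow, warm).
This model serves both as a standalone calculator and as a limit-case oracle
for the finite-volume solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import CYLINDER, HEMISPHERE, CoralShape, projected_area, surface_area, volume
from .properties import EffectiveProps


@dataclass(frozen=True)
class LumpedCoral:
    """Areas, volume and effective thermal mass of one coral."""

    area: float  # total convective area A, m^2
    area_projected: float  # irradiated area A_p, m^2
    volume: float  # m^3
    absorptivity: float  # tissue absorptivity alpha, dimensionless
    rho_cp: float  # effective volumetric heat capacity, J/(m^3 K)

    def __post_init__(self) -> None:
        if self.area_projected > self.area:
            raise ValueError("projected area cannot exceed total area")
        if not 0.0 <= self.absorptivity <= 1.0:
            raise ValueError("absorptivity must lie in [0, 1]")
        if min(self.area, self.volume, self.rho_cp) <= 0:
            raise ValueError("area, volume and rho_cp must be positive")

    @property
    def av(self) -> float:
        return self.area / self.volume

    @classmethod
    def from_shape(cls, coral: CoralShape, absorptivity: float, eff: EffectiveProps) -> "LumpedCoral":
        return cls(
            area=surface_area(coral),
            area_projected=projected_area(coral),
            volume=volume(coral),
            absorptivity=absorptivity,
            rho_cp=eff.rho_cp,
        )


@dataclass(frozen=True)
class ThermalResponse:
    """Steady warming, time constant and trajectory of one dark-light shift."""

    dT_ss: float  # K
    tau: float  # s
    t_on: float  # s
    trajectory: Callable[[np.ndarray], np.ndarray]


def steady_warming(alpha: float, irradiance: float, h: float, area_projected: float, area: float) -> float:
    """Steady surface warming dT_ss = alpha*I*A_p / (h*A) in kelvin."""
    if h <= 0:
        raise ValueError("heat-transfer coefficient must be positive")
    if irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    if area <= 0 or area_projected < 0:
        raise ValueError("areas must be positive")
    return alpha * irradiance * area_projected / (h * area)


def time_constant(rho_cp_eff: float, h: float, av: float) -> float:
    """Thermal time constant tau = (rho*Cp)_eff / (h*S) in seconds."""
    if h <= 0 or av <= 0:
        raise ValueError("h and the A/V ratio must be positive")
    if rho_cp_eff <= 0:
        raise ValueError("effective volumetric heat capacity must be positive")
    return rho_cp_eff / (h * av)


def transient_warming(dT_ss: float, tau: float, t_on: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """Exponential warm-up: 0 before ``t_on``, dT_ss*(1-exp(-(t-t_on)/tau)) after."""
    if tau <= 0:
        raise ValueError("time constant must be positive")

    def dT(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = dT_ss * -np.expm1(-np.maximum(t - t_on, 0.0) / tau)
        return out

    return dT


def h_from_correlation(
    reynolds: float,
    prandtl: float,
    shape: str,
    diameter: float,
    k_fluid: float,
) -> float:
    """Forced-convection heat-transfer coefficient h = Nu * k_f / d.

    Hemispheres use the Whitaker sphere correlation,
    Nu = 2 + (0.4 Re^1/2 + 0.06 Re^2/3) Pr^0.4 (viscosity ratio taken as 1);
    cylinders (branches in cross-flow) use Churchill-Bernstein.  Both reduce
    to the correct conduction limit as Re -> 0 for the sphere (Nu -> 2).
    Valid in the laminar range of the validation chamber (Re <~ 500); larger
    Re triggers a warning, not an error.
    """
    if reynolds < 0 or prandtl <= 0 or diameter <= 0 or k_fluid <= 0:
        raise ValueError("invalid correlation inputs")
    if reynolds > 500:
        warnings.warn(
            f"Re = {reynolds:.0f} is outside the laminar validity range (<~500)",
            stacklevel=2,
        )
    if shape == HEMISPHERE:
        nu = 2.0 + (0.4 * reynolds**0.5 + 0.06 * reynolds ** (2.0 / 3.0)) * prandtl**0.4
    elif shape == CYLINDER:
        nu = 0.3 + (
            0.62 * reynolds**0.5 * prandtl ** (1.0 / 3.0)
            / (1.0 + (0.4 / prandtl) ** (2.0 / 3.0)) ** 0.25
            * (1.0 + (reynolds / 282000.0) ** 0.625) ** 0.8
        )
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return nu * k_fluid / diameter


def respond(
    coral: LumpedCoral, irradiance: float, h: float, t_on: float = 0.0
) -> ThermalResponse:
    """Full lumped response: steady warming, time constant and trajectory."""
    dT_ss = steady_warming(coral.absorptivity, irradiance, h, coral.area_projected, coral.area)
    tau = time_constant(coral.rho_cp, h, coral.av)
    return ThermalResponse(dT_ss=dT_ss, tau=tau, t_on=t_on, trajectory=transient_warming(dT_ss, tau, t_on))
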