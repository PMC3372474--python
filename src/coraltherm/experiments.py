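"""Species presets and scripted replication of the validation experiments.

Five coral samples from the validation flow-chamber study are bundled as
presets: two steady-state hemispheres (Porites lobata, Favia sp.), a
steady-state branch (Stylophora pistillata), a transient hemisphere
(Cyphastrea serailia) and a transient branch (Seriatopora hystrix).  Four
scenarios are scripted on top of the solver:

* ``run_steady_sweep`` — steady surface warming across a 500-950 W/m^2
  irradiance sweep at 0.002 m/s, with a linear fit (warming is linear in
  irradiance because buoyancy is neglected, so the energy equation is linear
  on the frozen flow).
* ``run_dark_light`` — transient dark-light shift at 600 W/m^2 and the
  fitted thermal time constant.
* ``run_flow_comparison`` — absorptivity calibrated once per species at low
  flow (0.002 m/s), then warming predicted at high flow (0.013 m/s).
* ``run_sensitivity`` — skeletal bulk-volume perturbation (+-10%) at
  750 W/m^2, reported as warming trajectories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import CYLINDER, HEMISPHERE, SKELETON, TISSUE, ChamberDomain, CoralShape, Mesh, build_mesh
from .postprocess import LinearFitResult, TimeSeries, fit_time_constant, irradiance_response, sensitivity_study, surface_warming
from .properties import (
    TISSUE_POROSITY,
    MaterialSet,
    PorousZoneSpec,
    bulk_density_from_porosity,
    effective_props,
    porosity_from_density,
)
from .solver import (
    T_AMBIENT,
    EnergyModel,
    FieldState,
    FlowSolver,
    IrradianceSource,
    SolverConfig,
    solve_transient,
    validation_bcs,
)

log = logging.getLogger(__name__)

#: tissue absorptivity range inferred for these species in the validation study
ABSORPTIVITY_RANGE = (0.13, 0.28)

#: low/high flow speeds of the flow-comparison scenario (m/s)
LOW_FLOW, HIGH_FLOW = 0.002, 0.013

#: modelled low-flow surface warming (K) at 600 W/m^2 used as the
#: absorptivity-calibration target for each steady-state species
LOW_FLOW_MODEL_WARMING = {
    "Favia sp.": 0.50,
    "S. pistillata": 0.35,
    "P. lobata": 0.58,
}

#: high-flow modelled warming (K), for reference alongside predictions
HIGH_FLOW_MODEL_WARMING = {
    "Favia sp.": 0.35,
    "S. pistillata": 0.21,
    "P. lobata": 0.52,
}

#: dark-light shift times (s) of the transient scenario
DARK_LIGHT_T_ON = {"C. serailia": 143.0, "S. hystrix": 235.0}


@dataclass(frozen=True)
class SpeciesPreset:
    """One coral sample: shape, skeletal porosity and checks."""

    name: str
    coral: CoralShape
    skeletal_porosity: float
    porosity_assumed: bool = False
    resolution: tuple[int, int, int] = (48, 26, 28)
    margin: float | None = None  # near-coral refinement-window pad (m)
    re_low: float | None = None  # tabulated Re at 0.002 m/s
    re_high: float | None = None  # tabulated Re at 0.013 m/s

    def reynolds(self, u: float, nu: float) -> float:
        return u * self.coral.diameter / nu

    @property
    def bulk_density(self) -> float:
        return bulk_density_from_porosity(self.skeletal_porosity)


def make_presets() -> list[SpeciesPreset]:
    """The five validation corals with their dimensions and porosities."""
    return [
        SpeciesPreset(
            name="P. lobata",
            coral=CoralShape(HEMISPHERE, radius=0.0175),
            skeletal_porosity=0.475,
            resolution=(56, 30, 30),
            re_low=72,
            re_high=468,
        ),
        SpeciesPreset(
            name="S. pistillata",
            coral=CoralShape(CYLINDER, radius=0.003, height=0.006),
            skeletal_porosity=0.431,
            resolution=(56, 40, 38),
            re_low=12,
            re_high=80,
        ),
        SpeciesPreset(
            name="Favia sp.",
            coral=CoralShape(HEMISPHERE, radius=0.0175),
            skeletal_porosity=0.500,
            porosity_assumed=True,  # not measured; massive-coral value assumed
            resolution=(56, 30, 30),
            re_low=72,
            re_high=468,
        ),
        SpeciesPreset(
            name="C. serailia",
            coral=CoralShape(HEMISPHERE, radius=0.025),
            skeletal_porosity=0.500,
            porosity_assumed=True,  # sample unavailable; massive-coral value assumed
            resolution=(56, 30, 30),
            margin=1.0e-3,
            re_low=100,
        ),
        SpeciesPreset(
            name="S. hystrix",
            coral=CoralShape(CYLINDER, radius=0.0015, height=0.006),
            skeletal_porosity=0.405,
            resolution=(60, 42, 42),
            margin=1.0e-3,
            re_low=6,
        ),
    ]


def get_preset(name: str) -> SpeciesPreset:
    for p in make_presets():
        if p.name == name:
            return p
    raise KeyError(f"unknown species {name!r}; choose from "
                   f"{[p.name for p in make_presets()]}")


@dataclass
class Case:
    """Assembled simulation case: mesh, materials, zone specs, BCs, config."""

    preset: SpeciesPreset
    mesh: Mesh
    materials: MaterialSet
    porous: dict[int, PorousZoneSpec]
    eff: dict[int, object]
    bcs: object
    config: SolverConfig
    flow: FieldState | None = None
    residuals: list | None = None

    def solve_flow(self) -> FieldState:
        if self.flow is None:
            solver = FlowSolver(self.mesh, self.materials, self.porous, self.bcs, self.config)
            self.flow = solver.solve()
            self.residuals = list(solver.residuals)
            log.info(
                "flow converged for %s in %d iterations (residual %.2e)",
                self.preset.name, len(solver.residuals), solver.residuals[-1],
            )
        return self.flow

    def residual_frame(self) -> pd.DataFrame:
        """Continuity-residual history of the flow solve, one row per iteration."""
        if self.residuals is None:
            raise RuntimeError("no flow has been solved yet")
        return pd.DataFrame(
            {"iteration": range(len(self.residuals)), "continuity_residual": self.residuals}
        )


def build_case(
    preset: SpeciesPreset,
    u_inlet: float = LOW_FLOW,
    resolution: tuple[int, int, int] | None = None,
    materials: MaterialSet | None = None,
    tissue_porosity: float = TISSUE_POROSITY,
    skeletal_porosity: float | None = None,
    domain: ChamberDomain | None = None,
    config: SolverConfig | None = None,
    bottom_mode: str = "tangential",
) -> Case:
    """Mesh the chamber for a preset and assemble zone properties and BCs."""
    materials = materials or MaterialSet()
    domain = domain or ChamberDomain()
    phi_s = preset.skeletal_porosity if skeletal_porosity is None else skeletal_porosity
    mesh = build_mesh(domain, preset.coral, resolution or preset.resolution,
                      margin=preset.margin)
    d = preset.coral.diameter
    porous = {
        TISSUE: PorousZoneSpec.from_porosity(tissue_porosity, d),
        SKELETON: PorousZoneSpec.from_porosity(phi_s, d),
    }
    eff = {
        TISSUE: effective_props(tissue_porosity, materials),
        SKELETON: effective_props(phi_s, materials),
    }
    bcs = validation_bcs(u_inlet=u_inlet, bottom_mode=bottom_mode)
    return Case(preset, mesh, materials, porous, eff, bcs, config or SolverConfig())


def _unit_warming(case: Case) -> tuple[float, float, EnergyModel]:
    """Mean/max surface warming per unit absorbed flux (alpha*I = 1 W/m^2)."""
    flow = case.solve_flow()
    src = IrradianceSource(irradiance=1.0, absorptivity=1.0)
    energy = EnergyModel(case.mesh, case.materials, case.eff, flow, case.bcs, src)
    T = energy.solve_steady()
    mean, mx = surface_warming(replace(flow, T=T), case.mesh)
    return mean, mx, energy


def calibrate_absorptivity(
    case: Case, irradiance: float, target_dT: float, statistic: str = "max"
) -> float:
    """Absorptivity that reproduces ``target_dT`` at ``irradiance`` on this case.

    Warming is linear in alpha*I, so the calibration is a single division;
    the result is clipped to the species-plausible range [0.13, 0.28] with a
    warning when the unclipped value falls outside it.  ``statistic`` selects
    the surface-warming measure being matched: ``"max"`` (default) is the
    hottest surface volume — the analogue of a probe at the illuminated
    spot, which is how the reference warming values were measured —
    ``"mean"`` the area-weighted surface mean.
    """
    per_mean, per_max, _ = _unit_warming(case)
    per_unit = per_max if statistic == "max" else per_mean
    alpha = target_dT / (per_unit * irradiance)
    lo, hi = ABSORPTIVITY_RANGE
    if not lo <= alpha <= hi:
        warnings.warn(
            f"calibrated absorptivity {alpha:.3f} for {case.preset.name} falls outside "
            f"[{lo}, {hi}]; clipping", stacklevel=2,
        )
        alpha = min(max(alpha, lo), hi)
    return float(alpha)


def run_steady_sweep(
    species: str | SpeciesPreset,
    irradiances=(500.0, 600.0, 700.0, 825.0, 950.0),
    u_inlet: float = LOW_FLOW,
    absorptivity: float | None = None,
    resolution: tuple[int, int, int] | None = None,
    case: Case | None = None,
) -> tuple[pd.DataFrame, LinearFitResult | None]:
    """Steady warming across an irradiance sweep plus a linear fit.

    With fewer than 3 irradiances the fit is skipped and only the table is
    returned (with ``None`` in its place).
    """
    preset = species if isinstance(species, SpeciesPreset) else get_preset(species)
    case = case or build_case(preset, u_inlet=u_inlet, resolution=resolution)
    alpha = 0.5 * sum(ABSORPTIVITY_RANGE) if absorptivity is None else absorptivity
    per_unit_mean, per_unit_max, _ = _unit_warming(case)
    rows = [
        {
            "irradiance_W_m2": I,
            "dT_mean_K": alpha * I * per_unit_mean,
            "dT_max_K": alpha * I * per_unit_max,
        }
        for I in irradiances
    ]
    table = pd.DataFrame(rows)
    fit = None
    if len(table) >= 3:
        fit = irradiance_response(table[["irradiance_W_m2", "dT_mean_K"]].to_numpy())
    return table, fit


def run_dark_light(
    species: str | SpeciesPreset,
    irradiance: float = 600.0,
    t_on: float | None = None,
    absorptivity: float | None = None,
    resolution: tuple[int, int, int] | None = None,
    config: SolverConfig | None = None,
    case: Case | None = None,
) -> tuple[TimeSeries, float, float]:
    """Dark-light transient; returns (series, tau, plateau warming).

    The fitted time constant is independent of absorptivity (the trajectory
    scales linearly), so the mid-range alpha is used unless given.
    """
    preset = species if isinstance(species, SpeciesPreset) else get_preset(species)
    if t_on is None:
        t_on = DARK_LIGHT_T_ON.get(preset.name, 0.0)
    alpha = 0.5 * sum(ABSORPTIVITY_RANGE) if absorptivity is None else absorptivity
    cfg = config or SolverConfig()
    case = case or build_case(preset, u_inlet=LOW_FLOW, resolution=resolution, config=cfg)
    schedule = IrradianceSource(irradiance=irradiance, absorptivity=alpha, t_on=t_on)
    flow = case.solve_flow()
    series = solve_transient(
        case.mesh, case.materials, case.porous, case.eff, schedule, case.bcs, cfg, flow_state=flow
    )
    tau, dT_ss, _ = fit_time_constant(series, t_on)
    return series, tau, dT_ss


def run_flow_comparison(
    species_list=("Favia sp.", "S. pistillata", "P. lobata"),
    irradiance: float = 600.0,
    flows: tuple[float, float] = (LOW_FLOW, HIGH_FLOW),
    resolution: tuple[int, int, int] | None = None,
    targets: dict[str, float] | None = None,
    statistic: str = "max",
) -> pd.DataFrame:
    """Calibrated low-flow / predicted high-flow warming per species.

    Absorptivity is calibrated once per species so the low-flow solve matches
    the species' modelled low-flow warming (``targets``, defaulting to the
    bundled values), then frozen; the high-flow number is a genuine
    prediction.  ``statistic`` (``"max"``/``"mean"``) selects the warming
    measure used for calibration and prediction; both are tabulated.
    """
    targets = targets or LOW_FLOW_MODEL_WARMING
    u_lo, u_hi = flows
    idx = 1 if statistic == "max" else 0
    rows = []
    for name in species_list:
        preset = get_preset(name) if isinstance(name, str) else name
        case_lo = build_case(preset, u_inlet=u_lo, resolution=resolution)
        alpha = calibrate_absorptivity(case_lo, irradiance, targets[preset.name], statistic)
        unit_lo = _unit_warming(case_lo)[:2]
        case_hi = build_case(preset, u_inlet=u_hi, resolution=resolution)
        unit_hi = _unit_warming(case_hi)[:2]
        rows.append(
            {
                "species": preset.name,
                "absorptivity": alpha,
                "dT_low_K": alpha * irradiance * unit_lo[idx],
                "dT_high_K": alpha * irradiance * unit_hi[idx],
                "dT_low_mean_K": alpha * irradiance * unit_lo[0],
                "dT_high_mean_K": alpha * irradiance * unit_hi[0],
                "target_low_K": targets[preset.name],
            }
        )
        log.info("flow comparison %s: alpha=%.3f low=%.3f high=%.3f",
                 preset.name, alpha, rows[-1]["dT_low_K"], rows[-1]["dT_high_K"])
    return pd.DataFrame(rows)


def run_sensitivity(
    species: str | SpeciesPreset,
    volume_perturbation: float = 0.10,
    irradiance: float = 750.0,
    u_inlet: float = LOW_FLOW,
    resolution: tuple[int, int, int] | None = None,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Skeletal bulk-volume sensitivity at 750 W/m^2 and 0.002 m/s inflow.

    A +v bulk-volume perturbation at constant mass divides the bulk density
    by (1+v); the porosity follows from the density ratio.  Trajectories are
    compared on the surface-warming series.
    """
    preset = species if isinstance(species, SpeciesPreset) else get_preset(species)
    cfg = config or SolverConfig(end_time=900.0, min_after_on=300.0)
    rho_b0 = preset.bulk_density
    alpha = 0.5 * sum(ABSORPTIVITY_RANGE)

    def run_perturbed(pert: float) -> TimeSeries:
        phi = porosity_from_density(rho_b0 / (1.0 + pert))
        case = build_case(preset, u_inlet=u_inlet, resolution=resolution,
                          skeletal_porosity=phi, config=cfg)
        schedule = IrradianceSource(irradiance=irradiance, absorptivity=alpha, t_on=0.0)
        flow = case.solve_flow()
        return solve_transient(case.mesh, case.materials, case.porous, case.eff,
                               schedule, case.bcs, cfg, flow_state=flow)

    table = sensitivity_study(run_perturbed, volume_perturbation)
    table.attrs["parameters"] = {
        "inlet_reference_pressure_Pa": 0.0,
        "inlet_temperature_C": T_AMBIENT,
        "inlet_velocity_m_s": u_inlet,
        "skeletal_bulk_volume_perturbation": volume_perturbation,
        "heat_flux_W_m2": irradiance,
    }
    return table


def run_grid_study(
    species: str | SpeciesPreset,
    resolutions,
    irradiance: float = 750.0,
    u_inlet: float = LOW_FLOW,
    absorptivity: float = 0.2,
) -> pd.DataFrame:
    """Grid-independence study: steady warming vs cell count."""
    from .postprocess import grid_independence_study

    preset = species if isinstance(species, SpeciesPreset) else get_preset(species)

    def run_case(res):
        case = build_case(preset, resolution=tuple(res))
        per_unit, _, _ = _unit_warming(case)
        return case.mesh.n_cells, absorptivity * irradiance * per_unit

    return grid_independence_study(run_case, resolutions)
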