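"""YAML run-configuration files: load, validate, dispatch.

A run configuration is a small YAML document selecting a scenario and
overriding defaults, e.g.::

    scenario: steady-sweep        # steady-sweep | dark-light | flow-comparison
                                  # | sensitivity | grid-study | lumped
    species: "P. lobata"
    irradiances: [500, 600, 700, 825, 950]
    flow: 0.002                   # m/s
    absorptivity: 0.2
    resolution: [56, 30, 30]
    solver:
      dt: 1.0
      tol: 1.0e-6
      relax_u: 0.7
      relax_p: 0.3
    geometry:
      tissue_thickness: 0.001     # m
      tissue_porosity: 0.05

Unknown keys are rejected so typos fail loudly.  Every experiment is fully
reproducible from its configuration alone.
"""

from __future__ import annotations

import dataclasses

import yaml

from .solver import SolverConfig

_TOP_KEYS = {
    "scenario",
    "species",
    "irradiances",
    "irradiance",
    "flow",
    "flows",
    "absorptivity",
    "resolution",
    "resolutions",
    "t_on",
    "volume_perturbation",
    "solver",
    "geometry",
    "out",
}

SCENARIOS = ("steady-sweep", "dark-light", "flow-comparison", "sensitivity", "grid-study", "lumped")


def load_config(path) -> dict:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "scenario" in cfg and cfg["scenario"] not in SCENARIOS:
        raise ValueError(f"unknown scenario {cfg['scenario']!r}; choose from {SCENARIOS}")
    solver_keys = {f.name for f in dataclasses.fields(SolverConfig)}
    bad = set(cfg.get("solver", {}) or {}) - solver_keys
    if bad:
        raise ValueError(f"unknown solver keys: {sorted(bad)}")
    return cfg


def solver_config(cfg: dict) -> SolverConfig:
    return SolverConfig(**(cfg.get("solver", {}) or {}))
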