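"""Configuration loading, validation and presets.

A run is described by a small structured YAML file; interface units are the
laboratory ones (um, mW, degrees C, nm) and are converted to SI on load.
Example::

    laser:
      power_mw: 20.5
    sim:
      seed: 7

Any key not listed below is rejected.  ``dump_config(load_config(f))``
round-trips.  Named presets exist for the four laser powers of the reference
experiment (20.5, 40.5, 79.8 and 114 mW).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import yaml

from .langevin import SimulationConfig
from .thermal import ChamberGeometry, LaserSource, SolverSettings, ThermalModel
from .transport import DEFAULT_DT_TABLE, FluidModel, ParticleModel, load_dt_table

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_config", "preset", "POWER_PRESETS_MW"]

POWER_PRESETS_MW = (20.5, 40.5, 79.8, 114.0)


class ConfigError(ValueError):
    """Named configuration error: unknown key, bad unit or broken invariant."""


@dataclass(frozen=True)
class FieldGridSpec:
    """Cartesian output grid for the mid-plane field."""

    half_width: float = 150e-6  # [m]
    spacing: float = 0.5e-6  # [m]


@dataclass(frozen=True)
class AnalysisSettings:
    window_start: float = 600.0  # [s]
    window_end: float = 1200.0  # [s]
    n_radial_bins: int = 100
    radial_extent: float = 100e-6  # [m]
    center_pool_bins: int = 1
    force_particles: int = 3000
    force_region_half_width: float = 25e-6  # [m]
    n_force_bins: int = 100
    force_extent: float = 50e-6  # [m]


@dataclass(frozen=True)
class RunConfig:
    chamber: ChamberGeometry = dc_field(default_factory=ChamberGeometry)
    laser: LaserSource = dc_field(default_factory=lambda: LaserSource(power_in=20.5e-3))
    thermal: ThermalModel = dc_field(default_factory=ThermalModel)
    solver: SolverSettings = dc_field(default_factory=SolverSettings)
    fluid: FluidModel = dc_field(default_factory=FluidModel)
    particle: ParticleModel = dc_field(default_factory=ParticleModel)
    sim: SimulationConfig = dc_field(default_factory=SimulationConfig)
    field_grid: FieldGridSpec = dc_field(default_factory=FieldGridSpec)
    analysis: AnalysisSettings = dc_field(default_factory=AnalysisSettings)

    def __post_init__(self) -> None:
        if self.sim.init_half_width > self.sim.domain_half_width:
            raise ConfigError("init region larger than the simulation domain")
        if self.sim.domain_half_width * np.sqrt(2) > self.chamber.lateral_radius:
            raise ConfigError("simulation domain corner lies outside the solved radius")
        if self.sim.domain_half_width > self.field_grid.half_width:
            raise ConfigError("simulation domain extends beyond the output field grid")
        if abs(self.laser.path_length - self.chamber.water_thickness) > 1e-12:
            raise ConfigError("laser path length must equal the water thickness")


_SCHEMA = {
    "chamber": {"water_um", "glass_um", "spot_fwhm_um", "domain_radius_um"},
    "laser": {"power_mw", "alpha_per_m"},
    "thermal": {"k0", "k_slope", "T_ref", "k_glass", "ambient_C"},
    "solver": {"nr_source", "nz_water", "nz_glass", "tol_K", "max_iter"},
    "fluid": {"visc_prefactor", "visc_activation"},
    "particle": {"radius_nm", "dt_table", "dt_table_file"},
    "sim": {
        "dt_s",
        "duration_s",
        "record_interval_s",
        "n_particles",
        "seed",
        "init_halfwidth_um",
        "domain_halfwidth_um",
        "T_room_K",
        "thermophoresis",
    },
    "field": {"halfwidth_um", "spacing_um"},
    "analysis": {
        "window_start_s",
        "window_end_s",
        "n_radial_bins",
        "radial_extent_um",
        "center_pool_bins",
        "force_particles",
        "force_region_halfwidth_um",
        "n_force_bins",
        "force_extent_um",
    },
}


def _check_keys(data: dict) -> None:
    for section, keys in data.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if keys is None:
            continue
        if not isinstance(keys, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        unknown = set(keys) - _SCHEMA[section]
        if unknown:
            raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")


def _build(data: dict, base_dir: Path) -> RunConfig:
    try:
        return _build_inner(data, base_dir)
    except ConfigError:
        raise
    except ValueError as exc:  # invariant violations from component dataclasses
        raise ConfigError(str(exc)) from exc


def _build_inner(data: dict, base_dir: Path) -> RunConfig:
    g = lambda sec: data.get(sec) or {}

    ch = g("chamber")
    chamber = ChamberGeometry(
        water_thickness=ch.get("water_um", 8.0) * 1e-6,
        glass_thickness=ch.get("glass_um", 150.0) * 1e-6,
        source_diameter=ch.get("spot_fwhm_um", 27.6) * 1e-6,
        lateral_radius=ch.get("domain_radius_um", 300.0) * 1e-6,
    )
    la = g("laser")
    laser = LaserSource(
        power_in=la.get("power_mw", 20.5) * 1e-3,
        absorption_coeff=la.get("alpha_per_m", 967.0),
        path_length=chamber.water_thickness,
    )
    th = g("thermal")
    thermal = ThermalModel(
        k0=th.get("k0", 0.61),
        k_slope=th.get("k_slope", 0.0012),
        T_ref=th.get("T_ref", 298.0),
        k_glass=th.get("k_glass", 1.14),
        T_ambient=th.get("ambient_C", 24.0) + 273.15,
    )
    so = g("solver")
    solver = SolverSettings(
        nr_source=so.get("nr_source", 40),
        nz_water=so.get("nz_water", 17),
        nz_glass=so.get("nz_glass", 28),
        tol=so.get("tol_K", 1e-6),
        max_iter=so.get("max_iter", 100),
    )
    fl = g("fluid")
    fluid = FluidModel(
        visc_prefactor=fl.get("visc_prefactor", 2.761e-6),
        visc_activation=fl.get("visc_activation", 1713.0),
    )
    pa = g("particle")
    if "dt_table" in pa and "dt_table_file" in pa:
        raise ConfigError("give either particle.dt_table or particle.dt_table_file, not both")
    if "dt_table_file" in pa:
        table = load_dt_table(base_dir / pa["dt_table_file"])
    elif "dt_table" in pa:
        table = np.asarray(pa["dt_table"], dtype=float)
    else:
        table = DEFAULT_DT_TABLE.copy()
    particle = ParticleModel(radius=pa.get("radius_nm", 250.0) * 1e-9, dt_table=table)
    si = g("sim")
    sim = SimulationConfig(
        dt=si.get("dt_s", 0.05),
        duration=si.get("duration_s", 1200.0),
        record_interval=si.get("record_interval_s", 1.0),
        n_particles=si.get("n_particles", 1000),
        seed=si.get("seed", 0),
        init_half_width=si.get("init_halfwidth_um", 50.0) * 1e-6,
        domain_half_width=si.get("domain_halfwidth_um", 150.0) * 1e-6,
        T_room=si.get("T_room_K", 297.0),
        thermophoresis_enabled=si.get("thermophoresis", True),
    )
    fg = g("field")
    field_grid = FieldGridSpec(
        half_width=fg.get("halfwidth_um", 150.0) * 1e-6,
        spacing=fg.get("spacing_um", 0.5) * 1e-6,
    )
    an = g("analysis")
    analysis = AnalysisSettings(
        window_start=an.get("window_start_s", 600.0),
        window_end=an.get("window_end_s", 1200.0),
        n_radial_bins=an.get("n_radial_bins", 100),
        radial_extent=an.get("radial_extent_um", 100.0) * 1e-6,
        center_pool_bins=an.get("center_pool_bins", 1),
        force_particles=an.get("force_particles", 3000),
        force_region_half_width=an.get("force_region_halfwidth_um", 25.0) * 1e-6,
        n_force_bins=an.get("n_force_bins", 100),
        force_extent=an.get("force_extent_um", 50.0) * 1e-6,
    )
    return RunConfig(
        chamber=chamber,
        laser=laser,
        thermal=thermal,
        solver=solver,
        fluid=fluid,
        particle=particle,
        sim=sim,
        field_grid=field_grid,
        analysis=analysis,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Defaults fill every omitted key, so a minimal file (for instance just
    ``laser: {power_mw: 20.5}``) expands to the full reference
    configuration.  Unknown sections or keys raise ``ConfigError``.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(data)
    return _build(data, path.parent)


def dump_config(cfg: RunConfig) -> dict:
    """Resolved configuration as a plain dict in interface units
    (load(dump) reproduces the same RunConfig)."""
    return {
        "chamber": {
            "water_um": cfg.chamber.water_thickness * 1e6,
            "glass_um": cfg.chamber.glass_thickness * 1e6,
            "spot_fwhm_um": cfg.chamber.source_diameter * 1e6,
            "domain_radius_um": cfg.chamber.lateral_radius * 1e6,
        },
        "laser": {
            "power_mw": cfg.laser.power_in * 1e3,
            "alpha_per_m": cfg.laser.absorption_coeff,
        },
        "thermal": {
            "k0": cfg.thermal.k0,
            "k_slope": cfg.thermal.k_slope,
            "T_ref": cfg.thermal.T_ref,
            "k_glass": cfg.thermal.k_glass,
            "ambient_C": cfg.thermal.T_ambient - 273.15,
        },
        "solver": {
            "nr_source": cfg.solver.nr_source,
            "nz_water": cfg.solver.nz_water,
            "nz_glass": cfg.solver.nz_glass,
            "tol_K": cfg.solver.tol,
            "max_iter": cfg.solver.max_iter,
        },
        "fluid": {
            "visc_prefactor": cfg.fluid.visc_prefactor,
            "visc_activation": cfg.fluid.visc_activation,
        },
        "particle": {
            "radius_nm": cfg.particle.radius * 1e9,
            "dt_table": [[float(t), float(d)] for t, d in cfg.particle.dt_table],
        },
        "sim": {
            "dt_s": cfg.sim.dt,
            "duration_s": cfg.sim.duration,
            "record_interval_s": cfg.sim.record_interval,
            "n_particles": cfg.sim.n_particles,
            "seed": cfg.sim.seed,
            "init_halfwidth_um": cfg.sim.init_half_width * 1e6,
            "domain_halfwidth_um": cfg.sim.domain_half_width * 1e6,
            "T_room_K": cfg.sim.T_room,
            "thermophoresis": cfg.sim.thermophoresis_enabled,
        },
        "field": {
            "halfwidth_um": cfg.field_grid.half_width * 1e6,
            "spacing_um": cfg.field_grid.spacing * 1e6,
        },
        "analysis": {
            "window_start_s": cfg.analysis.window_start,
            "window_end_s": cfg.analysis.window_end,
            "n_radial_bins": cfg.analysis.n_radial_bins,
            "radial_extent_um": cfg.analysis.radial_extent * 1e6,
            "center_pool_bins": cfg.analysis.center_pool_bins,
            "force_particles": cfg.analysis.force_particles,
            "force_region_halfwidth_um": cfg.analysis.force_region_half_width * 1e6,
            "n_force_bins": cfg.analysis.n_force_bins,
            "force_extent_um": cfg.analysis.force_extent * 1e6,
        },
    }


def preset(power_mw: float = 20.5, seed: int = 0) -> RunConfig:
    """Reference configuration at one of the experimental laser powers."""
    base = RunConfig()
    laser = replace(base.laser, power_in=power_mw * 1e-3)
    sim = replace(base.sim, seed=seed)
    return replace(base, laser=laser, sim=sim)
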