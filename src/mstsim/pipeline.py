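"""End-to-end orchestration: heat -> simulate -> analyze.

`run_pipeline` executes the full chain — volumetric source construction,
nonlinear steady conduction solve, mid-plane field extraction, the seeded
thermophoretic run plus its seed-matched Brownian-only control, and the
radial-concentration and force profiles — and writes a manifest from which
the run can be reproduced bit for bit.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import (
    ForceProfile,
    RadialProfile,
    estimate_dt_from_soret,
    estimate_soret,
    force_profile,
    radial_concentration,
)
from .config import RunConfig, dump_config
from .field import TemperatureField2D
from .langevin import TrajectorySet, control_config, run
from .thermal import AxisymmetricSolution, midplane_field, solve_steady_temperature

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("mstsim.pipeline")


@dataclass
class PipelineResult:
    config: RunConfig
    q_v: float
    solution: AxisymmetricSolution
    field: TemperatureField2D
    traj_tph: TrajectorySet
    traj_ref: TrajectorySet
    radial: RadialProfile
    forces: ForceProfile
    manifest: dict

    @property
    def delta_t_max(self) -> float:
        return self.solution.delta_t_max

    @property
    def center_ratio(self) -> float:
        return self.radial.center_value(self.config.analysis.center_pool_bins)

    def soret_estimate(self) -> float:
        return estimate_soret(self.center_ratio, self.delta_t_max)

    def dt_estimate(self) -> float:
        return estimate_dt_from_soret(
            self.soret_estimate(), self.config.sim.T_room, self.config.particle, self.config.fluid
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, outdir=None, write_trajectories: bool = True) -> PipelineResult:
    """Run the full simulation chain; write outputs + manifest if ``outdir``.

    Output files (all regenerable from the manifest alone): field.csv,
    field.npz, traj_tph.csv, traj_ref.csv, radial_profile.csv,
    force_profile.csv, manifest.json.
    """
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    q_v = cfg.laser.q_v(cfg.chamber)
    log.info("stage heat: Q_V = %.4e W/m^3", q_v)
    solution = solve_steady_temperature(cfg.chamber, cfg.thermal, q_v, cfg.solver)
    field = midplane_field(solution, cfg.field_grid.half_width, cfg.field_grid.spacing)
    timings["heat_s"] = time.perf_counter() - t0
    log.info("stage heat done: dT_max = %.3f K (%d Picard iterations, %.2f s)",
             solution.delta_t_max, solution.n_iterations, timings["heat_s"])

    t0 = time.perf_counter()
    traj_tph = run(cfg.sim, field, cfg.particle, cfg.fluid)
    traj_ref = run(control_config(cfg.sim), field, cfg.particle, cfg.fluid)
    timings["simulate_s"] = time.perf_counter() - t0
    log.info("stage simulate done: %d particles, %d frames (x2 runs, %.2f s)",
             traj_tph.n_particles, traj_tph.n_frames, timings["simulate_s"])

    t0 = time.perf_counter()
    an = cfg.analysis
    edges = np.linspace(0.0, an.radial_extent, an.n_radial_bins + 1)
    radial = radial_concentration(
        traj_tph, traj_ref, edges=edges, window=(an.window_start, an.window_end)
    )
    f_edges = np.linspace(0.0, an.force_extent, an.n_force_bins + 1)
    forces = force_profile(
        field,
        cfg.particle,
        n_particles=an.force_particles,
        region_half_width=an.force_region_half_width,
        edges=f_edges,
        seed=cfg.sim.seed,
        fluid=cfg.fluid,
    )
    timings["analyze_s"] = time.perf_counter() - t0
    log.info("stage analyze done (%.2f s): center c/c0 = %.4f, force peak = %.3f fN",
             timings["analyze_s"], radial.center_value(an.center_pool_bins), forces.peak * 1e15)

    manifest = {
        "software": {"name": "mstsim", "version": __version__},
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": dump_config(cfg),
        "seed": cfg.sim.seed,
        "q_v_W_per_m3": q_v,
        "delta_t_max_K": solution.delta_t_max,
        "energy_balance_error": solution.energy_balance_error(),
        "center_ratio": radial.center_value(an.center_pool_bins),
        "center_pool_bins": an.center_pool_bins,
        "force_peak_fN": forces.peak * 1e15,
        "timings": timings,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        field.save_csv(outdir / "field.csv")
        field.save_npz(outdir / "field.npz")
        radial.save_csv(outdir / "radial_profile.csv")
        forces.save_csv(outdir / "force_profile.csv")
        files = ["field.csv", "field.npz", "radial_profile.csv", "force_profile.csv"]
        if write_trajectories:
            traj_tph.save_csv(outdir / "traj_tph.csv")
            traj_ref.save_csv(outdir / "traj_ref.csv")
            files += ["traj_tph.csv", "traj_ref.csv"]
        manifest["files"] = {name: _sha256(outdir / name) for name in files}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=cfg,
        q_v=q_v,
        solution=solution,
        field=field,
        traj_tph=traj_tph,
        traj_ref=traj_ref,
        radial=radial,
        forces=forces,
        manifest=manifest,
    )
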