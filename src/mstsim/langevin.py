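"""Seeded 2D overdamped-Langevin dynamics with thermophoretic drift.

Particles obey the overdamped Langevin equation gamma dr/dt = F_B + F_tph,
discretised with a fixed time step:

    r_{i+1} = r_i - D_T(T_i) grad(T)_i dt + dr_B,

where each Brownian component dr_B ~ N(0, 2 k_B T_room dt / gamma) with the
random-force temperature fixed at room temperature, and T_i, grad(T)_i are
obtained by first-order (bilinear) interpolation of a static mid-plane
temperature field at the particle position.  Normal deviates come from a
Box-Muller transform of a seeded uniform stream, so runs are bit-reproducible
for a fixed seed; particles do not interact.  Walls of the simulation box are
reflecting.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .constants import K_B
from .field import TemperatureField2D
from .transport import (
    DEFAULT_FLUID,
    FluidModel,
    ParticleModel,
    friction,
    interp_dt,
)

__all__ = [
    "RNGStream",
    "SimulationConfig",
    "TrajectorySet",
    "gaussian_pair",
    "brownian_displacement",
    "thermophoretic_displacement",
    "thermophoretic_force",
    "step",
    "run",
]


class RNGStream:
    """Seeded uniform stream feeding the Box-Muller normal generator.

    Identical seeds yield identical displacement sequences, bit for bit.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._gen = np.random.Generator(np.random.PCG64(self.seed))

    def uniform(self, size=None):
        return self._gen.random(size)

    def normal_pairs(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """n independent standard-normal pairs via the Box-Muller transform."""
        u1 = 1.0 - self._gen.random(n)  # (0, 1]: avoids log(0)
        u2 = self._gen.random(n)
        rad = np.sqrt(-2.0 * np.log(u1))
        ang = 2.0 * np.pi * u2
        return rad * np.cos(ang), rad * np.sin(ang)


def gaussian_pair(stream: RNGStream) -> tuple[float, float]:
    """Two independent standard-normal deviates (Box-Muller)."""
    z1, z2 = stream.normal_pairs(1)
    return float(z1[0]), float(z2[0])


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings for the Brownian-dynamics stage.

    Defaults mirror the reference depletion experiment: 1000 particles
    initialised uniformly in a 100 x 100 um^2 square, 1200 s of dynamics
    recorded every second, reflecting walls on the same square, room
    temperature 297 K for the random force.
    """

    dt: float = 0.05  # [s]
    duration: float = 1200.0  # [s]
    record_interval: float = 1.0  # [s]
    n_particles: int = 1000
    seed: int = 0
    init_half_width: float = 50e-6  # [m]
    domain_half_width: float = 150e-6  # [m]
    T_room: float = 297.0  # [K]
    thermophoresis_enabled: bool = True
    local_temperature_noise: bool = False  # use local T (not T_room) in the random force

    def __post_init__(self) -> None:
        if not (0 < self.dt <= self.record_interval <= self.duration or self.duration == 0):
            raise ValueError("require 0 < dt <= record_interval <= duration")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.init_half_width > self.domain_half_width:
            raise ValueError("init region must fit inside the domain")
        if self.T_room <= 0:
            raise ValueError("T_room must be positive")

    def fingerprint(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class TrajectorySet:
    """Recorded positions: times (F,), positions (F, N, 2) [m]."""

    times: np.ndarray
    positions: np.ndarray
    seed: int
    config_fingerprint: str = ""
    thermophoresis: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (frames, particles, 2)")
        if self.positions.shape[0] != self.times.size:
            raise ValueError("times and positions disagree on frame count")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.positions[i]

    def to_dataframe(self) -> pd.DataFrame:
        f, n, _ = self.positions.shape
        return pd.DataFrame(
            {
                "particle_id": np.tile(np.arange(n), f),
                "t_s": np.repeat(self.times, n),
                "x_um": self.positions[:, :, 0].ravel() * 1e6,
                "y_um": self.positions[:, :, 1].ravel() * 1e6,
            }
        )

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mstsim trajectories seed={self.seed} ")
            fh.write(f"fingerprint={self.config_fingerprint} thermophoresis={self.thermophoresis}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def load_csv(cls, path) -> "TrajectorySet":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first.lstrip("#").split():
                    if "=" in tok:
                        k, _, v = tok.partition("=")
                        meta[k] = v
        df = pd.read_csv(path, comment="#")
        times = np.sort(df["t_s"].unique())
        n = df["particle_id"].nunique()
        df = df.sort_values(["t_s", "particle_id"])
        pos = np.column_stack([df["x_um"].to_numpy(), df["y_um"].to_numpy()]) * 1e-6
        return cls(
            times=times,
            positions=pos.reshape(times.size, n, 2),
            seed=int(meta.get("seed", -1)),
            config_fingerprint=meta.get("fingerprint", ""),
            thermophoresis=meta.get("thermophoresis", "True") == "True",
        )

    def save_npz(self, path) -> None:
        np.savez(
            path,
            times=self.times,
            positions=self.positions,
            seed=np.int64(self.seed),
            config_fingerprint=np.str_(self.config_fingerprint),
            thermophoresis=np.bool_(self.thermophoresis),
        )

    @classmethod
    def load_npz(cls, path) -> "TrajectorySet":
        with np.load(path) as z:
            return cls(
                times=z["times"],
                positions=z["positions"],
                seed=int(z["seed"]),
                config_fingerprint=str(z["config_fingerprint"]),
                thermophoresis=bool(z["thermophoresis"]),
            )


def brownian_displacement(
    T_room: float,
    gamma: float,
    dt: float,
    stream: RNGStream,
    n: int = 1,
) -> np.ndarray:
    """(n, 2) Brownian displacements, each axis ~ N(0, 2 k_B T_room dt / gamma)."""
    if dt < 0 or gamma <= 0 or T_room <= 0:
        raise ValueError("require dt >= 0, gamma > 0, T_room > 0")
    if dt == 0:
        return np.zeros((n, 2))
    sigma = np.sqrt(2.0 * K_B * T_room * dt / gamma)
    zx, zy = stream.normal_pairs(n)
    return sigma * np.column_stack([zx, zy])


def thermophoretic_displacement(T, grad, dt: float, particle: ParticleModel) -> np.ndarray:
    """Deterministic drift -D_T(T) grad(T) dt (antiparallel to the gradient
    for thermophobic particles, D_T > 0)."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    grad = np.atleast_2d(np.asarray(grad, dtype=float))
    dt_mob = np.atleast_1d(interp_dt(T, particle.dt_table))
    return -dt_mob[:, None] * grad * dt


def thermophoretic_force(
    T,
    grad,
    particle: ParticleModel,
    fluid: FluidModel = DEFAULT_FLUID,
) -> np.ndarray:
    """Thermophoretic force -gamma(T) D_T(T) grad(T); magnitude
    gamma(T) D_T(T) |grad T| [N]."""
    grad = np.atleast_2d(np.asarray(grad, dtype=float))
    gam = np.atleast_1d(friction(T, particle.radius, fluid))
    dt_mob = np.atleast_1d(interp_dt(T, particle.dt_table))
    return -(gam * dt_mob)[:, None] * grad


def _reflect(pos: np.ndarray, half_width: float) -> np.ndarray:
    """Mirror positions back into the square [-hw, hw]^2 (a step crossing the
    wall by delta ends delta inside the wall)."""
    lo, hi = -half_width, half_width
    for _ in range(64):
        below = pos < lo
        above = pos > hi
        if not (below.any() or above.any()):
            return pos
        pos = np.where(below, 2 * lo - pos, pos)
        pos = np.where(above, 2 * hi - pos, pos)
    raise RuntimeError("reflection did not terminate; step much larger than domain")


def step(
    positions: np.ndarray,
    field: TemperatureField2D,
    config: SimulationConfig,
    particle: ParticleModel,
    stream: RNGStream,
    fluid: FluidModel = DEFAULT_FLUID,
    _gamma_room: float | None = None,
) -> np.ndarray:
    """Advance all particles by one time step; reflecting walls."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    T, grad = field.sample(pos)
    if config.local_temperature_noise:
        gam = friction(T, particle.radius, fluid)
        sigma = np.sqrt(2.0 * K_B * T * config.dt / gam)[:, None]
        zx, zy = stream.normal_pairs(n)
        disp = sigma * np.column_stack([zx, zy])
    else:
        gam = _gamma_room if _gamma_room is not None else friction(config.T_room, particle.radius, fluid)
        disp = brownian_displacement(config.T_room, gam, config.dt, stream, n)
    if config.thermophoresis_enabled:
        disp = disp + thermophoretic_displacement(T, grad, config.dt, particle)
    return _reflect(pos + disp, config.domain_half_width)


def _check_dt_stability(
    field: TemperatureField2D, config: SimulationConfig, particle: ParticleModel
) -> None:
    g_max = float(np.hypot(field.grad_x, field.grad_y).max())
    dt_max_mob = float(np.max(particle.dt_table[:, 1]))
    drift = dt_max_mob * g_max * config.dt
    cell = min(field.dx, field.dy)
    if drift > cell:
        warnings.warn(
            f"single-step thermophoretic drift ({drift:.2e} m) exceeds one field "
            f"cell ({cell:.2e} m); consider dt <= {config.dt * cell / drift:.3g} s",
            stacklevel=2,
        )


def run(
    config: SimulationConfig,
    field: TemperatureField2D,
    particle: ParticleModel,
    fluid: FluidModel = DEFAULT_FLUID,
) -> TrajectorySet:
    """Integrate ``config.n_particles`` non-interacting particles.

    Particles start uniformly at random in the init square; positions are
    recorded every ``record_interval``.  The same seed reproduces the same
    trajectory set bit for bit, and a thermophoresis-off control run with the
    same seed consumes the identical Brownian increment sequence.
    """
    if not field.contains_box(config.domain_half_width):
        raise ValueError("simulation domain extends beyond the temperature field")
    _check_dt_stability(field, config, particle)

    stream = RNGStream(config.seed)
    hw = config.init_half_width
    pos = hw * (2.0 * stream.uniform((config.n_particles, 2)) - 1.0)

    n_steps = int(round(config.duration / config.dt)) if config.duration > 0 else 0
    rec_every = max(1, int(round(config.record_interval / config.dt)))
    gamma_room = friction(config.T_room, particle.radius, fluid)

    frames = [pos.copy()]
    times = [0.0]
    for i in range(1, n_steps + 1):
        pos = step(pos, field, config, particle, stream, fluid, _gamma_room=gamma_room)
        if i % rec_every == 0:
            frames.append(pos.copy())
            times.append(i * config.dt)

    return TrajectorySet(
        times=np.asarray(times),
        positions=np.stack(frames),
        seed=config.seed,
        config_fingerprint=config.fingerprint(),
        thermophoresis=config.thermophoresis_enabled,
    )


def control_config(config: SimulationConfig) -> SimulationConfig:
    """Seed-matched Brownian-only twin of ``config``."""
    return replace(config, thermophoresis_enabled=False)
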