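"""Material and particle transport properties.

Closed-form models for the fluid (viscosity, Stokes friction, Stokes-Einstein
diffusion) and a tabulated, temperature-dependent thermophoretic mobility
D_T(T) for the suspended particle.

All functions accept scalars or numpy arrays for the temperature argument and
work in SI units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import K_B

__all__ = [
    "FluidModel",
    "ParticleModel",
    "DEFAULT_FLUID",
    "DEFAULT_DT_TABLE",
    "viscosity",
    "friction",
    "einstein_diffusion",
    "interp_dt",
    "soret_coefficient",
    "load_dt_table",
    "constant_soret_table",
]


@dataclass(frozen=True)
class FluidModel:
    """Arrhenius-type viscosity model mu(T) = A * exp(B / T) for water.

    The defaults approximate liquid water between roughly 273 and 370 K
    (mu(297 K) = 0.88 mPa s).
    """

    visc_prefactor: float = 2.761e-6  # A [Pa s]
    visc_activation: float = 1713.0  # B [K]

    def __post_init__(self) -> None:
        if self.visc_prefactor <= 0 or self.visc_activation <= 0:
            raise ValueError("viscosity model parameters must be positive")


DEFAULT_FLUID = FluidModel()

# Thermophoretic mobility of bare 500 nm polystyrene spheres in water,
# anchored at D_T(297 K) = 1.08e-12 m^2 K^-1 s^-1 with the weak positive
# temperature slope typical of aqueous polystyrene colloids.  Columns:
# T [K], D_T [m^2 K^-1 s^-1].  Replaceable via ParticleModel(dt_table=...).
DEFAULT_DT_TABLE = np.array(
    [
        [290.0, 0.94e-12],
        [297.0, 1.08e-12],
        [305.0, 1.24e-12],
        [313.0, 1.40e-12],
        [320.0, 1.54e-12],
    ]
)


def _validate_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("D_T table must have shape (n >= 2, 2): columns T, D_T")
    if np.any(np.diff(table[:, 0]) <= 0):
        raise ValueError("D_T table temperatures must be strictly increasing")
    return table


@dataclass(frozen=True, eq=False)
class ParticleModel:
    """A spherical particle: radius plus tabulated thermophoretic mobility."""

    radius: float = 250e-9  # [m]
    dt_table: np.ndarray = field(default_factory=lambda: DEFAULT_DT_TABLE.copy())

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")
        object.__setattr__(self, "dt_table", _validate_table(self.dt_table))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParticleModel):
            return NotImplemented
        return self.radius == other.radius and np.array_equal(self.dt_table, other.dt_table)

    def __hash__(self) -> int:
        return hash((self.radius, self.dt_table.tobytes()))


def viscosity(T, fluid: FluidModel = DEFAULT_FLUID):
    """Dynamic viscosity mu(T) [Pa s]; strictly decreasing in T."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    out = fluid.visc_prefactor * np.exp(fluid.visc_activation / T)
    return out if out.ndim else float(out)


def friction(T, radius: float, fluid: FluidModel = DEFAULT_FLUID):
    """Stokes drag coefficient gamma = 6 pi mu(T) a [kg/s]."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    return 6.0 * np.pi * viscosity(T, fluid) * radius


def einstein_diffusion(T, radius: float, fluid: FluidModel = DEFAULT_FLUID):
    """Stokes-Einstein diffusion coefficient D = k_B T / (6 pi mu a) [m^2/s]."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    T = np.asarray(T, dtype=float)
    out = K_B * T / friction(T, radius, fluid)
    return out if out.ndim else float(out)


def interp_dt(T, table: np.ndarray):
    """Thermophoretic mobility D_T(T) by linear interpolation of ``table``.

    Exact at table nodes; clamped to the end values outside the tabulated
    range (constant extrapolation avoids sign flips from short tables).
    """
    table = _validate_table(table)
    T = np.asarray(T, dtype=float)
    out = np.interp(T, table[:, 0], table[:, 1])
    return out if out.ndim else float(out)


def soret_coefficient(T, particle: ParticleModel, fluid: FluidModel = DEFAULT_FLUID):
    """Soret coefficient S_T(T) = D_T(T) / D(T) [1/K]."""
    return interp_dt(T, particle.dt_table) / einstein_diffusion(T, particle.radius, fluid)


def load_dt_table(path) -> np.ndarray:
    """Read a two-column D_T table (T_K, DT_m2_per_K_s); '#' starts a comment."""
    table = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    return _validate_table(table)


def constant_soret_table(
    s_t: float,
    radius: float,
    temperatures=None,
    fluid: FluidModel = DEFAULT_FLUID,
) -> np.ndarray:
    """Build a D_T(T) table realising a constant Soret coefficient.

    Samples D_T(T) = s_t * D(T) on ``temperatures`` (default 280..340 K every
    1 K) so that, up to the linear-interpolation error between nodes,
    S_T is independent of temperature.  Used by equilibrium cross-checks.
    """
    if temperatures is None:
        temperatures = np.arange(280.0, 341.0, 1.0)
    temperatures = np.asarray(temperatures, dtype=float)
    dts = s_t * einstein_diffusion(temperatures, radius, fluid)
    return np.column_stack([temperatures, dts])
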