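"""Steady-state heat conduction for the laser-heated sample chamber.

The chamber is a thin water layer sandwiched between two glass coverslips.
A focused near-infrared laser deposits heat in a cylindrical column of water
(diameter = beam FWHM, height = water thickness); the absorbed power follows
the Beer-Lambert law and is converted to a uniform volumetric source Q_V.

The temperature field obeys del . (k grad T) + Q = 0 with Q = Q_V inside the
heated cylinder and Q = 0 elsewhere, continuous temperature/flux at material
interfaces and ambient Dirichlet conditions on the outer surfaces.  Water
conductivity is temperature dependent, k(T) = k0 + k_slope (T - T_ref); the
resulting mild nonlinearity is resolved by Picard (fixed-point) iteration.

The geometry is rotationally symmetric, so the solve is performed in
axisymmetric (r, z) coordinates on a stretched cell-centred finite-volume
mesh (faces aligned with the source radius and the layer interfaces) and the
3D x-y mid-plane map is recovered by revolution.  Finite-volume discretisation
makes the discrete energy balance exact up to the linear-solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .field import TemperatureField2D

__all__ = [
    "ChamberGeometry",
    "LaserSource",
    "ThermalModel",
    "SolverSettings",
    "AxisymmetricSolution",
    "ConvergenceError",
    "absorbed_power",
    "volumetric_source",
    "solve_steady_temperature",
    "midplane_field",
]


class ConvergenceError(RuntimeError):
    """Raised when the Picard iteration fails to reach the tolerance."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Layered chamber: water film between two identical glass coverslips.

    The heated cylinder spans the full water thickness; its diameter is the
    laser-spot FWHM.  ``lateral_radius`` is the solver domain extent.
    """

    water_thickness: float = 8e-6  # [m]
    glass_thickness: float = 150e-6  # [m]
    source_diameter: float = 27.6e-6  # [m]
    lateral_radius: float = 300e-6  # [m]

    def __post_init__(self) -> None:
        for name in ("water_thickness", "glass_thickness", "source_diameter", "lateral_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.source_diameter / 2 >= self.lateral_radius:
            raise ValueError("source radius must be smaller than the lateral domain radius")

    @property
    def source_radius(self) -> float:
        return self.source_diameter / 2

    @property
    def source_volume(self) -> float:
        return math.pi * self.source_radius**2 * self.water_thickness


def absorbed_power(power_in: float, alpha: float, path: float) -> float:
    """Beer-Lambert absorbed power P_in (1 - exp(-alpha L)) [W]."""
    if power_in < 0 or alpha < 0 or path < 0:
        raise ValueError("power, absorption coefficient and path must be nonnegative")
    return power_in * -math.expm1(-alpha * path)


def volumetric_source(power_in: float, alpha: float, path: float, diameter: float) -> float:
    """Volumetric heat-source density Q_V [W/m^3].

    Absorbed power divided by the volume of the heated cylinder
    (pi (d/2)^2 L, with L the optical path = water thickness).
    """
    if diameter <= 0 or path <= 0:
        raise ValueError("diameter and path must be positive")
    return absorbed_power(power_in, alpha, path) / (math.pi * (diameter / 2) ** 2 * path)


@dataclass(frozen=True)
class LaserSource:
    """Laser heating parameters; ``q_v`` is derived via Beer-Lambert."""

    power_in: float  # [W]
    absorption_coeff: float = 967.0  # [1/m], water at 1560 nm
    path_length: float = 8e-6  # [m], = water thickness

    def __post_init__(self) -> None:
        if self.power_in < 0 or self.absorption_coeff < 0 or self.path_length <= 0:
            raise ValueError("invalid laser parameters")

    @property
    def absorbed(self) -> float:
        return absorbed_power(self.power_in, self.absorption_coeff, self.path_length)

    def q_v(self, geometry: ChamberGeometry) -> float:
        return volumetric_source(
            self.power_in, self.absorption_coeff, self.path_length, geometry.source_diameter
        )


@dataclass(frozen=True)
class ThermalModel:
    """Conductivities and boundary temperature.

    Water: k(T) = k0 + k_slope (T - T_ref).  Glass: constant ``k_glass``
    (borosilicate, 1.14 W/m/K by default).  The outer chamber surfaces are
    held at ``T_ambient``.
    """

    k0: float = 0.61  # [W/m/K]
    k_slope: float = 0.0012  # [W/m/K^2]
    T_ref: float = 298.0  # [K]
    k_glass: float = 1.14  # [W/m/K]
    T_ambient: float = 297.15  # [K] (24 C)

    def __post_init__(self) -> None:
        if self.T_ambient <= 0 or self.k_glass <= 0:
            raise ValueError("ambient temperature and glass conductivity must be positive")
        if self.k_water(self.T_ambient) <= 0:
            raise ValueError("water conductivity must be positive at ambient")

    def k_water(self, T):
        return self.k0 + self.k_slope * (np.asarray(T, dtype=float) - self.T_ref)


@dataclass(frozen=True)
class SolverSettings:
    """Mesh resolution and Picard-iteration controls.

    ``nr_source`` cells span the source radius (the fine uniform radial zone
    extends to 1.5x the source radius before geometric stretching takes
    over); ``nz_water`` (odd, so a cell centre sits exactly on the mid-plane)
    and ``nz_glass`` cells span the water layer and each coverslip.
    """

    nr_source: int = 40
    nz_water: int = 17
    nz_glass: int = 28
    r_growth: float = 1.08
    z_growth: float = 1.18
    tol: float = 1e-6  # [K], max nodal update
    max_iter: int = 100

    def __post_init__(self) -> None:
        if min(self.nr_source, self.nz_water, self.nz_glass) < 3:
            raise ValueError("need at least 3 cells per material layer")
        if self.nz_water % 2 == 0:
            raise ValueError("nz_water must be odd (mid-plane cell centre)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tolerance must be positive, max_iter >= 1")


def _geometric_edges(start: float, total: float, n: int, ratio: float) -> np.ndarray:
    """n cell widths growing by ``ratio``, rescaled to sum to ``total``."""
    w = ratio ** np.arange(n)
    w *= total / w.sum()
    return start + np.concatenate([[0.0], np.cumsum(w)])


def _radial_edges(geometry: ChamberGeometry, s: SolverSettings) -> np.ndarray:
    a = geometry.source_radius
    dr = a / s.nr_source
    n_inner = int(round(1.5 * s.nr_source))
    inner = np.linspace(0.0, 1.5 * a, n_inner + 1)
    remain = geometry.lateral_radius - 1.5 * a
    # choose outer cell count so the first stretched cell is ~dr wide
    n_outer = max(3, int(math.ceil(math.log1p(remain * (s.r_growth - 1) / (dr * s.r_growth)) / math.log(s.r_growth))))
    outer = _geometric_edges(1.5 * a, remain, n_outer, s.r_growth)
    return np.concatenate([inner, outer[1:]])


def _axial_edges(geometry: ChamberGeometry, s: SolverSettings) -> np.ndarray:
    h, t = geometry.water_thickness, geometry.glass_thickness
    water = np.linspace(-h / 2, h / 2, s.nz_water + 1)
    top = _geometric_edges(h / 2, t, s.nz_glass, s.z_growth)
    bottom = -top[::-1]
    return np.concatenate([bottom[:-1], water, top[1:]])


@dataclass
class AxisymmetricSolution:
    """Converged axisymmetric temperature solution on the (r, z) cell mesh."""

    r_edges: np.ndarray
    z_edges: np.ndarray
    T: np.ndarray  # [nr, nz] cell-centre temperatures [K]
    q_v: float
    geometry: ChamberGeometry
    thermal: ThermalModel
    n_iterations: int = 0
    boundary_flux: float = 0.0  # net conductive flux out through Dirichlet faces [W]

    r_centers: np.ndarray = dc_field(init=False)
    z_centers: np.ndarray = dc_field(init=False)

    def __post_init__(self) -> None:
        self.r_centers = 0.5 * (self.r_edges[:-1] + self.r_edges[1:])
        self.z_centers = 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def delta_t_max(self) -> float:
        """Maximum temperature rise above ambient [K]."""
        return float(self.T.max() - self.thermal.T_ambient)

    @property
    def source_power(self) -> float:
        return self.q_v * self.geometry.source_volume

    def energy_balance_error(self) -> float:
        """|boundary flux - source power| / source power (0 when unheated)."""
        if self.source_power == 0.0:
            return abs(self.boundary_flux)
        return abs(self.boundary_flux - self.source_power) / self.source_power

    def midplane_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, T(r)) on the water mid-plane z = 0."""
        j0 = int(np.argmin(np.abs(self.z_centers)))
        return self.r_centers.copy(), self.T[:, j0].copy()


def _assemble(
    re_: np.ndarray,
    ze: np.ndarray,
    k_cell: np.ndarray,
    source: np.ndarray,
    T_amb: float,
):
    """FV assembly: returns (A, b, dirichlet face conductances + cell index)."""
    nr, nz = k_cell.shape
    dr = np.diff(re_)
    dz = np.diff(ze)
    idx = np.arange(nr * nz).reshape(nr, nz)

    rows, cols, vals = [], [], []
    diag = np.zeros(nr * nz)
    b = source.astype(float).ravel().copy()

    def add_internal(i1, i2, G):
        rows.extend([i1.ravel(), i2.ravel(), i1.ravel(), i2.ravel()])
        cols.extend([i2.ravel(), i1.ravel(), i1.ravel(), i2.ravel()])
        vals.extend([-G.ravel(), -G.ravel(), G.ravel(), G.ravel()])

    # radial internal faces between cells (i, j) and (i+1, j)
    A_r = 2 * math.pi * re_[1:-1][:, None] * dz[None, :]
    res = (dr[:-1, None] / 2) / k_cell[:-1, :] + (dr[1:, None] / 2) / k_cell[1:, :]
    G_r = A_r / res
    add_internal(idx[:-1, :], idx[1:, :], G_r)

    # axial internal faces between (i, j) and (i, j+1)
    A_z = math.pi * (re_[1:] ** 2 - re_[:-1] ** 2)
    res = (dz[None, :-1] / 2) / k_cell[:, :-1] + (dz[None, 1:] / 2) / k_cell[:, 1:]
    G_z = A_z[:, None] / res
    add_internal(idx[:, :-1], idx[:, 1:], G_z)

    dir_cells = []
    dir_G = []

    # outer radial Dirichlet face (r = R); axis r = 0 is a symmetry face
    A_out = 2 * math.pi * re_[-1] * dz
    G_out = A_out / ((dr[-1] / 2) / k_cell[-1, :])
    dir_cells.append(idx[-1, :])
    dir_G.append(G_out)

    # bottom and top Dirichlet faces
    for j, half in ((0, dz[0] / 2), (nz - 1, dz[-1] / 2)):
        G_cap = A_z / (half / k_cell[:, j])
        dir_cells.append(idx[:, j])
        dir_G.append(G_cap)

    for cells, G in zip(dir_cells, dir_G):
        diag_add = np.zeros(nr * nz)
        np.add.at(diag_add, cells.ravel(), G.ravel())
        diag += diag_add
        bb = np.zeros(nr * nz)
        np.add.at(bb, cells.ravel(), (G * T_amb).ravel())
        b += bb

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    # internal-face contributions: off-diagonal -G, diagonal +G handled above
    A = sp.coo_matrix((vals, (rows, cols)), shape=(nr * nz, nr * nz)).tocsr()
    A = A + sp.diags(diag)
    return A, b, dir_cells, dir_G


def solve_steady_temperature(
    geometry: ChamberGeometry,
    thermal: ThermalModel,
    q_v: float,
    settings: SolverSettings | None = None,
) -> AxisymmetricSolution:
    """Solve the nonlinear steady conduction problem on the layered chamber.

    Picard iteration: conductivities are evaluated at the previous iterate's
    cell temperatures and the resulting linear finite-volume system solved by
    a sparse direct factorisation, until the maximum nodal update falls below
    ``settings.tol``.  Raises ``ConvergenceError`` (with the final residual)
    if the cap on iterations is reached.
    """
    if q_v < 0:
        raise ValueError("q_v must be nonnegative")
    s = settings or SolverSettings()
    re_ = _radial_edges(geometry, s)
    ze = _axial_edges(geometry, s)
    rc = 0.5 * (re_[:-1] + re_[1:])
    zc = 0.5 * (ze[:-1] + ze[1:])
    nr, nz = rc.size, zc.size

    water = np.abs(zc)[None, :] < geometry.water_thickness / 2
    water = np.broadcast_to(water, (nr, nz))
    in_source = water & (rc[:, None] < geometry.source_radius)

    vol = (math.pi * (re_[1:] ** 2 - re_[:-1] ** 2))[:, None] * np.diff(ze)[None, :]
    source = np.where(in_source, q_v, 0.0) * vol

    T = np.full((nr, nz), thermal.T_ambient)
    n_it = 0
    for n_it in range(1, s.max_iter + 1):
        k_cell = np.where(water, thermal.k_water(T), thermal.k_glass)
        if np.any(k_cell <= 0):
            raise ValueError("nonpositive conductivity encountered in the solved range")
        A, b, dir_cells, dir_G = _assemble(re_, ze, k_cell, source, thermal.T_ambient)
        T_new = spla.spsolve(A.tocsc(), b).reshape(nr, nz)
        resid = float(np.max(np.abs(T_new - T)))
        T = T_new
        if resid < s.tol:
            break
    else:
        raise ConvergenceError(
            f"Picard iteration did not converge in {s.max_iter} iterations; "
            f"last max temperature update {resid:.3e} K > tol {s.tol:.1e} K"
        )

    flux = 0.0
    for cells, G in zip(dir_cells, dir_G):
        flux += float(np.sum(G * (T.ravel()[cells.ravel()].reshape(G.shape) - thermal.T_ambient)))

    return AxisymmetricSolution(
        r_edges=re_,
        z_edges=ze,
        T=T,
        q_v=q_v,
        geometry=geometry,
        thermal=thermal,
        n_iterations=n_it,
        boundary_flux=flux,
    )


def midplane_field(
    solution: AxisymmetricSolution,
    half_width: float = 150e-6,
    spacing: float = 0.5e-6,
) -> TemperatureField2D:
    """Revolve the z = 0 radial profile onto a Cartesian x-y grid.

    Gradients are computed from the revolved temperature map by second-order
    central differences (one-sided at the edges) and stored on the nodes for
    later bilinear sampling.  Raises if the requested grid's corner radius
    exceeds the solved lateral extent.
    """
    if half_width <= 0 or spacing <= 0:
        raise ValueError("half_width and spacing must be positive")
    r, T_r = solution.midplane_profile()
    r_max = solution.r_edges[-1]
    if half_width * math.sqrt(2.0) > r_max:
        raise ValueError(
            f"requested grid corner radius {half_width * math.sqrt(2):.3e} m exceeds "
            f"solved radius {r_max:.3e} m"
        )
    # even extension through the axis: quadratic estimate of T(0)
    t0 = (T_r[0] * r[1] ** 2 - T_r[1] * r[0] ** 2) / (r[1] ** 2 - r[0] ** 2)
    r_ext = np.concatenate([[0.0], r, [r_max]])
    T_ext = np.concatenate([[t0], T_r, [solution.thermal.T_ambient]])

    n = int(round(half_width / spacing))
    ax = np.arange(-n, n + 1) * spacing
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    rho = np.hypot(xx, yy)
    T = np.interp(rho, r_ext, T_ext)
    return TemperatureField2D.from_temperature(ax, ax, T, ambient=thermal_ambient(solution))


def thermal_ambient(solution: AxisymmetricSolution) -> float:
    return solution.thermal.T_ambient
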