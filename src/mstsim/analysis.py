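"""Depletion analysis: radial concentration, Soret inversion, forces, MSD.

Turns trajectory sets into the quantities compared against dark-field
experiments: the radial concentration ratio c/c0 (thermophoretic run
normalised bin-by-bin by a Brownian-only control), the Soret coefficient and
thermophoretic mobility inverted from the exponential depletion law
c/c0 = exp(-S_T (T - T0)), the bin-averaged thermophoretic force magnitude,
and mean-squared-displacement curves for diffusion calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .field import TemperatureField2D
from .langevin import RNGStream, TrajectorySet, thermophoretic_force
from .transport import DEFAULT_FLUID, FluidModel, ParticleModel, einstein_diffusion

__all__ = [
    "RadialProfile",
    "ForceProfile",
    "default_radial_edges",
    "default_force_edges",
    "radial_concentration",
    "estimate_soret",
    "estimate_dt_from_soret",
    "equilibrium_profile_oracle",
    "force_profile",
    "msd",
]


def default_radial_edges() -> np.ndarray:
    """100 equal bins spanning 0-100 um."""
    return np.linspace(0.0, 100e-6, 101)


def default_force_edges() -> np.ndarray:
    """100 equal bins spanning 0-50 um."""
    return np.linspace(0.0, 50e-6, 101)


@dataclass
class RadialProfile:
    """Per-bin occupancies of the thermophoretic and control runs.

    ``ratio`` is NaN (undefined, never silently 0) where the reference bin
    is empty.
    """

    edges: np.ndarray
    counts_tph: np.ndarray
    counts_ref: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts_tph = np.asarray(self.counts_tph, dtype=float)
        self.counts_ref = np.asarray(self.counts_ref, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts_tph.shape != self.counts_ref.shape or self.counts_tph.size != self.edges.size - 1:
            raise ValueError("counts must have one entry per bin")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.counts_tph / self.counts_ref
        return np.where(self.counts_ref > 0, r, np.nan)

    def center_value(self, pool_bins: int = 1) -> float:
        """Ratio at the laser spot.

        ``pool_bins=1`` (default) returns the innermost bin with nonzero
        reference counts; ``pool_bins=n`` pools the innermost n bins before
        taking the ratio (more robust to small central occupancies — flagged
        to the caller by their own choice of n).
        """
        if pool_bins < 1:
            raise ValueError("pool_bins must be >= 1")
        if pool_bins > 1:
            tph = float(self.counts_tph[:pool_bins].sum())
            ref = float(self.counts_ref[:pool_bins].sum())
            if ref == 0:
                raise ValueError("no reference counts in the pooled central bins")
            return tph / ref
        defined = np.nonzero(self.counts_ref > 0)[0]
        if defined.size == 0:
            raise ValueError("reference run has no counts in any bin")
        i = defined[0]
        return float(self.counts_tph[i] / self.counts_ref[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_um": self.centers * 1e6,
                "counts_tph": self.counts_tph,
                "counts_ref": self.counts_ref,
                "ratio": self.ratio,
            }
        )

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class ForceProfile:
    """Bin-averaged |F_tph| [N] vs radius; NaN where a bin holds no samples."""

    edges: np.ndarray
    mean_force: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.mean_force = np.asarray(self.mean_force, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def peak(self) -> float:
        """Maximum bin-averaged force magnitude [N]."""
        return float(np.nanmax(self.mean_force))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_um": self.centers * 1e6,
                "mean_force_fN": self.mean_force * 1e15,
                "n_samples": self.n_samples,
            }
        )

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _radii_in_window(traj: TrajectorySet, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    sel = (traj.times >= t0) & (traj.times <= t1)
    if not sel.any():
        raise ValueError("averaging window contains no recorded frames")
    pos = traj.positions[sel]
    return np.hypot(pos[..., 0], pos[..., 1]).ravel()


def radial_concentration(
    traj_tph: TrajectorySet,
    traj_ref: TrajectorySet,
    edges: np.ndarray | None = None,
    window: tuple[float, float] = (600.0, 1200.0),
) -> RadialProfile:
    """Radial occupancy histograms and their ratio c/c0.

    Occupancies are accumulated over every recorded frame inside ``window``
    (equilibrium time-averaging); the ratio in bin i is N_i(tph) / N_i(ref).
    Both runs must share frame timing and particle count.
    """
    if traj_tph.n_particles != traj_ref.n_particles:
        raise ValueError("runs must have the same particle count")
    if traj_tph.n_frames != traj_ref.n_frames or not np.allclose(traj_tph.times, traj_ref.times):
        raise ValueError("runs must share recorded frame times")
    if edges is None:
        edges = default_radial_edges()
    w = (max(window[0], traj_tph.times[0]), min(window[1], traj_tph.times[-1]))
    counts_tph, _ = np.histogram(_radii_in_window(traj_tph, w), bins=edges)
    counts_ref, _ = np.histogram(_radii_in_window(traj_ref, w), bins=edges)
    return RadialProfile(edges=edges, counts_tph=counts_tph, counts_ref=counts_ref)


def estimate_soret(c_ratio: float, delta_T: float) -> float:
    """Invert the depletion law: S_T = -ln(c/c0) / (T - T0) [1/K].

    ``c_ratio`` > 1 (accumulation rather than depletion) yields a negative,
    thermophilic S_T and emits a warning.
    """
    if delta_T <= 0:
        raise ValueError("delta_T must be positive")
    if c_ratio <= 0:
        raise ValueError("concentration ratio must be positive")
    if c_ratio > 1:
        warnings.warn(
            "c/c0 > 1: accumulation at the hot spot; returning a negative "
            "(thermophilic) Soret coefficient",
            stacklevel=2,
        )
    return -float(np.log(c_ratio)) / float(delta_T)


def estimate_dt_from_soret(
    s_t: float,
    T: float,
    particle: ParticleModel,
    fluid: FluidModel = DEFAULT_FLUID,
) -> float:
    """Thermophoretic mobility D_T = S_T D(T) [m^2 K^-1 s^-1]."""
    return s_t * einstein_diffusion(T, particle.radius, fluid)


def equilibrium_profile_oracle(
    field: TemperatureField2D,
    s_t: float,
    radii: np.ndarray,
) -> np.ndarray:
    """Closed-form steady-state ratio exp(-S_T (T(r) - ambient)).

    Valid for a constant Soret coefficient; evaluated on the mid-plane
    radial temperature profile (sampled along +x).  Serves as the
    drift-diffusion steady-state oracle for long-time simulations.
    """
    radii = np.asarray(radii, dtype=float)
    pts = np.column_stack([radii, np.zeros_like(radii)])
    T, _ = field.sample(pts)
    return np.exp(-s_t * (T - field.ambient))


def force_profile(
    field: TemperatureField2D,
    particle: ParticleModel,
    n_particles: int = 3000,
    region_half_width: float = 25e-6,
    edges: np.ndarray | None = None,
    seed: int = 0,
    fluid: FluidModel = DEFAULT_FLUID,
) -> ForceProfile:
    """Bin-averaged thermophoretic force magnitude vs radius.

    Samples ``n_particles`` positions uniformly in the square of half-width
    ``region_half_width``, evaluates |F_tph| = gamma(T) D_T(T) |grad T| at
    each via bilinear field sampling, and averages within radial bins.
    Bins without samples are NaN.
    """
    if edges is None:
        edges = default_force_edges()
    edges = np.asarray(edges, dtype=float)
    stream = RNGStream(seed)
    pos = region_half_width * (2.0 * stream.uniform((n_particles, 2)) - 1.0)
    T, grad = field.sample(pos)
    f = thermophoretic_force(T, grad, particle, fluid)
    fmag = np.hypot(f[:, 0], f[:, 1])
    r = np.hypot(pos[:, 0], pos[:, 1])
    n, _ = np.histogram(r, bins=edges)
    fsum, _ = np.histogram(r, bins=edges, weights=fmag)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, fsum / np.maximum(n, 1), np.nan)
    return ForceProfile(edges=edges, mean_force=mean, n_samples=n)


def msd(traj: TrajectorySet, lags: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble- and time-averaged mean squared displacement.

    Returns (lag_times, msd) [s, m^2].  ``lags`` are frame-index lags;
    default 1..n_frames//4.
    """
    if lags is None:
        lags = np.arange(1, max(2, traj.n_frames // 4))
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= traj.n_frames):
        raise ValueError("lags must lie within the recorded range")
    dt_frame = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 0.0
    out = np.empty(lags.size)
    for k, lag in enumerate(lags):
        if lag == 0:
            out[k] = 0.0
            continue
        d = traj.positions[lag:] - traj.positions[:-lag]
        out[k] = float(np.mean(np.sum(d * d, axis=-1)))
    return lags * dt_frame, out
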