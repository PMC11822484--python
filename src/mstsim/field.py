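"""Gridded 2D temperature fields on the chamber mid-plane.

`TemperatureField2D` is the coupling object between the heat-conduction stage
and the particle stage: temperature and its precomputed gradient on a regular
Cartesian grid, sampled by bilinear (first-order) interpolation at particle
positions.

Fields are exchanged as delimited text (CSV with '#' header lines declaring
the axes and units) or as a bit-stable NumPy ``.npz`` container.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TemperatureField2D", "import_temperature_map"]

_SPACING_RTOL = 1e-9


def _check_axis(a: np.ndarray, name: str) -> float:
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError(f"{name} axis must be 1D with at least 2 points")
    d = np.diff(a)
    if np.any(d <= 0):
        raise ValueError(f"{name} axis must be strictly increasing")
    if not np.allclose(d, d[0], rtol=_SPACING_RTOL, atol=abs(d[0]) * _SPACING_RTOL):
        raise ValueError(f"{name} axis must be uniformly spaced")
    return float(d[0])


@dataclass
class TemperatureField2D:
    """Temperature [K] and gradient [K/m] on a regular (x, y) grid [m].

    Arrays are indexed ``T[ix, iy]`` ('ij' convention).
    """

    x: np.ndarray
    y: np.ndarray
    T: np.ndarray
    grad_x: np.ndarray
    grad_y: np.ndarray
    ambient: float = 297.15

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.grad_x = np.asarray(self.grad_x, dtype=float)
        self.grad_y = np.asarray(self.grad_y, dtype=float)
        self._dx = _check_axis(self.x, "x")
        self._dy = _check_axis(self.y, "y")
        shape = (self.x.size, self.y.size)
        for name in ("T", "grad_x", "grad_y"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_temperature(cls, x, y, T, ambient: float = 297.15) -> "TemperatureField2D":
        """Build a field from T alone; gradients by second-order central
        differences (one-sided at the edges)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        T = np.asarray(T, dtype=float)
        gx = np.gradient(T, x, axis=0)
        gy = np.gradient(T, y, axis=1)
        return cls(x=x, y=y, T=T, grad_x=gx, grad_y=gy, ambient=ambient)

    # -- geometry ----------------------------------------------------------

    @property
    def dx(self) -> float:
        return self._dx

    @property
    def dy(self) -> float:
        return self._dy

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        return float(self.x[0]), float(self.x[-1]), float(self.y[0]), float(self.y[-1])

    def contains_box(self, half_width: float, center=(0.0, 0.0)) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        cx, cy = center
        return (
            cx - half_width >= xmin
            and cx + half_width <= xmax
            and cy - half_width >= ymin
            and cy + half_width <= ymax
        )

    # -- sampling ----------------------------------------------------------

    def _locate(self, pos: np.ndarray):
        xmin, xmax, ymin, ymax = self.extent
        px, py = pos[..., 0], pos[..., 1]
        if np.any(px < xmin) or np.any(px > xmax) or np.any(py < ymin) or np.any(py > ymax):
            raise ValueError("position outside field bounds")
        tx = (px - xmin) / self._dx
        ty = (py - ymin) / self._dy
        ix = np.clip(tx.astype(np.intp), 0, self.x.size - 2)
        iy = np.clip(ty.astype(np.intp), 0, self.y.size - 2)
        return ix, iy, tx - ix, ty - iy

    def _bilinear(self, arr: np.ndarray, ix, iy, fx, fy):
        a00 = arr[ix, iy]
        a10 = arr[ix + 1, iy]
        a01 = arr[ix, iy + 1]
        a11 = arr[ix + 1, iy + 1]
        return (
            a00 * (1 - fx) * (1 - fy)
            + a10 * fx * (1 - fy)
            + a01 * (1 - fx) * fy
            + a11 * fx * fy
        )

    def sample(self, positions):
        """Bilinear T and gradient at ``positions`` (..., 2) [m].

        Returns ``(T, grad)`` with ``grad`` shaped (..., 2).  Exact at grid
        nodes.  Raises ``ValueError`` for out-of-bounds positions; the caller
        decides any fallback.
        """
        pos = np.asarray(positions, dtype=float)
        scalar = pos.ndim == 1
        pos = np.atleast_2d(pos)
        ix, iy, fx, fy = self._locate(pos)
        t = self._bilinear(self.T, ix, iy, fx, fy)
        gx = self._bilinear(self.grad_x, ix, iy, fx, fy)
        gy = self._bilinear(self.grad_y, ix, iy, fx, fy)
        grad = np.stack([gx, gy], axis=-1)
        if scalar:
            return float(t[0]), grad[0]
        return t, grad

    # -- IO ----------------------------------------------------------------

    def save_csv(self, path) -> None:
        nx, ny = self.x.size, self.y.size
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        df = pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "T": self.T.ravel(),
                "gx": self.grad_x.ravel(),
                "gy": self.grad_y.ravel(),
            }
        )
        header = io.StringIO()
        header.write("# mstsim temperature field\n")
        header.write("# units: m K K/m\n")
        header.write(f"# ambient_K: {self.ambient!r}\n")
        header.write(f"# nx: {nx}\n# ny: {ny}\n")
        with open(path, "w") as fh:
            fh.write(header.getvalue())
            df.to_csv(fh, index=False)

    @classmethod
    def load_csv(cls, path) -> "TemperatureField2D":
        return import_temperature_map(path)

    def save_npz(self, path) -> None:
        np.savez(
            path,
            x=self.x,
            y=self.y,
            T=self.T,
            grad_x=self.grad_x,
            grad_y=self.grad_y,
            ambient=np.float64(self.ambient),
        )

    @classmethod
    def load_npz(cls, path) -> "TemperatureField2D":
        with np.load(path) as z:
            return cls(
                x=z["x"],
                y=z["y"],
                T=z["T"],
                grad_x=z["grad_x"],
                grad_y=z["grad_y"],
                ambient=float(z["ambient"]),
            )


def _parse_header(path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def import_temperature_map(
    path,
    units: str = "K",
    length_units: str = "m",
    ambient: float | None = None,
) -> "TemperatureField2D":
    """Load an externally produced 2D temperature map from delimited text.

    The table must contain columns ``x, y, T`` (and optionally ``gx, gy``) on
    a full rectangular grid with strictly monotone axes; '#' lines at the top
    may declare metadata (``ambient_K``).  Temperatures may be in K or in
    degrees Celsius (``units='C'``); Celsius values are converted on load.
    If gradient columns are absent they are computed by central differences.
    Ragged or unsorted grids raise ``ValueError``.
    """
    meta = _parse_header(path)
    df = pd.read_csv(path, comment="#")
    required = {"x", "y", "T"}
    if not required.issubset(df.columns):
        raise ValueError(f"temperature map must have columns {sorted(required)}")
    scale = 1.0 if length_units == "m" else 1e-6 if length_units in ("um", "µm") else None
    if scale is None:
        raise ValueError(f"unsupported length units {length_units!r}")
    xs = np.unique(df["x"].to_numpy()) * scale
    ys = np.unique(df["y"].to_numpy()) * scale
    if xs.size * ys.size != len(df):
        raise ValueError("temperature map grid is ragged (not a full rectangle)")
    pivot = df.pivot(index="x", columns="y", values="T")
    T = pivot.to_numpy(dtype=float)
    if units.upper().startswith("C"):
        T = T + 273.15
    elif units.upper() != "K":
        raise ValueError(f"unsupported temperature units {units!r}")
    if ambient is None:
        ambient = float(meta.get("ambient_K", np.min(T)))
    if {"gx", "gy"}.issubset(df.columns):
        gx = df.pivot(index="x", columns="y", values="gx").to_numpy(dtype=float)
        gy = df.pivot(index="x", columns="y", values="gy").to_numpy(dtype=float)
        if units.upper().startswith("C") or scale != 1.0:
            # gradients are stored in K per length-unit; rescale length only
            gx = gx / scale
            gy = gy / scale
        return TemperatureField2D(x=xs, y=ys, T=T, grad_x=gx, grad_y=gy, ambient=ambient)
    return TemperatureField2D.from_temperature(xs, ys, T, ambient=ambient)
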