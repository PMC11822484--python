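"""Analytic temperature-field fixtures for testing and calibration.

Each family fills a `TemperatureField2D` with a closed-form temperature and
its *analytic* gradient on the nodes (rather than finite differences), so
oracle tests can compare sampled values against the generating formula
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import TemperatureField2D

__all__ = ["FixtureSpec", "make_fixture", "FAMILIES"]

FAMILIES = ("flat", "linear", "gaussian", "shell")


@dataclass(frozen=True)
class FixtureSpec:
    """Closed-form field family on a square grid.

    family:
      - ``flat``:     T = ambient
      - ``linear``:   T = ambient + amplitude * x / length_scale
      - ``gaussian``: T = ambient + amplitude * exp(-r^2 / (2 length_scale^2))
      - ``shell``:    T = ambient + amplitude inside r <= length_scale,
                      ambient + amplitude * length_scale / r outside (1/r tail)
    """

    family: str
    amplitude: float = 1.0  # [K]
    length_scale: float = 10e-6  # [m]
    half_width: float = 60e-6  # [m]
    spacing: float = 0.5e-6  # [m]
    ambient: float = 297.15  # [K]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown fixture family {self.family!r}; choose from {FAMILIES}")
        if self.length_scale <= 0 or self.half_width <= 0 or self.spacing <= 0:
            raise ValueError("length_scale, half_width and spacing must be positive")


def make_fixture(spec: FixtureSpec) -> TemperatureField2D:
    n = int(round(spec.half_width / spec.spacing))
    ax = np.arange(-n, n + 1) * spec.spacing
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    amb, A, L = spec.ambient, spec.amplitude, spec.length_scale

    if spec.family == "flat":
        T = np.full_like(xx, amb)
        gx = np.zeros_like(xx)
        gy = np.zeros_like(xx)
    elif spec.family == "linear":
        T = amb + A * xx / L
        gx = np.full_like(xx, A / L)
        gy = np.zeros_like(xx)
    elif spec.family == "gaussian":
        r2 = xx**2 + yy**2
        T = amb + A * np.exp(-r2 / (2 * L**2))
        pref = -(A / L**2) * np.exp(-r2 / (2 * L**2))
        gx = pref * xx
        gy = pref * yy
    else:  # shell: flat core, 1/r tail; |grad| = A L / r^2 outside the core
        r = np.hypot(xx, yy)
        outside = r > L
        with np.errstate(divide="ignore", invalid="ignore"):
            T = np.where(outside, amb + A * L / r, amb + A)
            pref = np.where(outside, -A * L / r**3, 0.0)
        pref = np.nan_to_num(pref)
        gx = pref * xx
        gy = pref * yy

    return TemperatureField2D(x=ax, y=ax, T=T, grad_x=gx, grad_y=gy, ambient=amb)
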