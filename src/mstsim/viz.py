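"""Static scatter-plot snapshots of particle configurations.

Convenience output mirroring the usual "particles around a laser spot"
panels; not used by any quantitative analysis.
"""

from __future__ import annotations

import numpy as np

from .langevin import TrajectorySet

__all__ = ["save_snapshot"]


def save_snapshot(traj: TrajectorySet, t: float, path, spot_radius: float | None = None) -> None:
    """Scatter the particle positions at the recorded frame nearest ``t``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = traj.frame_at(t) * 1e6
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pos[:, 0], pos[:, 1], s=4, c="k")
    if spot_radius is not None:
        theta = np.linspace(0, 2 * np.pi, 200)
        r = spot_radius * 1e6
        ax.plot(r * np.cos(theta), r * np.sin(theta), "r--", lw=0.8)
    ax.set_xlabel("x [um]")
    ax.set_ylabel("y [um]")
    ax.set_title(f"t = {t:g} s")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
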