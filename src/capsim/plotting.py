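"""Quick-look plots for domains, concentration frames and profiles."""

from __future__ import annotations

import numpy as np

from .engine import SimulationResult
from .geometry import CapsuleDomain
from .profiles import ClusterProfile

__all__ = ["plot_domain", "plot_frame", "plot_profiles"]


def _extent(grid):
    return (0, grid.side_length, 0, grid.side_length)


def plot_domain(domain: CapsuleDomain, ax=None, show_diffusivity=False):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = domain.diffusivity if show_diffusivity else domain.labels
    im = ax.imshow(np.asarray(data).T, origin="lower",
                   extent=_extent(domain.grid),
                   cmap="viridis" if show_diffusivity else "tab10",
                   interpolation="nearest")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.figure.colorbar(im, ax=ax,
                       label="D (µm²/s)" if show_diffusivity else "label")
    return ax


def plot_frame(result: SimulationResult, frame: int = -1, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(result.concentration[frame].T, origin="lower",
                   extent=_extent(result.domain.grid), cmap="inferno",
                   vmin=0, vmax=result.transport.C_inj)
    t = result.times_min[frame]
    ax.set_title(f"antibody concentration at t = {t:g} min")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.figure.colorbar(im, ax=ax, label="C (µg/mL)")
    return ax


def plot_profiles(profiles: list[ClusterProfile], ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for p in profiles:
        ax.plot(p.times, p.values, label=p.roi.id)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("normalized signal" if profiles and profiles[0].normalized
                  else "mean concentration (µg/mL)")
    ax.legend()
    return ax
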