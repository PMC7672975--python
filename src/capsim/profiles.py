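"""ROI time-profile extraction, normalization and arrival/slope metrics.

A cluster profile is the arithmetic mean of the concentration field over the
nodes of a circular region of interest, one value per recorded frame — the
computational analogue of a mean-fluorescence trace averaged over a cell
cluster cross-section.  Two scalar descriptors summarize such a trace:

* **delay time** — the first time the signal exceeds 5% of its maximum
  (linear interpolation between frames), a proxy for antibody arrival;
* **log-phase slope** — the OLS slope through the points lying between 15%
  and 85% of the maximum, the steepness of the rising phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import SimulationResult
from .exceptions import (
    DegenerateProfileError,
    GeometryError,
    InsufficientDataError,
)
from .geometry import GridSpec

__all__ = [
    "ROISpec",
    "ClusterProfile",
    "extract_profile",
    "normalize_profile",
    "delay_time",
    "log_phase_slope",
]


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest: id, center (µm) and radius (µm)."""

    id: str
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("ROI radius must be positive")

    def node_mask(self, grid: GridSpec) -> np.ndarray:
        x, y = grid.node_centers()
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 \
            <= self.radius**2


@dataclass(frozen=True)
class ClusterProfile:
    """Mean-signal time series for one ROI.

    ``area`` is the rasterized ROI area (member-node count times dx^2).
    """

    roi: ROISpec
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False
    area: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def extract_profile(result: SimulationResult, roi: ROISpec) -> ClusterProfile:
    """Mean concentration over the ROI disc, one value per frame."""
    mask = roi.node_mask(result.domain.grid)
    n_nodes = int(mask.sum())
    if n_nodes == 0:
        raise GeometryError(f"ROI {roi.id!r} contains no grid nodes")
    values = result.concentration[:, mask].mean(axis=1)
    area = n_nodes * result.domain.grid.dx**2
    return ClusterProfile(roi=roi, times=result.times_min.copy(),
                          values=values, area=area)


def normalize_profile(p: ClusterProfile) -> ClusterProfile:
    """Min-max normalize a profile to [0, 1]."""
    lo, hi = float(p.values.min()), float(p.values.max())
    if hi <= lo:
        raise DegenerateProfileError(
            f"profile {p.roi.id!r} is constant; cannot normalize"
        )
    return replace(p, values=(p.values - lo) / (hi - lo), normalized=True)


def delay_time(p: ClusterProfile, threshold_frac: float = 0.05) -> float:
    """First time the profile exceeds ``threshold_frac`` of its maximum.

    Linear interpolation between the bracketing frames; 0 if the profile is
    already above threshold at its first sample; NaN if it never crosses.
    """
    v = p.values
    if v.max() <= v.min():
        raise DegenerateProfileError("delay time of a constant profile is undefined")
    threshold = threshold_frac * float(v.max())
    above = v > threshold
    if above[0]:
        return 0.0
    if not above.any():
        return float("nan")
    k = int(np.argmax(above))
    t0, t1 = p.times[k - 1], p.times[k]
    v0, v1 = v[k - 1], v[k]
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def log_phase_slope(p: ClusterProfile,
                    band: tuple[float, float] = (0.15, 0.85)) -> float:
    """OLS slope (signal/min) through the points inside the log-phase band.

    The band is ``band`` times the profile maximum; at least 3 points must
    fall inside it.
    """
    v = p.values
    vmax = float(v.max())
    lo, hi = band[0] * vmax, band[1] * vmax
    sel = (v >= lo) & (v <= hi)
    if int(sel.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(sel.sum())} points inside the {band} band; need >= 3"
        )
    slope, _ = np.polyfit(p.times[sel], v[sel], 1)
    return float(slope)
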