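"""Capsule domain construction: grid, tumor-microenvironment elements, diffusivity.

The physical scene is a hydrogel (alginate) capsule immersed in culture
medium, discretized on a square mesh of equally spaced nodes.  Nodes are
labeled by the material they contain — exterior medium, capsule medium,
cancer-spheroid cells, fibroblasts or collagen fibers — and each node carries
an antibody diffusivity.  Collagen fibers are total transport barriers
(zero diffusivity); inside a cancer spheroid the diffusivity decreases
linearly toward the spheroid center, reflecting the denser packing of the
core:

    D(d) = D_cell_max * d / r_sph

where ``d`` is the distance of the node to the spheroid center and ``r_sph``
the spheroid radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .exceptions import (
    ConfigurationError,
    GeometryError,
    MaskFormatError,
    PlacementError,
)

__all__ = [
    "Label",
    "GridSpec",
    "TransportConfig",
    "PlacementConfig",
    "CapsuleDomain",
    "build_domain",
    "place_elements",
    "digitize",
    "init_diffusivity",
    "distance_to_periphery",
]


class Label(IntEnum):
    """Node material labels.  Values 2-4 match the labeled-mask convention."""

    EXTERIOR = 0
    MEDIUM = 1
    CANCER = 2
    FIBROBLAST = 3
    FIBER = 4


#: Pixel values accepted in labeled masks (0 doubles as background/medium).
_MASK_LABELED = {0, 2, 3, 4}
_MASK_BINARY = {0, 1}

#: Fiber orientations (degrees) to index-space unit steps.
_FIBER_STEPS = {
    0.0: (1, 0),
    45.0: (1, 1),
    90.0: (0, 1),
    135.0: (-1, 1),
}


@dataclass(frozen=True)
class GridSpec:
    """Square mesh holding the capsule disc.

    Parameters
    ----------
    nodes_per_side : int
        Number of equally spaced nodes along each side.
    side_length : float
        Physical side length in micrometers.
    capsule_radius : float
        Radius of the capsule disc in micrometers.
    capsule_center : tuple of float, optional
        Capsule center in micrometers; defaults to the mesh center.

    Node ``(i, j)`` has its center at ``((i + 0.5) dx, (j + 0.5) dx)``
    measured from the mesh corner, with ``dx = side_length / nodes_per_side``.
    """

    nodes_per_side: int = 200
    side_length: float = 1000.0
    capsule_radius: float = 350.0
    capsule_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.nodes_per_side < 2:
            raise ConfigurationError("nodes_per_side must be >= 2")
        if self.side_length <= 0:
            raise ConfigurationError("side_length must be positive")
        if not 0 <= self.capsule_radius <= self.side_length / 2:
            raise ConfigurationError(
                "capsule_radius must lie in [0, side_length/2], got "
                f"{self.capsule_radius}"
            )
        if self.capsule_center is None:
            c = self.side_length / 2.0
            object.__setattr__(self, "capsule_center", (c, c))

    @property
    def dx(self) -> float:
        """Node spacing in micrometers."""
        return self.side_length / self.nodes_per_side

    def node_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of node-center coordinates, 'ij' indexed."""
        coords = (np.arange(self.nodes_per_side) + 0.5) * self.dx
        return np.meshgrid(coords, coords, indexing="ij")

    def radius_map(self) -> np.ndarray:
        """Distance of every node center from the capsule center."""
        x, y = self.node_centers()
        cx, cy = self.capsule_center
        return np.hypot(x - cx, y - cy)


@dataclass(frozen=True)
class TransportConfig:
    """Transport constants of the experiment being emulated.

    ``D_medium`` is the antibody diffusivity in the hydrogel/medium
    (0.15 µm²/s), cellular diffusivity is ``D_medium / cell_ratio``
    (ratio 100, giving 0.0015 µm²/s), and the exterior bath is held at the
    injection concentration ``C_inj`` = 13 µg/mL.  ``interface_mode``
    selects how per-face diffusivities are formed from the two adjacent
    nodes; the harmonic mean makes zero-diffusivity fibers exact barriers.
    """

    D_medium: float = 0.15
    cell_ratio: float = 100.0
    C_inj: float = 13.0
    interface_mode: str = "harmonic"

    def __post_init__(self) -> None:
        if self.D_medium <= 0:
            raise ConfigurationError("D_medium must be positive")
        if self.cell_ratio <= 0:
            raise ConfigurationError("cell_ratio must be positive")
        if self.C_inj <= 0:
            raise ConfigurationError("C_inj must be positive")
        if self.interface_mode not in ("harmonic", "arithmetic"):
            raise ConfigurationError(
                f"interface_mode must be 'harmonic' or 'arithmetic', "
                f"got {self.interface_mode!r}"
            )

    @property
    def D_cell(self) -> float:
        return self.D_medium / self.cell_ratio


@dataclass(frozen=True)
class PlacementConfig:
    """Counts, sizes and spatial preferences of the stochastic capsule.

    Fibroblasts are placed either as single cells (radius 11.5 µm) or as
    small clusters (radius 17.5 µm), with a tunable preference for the
    outer ring of the capsule (the outermost ``outer_ring_fraction`` of the
    radius, 20% by default): each fibroblast center is drawn from the outer
    annulus with probability ``outer_ring_prob``, otherwise uniformly over
    the disc.  Collagen fibers are straight 30 µm segments at one of four
    orientations (0/45/90/135 degrees).  Placement uses rejection sampling
    against previously placed elements and is a deterministic function of
    ``seed``.
    """

    seed: int = 0
    n_spheroids: int = 1
    spheroid_radius: float = 50.0
    n_fibro_single: int = 30
    fibro_single_radius: float = 11.5
    n_fibro_cluster: int = 8
    fibro_cluster_radius: float = 17.5
    outer_ring_fraction: float = 0.2
    outer_ring_prob: float = 0.7
    n_fibers: int = 0
    fiber_length: float = 30.0
    fiber_orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        for name in ("spheroid_radius", "fibro_single_radius",
                     "fibro_cluster_radius", "fiber_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.outer_ring_fraction <= 1:
            raise ConfigurationError("outer_ring_fraction must be in (0, 1]")
        if not 0 <= self.outer_ring_prob <= 1:
            raise ConfigurationError("outer_ring_prob must be in [0, 1]")
        if len(self.fiber_orientations) == 0:
            raise ConfigurationError("fiber_orientations must be non-empty")
        for o in self.fiber_orientations:
            if float(o) not in _FIBER_STEPS:
                raise ConfigurationError(
                    f"unsupported fiber orientation {o}; "
                    "allowed: 0, 45, 90, 135 degrees"
                )
        if self.max_attempts < 1:
            raise ConfigurationError("max_attempts must be >= 1")


@dataclass
class CapsuleDomain:
    """Labeled capsule mesh with per-node diffusivity.

    Attributes
    ----------
    grid : GridSpec
    labels : ndarray of int8, shape (N, N)
        One :class:`Label` per node.
    diffusivity : ndarray of float or None
        Per-node antibody diffusivity (µm²/s); ``None`` until
        :func:`init_diffusivity` has run.
    spheroids : list of ((x, y), radius)
        Registered cancer spheroids, used for the radial diffusivity grade.
    elements : list of dict
        Geometric registry of every placed element (kind, center, radius or
        length/orientation) so a domain can be re-rasterized on another mesh.
    """

    grid: GridSpec
    labels: np.ndarray
    diffusivity: np.ndarray | None = None
    spheroids: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    elements: list[dict] = field(default_factory=list)
    seed: int | None = None

    def copy(self) -> "CapsuleDomain":
        return CapsuleDomain(
            grid=self.grid,
            labels=self.labels.copy(),
            diffusivity=None if self.diffusivity is None else self.diffusivity.copy(),
            spheroids=list(self.spheroids),
            elements=[dict(e) for e in self.elements],
            seed=self.seed,
        )

    @property
    def exterior_mask(self) -> np.ndarray:
        return self.labels == Label.EXTERIOR

    @property
    def cell_mask(self) -> np.ndarray:
        """Nodes that carry antibody binding sites (cancer + fibroblast)."""
        return (self.labels == Label.CANCER) | (self.labels == Label.FIBROBLAST)

    def count(self, label: Label) -> int:
        return int(np.count_nonzero(self.labels == label))


def build_domain(grid: GridSpec) -> CapsuleDomain:
    """Create a bare capsule domain: capsule disc MEDIUM, rest EXTERIOR.

    A node belongs to the capsule iff its center lies within
    ``capsule_radius`` of the capsule center.
    """
    r = grid.radius_map()
    labels = np.where(r <= grid.capsule_radius,
                      np.int8(Label.MEDIUM), np.int8(Label.EXTERIOR))
    return CapsuleDomain(grid=grid, labels=labels)


def _disc_nodes(grid: GridSpec, center: tuple[float, float], radius: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of nodes whose centers fall inside a disc."""
    dx = grid.dx
    n = grid.nodes_per_side
    cx, cy = center
    i_lo = max(int((cx - radius) / dx - 1), 0)
    i_hi = min(int((cx + radius) / dx + 2), n)
    j_lo = max(int((cy - radius) / dx - 1), 0)
    j_hi = min(int((cy + radius) / dx + 2), n)
    ii, jj = np.meshgrid(np.arange(i_lo, i_hi), np.arange(j_lo, j_hi),
                         indexing="ij")
    x = (ii + 0.5) * dx
    y = (jj + 0.5) * dx
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
    return ii[inside], jj[inside]


def _fiber_nodes(grid: GridSpec, center: tuple[float, float], length: float,
                 orientation: float) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a straight fiber as a 1-node-thick run of nodes.

    The fiber center is snapped to the nearest node center; the run steps by
    one node (axial orientations) or one diagonal node (45/135 degrees), with
    ``ceil(length / step)`` nodes so the rasterized span covers the physical
    length.
    """
    dx = grid.dx
    di, dj = _FIBER_STEPS[float(orientation)]
    step = dx * math.hypot(di, dj)
    n_nodes = max(int(math.ceil(length / step)), 1)
    ci = int(round(center[0] / dx - 0.5))
    cj = int(round(center[1] / dx - 0.5))
    offsets = np.arange(n_nodes) - n_nodes // 2
    ii = ci + offsets * di
    jj = cj + offsets * dj
    return ii, jj


def _sample_disc_center(rng: np.random.Generator, grid: GridSpec,
                        r_min: float, r_max: float) -> tuple[float, float]:
    """Area-uniform point in the annulus [r_min, r_max] around the capsule center."""
    rad = math.sqrt(rng.uniform(r_min**2, r_max**2))
    theta = rng.uniform(0.0, 2.0 * math.pi)
    cx, cy = grid.capsule_center
    return cx + rad * math.cos(theta), cy + rad * math.sin(theta)


def place_elements(domain: CapsuleDomain, cfg: PlacementConfig) -> CapsuleDomain:
    """Populate a bare domain with spheroids, fibroblasts and fibers.

    Elements are placed largest-first (spheroids, fibroblast clusters,
    single fibroblasts, fibers) by rejection sampling: a candidate is
    accepted only if every one of its nodes lies strictly inside the capsule
    disc and is still MEDIUM.  Raises :class:`PlacementError` when a class
    cannot be placed within ``cfg.max_attempts`` attempts.
    """
    if np.any((domain.labels != Label.MEDIUM) & (domain.labels != Label.EXTERIOR)):
        raise ConfigurationError("place_elements requires a bare MEDIUM/EXTERIOR domain")
    out = domain.copy()
    out.seed = cfg.seed
    rng = np.random.default_rng(cfg.seed)
    grid = out.grid
    R = grid.capsule_radius
    radii = grid.radius_map()

    def try_place(kind: str, node_fn, sampler, record: dict) -> None:
        for _ in range(cfg.max_attempts):
            center = sampler()
            ii, jj = node_fn(center)
            if len(np.atleast_1d(ii)) == 0:
                continue
            if np.any(ii < 0) or np.any(ii >= grid.nodes_per_side) \
                    or np.any(jj < 0) or np.any(jj >= grid.nodes_per_side):
                continue
            if np.any(radii[ii, jj] >= R):  # strict containment
                continue
            if np.any(out.labels[ii, jj] != Label.MEDIUM):
                continue
            out.labels[ii, jj] = record["label"]
            entry = dict(record)
            entry.pop("label")
            entry["kind"] = kind
            entry["center"] = (float(center[0]), float(center[1]))
            out.elements.append(entry)
            if kind == "spheroid":
                out.spheroids.append((entry["center"], record["radius"]))
            return
        raise PlacementError(
            f"could not place a {kind} within {cfg.max_attempts} attempts"
        )

    def disc_sampler(r_elem: float):
        r_max = max(R - r_elem, 0.0)
        return lambda: _sample_disc_center(rng, grid, 0.0, r_max)

    def fibro_sampler(r_elem: float):
        r_max = max(R - r_elem, 0.0)
        r_ring = min((1.0 - cfg.outer_ring_fraction) * R, r_max)

        def sample():
            if rng.uniform() < cfg.outer_ring_prob:
                return _sample_disc_center(rng, grid, r_ring, r_max)
            return _sample_disc_center(rng, grid, 0.0, r_max)

        return sample

    for _ in range(cfg.n_spheroids):
        r = cfg.spheroid_radius
        try_place("spheroid", lambda c: _disc_nodes(grid, c, r),
                  disc_sampler(r), {"label": Label.CANCER, "radius": r})
    for _ in range(cfg.n_fibro_cluster):
        r = cfg.fibro_cluster_radius
        try_place("fibro_cluster", lambda c: _disc_nodes(grid, c, r),
                  fibro_sampler(r), {"label": Label.FIBROBLAST, "radius": r})
    for _ in range(cfg.n_fibro_single):
        r = cfg.fibro_single_radius
        try_place("fibro_single", lambda c: _disc_nodes(grid, c, r),
                  fibro_sampler(r), {"label": Label.FIBROBLAST, "radius": r})
    for _ in range(cfg.n_fibers):
        length = cfg.fiber_length
        orientation = float(rng.choice(cfg.fiber_orientations))
        try_place("fiber",
                  lambda c, o=orientation: _fiber_nodes(grid, c, length, o),
                  disc_sampler(length / 2.0),
                  {"label": Label.FIBER, "length": length,
                   "orientation": orientation})
    return out


def rasterize_elements(grid: GridSpec, elements: list[dict],
                       seed: int | None = None) -> CapsuleDomain:
    """Re-rasterize a recorded element registry on a (possibly different) mesh.

    Used by the coarse-mesh calibration mode: the same physical geometry is
    painted onto a coarser grid.  Overlap checks are not repeated — the
    registry is assumed to come from a valid placement.
    """
    out = build_domain(grid)
    out.seed = seed
    order = {"spheroid": 0, "fibro_cluster": 1, "fibro_single": 2, "fiber": 3}
    for entry in sorted(elements, key=lambda e: order.get(e["kind"], 9)):
        kind = entry["kind"]
        center = tuple(entry["center"])
        if kind == "fiber":
            ii, jj = _fiber_nodes(grid, center, entry["length"],
                                  entry["orientation"])
            label = Label.FIBER
        else:
            ii, jj = _disc_nodes(grid, center, entry["radius"])
            label = Label.CANCER if kind == "spheroid" else Label.FIBROBLAST
        keep = (ii >= 0) & (ii < grid.nodes_per_side) \
            & (jj >= 0) & (jj < grid.nodes_per_side)
        out.labels[ii[keep], jj[keep]] = label
        out.elements.append(dict(entry))
        if kind == "spheroid":
            out.spheroids.append((center, entry["radius"]))
    return out


def digitize(mask: np.ndarray, grid: GridSpec,
             spheroid_spec: list[tuple[tuple[float, float], float]] | None = None,
             ) -> CapsuleDomain:
    """Build a domain from a labeled raster mask of a capsule cross-section.

    ``mask`` is a 2-D integer array whose pixel values follow the labeled
    convention (0 = background/medium, 2 = cancer, 3 = fibroblast,
    4 = fiber) or the binary convention (0 = background, 1 = cell, taken as
    fibroblast tissue).  The mask must be an integer multiple of the mesh
    resolution; each node takes the majority pixel label of its block (ties
    break toward the smallest label value).  Nodes outside the capsule disc
    are EXTERIOR regardless of the mask.  ``spheroid_spec`` entries — the
    manually added cancer spheroids — override node labels to CANCER and are
    registered for the radial diffusivity grade.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MaskFormatError(f"mask must be 2-D, got shape {mask.shape}")
    n = grid.nodes_per_side
    if mask.shape[0] % n or mask.shape[1] % n or mask.shape[0] != mask.shape[1]:
        raise MaskFormatError(
            f"mask shape {mask.shape} is not a square integer multiple of the "
            f"{n}x{n} mesh"
        )
    values = set(np.unique(mask).tolist())
    if values <= _MASK_BINARY:
        value_map = {0: Label.MEDIUM, 1: Label.FIBROBLAST}
    elif values <= _MASK_LABELED:
        value_map = {0: Label.MEDIUM, 2: Label.CANCER,
                     3: Label.FIBROBLAST, 4: Label.FIBER}
    else:
        raise MaskFormatError(
            f"mask contains unknown pixel values {sorted(values - _MASK_LABELED - _MASK_BINARY)}"
        )

    f = mask.shape[0] // n
    blocks = mask.reshape(n, f, n, f).transpose(0, 2, 1, 3).reshape(n, n, f * f)
    keys = sorted(value_map)
    counts = np.stack([(blocks == v).sum(axis=-1) for v in keys])
    majority = np.asarray(keys)[np.argmax(counts, axis=0)]

    labels = np.empty((n, n), dtype=np.int8)
    for v, lab in value_map.items():
        labels[majority == v] = lab
    outside = grid.radius_map() > grid.capsule_radius
    labels[outside] = Label.EXTERIOR

    domain = CapsuleDomain(grid=grid, labels=labels)
    for center, radius in (spheroid_spec or []):
        ii, jj = _disc_nodes(grid, tuple(center), radius)
        keep = ~outside[ii, jj]
        domain.labels[ii[keep], jj[keep]] = Label.CANCER
        domain.spheroids.append((tuple(float(c) for c in center), float(radius)))
        domain.elements.append({"kind": "spheroid",
                                "center": tuple(float(c) for c in center),
                                "radius": float(radius)})
    if not np.any((domain.labels == Label.CANCER)
                  | (domain.labels == Label.FIBROBLAST)
                  | (domain.labels == Label.FIBER)):
        warnings.warn("digitized mask contains no cells or fibers",
                      stacklevel=2)
    return domain


def init_diffusivity(domain: CapsuleDomain, cfg: TransportConfig,
                     grade_clusters: bool = False) -> CapsuleDomain:
    """Assign the initial per-node diffusivity field.

    MEDIUM and EXTERIOR nodes get ``D_medium``; fibroblasts get
    ``D_cell = D_medium / cell_ratio``; fibers get 0.  Cancer nodes inside a
    registered spheroid follow the linear radial grade
    ``D_cell * d / r_sph``; cancer nodes outside any registered spheroid get
    the full ``D_cell``.  With ``grade_clusters=True`` the radial grade is
    also applied inside fibroblast clusters.
    """
    out = domain.copy()
    D = np.full(out.labels.shape, cfg.D_medium, dtype=np.float64)
    D[out.labels == Label.FIBROBLAST] = cfg.D_cell
    D[out.labels == Label.CANCER] = cfg.D_cell
    D[out.labels == Label.FIBER] = 0.0

    x, y = out.grid.node_centers()

    def grade(center, radius, member_label):
        ii, jj = _disc_nodes(out.grid, center, radius)
        sel = out.labels[ii, jj] == member_label
        ii, jj = ii[sel], jj[sel]
        d = np.hypot(x[ii, jj] - center[0], y[ii, jj] - center[1])
        D[ii, jj] = cfg.D_cell * d / radius

    for center, radius in out.spheroids:
        grade(center, radius, Label.CANCER)
    if grade_clusters:
        for entry in out.elements:
            if entry["kind"] == "fibro_cluster":
                grade(entry["center"], entry["radius"], Label.FIBROBLAST)

    out.diffusivity = D
    return out


def distance_to_periphery(domain: CapsuleDomain,
                          roi_center: tuple[float, float]) -> float:
    """Distance (µm) from a point inside the capsule to the capsule boundary."""
    cx, cy = domain.grid.capsule_center
    d = math.hypot(roi_center[0] - cx, roi_center[1] - cy)
    if d > domain.grid.capsule_radius:
        raise GeometryError(
            f"point {roi_center} lies outside the capsule "
            f"(distance {d:.1f} > radius {domain.grid.capsule_radius})"
        )
    return domain.grid.capsule_radius - d
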