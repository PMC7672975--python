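"""Synthetic data generation: noisy sigmoid traces, pseudo-experiments, masks.

The reference light-sheet movies behind this framework are not publicly
deposited, so every test input is generated here: Richards-curve traces
with known parameters, full pseudo-experiments (simulator output for a
seeded capsule with known ground-truth saturation parameters plus
multiplicative Gaussian noise emulating fluorescence fluctuation), and
rendered label masks for digitization round-trips.  A
:class:`FixtureManifest` records everything needed — seed, hidden truth,
geometry — to regenerate a fixture byte-identically; the hidden truth is
stored only in the manifest, never in the emitted profile CSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SaturationParams, SimulationConfig, run_simulation
from .exceptions import ConfigurationError
from .geometry import (
    CapsuleDomain,
    GridSpec,
    Label,
    PlacementConfig,
    TransportConfig,
    build_domain,
    init_diffusivity,
    place_elements,
)
from .growth import richards_curve
from .profiles import ClusterProfile, ROISpec, extract_profile

__all__ = ["FixtureManifest", "make_richards_profile",
           "make_pseudo_experiment", "render_mask"]

_NOISE_STREAM = 104729  # seed offset separating noise from placement RNG


@dataclass
class FixtureManifest:
    """Reproducibility record for a pseudo-experimental fixture."""

    seed: int
    true_saturation: dict
    noise_sigma: float
    grid: dict
    placement: dict
    transport: dict
    simulation: dict
    rois: list
    files: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "FixtureManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))


def make_richards_profile(M: float, beta: float, gamma: float, P0: float,
                          times, noise_sigma: float = 0.0,
                          seed: int | None = None,
                          roi_id: str = "synthetic") -> ClusterProfile:
    """Sample a Richards curve with multiplicative Gaussian noise.

    values = P(t) * (1 + eps_t), eps_t ~ N(0, noise_sigma), clipped at 0;
    deterministic for a given seed.
    """
    if M <= 0 or beta <= 0 or gamma <= 0 or P0 <= 0 or noise_sigma < 0:
        raise ConfigurationError(
            "require M, beta, gamma, P0 > 0 and noise_sigma >= 0"
        )
    times = np.asarray(times, dtype=float)
    clean = richards_curve(times, M, beta, gamma, P0, t0=float(times[0]))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean * (1.0 + rng.normal(0.0, noise_sigma, size=clean.shape))
    values = np.clip(clean, 0.0, None)
    roi = ROISpec(roi_id, (0.0, 0.0), 1.0)
    return ClusterProfile(roi=roi, times=times, values=values)


def apply_noise(values: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Multiplicative Gaussian noise, clipped at zero, seeded."""
    if sigma == 0:
        return np.asarray(values, dtype=float).copy()
    rng = np.random.default_rng(seed)
    noisy = values * (1.0 + rng.normal(0.0, sigma, size=np.shape(values)))
    return np.clip(noisy, 0.0, None)


def make_pseudo_experiment(placement_cfg: PlacementConfig,
                           transport_cfg: TransportConfig,
                           true_sat: SaturationParams,
                           rois: list[ROISpec],
                           noise_sigma: float = 0.02,
                           seed: int = 0,
                           grid: GridSpec | None = None,
                           sim_config: SimulationConfig | None = None,
                           out_dir=None,
                           ) -> tuple[pd.DataFrame, FixtureManifest, CapsuleDomain]:
    """Generate a pseudo-experimental profile set with hidden ground truth.

    Builds a seeded stochastic capsule, runs the forward model with
    ``true_sat``, extracts the requested ROI profiles and perturbs each with
    multiplicative noise.  Returns the long-format profile table
    (roi_id, time_min, value), the manifest, and the domain used.  When
    ``out_dir`` is given, writes ``profiles.csv`` and ``manifest.yaml``.
    """
    grid = grid or GridSpec()
    sim_config = sim_config or SimulationConfig(store_diffusivity=False)
    domain = place_elements(build_domain(grid), placement_cfg)
    domain = init_diffusivity(domain, transport_cfg)
    result = run_simulation(domain, sim_config, true_sat, transport_cfg)

    frames = []
    for k, roi in enumerate(rois):
        profile = extract_profile(result, roi)
        noisy = apply_noise(profile.values, noise_sigma,
                            seed + _NOISE_STREAM + k)
        frames.append(pd.DataFrame({"roi_id": roi.id,
                                    "time_min": profile.times,
                                    "value": noisy}))
    table = pd.concat(frames, ignore_index=True)

    manifest = FixtureManifest(
        seed=int(seed),
        true_saturation={"a": true_sat.a, "n": true_sat.n, "p": true_sat.p,
                         "saturation_fraction": true_sat.saturation_fraction,
                         "dt_ref": true_sat.dt_ref},
        noise_sigma=float(noise_sigma),
        grid={"nodes_per_side": grid.nodes_per_side,
              "side_length": grid.side_length,
              "capsule_radius": grid.capsule_radius,
              "capsule_center": list(grid.capsule_center)},
        placement={f.name: getattr(placement_cfg, f.name)
                   if not isinstance(getattr(placement_cfg, f.name), tuple)
                   else list(getattr(placement_cfg, f.name))
                   for f in dataclasses.fields(placement_cfg)},
        transport={"D_medium": transport_cfg.D_medium,
                   "cell_ratio": transport_cfg.cell_ratio,
                   "C_inj": transport_cfg.C_inj,
                   "interface_mode": transport_cfg.interface_mode},
        simulation={"total_time_min": sim_config.total_time_min,
                    "frame_interval_min": sim_config.frame_interval_min},
        rois=[{"id": r.id, "center": list(r.center), "radius": r.radius}
              for r in rois],
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / "profiles.csv"
        table.to_csv(csv_path, index=False, float_format="%.10g")
        manifest.files["profiles"] = csv_path.name
        manifest.to_yaml(out_dir / "manifest.yaml")
    return table, manifest, domain


def regenerate(manifest: FixtureManifest, out_dir=None):
    """Rebuild a fixture from its manifest (bitwise-reproducible CSVs)."""
    grid = GridSpec(nodes_per_side=manifest.grid["nodes_per_side"],
                    side_length=manifest.grid["side_length"],
                    capsule_radius=manifest.grid["capsule_radius"],
                    capsule_center=tuple(manifest.grid["capsule_center"]))
    pl = dict(manifest.placement)
    pl["fiber_orientations"] = tuple(pl["fiber_orientations"])
    placement = PlacementConfig(**pl)
    transport = TransportConfig(**manifest.transport)
    sat = SaturationParams(**manifest.true_saturation)
    sim = SimulationConfig(store_diffusivity=False, **manifest.simulation)
    rois = [ROISpec(r["id"], tuple(r["center"]), r["radius"])
            for r in manifest.rois]
    return make_pseudo_experiment(placement, transport, sat, rois,
                                  noise_sigma=manifest.noise_sigma,
                                  seed=manifest.seed, grid=grid,
                                  sim_config=sim, out_dir=out_dir)


def make_fiber_scenario(grid: GridSpec | None = None,
                        transport: TransportConfig | None = None
                        ) -> tuple[CapsuleDomain, CapsuleDomain, dict]:
    """Paired capsules identical except for collagen fibers.

    Three fibroblast clusters are placed deterministically: one near the
    periphery (unshielded), one at the capsule center enclosed by a closed
    square loop of fiber nodes (total barrier), and one at intermediate
    depth partially shielded by a single fiber segment perpendicular to the
    radial inflow direction.  Returns (no-fiber domain, fiber domain,
    {"cluster1": ROISpec, "cluster2": ..., "cluster3": ...}); both domains
    have initialized diffusivity.
    """
    from .geometry import Label as L
    from .geometry import _disc_nodes, _fiber_nodes

    grid = grid or GridSpec()
    transport = transport or TransportConfig()
    cx, cy = grid.capsule_center
    R = grid.capsule_radius
    r_cl = 17.5
    centers = {
        "cluster1": (cx, cy + R - 1.5 * r_cl),  # peripheral
        "cluster2": (cx, cy - 0.75 * R),        # enclosed by fiber loop
        "cluster3": (cx + 0.75 * R, cy),        # partially shielded
    }
    base = build_domain(grid)
    rmap = grid.radius_map()
    for center in centers.values():
        ii, jj = _disc_nodes(grid, center, r_cl)
        keep = rmap[ii, jj] < R
        base.labels[ii[keep], jj[keep]] = L.FIBROBLAST
        base.elements.append({"kind": "fibro_cluster", "center": center,
                              "radius": r_cl})

    fibered = base.copy()
    dx = grid.dx
    # closed square loop around cluster2, 2 cluster radii half-width
    half = int(round(2.0 * r_cl / dx))
    c2 = centers["cluster2"]
    ci = int(round(c2[0] / dx - 0.5))
    cj = int(round(c2[1] / dx - 0.5))
    fibered.labels[ci - half:ci + half + 1, cj - half] = L.FIBER
    fibered.labels[ci - half:ci + half + 1, cj + half] = L.FIBER
    fibered.labels[ci - half, cj - half:cj + half + 1] = L.FIBER
    fibered.labels[ci + half, cj - half:cj + half + 1] = L.FIBER
    fibered.elements.append({"kind": "fiber_loop",
                             "center": c2,
                             "half_width": half * dx})
    # single perpendicular (vertical) fiber midway between cluster3 and the
    # periphery, blocking the radial inflow direction
    fiber_center = (cx + 0.875 * R, cy)
    ii, jj = _fiber_nodes(grid, fiber_center, 6.0 * r_cl, 90.0)
    keep = rmap[ii, jj] < R
    fibered.labels[ii[keep], jj[keep]] = L.FIBER
    fibered.elements.append({"kind": "fiber", "center": fiber_center,
                             "length": 6.0 * r_cl, "orientation": 90.0})

    rois = {name: ROISpec(name, center, r_cl)
            for name, center in centers.items()}
    return (init_diffusivity(base, transport),
            init_diffusivity(fibered, transport), rois)


def render_mask(domain: CapsuleDomain, upscale: int = 1) -> np.ndarray:
    """Render a domain as a labeled raster (inverse of digitization).

    Each node becomes an ``upscale x upscale`` pixel block carrying the
    node's mask value: 0 for medium/exterior background, 2/3/4 for
    cancer/fibroblast/fiber.
    """
    if upscale < 1:
        raise ConfigurationError("upscale must be >= 1")
    mask = domain.labels.astype(np.uint8).copy()
    mask[(mask == Label.MEDIUM) | (mask == Label.EXTERIOR)] = 0
    return np.kron(mask, np.ones((upscale, upscale), dtype=np.uint8))
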