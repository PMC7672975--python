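"""File formats: run configs (YAML), CSV tables, label masks, frame stacks."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .engine import SaturationParams, SimulationConfig, SimulationResult
from .exceptions import ConfigurationError, MaskFormatError
from .geometry import CapsuleDomain, GridSpec, PlacementConfig, TransportConfig
from .profiles import ClusterProfile, ROISpec

CONFIG_VERSION = 1

__all__ = [
    "load_run_config", "save_domain", "read_mask", "write_mask",
    "save_frames", "profiles_to_csv", "profiles_from_csv", "rois_from_config",
]


def _build_section(cls, data: dict, section: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(f"[{section}] {exc}") from exc


def load_run_config(path) -> dict:
    """Parse and validate a YAML run config into typed config objects.

    Returns a dict with keys grid, transport, saturation, simulation, and
    exactly one of placement / mask, plus rois (list of ROISpec) and seed.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    known = {"version", "seed", "grid", "transport", "saturation",
             "simulation", "placement", "mask", "rois"}
    for key in raw:
        if key not in known:
            raise ConfigurationError(f"unknown config key {key!r}")
    if "placement" in raw and "mask" in raw:
        raise ConfigurationError(
            "config must supply exactly one of 'placement' or 'mask'"
        )

    out: dict = {"version": raw.get("version", CONFIG_VERSION),
                 "seed": int(raw.get("seed", 0))}
    grid_raw = dict(raw.get("grid", {}))
    if "capsule_center" in grid_raw and grid_raw["capsule_center"] is not None:
        grid_raw["capsule_center"] = tuple(grid_raw["capsule_center"])
    out["grid"] = _build_section(GridSpec, grid_raw, "grid")
    out["transport"] = _build_section(TransportConfig,
                                      dict(raw.get("transport", {})),
                                      "transport")
    out["saturation"] = _build_section(SaturationParams,
                                       dict(raw.get("saturation", {})),
                                       "saturation")
    out["simulation"] = _build_section(SimulationConfig,
                                       dict(raw.get("simulation", {})),
                                       "simulation")
    if "mask" in raw:
        out["mask"] = dict(raw["mask"])
        if "path" not in out["mask"]:
            raise ConfigurationError("[mask] requires a 'path' key")
    else:
        pl = dict(raw.get("placement", {}))
        pl.setdefault("seed", out["seed"])
        if "fiber_orientations" in pl:
            pl["fiber_orientations"] = tuple(
                float(o) for o in pl["fiber_orientations"])
        out["placement"] = _build_section(PlacementConfig, pl, "placement")
    out["rois"] = [ROISpec(str(r["id"]), tuple(r["center"]), float(r["radius"]))
                   for r in raw.get("rois", [])]
    return out


def save_domain(domain: CapsuleDomain, out_dir) -> None:
    """Export a domain: labels CSV, diffusivity CSV, geometry manifest YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "labels.csv", domain.labels, fmt="%d", delimiter=",")
    if domain.diffusivity is not None:
        np.savetxt(out_dir / "diffusivity.csv", domain.diffusivity,
                   fmt="%.10g", delimiter=",")
    g = domain.grid
    manifest = {
        "nodes_per_side": g.nodes_per_side,
        "side_length_um": g.side_length,
        "capsule_radius_um": g.capsule_radius,
        "capsule_center_um": list(g.capsule_center),
        "seed": domain.seed,
        "elements": [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in e.items()}
            for e in domain.elements
        ],
    }
    (out_dir / "domain.yaml").write_text(yaml.safe_dump(manifest,
                                                        sort_keys=False))


def write_mask(mask: np.ndarray, path, um_per_pixel: float,
               grid: GridSpec | None = None) -> None:
    """Write a label mask (PNG or TIFF) plus its geometry sidecar YAML."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.astype(np.uint8))
    else:
        iio.imwrite(path, mask.astype(np.uint8))
    sidecar = {"um_per_pixel": float(um_per_pixel)}
    if grid is not None:
        sidecar["capsule_center_um"] = list(grid.capsule_center)
        sidecar["capsule_radius_um"] = float(grid.capsule_radius)
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_mask(path) -> np.ndarray:
    """Read a single-channel label mask image as an integer array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        mask = tifffile.imread(path)
    else:
        mask = iio.imread(path)
    mask = np.asarray(mask)
    if mask.ndim == 3:
        if not np.all(mask[..., 0] == mask[..., -1]):
            raise MaskFormatError("mask must be single-channel")
        mask = mask[..., 0]
    return mask.astype(np.int64)


def save_frames(result: SimulationResult, out_dir,
                tiff: bool = True, csv: bool = False) -> None:
    """Write the concentration stack (multi-page float32 TIFF and/or CSVs)
    plus a frame-times manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if tiff:
        tifffile.imwrite(out_dir / "concentration.tiff",
                         result.concentration.astype(np.float32))
        if result.diffusivity_frames is not None:
            tifffile.imwrite(out_dir / "diffusivity.tiff",
                             result.diffusivity_frames.astype(np.float32))
    if csv:
        for k, t in enumerate(result.times_min):
            np.savetxt(out_dir / f"frame_{k:04d}.csv",
                       result.concentration[k], fmt="%.8g", delimiter=",")
    pd.DataFrame({"frame": np.arange(result.n_frames),
                  "time_min": result.times_min}
                 ).to_csv(out_dir / "times.csv", index=False)


def profiles_to_csv(profiles: list[ClusterProfile], path) -> None:
    """Long-format profile CSV: roi_id, time_min, value."""
    frames = [pd.DataFrame({"roi_id": p.roi.id, "time_min": p.times,
                            "value": p.values}) for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")


def profiles_from_csv(path, rois: dict[str, ROISpec] | None = None
                      ) -> dict[str, ClusterProfile]:
    """Read a long-format profile CSV into per-ROI profiles."""
    table = pd.read_csv(path)
    required = {"roi_id", "time_min", "value"}
    if not required <= set(table.columns):
        raise ConfigurationError(
            f"profile CSV must have columns {sorted(required)}"
        )
    out = {}
    for roi_id, group in table.groupby("roi_id", sort=False):
        roi = (rois or {}).get(str(roi_id)) \
            or ROISpec(str(roi_id), (0.0, 0.0), 1.0)
        group = group.sort_values("time_min")
        out[str(roi_id)] = ClusterProfile(
            roi=roi, times=group["time_min"].to_numpy(),
            values=group["value"].to_numpy())
    return out
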