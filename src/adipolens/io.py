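"""Reading and writing run artifacts.

Volumes (fluence grids and cell masks) are multi-page TIFF stacks with z as
the page axis, so they open directly in standard image tools; each carries a
JSON sidecar (``<file>.json``) with the voxel pitch, origin and bookkeeping.
Scenes are JSON; spots and profiles are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .analysis import AxialProfile, FocalSpot
from .scene import VoxelMask
from .tracer import FluenceGrid, TraceSummary

__all__ = [
    "write_fluence", "read_fluence",
    "write_mask", "read_mask",
    "write_spots_csv", "read_spots_csv",
    "write_profile_csv", "read_profile_csv",
    "write_summary",
]


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_fluence(grid: FluenceGrid, path) -> None:
    """32-bit float TIFF stack (pages = z, rows = y, cols = x) + sidecar."""
    data = np.ascontiguousarray(grid.values.astype(np.float32).transpose(2, 1, 0))
    tifffile.imwrite(path, data)
    _sidecar(path).write_text(json.dumps({
        "pitch_um": grid.pitch,
        "origin_um": list(map(float, grid.origin)),
        "rays_launched": grid.rays_launched,
        "axis_order": "pages=z, rows=y, cols=x",
    }, indent=1))


def read_fluence(path) -> FluenceGrid:
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path)
    return FluenceGrid(values=np.ascontiguousarray(data.transpose(2, 1, 0)),
                       pitch=meta["pitch_um"],
                       origin=np.array(meta["origin_um"]),
                       rays_launched=meta["rays_launched"])


def write_mask(mask: VoxelMask, path) -> None:
    """8-bit TIFF stack (nonzero = cell interior) + sidecar."""
    data = np.ascontiguousarray(
        (mask.occupancy.astype(np.uint8) * 255).transpose(2, 1, 0))
    tifffile.imwrite(path, data)
    _sidecar(path).write_text(json.dumps({
        "voxel_pitch_um": mask.voxel_pitch,
        "origin_um": list(map(float, mask.origin)),
        "axis_order": "pages=z, rows=y, cols=x",
    }, indent=1))


def read_mask(path) -> VoxelMask:
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path)
    return VoxelMask(occupancy=np.ascontiguousarray(data.transpose(2, 1, 0)) != 0,
                     voxel_pitch=meta["voxel_pitch_um"],
                     origin=np.array(meta["origin_um"]))


def write_spots_csv(spots: list[FocalSpot], path) -> None:
    pd.DataFrame([{
        "x_um": s.position[0], "y_um": s.position[1], "z_um": s.position[2],
        "peak": s.peak_value, "prominence": s.prominence,
        "fwhm_axial_um": s.fwhm_axial, "fwhm_lateral_um": s.fwhm_lateral,
    } for s in spots]).to_csv(path, index=False)


def read_spots_csv(path) -> list[FocalSpot]:
    df = pd.read_csv(path)
    return [FocalSpot(position=np.array([r.x_um, r.y_um, r.z_um]),
                      peak_value=r.peak, prominence=r.prominence,
                      fwhm_axial=r.fwhm_axial_um, fwhm_lateral=r.fwhm_lateral_um)
            for r in df.itertuples()]


def write_profile_csv(profile: AxialProfile, path) -> None:
    pd.DataFrame({"z_um": profile.z_positions,
                  "value": profile.values}).to_csv(path, index=False)


def read_profile_csv(path) -> AxialProfile:
    df = pd.read_csv(path)
    return AxialProfile(z_positions=df["z_um"].to_numpy(),
                        values=df["value"].to_numpy())


def write_summary(summary: TraceSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.as_dict(), indent=1))
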