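"""Canonical simulation experiments and their study conditions.

Each function sets up one of the package's reference computations — the cell
diameter statistics, the Fresnel reflectance of a flat interface measured by
Monte Carlo, the single-cell ball-lens focus, and the emergent multi-spot
focusing in a quasi-ordered slab — with the standard tissue parameters
(60 ± 10 µm cells, m = 1.03 in tissue / 1.44 in air, s = 10⁻³ mm steps,
500 µm-class slab depth).  The analysis scripts, the test suite and the
acceptance script all run these same conditions.
"""

from __future__ import annotations

import numpy as np

from .analysis import axial_profile, detect_focal_spots, paraxial_ball_lens_focus
from .scene import (GeometryParams, Scene, SceneMedium, SlabSpec, SphereSpec,
                    draw_diameters, generate_packed_sphere_slab,
                    make_flat_interface_scene, make_single_cell_scene)
from .tracer import FluenceGrid, SimConfig, trace

__all__ = [
    "diameter_statistics",
    "flat_interface_reflectance_mc",
    "single_sphere_focus",
    "lattice_multifocus",
    "LATTICE_COUNTS",
    "LATTICE_SLAB",
]

#: the quasi-ordered slab: 5 x 5 lateral cells, 8 layers deep at 70 µm pitch
LATTICE_COUNTS = (5, 5, 8)
LATTICE_SLAB = SlabSpec(350.0, 350.0, 560.0)


def diameter_statistics(n: int = 10_000, seed: int = 0) -> dict:
    """Sample ``n`` cell diameters from the 60 ± 10 µm uniform band."""
    params = GeometryParams((1, 1, 1), seed=seed)
    d = draw_diameters(params, n, np.random.default_rng(seed))
    return {"n": n, "mean_um": float(d.mean()), "min_um": float(d.min()),
            "max_um": float(d.max())}


def flat_interface_reflectance_mc(n_rays: int = 100_000, seed: int = 0,
                                  n1: float = 1.0, n2: float = 1.5) -> dict:
    """Stochastic reflectance of a flat n1 -> n2 interface at normal incidence.

    The expected fraction is the Fresnel normal-incidence reflectance
    ((n1 - n2) / (n1 + n2))^2 = 0.04 for glass from air.
    """
    scene = make_flat_interface_scene(n1, n2)
    cfg = SimConfig(n_rays=n_rays, seed=seed, grid_pitch=4.0,
                    beam_center=(100.0, 100.0), beam_radius=2.0)
    _, summary = trace(scene, cfg)
    r = (n1 - n2) / (n1 + n2)
    return {"n": n_rays,
            "reflected_fraction": summary.back_reflected / n_rays,
            "expected": r * r,
            "summary": summary}


def single_sphere_focus(m: float, seed: int = 0, n_rays: int = 100_000,
                        d: float = 60.0) -> dict:
    """Trace a near-axis beam through one spherical cell and locate the focus.

    The launch disc has radius 0.05 d (paraxial regime); the measured focal
    distance is the plateau-centroid peak of the on-axis fluence profile
    downstream of the cell, referenced to the sphere centre, and is compared
    with the ball-lens formula m d / (4 (m - 1)).  Weak lenses (m = 1.03)
    get a long downstream margin so the whole caustic fits in the volume.
    """
    medium = SceneMedium.in_air(m) if m > 1.2 else SceneMedium.tissue(m)
    f = paraxial_ball_lens_focus(d, m)
    margin = max(2.0 * d, 2.0 * f - d)
    scene = make_single_cell_scene(SphereSpec(np.zeros(3), d / 2.0), medium,
                                   downstream_margin=margin)
    cx = scene.slab.x_extent / 2.0
    zc = scene.spheres[0].center[2]
    cfg = SimConfig(n_rays=n_rays, seed=seed, grid_pitch=1.0,
                    beam_center=(cx, cx), beam_radius=0.05 * d)
    grid, summary = trace(scene, cfg)
    prof = axial_profile(grid, cx, cx, 1.0)
    z_focus = prof.peak_z(frac=0.9, z_min=zc + d / 2.0)
    measured = z_focus - zc
    return {"n": n_rays, "measured_um": float(measured), "paraxial_um": float(f),
            "rel_error": float(abs(measured - f) / f), "summary": summary}


def lattice_multifocus(scene_seed: int = 2, trace_seed: int = 3,
                       n_rays: int = 100_000, m: float = 1.03,
                       jitter: float = 0.3,
                       min_prominence: float = 0.1,
                       min_separation: float = 20.0) -> dict:
    """The emergent longitudinal multi-spot focusing experiment.

    A 560 µm slab of 5 x 5 x 8 quasi-regularly packed cells (d = 60 ± 10 µm,
    relative index m) is illuminated across its full face; focal spots are
    detected in the fluence volume and those within 25 µm laterally of the
    slab axis are counted as the central cell column's axial focus chain.

    Spot detection is restricted to the interior of the volume, one lattice
    cell (70 µm) away from the absorbing side walls: the wall-adjacent
    columns are edge-affected (the finite illuminated field leaks sideways
    there) and would otherwise set the global maximum that the relative
    prominence threshold is measured against.
    """
    params = GeometryParams(LATTICE_COUNTS, 60.0, 10.0, jitter, seed=scene_seed)
    scene = generate_packed_sphere_slab(params, LATTICE_SLAB, SceneMedium.tissue(m))
    cfg = SimConfig(n_rays=n_rays, seed=trace_seed, grid_pitch=2.0)
    grid, summary = trace(scene, cfg)
    margin = int(round(70.0 / cfg.grid_pitch))
    interior = FluenceGrid(
        values=grid.values[margin:-margin, margin:-margin, :],
        pitch=grid.pitch, origin=grid.origin + np.array([70.0, 70.0, 0.0]),
        rays_launched=grid.rays_launched)
    spots = detect_focal_spots(interior, min_prominence, min_separation)
    cx, cy = LATTICE_SLAB.x_extent / 2.0, LATTICE_SLAB.y_extent / 2.0
    axial = [s for s in spots
             if abs(s.position[0] - cx) <= 25.0 and abs(s.position[1] - cy) <= 25.0]
    return {"n": n_rays, "scene": scene, "grid": grid, "summary": summary,
            "spots": spots, "axial_spots": axial,
            "n_spots": len(spots), "n_axial_spots": len(axial)}
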