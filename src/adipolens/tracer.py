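"""Monte Carlo photon marching through a scene.

Photons start on the illuminated face z = 0 travelling along +z, advance by a
constant geometric step s, and deposit path length into a voxel grid at each
step midpoint (a collision-free fluence estimator: the accumulated value per
voxel is proportional to the local light intensity).  At every interface
crossing the unpolarized Fresnel reflectance decides stochastically between
specular reflection and Snell refraction; total internal reflection always
reflects.  Each photon is traced until it leaves the slab (transmitted,
back-reflected or out the side) or exhausts the step budget.

:func:`trace` runs the compiled kernels in :mod:`adipolens._kernels`; the
photon-level operations (:func:`launch_photon`, :func:`step_photon`,
:func:`detect_crossing`, :func:`handle_interface`) are the same physics in
plain Python, usable step by step and cross-checked against the kernels in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, optics
from .scene import ConfigurationError, Scene, SlabSpec, SceneMedium

__all__ = [
    "SimConfig",
    "FluenceGrid",
    "TraceSummary",
    "Photon",
    "Crossing",
    "launch_photon",
    "step_photon",
    "detect_crossing",
    "handle_interface",
    "trace",
]

#: photon status values
ALIVE = "alive"
TRANSMITTED = "transmitted"
BACK_REFLECTED = "back_reflected"
SIDE_EXIT = "side_exit"


@dataclass
class SimConfig:
    """Monte Carlo run parameters.

    Parameters
    ----------
    step_mm : float
        Constant marching step s in mm (default 1e-3 mm = 1 µm); sets the
        geometric accuracy of the simulation.  Converted to µm once at
        ingestion; everything downstream is in µm.
    n_rays : int
        Number of individual rays.
    seed : int
        Seed of the single RNG driving launches and Fresnel decisions.
    max_steps : int or None
        Step budget per photon; default 10 x thickness / s (bounds photons
        trapped in total-internal-reflection orbits).
    grid_pitch, grid_shape, grid_origin :
        Fluence-voxel geometry (µm).  By default the grid covers the whole
        slab at ``grid_pitch`` resolution.
    launch_window : ((x0, x1), (y0, y1)) or None
        Rectangular launch region on the z = 0 face; default the full face.
    beam_center, beam_radius :
        If ``beam_radius`` is set, launches are uniform over a disc instead
        (a circular beam), centred on ``beam_center`` (default slab centre).
    """

    step_mm: float = 1e-3
    n_rays: int = 1_000_000
    seed: int = 0
    max_steps: int | None = None
    grid_pitch: float = 2.0
    grid_shape: tuple[int, int, int] | None = None
    grid_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    launch_window: tuple[tuple[float, float], tuple[float, float]] | None = None
    beam_center: tuple[float, float] | None = None
    beam_radius: float | None = None

    def __post_init__(self) -> None:
        if not self.step_mm > 0:
            raise ConfigurationError(f"step_mm must be > 0, got {self.step_mm}")
        if int(self.n_rays) < 1:
            raise ConfigurationError(f"n_rays must be >= 1, got {self.n_rays}")
        if not self.grid_pitch > 0:
            raise ConfigurationError(f"grid_pitch must be > 0, got {self.grid_pitch}")
        if self.beam_radius is not None and not self.beam_radius > 0:
            raise ConfigurationError("beam_radius must be > 0")

    @property
    def step_um(self) -> float:
        return self.step_mm * 1000.0

    def resolved_max_steps(self, slab: SlabSpec) -> int:
        floor_steps = math.ceil(slab.thickness / self.step_um)
        if self.max_steps is None:
            return 10 * floor_steps
        if self.max_steps < floor_steps:
            raise ConfigurationError(
                f"max_steps={self.max_steps} cannot be smaller than "
                f"thickness/step = {floor_steps}")
        return int(self.max_steps)

    def resolved_grid(self, slab: SlabSpec) -> tuple[tuple[int, int, int], np.ndarray]:
        if self.grid_shape is not None:
            return tuple(int(c) for c in self.grid_shape), np.asarray(self.grid_origin, float)
        shape = (math.ceil(slab.x_extent / self.grid_pitch),
                 math.ceil(slab.y_extent / self.grid_pitch),
                 math.ceil(slab.thickness / self.grid_pitch))
        return shape, np.asarray(self.grid_origin, float)


@dataclass
class FluenceGrid:
    """Accumulated path length (µm) per voxel: the simulated intensity map."""

    values: np.ndarray          # (nx, ny, nz) float32, axis order x, y, z
    pitch: float                # µm
    origin: np.ndarray          # µm, corner of voxel (0,0,0)
    rays_launched: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("fluence values must be 3D")
        if self.rays_launched <= 0:
            raise ConfigurationError("rays_launched must be positive")

    def per_ray(self) -> np.ndarray:
        """Fluence normalized per launched ray and per voxel volume
        (µm / µm^3 / ray), comparable across runs of different n_rays."""
        return self.values.astype(np.float64) / (self.rays_launched * self.pitch ** 3)

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.pitch


@dataclass
class TraceSummary:
    """Terminal bookkeeping of one trace run."""

    n_rays: int
    transmitted: int
    back_reflected: int
    side_exit: int
    max_steps_terminated: int
    multi_crossing_warnings: int
    total_steps: int

    @property
    def terminal_total(self) -> int:
        return (self.transmitted + self.back_reflected + self.side_exit
                + self.max_steps_terminated)

    def as_dict(self) -> dict:
        return {
            "n_rays": self.n_rays,
            "transmitted": self.transmitted,
            "back_reflected": self.back_reflected,
            "side_exit": self.side_exit,
            "max_steps_terminated": self.max_steps_terminated,
            "multi_crossing_warnings": self.multi_crossing_warnings,
            "total_steps": self.total_steps,
        }


# ---------------------------------------------------------------------------
# photon-level operations (plain Python mirror of the kernels)
# ---------------------------------------------------------------------------

@dataclass
class Photon:
    position: np.ndarray
    direction: np.ndarray
    status: str = ALIVE
    steps_taken: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)


@dataclass
class Crossing:
    """An interface crossing within one marching step."""

    point: np.ndarray           # µm
    normal: np.ndarray          # outward unit normal of the body at point
    t: float                    # distance from segment start, µm
    entering: bool              # True when the photon enters the body
    warn_multiple: bool = False  # >1 interface fell inside the step


def launch_photon(rng: np.random.Generator, slab: SlabSpec,
                  window=None) -> Photon:
    """New photon on the z = 0 face, direction (0, 0, 1), position uniform
    over the slab face (or over ``window`` = ((x0,x1),(y0,y1)))."""
    (x0, x1), (y0, y1) = window or ((0.0, slab.x_extent), (0.0, slab.y_extent))
    return Photon(position=np.array([rng.uniform(x0, x1), rng.uniform(y0, y1), 0.0]),
                  direction=np.array([0.0, 0.0, 1.0]))


def step_photon(p: Photon, s_um: float) -> Photon:
    """Advance an alive photon by the constant step s (µm) along its direction."""
    if p.status != ALIVE:
        raise ConfigurationError("cannot step a terminated photon")
    p.position = p.position + p.direction * s_um
    p.steps_taken += 1
    return p


def detect_crossing(scene: Scene, p_prev, p_next) -> Crossing | None:
    """Locate the interface crossed between two step endpoints, if any.

    Sphere scenes use the analytic ray-sphere intersection; voxel-mask scenes
    bisect to a tolerance of 1/100 of the step.  When more than one interface
    falls inside the step the nearest crossing is returned with
    ``warn_multiple`` set.
    """
    p_prev = np.asarray(p_prev, dtype=float)
    p_next = np.asarray(p_next, dtype=float)
    seg = p_next - p_prev
    s = float(np.linalg.norm(seg))
    if s == 0.0:
        return None
    e = seg / s

    if scene.spheres is not None:
        from .scene import _containing_sphere
        cur = _containing_sphere(scene, p_prev)
        nxt = _containing_sphere(scene, p_next)
        if cur == nxt:
            return None
        centers, radii = scene.sphere_arrays()
        best_t, best_j = -1.0, -1
        if cur >= 0:
            t = _kernels._sphere_exit_t(*p_prev, *e, *centers[cur], radii[cur])
            if 1e-12 < t <= s + 1e-9:
                best_t, best_j = t, cur
        if nxt >= 0 and nxt != cur:
            t = _kernels._sphere_entry_t(*p_prev, *e, *centers[nxt], radii[nxt])
            if 1e-12 < t <= s + 1e-9 and (best_j < 0 or t < best_t):
                best_t, best_j = t, nxt
        if best_j < 0:
            return None
        point = p_prev + e * best_t
        normal = (point - centers[best_j]) / radii[best_j]
        return Crossing(point=point, normal=normal, t=best_t,
                        entering=(best_j != cur),
                        warn_multiple=(cur >= 0 and nxt >= 0 and nxt != cur))

    mask = scene.mask
    cur = mask.contains(p_prev)
    nxt = mask.contains(p_next)
    if cur == nxt:
        return None
    tol = s / 100.0
    tlo, thi = 0.0, s
    while thi - tlo > tol:
        tm = 0.5 * (tlo + thi)
        if mask.contains(p_prev + e * tm) == cur:
            tlo = tm
        else:
            thi = tm
    t = 0.5 * (tlo + thi)
    point = p_prev + e * t
    normal = scene.mask_field().outward_normal(point)
    return Crossing(point=point, normal=normal, t=t, entering=not cur)


def handle_interface(p: Photon, crossing: Crossing, medium: SceneMedium,
                     rng: np.random.Generator, step_um: float = 1.0) -> Photon:
    """Resolve one interface crossing on an alive photon.

    Moves the photon to the crossing point, decides reflection vs refraction
    (TIR always reflects; otherwise reflect with probability R of the
    unpolarized Fresnel formula), and offsets the photon by step/100 along
    its new direction so the next membership query is unambiguous.
    """
    if p.status != ALIVE:
        raise ConfigurationError("photon is not alive")
    n1 = medium.n_in if not crossing.entering else medium.n_out
    n2 = medium.n_out if not crossing.entering else medium.n_in
    mu = n1 / n2
    n = optics.orient_against(p.direction, crossing.normal)
    a = float(p.direction @ n)
    if abs(a) < optics.GRAZING_TOL:
        p.position = crossing.point
        p.status = SIDE_EXIT  # degenerate grazing geometry: terminate
        return p
    alpha_i = math.acos(min(1.0, -a))
    alpha_t = optics.snell_angle(alpha_i, mu)
    if alpha_t is None:
        new_dir = optics.reflect(p.direction, n)
    else:
        R = optics.fresnel_reflectance(alpha_i, alpha_t, mu=mu).R
        if rng.uniform() < R:
            new_dir = optics.reflect(p.direction, n)
        else:
            new_dir = optics.refract(p.direction, n, mu)
    p.direction = new_dir / np.linalg.norm(new_dir)
    p.position = crossing.point + p.direction * (step_um / 100.0)
    return p


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def _build_cell_list(centers: np.ndarray, radii: np.ndarray, slab: SlabSpec):
    """Uniform-grid acceleration structure: per cell, the spheres whose
    bounding box intersects it (so a point query checks only one cell)."""
    if len(radii) == 0:
        cs = max(slab.x_extent, slab.y_extent, slab.thickness)
        return (np.zeros(2, dtype=np.int64), np.zeros(0, dtype=np.int64),
                cs, 1, 1, 1)
    cs = float(2.0 * radii.max())
    ncx = max(1, math.ceil(slab.x_extent / cs))
    ncy = max(1, math.ceil(slab.y_extent / cs))
    ncz = max(1, math.ceil(slab.thickness / cs))
    buckets: list[list[int]] = [[] for _ in range(ncx * ncy * ncz)]
    for j in range(len(radii)):
        lo = np.clip(np.floor((centers[j] - radii[j]) / cs).astype(int), 0,
                     [ncx - 1, ncy - 1, ncz - 1])
        hi = np.clip(np.floor((centers[j] + radii[j]) / cs).astype(int), 0,
                     [ncx - 1, ncy - 1, ncz - 1])
        for ix in range(lo[0], hi[0] + 1):
            for iy in range(lo[1], hi[1] + 1):
                for iz in range(lo[2], hi[2] + 1):
                    buckets[(ix * ncy + iy) * ncz + iz].append(j)
    start = np.zeros(len(buckets) + 1, dtype=np.int64)
    for i, b in enumerate(buckets):
        start[i + 1] = start[i] + len(b)
    items = np.fromiter((j for b in buckets for j in b), dtype=np.int64,
                        count=int(start[-1]))
    return start, items, cs, ncx, ncy, ncz


def _launch_params(scene: Scene, config: SimConfig):
    slab = scene.slab
    if config.beam_radius is not None:
        cx, cy = config.beam_center or (slab.x_extent / 2.0, slab.y_extent / 2.0)
        return 1, float(cx), float(cy), float(config.beam_radius), 0.0
    (x0, x1), (y0, y1) = config.launch_window or (
        (0.0, slab.x_extent), (0.0, slab.y_extent))
    return 0, float(x0), float(x1), float(y0), float(y1)


#: rays per kernel call; progress is reported (and the RNG re-seeded from a
#: fixed per-chunk derivation) at this granularity, so results are
#: bit-identical regardless of whether a progress callback is attached
CHUNK_RAYS = 10_000


def _chunk_seed(seed: int, k: int) -> int:
    return (int(seed) + 0x9E3779B1 * (k + 1)) % (2 ** 32 - 1)


def trace(scene: Scene, config: SimConfig,
          progress=None) -> tuple[FluenceGrid, TraceSummary]:
    """Trace ``config.n_rays`` photons through ``scene``.

    Fully deterministic for a fixed ``config.seed``.  Returns the fluence
    grid (path length per voxel, float32) and the terminal-status summary;
    the terminal counts always sum to ``n_rays``.  ``progress(done, total)``
    is invoked after every :data:`CHUNK_RAYS` rays.
    """
    slab = scene.slab
    s = config.step_um
    max_steps = config.resolved_max_steps(slab)
    shape, origin = config.resolved_grid(slab)
    fl = np.zeros(shape, dtype=np.float64)
    counts = np.zeros(6, dtype=np.int64)
    mode, q0, q1, q2, q3 = _launch_params(scene, config)

    n_total = int(config.n_rays)
    if scene.spheres is not None:
        centers, radii = scene.sphere_arrays()
        start, items, cs, ncx, ncy, ncz = _build_cell_list(centers, radii, slab)

        def run(n, seed):
            _kernels.trace_spheres(
                centers, radii, start, items, cs, ncx, ncy, ncz,
                slab.x_extent, slab.y_extent, slab.thickness,
                scene.medium.n_out, scene.medium.n_in,
                s, n, max_steps, seed,
                fl, origin[0], origin[1], origin[2], config.grid_pitch,
                mode, q0, q1, q2, q3, counts)
    else:
        mf = scene.mask_field()
        mask = scene.mask

        def run(n, seed):
            _kernels.trace_mask(
                mask.occupancy.view(np.uint8),
                mf.grad[0], mf.grad[1], mf.grad[2],
                mask.origin[0], mask.origin[1], mask.origin[2], mask.voxel_pitch,
                slab.x_extent, slab.y_extent, slab.thickness,
                scene.medium.n_out, scene.medium.n_in,
                s, n, max_steps, seed,
                fl, origin[0], origin[1], origin[2], config.grid_pitch,
                mode, q0, q1, q2, q3, counts)

    done = 0
    k = 0
    while done < n_total:
        n = min(CHUNK_RAYS, n_total - done)
        run(n, _chunk_seed(config.seed, k))
        done += n
        k += 1
        if progress is not None:
            progress(done, n_total)

    grid = FluenceGrid(values=fl.astype(np.float32), pitch=config.grid_pitch,
                       origin=origin, rays_launched=int(config.n_rays))
    summary = TraceSummary(
        n_rays=int(config.n_rays),
        transmitted=int(counts[0]), back_reflected=int(counts[1]),
        side_exit=int(counts[2]), max_steps_terminated=int(counts[3]),
        multi_crossing_warnings=int(counts[4]), total_steps=int(counts[5]))
    return grid, summary
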