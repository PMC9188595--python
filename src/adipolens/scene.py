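"""Tissue geometry: slabs of quasi-regularly packed spheres and voxel-mask cells.

The slab scene is the synthetic stand-in for a layer of adipose tissue: each
adipocyte is an optically soft sphere (relative index m close to 1) sitting
near a cubic-lattice site, with diameters drawn uniformly from a band around
the typical cell size.  A voxel mask describes an arbitrary closed cell shape
(e.g. a segmented adipocyte) for the single-cell lensing case.

All positions and lengths are in micrometres.  z = 0 is the illuminated face
of the slab and z grows along the propagation direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ConfigurationError",
    "OutsideDomain",
    "SphereSpec",
    "SlabSpec",
    "SceneMedium",
    "VoxelMask",
    "GeometryParams",
    "Scene",
    "generate_packed_sphere_slab",
    "make_single_cell_scene",
    "medium_index_at",
    "surface_normal_at",
]

#: interstitial refractive index used for tissue scenes; only the ratio
#: m = n_in / n_out enters the optics, so this merely fixes absolute units
N_INTERSTITIAL = 1.36


class ConfigurationError(ValueError):
    """A scene or generator parameter violates its documented constraints."""


class OutsideDomain(Exception):
    """A query point lies outside the slab bounding box (the tracer treats
    this as the photon having exited)."""


@dataclass(frozen=True)
class SphereSpec:
    """One spherical cell: center (µm, 3-vector) and radius (µm)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        object.__setattr__(self, "center", c)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ConfigurationError("center must be a finite 3-vector")
        if not self.radius > 0:
            raise ConfigurationError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class SlabSpec:
    """Rectangular slab: x in [0, x_extent], y in [0, y_extent],
    z in [0, thickness] (µm)."""

    x_extent: float
    y_extent: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("x_extent", "y_extent", "thickness"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")

    def contains(self, p) -> bool:
        x, y, z = p
        return (0.0 <= x <= self.x_extent and 0.0 <= y <= self.y_extent
                and 0.0 <= z <= self.thickness)


@dataclass(frozen=True)
class SceneMedium:
    """Refractive indices: n_out outside the cells, n_in inside.

    The relative index m = n_in / n_out is what controls the lensing
    (m = 1.03 for adipocytes in tissue, 1.44 for a cell in air).
    """

    n_out: float
    n_in: float

    def __post_init__(self) -> None:
        if self.n_out < 1.0:
            raise ConfigurationError(f"n_out must be >= 1, got {self.n_out}")
        if not self.n_in > 0:
            raise ConfigurationError(f"n_in must be > 0, got {self.n_in}")

    @property
    def m(self) -> float:
        """Relative refractive index n_in / n_out."""
        return self.n_in / self.n_out

    @classmethod
    def tissue(cls, m: float = 1.03, n_out: float = N_INTERSTITIAL) -> "SceneMedium":
        """Cells embedded in interstitial fluid with relative index ``m``."""
        return cls(n_out=n_out, n_in=m * n_out)

    @classmethod
    def in_air(cls, m: float = 1.44) -> "SceneMedium":
        """A cell surrounded by air (n_out = 1)."""
        return cls(n_out=1.0, n_in=m)


@dataclass(frozen=True)
class VoxelMask:
    """Binary occupancy volume: nonzero voxels are cell interior.

    Voxel (i, j, k) is centered at ``origin + (i+1/2, j+1/2, k+1/2) * pitch``
    (0-based indices, axis order x, y, z).
    """

    occupancy: np.ndarray
    voxel_pitch: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        occ = np.ascontiguousarray(np.asarray(self.occupancy) != 0)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if occ.ndim != 3:
            raise ConfigurationError("occupancy must be a 3D array")
        if not self.voxel_pitch > 0:
            raise ConfigurationError(f"voxel_pitch must be > 0, got {self.voxel_pitch}")
        if not occ.any():
            raise ConfigurationError("mask must contain at least one occupied voxel")

    def contains(self, p) -> bool:
        idx = np.floor((np.asarray(p, float) - self.origin) / self.voxel_pitch).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.occupancy.shape):
            return False
        return bool(self.occupancy[idx[0], idx[1], idx[2]])


class _MaskField:
    """Smoothed occupancy field and its gradient, for sub-voxel normals.

    Raw binary gradients are quantized to the axes; Gaussian smoothing
    restores sub-voxel orientation.  The default sigma of 2 voxels keeps the
    normal-direction noise well below the paraxial surface tilt that drives
    the lensing (about 1 degree median error on a rasterized sphere at
    1 µm pitch; narrower smoothing leaves several degrees of noise, which
    visibly biases the traced focal position).  The outward normal is the
    normalized negative gradient of the smoothed field (the field grows
    toward the interior).
    """

    def __init__(self, mask: VoxelMask, sigma_voxels: float = 2.0):
        self.mask = mask
        smooth = ndimage.gaussian_filter(mask.occupancy.astype(np.float64), sigma=sigma_voxels)
        self.smooth = smooth
        gx, gy, gz = np.gradient(smooth, mask.voxel_pitch)
        self.grad = (np.ascontiguousarray(gx), np.ascontiguousarray(gy),
                     np.ascontiguousarray(gz))

    def _trilinear(self, vol: np.ndarray, p) -> float:
        # sample at voxel-center grid coordinates
        u = (np.asarray(p, float) - self.mask.origin) / self.mask.voxel_pitch - 0.5
        u = np.clip(u, 0.0, np.array(vol.shape) - 1.0 - 1e-9)
        i0 = np.floor(u).astype(int)
        f = u - i0
        i1 = np.minimum(i0 + 1, np.array(vol.shape) - 1)
        acc = 0.0
        for dx, wx in ((0, 1 - f[0]), (1, f[0])):
            for dy, wy in ((0, 1 - f[1]), (1, f[1])):
                for dz, wz in ((0, 1 - f[2]), (1, f[2])):
                    ii = i1 if dx else i0
                    jj = i1 if dy else i0
                    kk = i1 if dz else i0
                    acc += wx * wy * wz * vol[ii[0], jj[1], kk[2]]
        return float(acc)

    def value(self, p) -> float:
        return self._trilinear(self.smooth, p)

    def outward_normal(self, p) -> np.ndarray:
        g = np.array([self._trilinear(self.grad[0], p),
                      self._trilinear(self.grad[1], p),
                      self._trilinear(self.grad[2], p)])
        nrm = np.linalg.norm(g)
        if nrm == 0.0:
            raise ConfigurationError("zero gradient: point is not near the mask surface")
        return -g / nrm


@dataclass
class Scene:
    """A slab, its optical medium, and the interior bodies (spheres or mask)."""

    slab: SlabSpec
    medium: SceneMedium
    spheres: list[SphereSpec] | None = None
    mask: VoxelMask | None = None

    def __post_init__(self) -> None:
        if (self.spheres is None) == (self.mask is None):
            raise ConfigurationError("scene needs exactly one of: sphere list, voxel mask")
        if self.spheres is not None:
            for s in self.spheres:
                if not self.slab.contains(s.center):
                    raise ConfigurationError(
                        f"sphere center {s.center} lies outside the slab")
        self._arrays: tuple[np.ndarray, np.ndarray] | None = None
        self._mask_field: _MaskField | None = None

    # -- cached dense views -------------------------------------------------

    def sphere_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers (N,3), radii (N,)) as contiguous float64 arrays."""
        if self.spheres is None:
            raise ConfigurationError("not a sphere scene")
        if self._arrays is None:
            if len(self.spheres) == 0:
                self._arrays = (np.zeros((0, 3)), np.zeros(0))
            else:
                self._arrays = (
                    np.ascontiguousarray([s.center for s in self.spheres], dtype=float),
                    np.ascontiguousarray([s.radius for s in self.spheres], dtype=float),
                )
        return self._arrays

    def mask_field(self) -> _MaskField:
        if self.mask is None:
            raise ConfigurationError("not a voxel-mask scene")
        if self._mask_field is None:
            self._mask_field = _MaskField(self.mask)
        return self._mask_field

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialize a sphere scene (or the metadata of a mask scene) to JSON."""
        doc: dict = {
            "slab": {"x_extent": self.slab.x_extent, "y_extent": self.slab.y_extent,
                     "thickness": self.slab.thickness},
            "medium": {"n_out": self.medium.n_out, "n_in": self.medium.n_in},
        }
        if self.spheres is not None:
            doc["spheres"] = [
                {"center": list(map(float, s.center)), "radius": float(s.radius)}
                for s in self.spheres
            ]
        else:
            doc["mask"] = {"shape": list(self.mask.occupancy.shape),
                           "voxel_pitch": self.mask.voxel_pitch,
                           "origin": list(map(float, self.mask.origin))}
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Scene":
        """Load a sphere scene written by :meth:`to_json` (path or JSON text)."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        doc = json.loads(text)
        if "spheres" not in doc:
            raise ConfigurationError("JSON scenes with voxel masks need the mask "
                                     "TIFF loaded separately (see adipolens.io)")
        return cls(
            slab=SlabSpec(**doc["slab"]),
            medium=SceneMedium(**doc["medium"]),
            spheres=[SphereSpec(np.array(s["center"]), s["radius"]) for s in doc["spheres"]],
        )


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the quasi-regular sphere packing.

    One sphere per cubic-lattice site; each center is jittered by a uniform
    per-axis offset of magnitude <= jitter_fraction * pitch / 2, and each
    diameter is drawn uniformly from
    [mean_diameter - diameter_halfwidth, mean_diameter + diameter_halfwidth].
    """

    lattice_counts: tuple[int, int, int]
    mean_diameter: float = 60.0
    diameter_halfwidth: float = 10.0
    jitter_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lattice_counts) != 3 or any(int(c) < 1 for c in self.lattice_counts):
            raise ConfigurationError("lattice_counts must be three positive integers")
        if not self.mean_diameter - self.diameter_halfwidth > 0:
            raise ConfigurationError(
                "mean_diameter - diameter_halfwidth must be > 0 "
                f"(got {self.mean_diameter} - {self.diameter_halfwidth})")
        if not 0.0 <= self.jitter_fraction < 1.0:
            raise ConfigurationError(
                f"jitter_fraction must be in [0, 1), got {self.jitter_fraction}")


def draw_diameters(params: GeometryParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` cell diameters: Uniform(mean - halfwidth, mean + halfwidth)."""
    return rng.uniform(params.mean_diameter - params.diameter_halfwidth,
                       params.mean_diameter + params.diameter_halfwidth, n)


def generate_packed_sphere_slab(params: GeometryParams, slab: SlabSpec,
                                medium: SceneMedium) -> Scene:
    """Generate the quasi-regularly packed sphere slab.

    One sphere per lattice site of a cubic grid filling the slab (pitch =
    extent / count per axis).  Placement is sequential in site order; a
    jittered placement overlapping an already-placed sphere is re-drawn (up
    to 100 attempts, then the un-jittered site is used).  Deterministic for
    a fixed ``params.seed``.

    Raises
    ------
    ConfigurationError
        If the lattice pitch on any axis is smaller than
        ``mean_diameter + diameter_halfwidth`` (the packing could then
        overlap even at zero jitter).
    """
    nx, ny, nz = (int(c) for c in params.lattice_counts)
    pitch = np.array([slab.x_extent / nx, slab.y_extent / ny, slab.thickness / nz])
    dmax = params.mean_diameter + params.diameter_halfwidth
    if pitch.min() < dmax - 1e-9:
        axis = "xyz"[int(np.argmin(pitch))]
        raise ConfigurationError(
            f"lattice pitch along {axis} ({pitch.min():.4g} µm) is smaller than "
            f"mean_diameter + diameter_halfwidth ({dmax:.4g} µm); enlarge the "
            "slab or reduce lattice_counts")

    rng = np.random.default_rng(params.seed)
    n_sites = nx * ny * nz
    diameters = draw_diameters(params, n_sites, rng)

    half_jit = params.jitter_fraction * pitch / 2.0
    centers = np.empty((n_sites, 3))
    radii = diameters / 2.0
    placed: dict[tuple[int, int, int], int] = {}

    def neighbors(site):
        ix, iy, iz = site
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    j = placed.get((ix + dx, iy + dy, iz + dz))
                    if j is not None:
                        yield j

    k = 0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                site = np.array([ix + 0.5, iy + 0.5, iz + 0.5]) * pitch
                c = site
                for _attempt in range(100):
                    cand = site + rng.uniform(-half_jit, half_jit)
                    ok = all(
                        np.linalg.norm(cand - centers[j]) >= radii[k] + radii[j]
                        for j in neighbors((ix, iy, iz))
                    )
                    if ok:
                        c = cand
                        break
                centers[k] = c
                placed[(ix, iy, iz)] = k
                k += 1

    spheres = [SphereSpec(centers[i], radii[i]) for i in range(n_sites)]
    return Scene(slab=slab, medium=medium, spheres=spheres)


def make_single_cell_scene(shape: SphereSpec | VoxelMask, medium: SceneMedium,
                           downstream_margin: float | None = None,
                           lateral_margin: float | None = None) -> Scene:
    """Scene with exactly one interior body, centered laterally in a slab
    that encloses it with at least one body-diameter of downstream margin
    (room for the focal region).

    ``downstream_margin`` / ``lateral_margin`` override the default margins
    (one diameter downstream, half a diameter laterally / upstream).
    """
    if isinstance(shape, SphereSpec):
        d = 2.0 * shape.radius
        lat = d / 2.0 if lateral_margin is None else lateral_margin
        down = d if downstream_margin is None else downstream_margin
        side = d + 2.0 * lat
        slab = SlabSpec(side, side, d / 2.0 + d + down)
        center = np.array([side / 2.0, side / 2.0, d / 4.0 + shape.radius])
        return Scene(slab=slab, medium=medium,
                     spheres=[SphereSpec(center, shape.radius)])

    if isinstance(shape, VoxelMask):
        extent = np.array(shape.occupancy.shape) * shape.voxel_pitch
        d = float(extent.max())
        lat = d / 2.0 if lateral_margin is None else lateral_margin
        down = d if downstream_margin is None else downstream_margin
        slab = SlabSpec(extent[0] + 2 * lat, extent[1] + 2 * lat,
                        extent[2] + d / 4.0 + down)
        origin = np.array([lat, lat, d / 4.0])
        mask = VoxelMask(shape.occupancy, shape.voxel_pitch, origin)
        return Scene(slab=slab, medium=medium, mask=mask)

    raise ConfigurationError(f"unsupported shape type {type(shape).__name__}")


def make_flat_interface_scene(n_out: float = 1.0, n_in: float = 1.5,
                              slab_side: float = 200.0) -> Scene:
    """A locally flat dielectric interface, for reflectance statistics.

    Built as a single very large sphere whose front apex sits just inside
    the illuminated face and whose rear surface lies outside the slab, so a
    narrow axial beam meets exactly one interface, at near-normal incidence
    (the sagitta across a few-µm beam is negligible).  Photons reflected at
    the interface exit through z < 0 and are counted as back-reflected;
    refracted ones traverse the sphere interior and exit transmitted.
    """
    slab = SlabSpec(slab_side, slab_side, slab_side)
    r = slab_side / 2.0 - 0.4
    center = np.array([slab_side / 2.0, slab_side / 2.0, slab_side / 2.0 + 1.0])
    return Scene(slab=slab, medium=SceneMedium(n_out=n_out, n_in=n_in),
                 spheres=[SphereSpec(center, r)])


def _containing_sphere(scene: Scene, p: np.ndarray) -> int:
    centers, radii = scene.sphere_arrays()
    if len(radii) == 0:
        return -1
    d2 = np.einsum("ij,ij->i", centers - p, centers - p)
    hits = np.nonzero(d2 <= radii * radii)[0]  # boundary counts as inside
    return int(hits[0]) if hits.size else -1


def medium_index_at(scene: Scene, p) -> float:
    """Refractive index at point ``p`` (µm).

    Points on a body surface count as interior (a stated convention that
    removes a measure-zero ambiguity).  Raises :class:`OutsideDomain` for
    points outside the slab bounding box.
    """
    p = np.asarray(p, dtype=float)
    if not scene.slab.contains(p):
        raise OutsideDomain(p)
    if scene.spheres is not None:
        inside = _containing_sphere(scene, p) >= 0
    else:
        inside = scene.mask.contains(p)
    return scene.medium.n_in if inside else scene.medium.n_out


def surface_normal_at(scene: Scene, p, tol: float = 0.1) -> np.ndarray:
    """Outward unit normal of the body surface nearest to ``p``.

    ``p`` must lie within ``tol`` (µm) of an interface.  Sphere scenes use
    the exact radial normal; mask scenes the smoothed-gradient normal.
    """
    p = np.asarray(p, dtype=float)
    if scene.spheres is not None:
        centers, radii = scene.sphere_arrays()
        if len(radii) == 0:
            raise ConfigurationError("scene has no bodies")
        d = np.linalg.norm(centers - p, axis=1)
        gap = np.abs(d - radii)
        j = int(np.argmin(gap))
        if gap[j] > tol:
            raise ConfigurationError(
                f"point is {gap[j]:.3g} µm from the nearest interface (> tol {tol})")
        v = p - centers[j]
        return v / np.linalg.norm(v)
    fieldv = scene.mask_field()
    val = fieldv.value(p)
    if not 0.02 < val < 0.98:
        raise ConfigurationError(
            f"point is not near the mask surface (smoothed occupancy {val:.3g})")
    return fieldv.outward_normal(p)
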