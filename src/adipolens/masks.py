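"""Synthetic voxel-mask cell shapes.

Stand-ins for segmented adipocyte boundaries: an exact sphere, an ellipsoid,
and a "dented" sphere whose radius carries a smooth seeded perturbation
(up to 15% of the radius) mimicking the imperfect lens shape of a real cell.
All shapes are star-convex about their centre, so the mask is guaranteed to
be a single closed connected component.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .scene import ConfigurationError, VoxelMask

__all__ = ["make_fixture_mask"]

#: maximum relative radial perturbation of the dented sphere
DENT_AMPLITUDE = 0.12


def _coords(shape_vox: tuple[int, int, int], pitch: float) -> tuple[np.ndarray, ...]:
    axes = [(np.arange(n) + 0.5) * pitch for n in shape_vox]
    return np.meshgrid(*axes, indexing="ij")


def _dent_field(ux, uy, uz, rng: np.random.Generator) -> np.ndarray:
    """Smooth random function on the unit sphere, normalized to [-1, 1]:
    a seeded combination of low-order direction harmonics."""
    val = np.zeros_like(ux)
    for _ in range(6):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        amp = rng.uniform(-1.0, 1.0)
        c = ux * v[0] + uy * v[1] + uz * v[2]
        # cos(k * angle)-like terms from Chebyshev polynomials of c
        val += amp * (4.0 * c ** 3 - 3.0 * c)
    peak = np.abs(val).max()
    return val / peak if peak > 0 else val


def make_fixture_mask(kind: str, size, pitch: float, seed: int = 0) -> VoxelMask:
    """Generate a closed single-component binary cell mask.

    Parameters
    ----------
    kind : {"sphere", "ellipsoid", "dented_sphere"}
    size : float or 3-sequence of float
        Diameter (µm); for the ellipsoid a 3-sequence of axis diameters.
    pitch : float
        Voxel pitch (µm); must resolve the shape (pitch <= min_size / 20).
    seed : int
        Seeds the dented-sphere perturbation; other kinds are deterministic.
    """
    sizes = np.atleast_1d(np.asarray(size, dtype=float))
    if sizes.size == 1:
        sizes = np.repeat(sizes, 3)
    if sizes.size != 3 or np.any(sizes <= 0):
        raise ConfigurationError("size must be a positive scalar or 3-sequence (µm)")
    if pitch > sizes.min() / 20.0:
        raise ConfigurationError(
            f"pitch {pitch} µm too coarse for size {sizes.min()} µm "
            "(need pitch <= size/20)")
    if kind not in ("sphere", "ellipsoid", "dented_sphere"):
        raise ConfigurationError(f"unknown fixture kind {kind!r}")

    pad = 7.0 * pitch  # room for the smoothed-field normals at the surface
    shape_vox = tuple(int(np.ceil((s + 2 * pad) / pitch)) for s in sizes)
    cx, cy, cz = (n * pitch / 2.0 for n in shape_vox)
    X, Y, Z = _coords(shape_vox, pitch)
    dx, dy, dz = X - cx, Y - cy, Z - cz

    if kind == "ellipsoid":
        a, b, c = sizes / 2.0
        occ = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
    else:
        r0 = sizes[0] / 2.0
        rad = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
        if kind == "sphere":
            occ = rad <= r0
        else:  # dented_sphere
            rng = np.random.default_rng(seed)
            safe = np.where(rad > 0, rad, 1.0)
            dent = _dent_field(dx / safe, dy / safe, dz / safe, rng)
            occ = rad <= r0 * (1.0 + DENT_AMPLITUDE * dent)

    labels, ncomp = ndimage.label(occ)
    if ncomp != 1:  # star-convex construction should guarantee this
        raise ConfigurationError(f"mask is not a single component (got {ncomp})")
    return VoxelMask(occupancy=occ, voxel_pitch=pitch)
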