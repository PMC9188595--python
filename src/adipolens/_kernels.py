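"""Compiled Monte Carlo marching kernels.

The marching loop advances every photon by a constant geometric step s,
deposits path length into a voxel fluence grid at each step midpoint, and
resolves refraction/reflection at sphere or voxel-mask interfaces.  These
kernels are the hot path (1e5-1e6 rays x hundreds of steps); the physics is
identical to the pure-Python operations in :mod:`adipolens.tracer`, which the
test suite cross-checks against them.

Terminal-status/counter layout shared by both kernels::

    counts[0] transmitted        (z >= thickness)
    counts[1] back_reflected     (z < 0)
    counts[2] side_exit          (lateral exit or degenerate grazing hit)
    counts[3] max_steps reached
    counts[4] multi-interface-in-one-step warnings
    counts[5] total steps taken
"""

import numba as nb
import numpy as np

GRAZING_TOL = 1e-9
NORMAL_INCIDENCE_SIN_TOL = 1e-6


@nb.njit(inline="always")
def _clampi(i, n):
    if i < 0:
        return 0
    if i >= n:
        return n - 1
    return i


@nb.njit(inline="always")
def _deposit(fl, gox, goy, goz, gp, mx, my, mz, length):
    if mx < gox or my < goy or mz < goz:
        return
    i = int((mx - gox) / gp)
    j = int((my - goy) / gp)
    k = int((mz - goz) / gp)
    if i < fl.shape[0] and j < fl.shape[1] and k < fl.shape[2]:
        fl[i, j, k] += length


@nb.njit(inline="always")
def _exit_travel(x, y, z, ex, ey, ez, qx, qy, qz, sx, sy, sz, s):
    """Path length to the first violated slab face (deposits stop at the
    boundary; the part of the final step outside the slab is not fluence)."""
    t = s
    if qz < 0.0:
        t = min(t, -z / ez)
    elif qz >= sz:
        t = min(t, (sz - z) / ez)
    if qx < 0.0:
        t = min(t, -x / ex)
    elif qx > sx:
        t = min(t, (sx - x) / ex)
    if qy < 0.0:
        t = min(t, -y / ey)
    elif qy > sy:
        t = min(t, (sy - y) / ey)
    return t


@nb.njit(inline="always")
def _find_sphere(px, py, pz, centers, radii, cell_start, cell_items,
                 cs, ncx, ncy, ncz):
    """Index of the sphere containing the point (boundary counts inside), or -1."""
    ix = _clampi(int(px / cs), ncx)
    iy = _clampi(int(py / cs), ncy)
    iz = _clampi(int(pz / cs), ncz)
    c = (ix * ncy + iy) * ncz + iz
    for k in range(cell_start[c], cell_start[c + 1]):
        j = cell_items[k]
        dx = px - centers[j, 0]
        dy = py - centers[j, 1]
        dz = pz - centers[j, 2]
        if dx * dx + dy * dy + dz * dz <= radii[j] * radii[j]:
            return j
    return -1


@nb.njit(inline="always")
def _sphere_exit_t(px, py, pz, ex, ey, ez, cx, cy, cz, r):
    """Forward distance to the exit point of a sphere containing p."""
    ox = px - cx
    oy = py - cy
    oz = pz - cz
    b = ex * ox + ey * oy + ez * oz
    c0 = ox * ox + oy * oy + oz * oz - r * r
    disc = b * b - c0
    if disc < 0.0:
        return -1.0
    return -b + np.sqrt(disc)


@nb.njit(inline="always")
def _sphere_entry_t(px, py, pz, ex, ey, ez, cx, cy, cz, r):
    """Forward distance to the entry point of a sphere not containing p."""
    ox = px - cx
    oy = py - cy
    oz = pz - cz
    b = ex * ox + ey * oy + ez * oz
    c0 = ox * ox + oy * oy + oz * oz - r * r
    disc = b * b - c0
    if disc < 0.0:
        return -1.0
    return -b - np.sqrt(disc)


@nb.njit(inline="always")
def _interact(ex, ey, ez, nxv, nyv, nzv, mu):
    """Reflect or refract direction e at a surface with outward normal n.

    Draws one uniform variate for the Fresnel decision.  Returns the new
    direction and a flag: 0 refracted, 1 reflected, 2 degenerate grazing.
    """
    a = ex * nxv + ey * nyv + ez * nzv
    if a > 0.0:
        nxv = -nxv
        nyv = -nyv
        nzv = -nzv
        a = -a
    if a > -GRAZING_TOL:
        return 0.0, 0.0, 0.0, 2
    cosi = -a
    if cosi > 1.0:
        cosi = 1.0
    sini = np.sqrt(1.0 - cosi * cosi)
    sint = mu * sini
    do_reflect = False
    if sint >= 1.0:
        do_reflect = True  # total internal reflection
    else:
        if sini < NORMAL_INCIDENCE_SIN_TOL:
            rr = (mu - 1.0) / (mu + 1.0)
            R = rr * rr
        else:
            ai = np.arccos(cosi)
            at = np.arcsin(sint)
            d = ai - at
            ssum = ai + at
            sd = np.sin(d)
            ss = np.sin(ssum)
            cd = np.cos(d)
            cs_ = np.cos(ssum)
            R = 0.5 * (sd * sd) / (ss * ss) * (1.0 + (cs_ * cs_) / (cd * cd))
            if R > 1.0:
                R = 1.0
        if np.random.random() < R:
            do_reflect = True
    if do_reflect:
        ex2 = ex - 2.0 * a * nxv
        ey2 = ey - 2.0 * a * nyv
        ez2 = ez - 2.0 * a * nzv
        flag = 1
    else:
        disc = (1.0 - mu * mu) / (mu * mu * a * a) + 1.0
        if disc < 0.0:  # unreachable: sint < 1 implies disc >= 0
            return 0.0, 0.0, 0.0, 2
        g = (np.sqrt(disc) - 1.0) * mu * a
        ex2 = mu * ex + g * nxv
        ey2 = mu * ey + g * nyv
        ez2 = mu * ez + g * nzv
        flag = 0
    nrm = np.sqrt(ex2 * ex2 + ey2 * ey2 + ez2 * ez2)
    return ex2 / nrm, ey2 / nrm, ez2 / nrm, flag


@nb.njit(inline="always")
def _launch(launch_mode, q0, q1, q2, q3):
    if launch_mode == 1:  # uniform disc (circular beam)
        while True:
            ux = 2.0 * np.random.random() - 1.0
            uy = 2.0 * np.random.random() - 1.0
            if ux * ux + uy * uy <= 1.0:
                return q0 + q2 * ux, q1 + q2 * uy
    # rectangular window [q0, q1] x [q2, q3]
    return (q0 + np.random.random() * (q1 - q0),
            q2 + np.random.random() * (q3 - q2))


@nb.njit
def trace_spheres(centers, radii, cell_start, cell_items, cs, ncx, ncy, ncz,
                  sx, sy, sz, n_out, n_in, s, n_rays, max_steps, seed,
                  fl, gox, goy, goz, gp,
                  launch_mode, q0, q1, q2, q3, counts):
    np.random.seed(seed)
    eps = s * 0.01
    for _ray in range(n_rays):
        x, y = _launch(launch_mode, q0, q1, q2, q3)
        z = 0.0
        ex = 0.0
        ey = 0.0
        ez = 1.0
        cur = _find_sphere(x, y, z, centers, radii, cell_start, cell_items,
                           cs, ncx, ncy, ncz)
        steps = 0
        while True:
            if steps >= max_steps:
                counts[3] += 1
                break
            steps += 1
            qx = x + ex * s
            qy = y + ey * s
            qz = z + ez * s
            if (qz < 0.0 or qz >= sz or qx < 0.0 or qx > sx
                    or qy < 0.0 or qy > sy):
                t = _exit_travel(x, y, z, ex, ey, ez, qx, qy, qz, sx, sy, sz, s)
                _deposit(fl, gox, goy, goz, gp,
                         x + 0.5 * ex * t, y + 0.5 * ey * t, z + 0.5 * ez * t, t)
                if qz < 0.0:
                    counts[1] += 1
                elif qz >= sz:
                    counts[0] += 1
                else:
                    counts[2] += 1
                break
            nxt = _find_sphere(qx, qy, qz, centers, radii, cell_start,
                               cell_items, cs, ncx, ncy, ncz)
            if nxt == cur:
                _deposit(fl, gox, goy, goz, gp,
                         0.5 * (x + qx), 0.5 * (y + qy), 0.5 * (z + qz), s)
                x = qx
                y = qy
                z = qz
                continue
            # interface inside this step: locate the nearest crossing
            tb = -1.0
            jb = -1
            if cur >= 0:
                t = _sphere_exit_t(x, y, z, ex, ey, ez, centers[cur, 0],
                                   centers[cur, 1], centers[cur, 2], radii[cur])
                if 1e-12 < t <= s + 1e-9:
                    tb = t
                    jb = cur
            if nxt >= 0 and nxt != cur:
                t = _sphere_entry_t(x, y, z, ex, ey, ez, centers[nxt, 0],
                                    centers[nxt, 1], centers[nxt, 2], radii[nxt])
                if 1e-12 < t <= s + 1e-9 and (jb < 0 or t < tb):
                    tb = t
                    jb = nxt
            if jb < 0:
                # tangential/numerically degenerate change: accept the move
                counts[4] += 1
                _deposit(fl, gox, goy, goz, gp,
                         0.5 * (x + qx), 0.5 * (y + qy), 0.5 * (z + qz), s)
                x = qx
                y = qy
                z = qz
                cur = nxt
                continue
            if cur >= 0 and nxt >= 0 and nxt != cur:
                counts[4] += 1  # exit + immediate entry within one step
            cpx = x + ex * tb
            cpy = y + ey * tb
            cpz = z + ez * tb
            _deposit(fl, gox, goy, goz, gp,
                     0.5 * (x + cpx), 0.5 * (y + cpy), 0.5 * (z + cpz), tb)
            nxv = (cpx - centers[jb, 0]) / radii[jb]
            nyv = (cpy - centers[jb, 1]) / radii[jb]
            nzv = (cpz - centers[jb, 2]) / radii[jb]
            n1 = n_in if cur >= 0 else n_out
            n2 = n_out if jb == cur else n_in
            ex2, ey2, ez2, flag = _interact(ex, ey, ez, nxv, nyv, nzv, n1 / n2)
            if flag == 2:
                counts[2] += 1
                break
            ex = ex2
            ey = ey2
            ez = ez2
            x = cpx + ex * eps
            y = cpy + ey * eps
            z = cpz + ez * eps
            if z < 0.0:
                counts[1] += 1
                break
            if z >= sz:
                counts[0] += 1
                break
            if x < 0.0 or x > sx or y < 0.0 or y > sy:
                counts[2] += 1
                break
            cur = _find_sphere(x, y, z, centers, radii, cell_start, cell_items,
                               cs, ncx, ncy, ncz)
        counts[5] += steps


@nb.njit(inline="always")
def _in_mask(px, py, pz, occ, mox, moy, moz, mp):
    i = int(np.floor((px - mox) / mp))
    j = int(np.floor((py - moy) / mp))
    k = int(np.floor((pz - moz) / mp))
    if 0 <= i < occ.shape[0] and 0 <= j < occ.shape[1] and 0 <= k < occ.shape[2]:
        return occ[i, j, k] != 0
    return False


@nb.njit(inline="always")
def _trilinear(vol, mox, moy, moz, mp, px, py, pz):
    """Sample a voxel-center grid (value of voxel i at origin+(i+1/2)*pitch)."""
    ux = (px - mox) / mp - 0.5
    uy = (py - moy) / mp - 0.5
    uz = (pz - moz) / mp - 0.5
    nx0 = vol.shape[0]
    ny0 = vol.shape[1]
    nz0 = vol.shape[2]
    if ux < 0.0:
        ux = 0.0
    if uy < 0.0:
        uy = 0.0
    if uz < 0.0:
        uz = 0.0
    if ux > nx0 - 1.000001:
        ux = nx0 - 1.000001
    if uy > ny0 - 1.000001:
        uy = ny0 - 1.000001
    if uz > nz0 - 1.000001:
        uz = nz0 - 1.000001
    i0 = int(ux)
    j0 = int(uy)
    k0 = int(uz)
    fx = ux - i0
    fy = uy - j0
    fz = uz - k0
    i1 = i0 + 1
    j1 = j0 + 1
    k1 = k0 + 1
    return ((1 - fx) * ((1 - fy) * ((1 - fz) * vol[i0, j0, k0] + fz * vol[i0, j0, k1])
                        + fy * ((1 - fz) * vol[i0, j1, k0] + fz * vol[i0, j1, k1]))
            + fx * ((1 - fy) * ((1 - fz) * vol[i1, j0, k0] + fz * vol[i1, j0, k1])
                    + fy * ((1 - fz) * vol[i1, j1, k0] + fz * vol[i1, j1, k1])))


@nb.njit
def trace_mask(occ, gradx, grady, gradz, mox, moy, moz, mp,
               sx, sy, sz, n_out, n_in, s, n_rays, max_steps, seed,
               fl, gox, goy, goz, gp,
               launch_mode, q0, q1, q2, q3, counts):
    np.random.seed(seed)
    eps = s * 0.01
    tol = s * 0.01  # bisection tolerance for the crossing location
    for _ray in range(n_rays):
        x, y = _launch(launch_mode, q0, q1, q2, q3)
        z = 0.0
        ex = 0.0
        ey = 0.0
        ez = 1.0
        cur = _in_mask(x, y, z, occ, mox, moy, moz, mp)
        steps = 0
        while True:
            if steps >= max_steps:
                counts[3] += 1
                break
            steps += 1
            qx = x + ex * s
            qy = y + ey * s
            qz = z + ez * s
            if (qz < 0.0 or qz >= sz or qx < 0.0 or qx > sx
                    or qy < 0.0 or qy > sy):
                t = _exit_travel(x, y, z, ex, ey, ez, qx, qy, qz, sx, sy, sz, s)
                _deposit(fl, gox, goy, goz, gp,
                         x + 0.5 * ex * t, y + 0.5 * ey * t, z + 0.5 * ez * t, t)
                if qz < 0.0:
                    counts[1] += 1
                elif qz >= sz:
                    counts[0] += 1
                else:
                    counts[2] += 1
                break
            nxt = _in_mask(qx, qy, qz, occ, mox, moy, moz, mp)
            if nxt == cur:
                _deposit(fl, gox, goy, goz, gp,
                         0.5 * (x + qx), 0.5 * (y + qy), 0.5 * (z + qz), s)
                x = qx
                y = qy
                z = qz
                continue
            # bisect the binary membership change to tolerance s/100; the
            # crossing lands on the rasterized surface (+- half a voxel of
            # the true one), which bounds the geometric accuracy of mask
            # scenes at the voxel pitch
            tlo = 0.0
            thi = s
            while thi - tlo > tol:
                tm = 0.5 * (tlo + thi)
                if _in_mask(x + ex * tm, y + ey * tm, z + ez * tm,
                            occ, mox, moy, moz, mp) == cur:
                    tlo = tm
                else:
                    thi = tm
            tb = 0.5 * (tlo + thi)
            cpx = x + ex * tb
            cpy = y + ey * tb
            cpz = z + ez * tb
            _deposit(fl, gox, goy, goz, gp,
                     0.5 * (x + cpx), 0.5 * (y + cpy), 0.5 * (z + cpz), tb)
            gx = _trilinear(gradx, mox, moy, moz, mp, cpx, cpy, cpz)
            gy = _trilinear(grady, mox, moy, moz, mp, cpx, cpy, cpz)
            gz = _trilinear(gradz, mox, moy, moz, mp, cpx, cpy, cpz)
            gn = np.sqrt(gx * gx + gy * gy + gz * gz)
            if gn > 0.0:
                nxv = -gx / gn  # outward: smoothed occupancy grows inward
                nyv = -gy / gn
                nzv = -gz / gn
            else:
                nxv = -ex  # degenerate: treat as normal incidence
                nyv = -ey
                nzv = -ez
            if cur:
                n1 = n_in
                n2 = n_out
            else:
                n1 = n_out
                n2 = n_in
            ex2, ey2, ez2, flag = _interact(ex, ey, ez, nxv, nyv, nzv, n1 / n2)
            if flag == 2:
                counts[2] += 1
                break
            ex = ex2
            ey = ey2
            ez = ez2
            x = cpx + ex * eps
            y = cpy + ey * eps
            z = cpz + ez * eps
            if z < 0.0:
                counts[1] += 1
                break
            if z >= sz:
                counts[0] += 1
                break
            if x < 0.0 or x > sx or y < 0.0 or y > sy:
                counts[2] += 1
                break
            cur = _in_mask(x, y, z, occ, mox, moy, moz, mp)
        counts[5] += steps
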