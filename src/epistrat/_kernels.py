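"""Numba kernels for short-range force evaluation.

The inter-cellular Lennard-Jones forces are the hot loop (an n-body problem
with a hard cutoff), so candidate pairs are found with a cell-linked binning
pass and forces are accumulated over an explicit pair list.  All loops are
sequential with a fixed iteration order so that runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_pairs", "accumulate_inter", "accumulate_intra"]


@njit(cache=True)
def _bin_index(x, lo, inv_w, nbins):
    i = int((x - lo) * inv_w)
    if i < 0:
        i = 0
    elif i >= nbins:
        i = nbins - 1
    return i


@njit(cache=True)
def build_pairs(pos, cell_of, lx, ly, periodic_xy, cutoff):
    """Candidate element pairs (i < j, different cells) within ``cutoff``.

    x and y are wrapped into [0, lx) x [0, ly) for binning when
    ``periodic_xy``; z is unbounded and binned adaptively.  Returns an
    (m, 2) int64 array.
    """
    n = pos.shape[0]
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)

    # working (wrapped) coordinates
    wx = np.empty(n)
    wy = np.empty(n)
    wz = pos[:, 2]
    for i in range(n):
        if periodic_xy:
            wx[i] = pos[i, 0] % lx
            wy[i] = pos[i, 1] % ly
        else:
            wx[i] = pos[i, 0]
            wy[i] = pos[i, 1]

    xlo = 0.0 if periodic_xy else wx.min()
    ylo = 0.0 if periodic_xy else wy.min()
    xhi = lx if periodic_xy else wx.max() + 1e-9
    yhi = ly if periodic_xy else wy.max() + 1e-9
    zlo = wz.min()
    zhi = wz.max() + 1e-9

    nbx = max(1, int((xhi - xlo) / cutoff))
    nby = max(1, int((yhi - ylo) / cutoff))
    nbz = max(1, int((zhi - zlo) / cutoff))
    inv_wx = nbx / (xhi - xlo)
    inv_wy = nby / (yhi - ylo)
    inv_wz = nbz / (zhi - zlo)

    nbins = nbx * nby * nbz
    count = np.zeros(nbins, dtype=np.int64)
    binid = np.empty(n, dtype=np.int64)
    for i in range(n):
        bx = _bin_index(wx[i], xlo, inv_wx, nbx)
        by = _bin_index(wy[i], ylo, inv_wy, nby)
        bz = _bin_index(wz[i], zlo, inv_wz, nbz)
        b = (bx * nby + by) * nbz + bz
        binid[i] = b
        count[b] += 1
    start = np.zeros(nbins + 1, dtype=np.int64)
    for b in range(nbins):
        start[b + 1] = start[b] + count[b]
    order = np.empty(n, dtype=np.int64)
    fill = start[:-1].copy()
    for i in range(n):
        b = binid[i]
        order[fill[b]] = i
        fill[b] += 1

    c2 = cutoff * cutoff
    wrap_x = periodic_xy and nbx > 2
    wrap_y = periodic_xy and nby > 2

    # single pass into a preallocated list, grown on overflow
    cap = 512 * n + 1024
    pairs = np.empty((cap, 2), dtype=np.int64)
    m = 0
    overflow = False
    for bx in range(nbx):
        for by in range(nby):
            for bz in range(nbz):
                b = (bx * nby + by) * nbz + bz
                if start[b] == start[b + 1]:
                    continue
                for dx in range(-1, 2):
                    cx = bx + dx
                    if wrap_x:
                        cx = cx % nbx
                    elif cx < 0 or cx >= nbx:
                        continue
                    for dy in range(-1, 2):
                        cy = by + dy
                        if wrap_y:
                            cy = cy % nby
                        elif cy < 0 or cy >= nby:
                            continue
                        for dz in range(-1, 2):
                            cz = bz + dz
                            if cz < 0 or cz >= nbz:
                                continue
                            c = (cx * nby + cy) * nbz + cz
                            if c < b:
                                continue
                            same = c == b
                            for ii in range(start[b], start[b + 1]):
                                i = order[ii]
                                jj0 = ii + 1 if same else start[c]
                                for jj in range(jj0, start[c + 1]):
                                    j = order[jj]
                                    if cell_of[i] == cell_of[j]:
                                        continue
                                    ddx = wx[i] - wx[j]
                                    ddy = wy[i] - wy[j]
                                    if periodic_xy:
                                        if ddx > 0.5 * lx:
                                            ddx -= lx
                                        elif ddx < -0.5 * lx:
                                            ddx += lx
                                        if ddy > 0.5 * ly:
                                            ddy -= ly
                                        elif ddy < -0.5 * ly:
                                            ddy += ly
                                    ddz = wz[i] - wz[j]
                                    if ddx * ddx + ddy * ddy + ddz * ddz <= c2:
                                        if m >= cap:
                                            overflow = True
                                        else:
                                            if i < j:
                                                pairs[m, 0] = i
                                                pairs[m, 1] = j
                                            else:
                                                pairs[m, 0] = j
                                                pairs[m, 1] = i
                                        m += 1
    if overflow:
        raise RuntimeError(
            "neighbor pair list overflow: >96 candidate pairs per element"
        )
    return pairs[:m]


@njit(cache=True)
def accumulate_inter(
    pos, pairs, elem_class, forces,
    lx, ly, periodic_xy,
    fa, fb, eps, sigma, cutoff, rmin,
):
    """Add Lennard-Jones inter-cellular forces over the pair list.

    The pair strength is ``fa`` when both elements belong to cells of the
    same class, ``fb`` otherwise; the interaction is truncated to exactly
    zero beyond ``cutoff`` and its magnitude is clamped at the value attained
    at separation ``rmin`` (returns the number of clamped pairs).
    """
    c2 = cutoff * cutoff
    s6 = sigma ** 6
    s12 = s6 * s6
    n_clamped = 0
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic_xy:
            dx -= lx * np.rint(dx / lx)
            dy -= ly * np.rint(dy / ly)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > c2 or r2 == 0.0:
            continue
        if r2 < rmin * rmin:
            r2 = rmin * rmin
            n_clamped += 1
        f = fa if elem_class[i] == elem_class[j] else fb
        inv_r2 = 1.0 / r2
        inv_r6 = inv_r2 * inv_r2 * inv_r2
        # F(r) * (1/r): magnitude of -dV/dr along the separation, over r
        fac = f * eps * (12.0 * s12 * inv_r6 * inv_r6 - 6.0 * s6 * inv_r6) * inv_r2
        fx = fac * dx
        fy = fac * dy
        fz = fac * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return n_clamped


@njit(cache=True)
def relax_field(s, source, dfx, dfy, dfz, ds, dt, h2, n_substeps,
                periodic_xy, top_absorbing):
    """Forward-Euler relaxation of the reaction-diffusion field.

    ``dfx/dfy/dfz`` are face-averaged diffusivities on the +x/+y/+z faces
    (outer non-periodic faces carry zero flux).  Returns the number of
    negative-clip events.
    """
    nx, ny, nz = s.shape
    new = np.empty_like(s)
    n_clip = 0
    for _ in range(n_substeps):
        for i in range(nx):
            ip = (i + 1) % nx
            im = (i - 1) % nx
            x_hi_edge = i == nx - 1 and not periodic_xy
            x_lo_edge = i == 0 and not periodic_xy
            for j in range(ny):
                jp = (j + 1) % ny
                jm = (j - 1) % ny
                y_hi_edge = j == ny - 1 and not periodic_xy
                y_lo_edge = j == 0 and not periodic_xy
                for k in range(nz):
                    v = s[i, j, k]
                    div = 0.0
                    if not x_hi_edge:
                        div += dfx[i, j, k] * (s[ip, j, k] - v)
                    if not x_lo_edge:
                        div -= dfx[im, j, k] * (v - s[im, j, k])
                    if not y_hi_edge:
                        div += dfy[i, j, k] * (s[i, jp, k] - v)
                    if not y_lo_edge:
                        div -= dfy[i, jm, k] * (v - s[i, jm, k])
                    if k < nz - 1:
                        div += dfz[i, j, k] * (s[i, j, k + 1] - v)
                    if k > 0:
                        div -= dfz[i, j, k - 1] * (v - s[i, j, k - 1])
                    out = v + dt * (div / h2 - ds * v + source[i, j, k])
                    if out < 0.0:
                        out = 0.0
                        n_clip += 1
                    new[i, j, k] = out
        s[:, :, :] = new
        if top_absorbing:
            s[:, :, nz - 1] = 0.0
    return n_clip


@njit(cache=True)
def accumulate_intra(pos, cell_start, forces, mu, r0):
    """Add the all-pairs harmonic spring forces within each cell."""
    ncells = cell_start.shape[0] - 1
    for c in range(ncells):
        a = cell_start[c]
        b = cell_start[c + 1]
        for i in range(a, b):
            for j in range(i + 1, b):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if r == 0.0:
                    continue
                fac = -mu * (r - r0) / r
                fx = fac * dx
                fy = fac * dy
                fz = fac * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
    return 0
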