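"""Numba-compiled inner loops: diffusion stencil, mechanics, voxel sampling.

All kernels operate on plain numpy arrays so the surrounding modules stay
testable without touching compiled code paths directly. Distances are in um,
times in seconds unless noted.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def diffuse(conc, mask, source, sink, D, k, h, dt_sub, n_sub):
    """Explicit finite-difference update of diffusion + decay + source - sink.

    No-flux boundaries on every face of the masked region (neighbour fluxes
    are only exchanged between in-mask voxels). ``sink`` is a nonnegative
    removal rate (conc/s) clamped per substep to the available mass so the
    field stays nonnegative. Returns (source_in, decay_out, sink_out,
    n_clamped) as concentration-sums (multiply by voxel volume for mass).
    """
    nx, ny, nz = conc.shape
    work = np.empty_like(conc)
    alpha = D / (h * h)
    # decay integrated exactly per substep (operator splitting), so a pure
    # decay problem reproduces the closed-form exponential to roundoff
    decay_factor = np.exp(-k * dt_sub)
    source_in = 0.0
    decay_out = 0.0
    sink_out = 0.0
    n_clamped = 0
    for _ in range(n_sub):
        for i in range(nx):
            for j in range(ny):
                for l in range(nz):
                    if not mask[i, j, l]:
                        work[i, j, l] = 0.0
                        continue
                    c = conc[i, j, l]
                    lap = 0.0
                    if i > 0 and mask[i - 1, j, l]:
                        lap += conc[i - 1, j, l] - c
                    if i < nx - 1 and mask[i + 1, j, l]:
                        lap += conc[i + 1, j, l] - c
                    if j > 0 and mask[i, j - 1, l]:
                        lap += conc[i, j - 1, l] - c
                    if j < ny - 1 and mask[i, j + 1, l]:
                        lap += conc[i, j + 1, l] - c
                    if l > 0 and mask[i, j, l - 1]:
                        lap += conc[i, j, l - 1] - c
                    if l < nz - 1 and mask[i, j, l + 1]:
                        lap += conc[i, j, l + 1] - c
                    new = c + dt_sub * (alpha * lap + source[i, j, l])
                    source_in += source[i, j, l] * dt_sub
                    decayed = new * decay_factor
                    decay_out += new - decayed
                    new = decayed
                    removal = sink[i, j, l] * dt_sub
                    if removal > new:
                        if removal > 0.0:
                            n_clamped += 1
                        removal = max(new, 0.0)
                    new -= removal
                    sink_out += removal
                    if new < 0.0:
                        new = 0.0
                    work[i, j, l] = new
        conc[:, :, :] = work
    return source_in, decay_out, sink_out, n_clamped


@njit(cache=True)
def sample_local_mean(conc, mask, pos, rad, ox, oy, oz, h):
    """Mean concentration over in-mask voxels whose centre lies within each
    cell's sphere; falls back to the nearest in-mask voxel when the sphere
    covers no voxel centre. Returns -1 for a cell fully outside the grid."""
    n = pos.shape[0]
    nx, ny, nz = conc.shape
    out = np.empty(n)
    for c in range(n):
        x, y, z = pos[c, 0], pos[c, 1], pos[c, 2]
        r = rad[c]
        i0 = max(int(np.floor((x - r - ox) / h)), 0)
        i1 = min(int(np.floor((x + r - ox) / h)), nx - 1)
        j0 = max(int(np.floor((y - r - oy) / h)), 0)
        j1 = min(int(np.floor((y + r - oy) / h)), ny - 1)
        l0 = max(int(np.floor((z - r - oz) / h)), 0)
        l1 = min(int(np.floor((z + r - oz) / h)), nz - 1)
        total = 0.0
        count = 0
        best = 1.0e30
        bi = -1
        bj = -1
        bl = -1
        for i in range(i0, i1 + 1):
            cx = ox + (i + 0.5) * h
            for j in range(j0, j1 + 1):
                cy = oy + (j + 0.5) * h
                for l in range(l0, l1 + 1):
                    if not mask[i, j, l]:
                        continue
                    cz = oz + (l + 0.5) * h
                    d2 = (cx - x) ** 2 + (cy - y) ** 2 + (cz - z) ** 2
                    if d2 <= r * r:
                        total += conc[i, j, l]
                        count += 1
                    if d2 < best:
                        best = d2
                        bi, bj, bl = i, j, l
        if count > 0:
            out[c] = total / count
            continue
        if i0 > i1 or j0 > j1 or l0 > l1:
            # sphere does not even overlap the grid box: fully outside
            out[c] = -1.0
            continue
        if bi < 0:
            # bounding box held no in-mask voxel (cell at the rim or just
            # outside); fall back to the nearest in-mask voxel globally
            for i in range(nx):
                cx = ox + (i + 0.5) * h
                for j in range(ny):
                    cy = oy + (j + 0.5) * h
                    for l in range(nz):
                        if not mask[i, j, l]:
                            continue
                        cz = oz + (l + 0.5) * h
                        d2 = (cx - x) ** 2 + (cy - y) ** 2 + (cz - z) ** 2
                        if d2 < best:
                            best = d2
                            bi, bj, bl = i, j, l
        if bi >= 0:
            out[c] = conc[bi, bj, bl]
        else:
            out[c] = -1.0
    return out


@njit(cache=True)
def deposit_cell_rates(target, mask, pos, rad, rates, ox, oy, oz, h):
    """Add ``rates[c]`` to every in-mask voxel whose centre lies inside cell
    c's sphere (nearest voxel as fallback). Used for thymocyte IL-7 sinks and
    autocrine sources."""
    n = pos.shape[0]
    nx, ny, nz = target.shape
    for c in range(n):
        if rates[c] == 0.0:
            continue
        x, y, z = pos[c, 0], pos[c, 1], pos[c, 2]
        r = rad[c]
        i0 = max(int(np.floor((x - r - ox) / h)), 0)
        i1 = min(int(np.floor((x + r - ox) / h)), nx - 1)
        j0 = max(int(np.floor((y - r - oy) / h)), 0)
        j1 = min(int(np.floor((y + r - oy) / h)), ny - 1)
        l0 = max(int(np.floor((z - r - oz) / h)), 0)
        l1 = min(int(np.floor((z + r - oz) / h)), nz - 1)
        hit = False
        best = 1.0e30
        bi, bj, bl = -1, -1, -1
        for i in range(i0, i1 + 1):
            cx = ox + (i + 0.5) * h
            for j in range(j0, j1 + 1):
                cy = oy + (j + 0.5) * h
                for l in range(l0, l1 + 1):
                    if not mask[i, j, l]:
                        continue
                    cz = oz + (l + 0.5) * h
                    d2 = (cx - x) ** 2 + (cy - y) ** 2 + (cz - z) ** 2
                    if d2 <= r * r:
                        target[i, j, l] += rates[c]
                        hit = True
                    if d2 < best:
                        best = d2
                        bi, bj, bl = i, j, l
        if not hit and bi >= 0:
            target[bi, bj, bl] += rates[c]


@njit(cache=True)
def mechanics_step(
    pos,
    rad,
    exit_bound,
    tec_centers,
    tec_radii,
    domain_radius,
    wall_y,
    relax,
    adh_ratio,
    adh_range,
    contact_range,
):
    """Passive displacements from cell-cell, cell-TEC and wall interactions.

    Overdamped: the displacement is ``relax`` times the linear-spring overlap
    (repulsive inside contact, weakly adhesive out to ``adh_range`` times the
    contact distance). TEC spheres exert forces but never move. Exit-bound
    cells ignore the outer radial wall so they can physically leave. Returns
    (disp, notch_contact) where notch_contact marks cells whose surface gap
    to any Dll4+ TEC sphere is <= contact_range.
    """
    n = pos.shape[0]
    m = tec_centers.shape[0]
    disp = np.zeros((n, 3))
    contact = np.zeros(n, dtype=np.uint8)
    n_clipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            d2 = dx * dx + dy * dy
            cdist = rad[i] + rad[j]
            cut = adh_range * cdist
            if d2 > cut * cut or d2 == 0.0:
                continue
            d = np.sqrt(d2)
            if d < cdist:
                f = relax * (cdist - d)
            else:
                f = -relax * adh_ratio * (d - cdist)
            ux = dx / d
            uy = dy / d
            disp[i, 0] += f * ux
            disp[i, 1] += f * uy
            disp[j, 0] -= f * ux
            disp[j, 1] -= f * uy
        for t in range(m):
            dx = pos[i, 0] - tec_centers[t, 0]
            dy = pos[i, 1] - tec_centers[t, 1]
            d2 = dx * dx + dy * dy
            cdist = rad[i] + tec_radii[t]
            reach = cdist + contact_range
            cut = adh_range * cdist
            if cut < reach:
                cut = reach
            if d2 > cut * cut or d2 == 0.0:
                continue
            d = np.sqrt(d2)
            if d <= reach:
                contact[i] = 1
            if d < cdist:
                f = relax * (cdist - d)
            elif d < adh_range * cdist:
                f = -relax * adh_ratio * (d - cdist)
            else:
                f = 0.0
            if f != 0.0:
                disp[i, 0] += f * dx / d
                disp[i, 1] += f * dy / d
        # cap the interaction displacement at one cell radius (runaway
        # overlap protection; counted so the caller can warn)
        dmag = np.sqrt(disp[i, 0] ** 2 + disp[i, 1] ** 2)
        if dmag > rad[i]:
            n_clipped += 1
            scale = rad[i] / dmag
            disp[i, 0] *= scale
            disp[i, 1] *= scale
        # confinement: midline chord wall and outer radial wall (projected
        # back fully so cells never leave the slice except through exit)
        if pos[i, 1] + disp[i, 1] > wall_y - rad[i]:
            disp[i, 1] += wall_y - rad[i] - (pos[i, 1] + disp[i, 1])
        if exit_bound[i] == 0:
            rx = pos[i, 0] + disp[i, 0]
            ry = pos[i, 1] + disp[i, 1]
            rr = np.sqrt(rx * rx + ry * ry)
            lim = domain_radius - rad[i]
            if rr > lim and rr > 0.0:
                pull = rr - lim
                disp[i, 0] -= pull * rx / rr
                disp[i, 1] -= pull * ry / rr
    return disp, contact, n_clipped


@njit(cache=True)
def pair_energy(pos, rad, relax, adh_ratio, adh_range):
    """Total pair potential (consistent with the force law), for audits."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            d = np.sqrt(dx * dx + dy * dy)
            cdist = rad[i] + rad[j]
            if d < cdist:
                e += 0.5 * relax * (cdist - d) ** 2
            elif d < adh_range * cdist:
                e += 0.5 * relax * adh_ratio * (d - cdist) ** 2 \
                    - 0.5 * relax * adh_ratio * (adh_range - 1.0) ** 2 * cdist ** 2
    return e
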