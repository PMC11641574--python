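"""Numba kernels for the solvent-bead short-range force loop.

The only O(N) hot path in the model is the WCA interaction between
solvent particles and motor beads.  Beads are binned into a cell grid
with edge >= the largest search radius; candidate solvent particles
scan the 27 surrounding cells, either directly (single-step reference
path) or once per MD interval to build a candidate -> bead Verlet
neighbor list for the fused multi-substep integrator.  The force pass
also records, per solvent particle, whether it sits inside the reaction
zone of any E1 or E2 bead and whether it is inside *any* WCA cutoff
(species flips are only allowed at exactly zero pair energy, so the
reaction step needs that flag).
"""

import numba as nb
import numpy as np


@nb.njit(cache=True)
def bead_cell_csr(bpos, edge, ncx, ncy, ncz):
    """Bin bead positions (wrapped into the box) into a CSR cell list."""
    nb_ = bpos.shape[0]
    ncells = ncx * ncy * ncz
    cell = np.empty(nb_, dtype=np.int64)
    for j in range(nb_):
        cx = int(bpos[j, 0] / edge)
        cy = int(bpos[j, 1] / edge)
        cz = int(bpos[j, 2] / edge)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        cell[j] = (cx * ncy + cy) * ncz + cz
    counts = np.zeros(ncells + 1, dtype=np.int64)
    for j in range(nb_):
        counts[cell[j] + 1] += 1
    for c in range(ncells):
        counts[c + 1] += counts[c]
    order = np.empty(nb_, dtype=np.int64)
    fill = counts[:-1].copy()
    for j in range(nb_):
        order[fill[cell[j]]] = j
        fill[cell[j]] += 1
    return counts, order


@nb.njit(cache=True)
def select_and_stream(spos, svel, box, center, rbound2, dt):
    """Single pass over the solvent: particles inside the motor bounding
    sphere become candidates; everything else streams ballistically over
    the interval (force-free) and is wrapped back into the box."""
    n = spos.shape[0]
    flag = np.empty(n, dtype=np.uint8)
    ncand = 0
    for i in range(n):
        dx = spos[i, 0] - center[0]
        dy = spos[i, 1] - center[1]
        dz = spos[i, 2] - center[2]
        if dx > 0.5 * box[0]:
            dx -= box[0]
        elif dx < -0.5 * box[0]:
            dx += box[0]
        if dy > 0.5 * box[1]:
            dy -= box[1]
        elif dy < -0.5 * box[1]:
            dy += box[1]
        if dz > 0.5 * box[2]:
            dz -= box[2]
        elif dz < -0.5 * box[2]:
            dz += box[2]
        if dx * dx + dy * dy + dz * dz < rbound2:
            flag[i] = 1
            ncand += 1
        else:
            flag[i] = 0
            for d in range(3):
                x = spos[i, d] + dt * svel[i, d]
                if x >= box[d]:
                    x -= box[d]
                    if x >= box[d]:
                        x = x % box[d]
                elif x < 0.0:
                    x += box[d]
                    if x < 0.0:
                        x = x % box[d]
                spos[i, d] = x
    cand = np.empty(ncand, dtype=np.int64)
    k = 0
    for i in range(n):
        if flag[i] == 1:
            cand[k] = i
            k += 1
    return cand


@nb.njit(cache=True)
def _neighbor_list(spos, cand, bpos, box, edge, ncx, ncy, ncz,
                   cellstart, cellorder, rlist2):
    """Candidate -> bead Verlet list (CSR) within sqrt(rlist2)."""
    ncand = cand.shape[0]
    hx, hy, hz = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    nstart = np.empty(ncand + 1, dtype=np.int64)
    cap = 16 * ncand + 64
    nlist = np.empty(cap, dtype=np.int64)
    fill = 0
    if True:
        for a in range(ncand):
            nstart[a] = fill
            i = cand[a]
            x, y, z = spos[i, 0], spos[i, 1], spos[i, 2]
            cx = int(x / edge)
            cy = int(y / edge)
            cz = int(z / edge)
            if cx >= ncx:
                cx = ncx - 1
            if cy >= ncy:
                cy = ncy - 1
            if cz >= ncz:
                cz = ncz - 1
            for ox in range(-1, 2):
                gx = cx + ox
                if gx < 0:
                    gx += ncx
                elif gx >= ncx:
                    gx -= ncx
                for oy in range(-1, 2):
                    gy = cy + oy
                    if gy < 0:
                        gy += ncy
                    elif gy >= ncy:
                        gy -= ncy
                    for oz in range(-1, 2):
                        gz = cz + oz
                        if gz < 0:
                            gz += ncz
                        elif gz >= ncz:
                            gz -= ncz
                        cc = (gx * ncy + gy) * ncz + gz
                        for p in range(cellstart[cc], cellstart[cc + 1]):
                            j = cellorder[p]
                            dx = x - bpos[j, 0]
                            dy = y - bpos[j, 1]
                            dz = z - bpos[j, 2]
                            if dx > hx:
                                dx -= box[0]
                            elif dx < -hx:
                                dx += box[0]
                            if dy > hy:
                                dy -= box[1]
                            elif dy < -hy:
                                dy += box[1]
                            if dz > hz:
                                dz -= box[2]
                            elif dz < -hz:
                                dz += box[2]
                            if dx * dx + dy * dy + dz * dz < rlist2:
                                if fill < cap:
                                    nlist[fill] = j
                                fill += 1
    nstart[ncand] = fill
    # cap is ~3x the geometric packing bound, so overflow cannot happen
    # with physical configurations; signal it anyway rather than miscount
    if fill > cap:
        nstart[ncand] = -1
    return nstart, nlist


@nb.njit(cache=True)
def verlet_substeps(spos, svel, fsolv, sspecies, cand,
                    mpos, mvel, fmot, mmass, bead_idx, bspecies_bead,
                    spring_i, spring_j, spring_r0, ks,
                    eps, sigma2_by_type, rc2_by_type, rrxn2_by_type,
                    box, edge, ncx, ncy, ncz, rlist2,
                    n_inner, dt_outer, ms):
    """``n_inner`` fused velocity-Verlet substeps over one MD interval.

    A candidate -> bead Verlet neighbor list is built once at entry (its
    skin exceeds any possible relative displacement within the interval
    by a wide margin); substeps then evaluate only listed pairs.
    ``fsolv``/``fmot`` must hold the forces at the entry positions and
    are left holding the forces at the exit positions.  Returns the final
    potential energy, per-candidate reaction-zone/cutoff flags, and an
    overlap index (-1 if none).
    """
    ncand = cand.shape[0]
    nbead = bead_idx.shape[0]
    nmot = mpos.shape[0]
    dt = dt_outer / n_inner
    half = 0.5 * dt
    bpos_w = np.empty((nbead, 3))
    for k in range(nbead):
        for d in range(3):
            bpos_w[k, d] = mpos[bead_idx[k], d] % box[d]
    cellstart, cellorder = bead_cell_csr(bpos_w, edge, ncx, ncy, ncz)
    nstart, nlist = _neighbor_list(spos, cand, bpos_w, box, edge,
                                   ncx, ncy, ncz, cellstart, cellorder,
                                   rlist2)
    fb = np.empty((nbead, 3))
    zone1 = np.zeros(ncand, dtype=np.uint8)
    zone2 = np.zeros(ncand, dtype=np.uint8)
    anycut = np.zeros(ncand, dtype=np.uint8)
    utot = 0.0
    overlap = -1
    if nstart[ncand] < 0:  # neighbor-list overflow: refuse to integrate
        return utot, zone1, zone2, anycut, -2
    hx, hy, hz = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    for _ in range(n_inner):
        # half kick
        for a in range(ncand):
            i = cand[a]
            svel[i, 0] += half * fsolv[i, 0] / ms
            svel[i, 1] += half * fsolv[i, 1] / ms
            svel[i, 2] += half * fsolv[i, 2] / ms
        for k in range(nmot):
            invm = half / mmass[k]
            mvel[k, 0] += invm * fmot[k, 0]
            mvel[k, 1] += invm * fmot[k, 1]
            mvel[k, 2] += invm * fmot[k, 2]
        # drift
        for a in range(ncand):
            i = cand[a]
            for d in range(3):
                x = spos[i, d] + dt * svel[i, d]
                if x >= box[d]:
                    x -= box[d]
                elif x < 0.0:
                    x += box[d]
                spos[i, d] = x
        for k in range(nmot):
            for d in range(3):
                mpos[k, d] += dt * mvel[k, d]
        for k in range(nbead):
            for d in range(3):
                bpos_w[k, d] = mpos[bead_idx[k], d] % box[d]
        # forces at new positions
        utot = 0.0
        for k in range(nbead):
            fb[k, 0] = 0.0
            fb[k, 1] = 0.0
            fb[k, 2] = 0.0
        for a in range(ncand):
            i = cand[a]
            x, y, z = spos[i, 0], spos[i, 1], spos[i, 2]
            si = sspecies[i]
            fsx = 0.0
            fsy = 0.0
            fsz = 0.0
            z1 = np.uint8(0)
            z2 = np.uint8(0)
            ac = np.uint8(0)
            for p in range(nstart[a], nstart[a + 1]):
                j = nlist[p]
                dx = x - bpos_w[j, 0]
                dy = y - bpos_w[j, 1]
                dz = z - bpos_w[j, 2]
                if dx > hx:
                    dx -= box[0]
                elif dx < -hx:
                    dx += box[0]
                if dy > hy:
                    dy -= box[1]
                elif dy < -hy:
                    dy += box[1]
                if dz > hz:
                    dz -= box[2]
                elif dz < -hz:
                    dz += box[2]
                r2 = dx * dx + dy * dy + dz * dz
                bt = bspecies_bead[j] - 1
                if bt == 1 and r2 < rrxn2_by_type[1]:
                    z1 = np.uint8(1)
                elif bt == 2 and r2 < rrxn2_by_type[2]:
                    z2 = np.uint8(1)
                if r2 < rc2_by_type[bt]:
                    ac = np.uint8(1)
                    if r2 < 1e-12:
                        overlap = i
                        continue
                    e = eps[si, bt]
                    s2 = sigma2_by_type[bt] / r2
                    s6 = s2 * s2 * s2
                    s12 = s6 * s6
                    utot += 4.0 * e * (s12 - s6 + 0.25)
                    fr = 24.0 * e * (2.0 * s12 - s6) / r2
                    fsx += fr * dx
                    fsy += fr * dy
                    fsz += fr * dz
                    fb[j, 0] -= fr * dx
                    fb[j, 1] -= fr * dy
                    fb[j, 2] -= fr * dz
            fsolv[i, 0] = fsx
            fsolv[i, 1] = fsy
            fsolv[i, 2] = fsz
            zone1[a] = z1
            zone2[a] = z2
            anycut[a] = ac
        for k in range(nmot):
            fmot[k, 0] = 0.0
            fmot[k, 1] = 0.0
            fmot[k, 2] = 0.0
        # springs
        for s in range(spring_i.shape[0]):
            i = spring_i[s]
            j = spring_j[s]
            dx = mpos[i, 0] - mpos[j, 0]
            dy = mpos[i, 1] - mpos[j, 1]
            dz = mpos[i, 2] - mpos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            stretch = r - spring_r0[s]
            utot += 0.5 * ks * stretch * stretch
            fr = -ks * stretch / r
            fmot[i, 0] += fr * dx
            fmot[i, 1] += fr * dy
            fmot[i, 2] += fr * dz
            fmot[j, 0] -= fr * dx
            fmot[j, 1] -= fr * dy
            fmot[j, 2] -= fr * dz
        for k in range(nbead):
            i = bead_idx[k]
            fmot[i, 0] += fb[k, 0]
            fmot[i, 1] += fb[k, 1]
            fmot[i, 2] += fb[k, 2]
        # half kick with new forces
        for a in range(ncand):
            i = cand[a]
            svel[i, 0] += half * fsolv[i, 0] / ms
            svel[i, 1] += half * fsolv[i, 1] / ms
            svel[i, 2] += half * fsolv[i, 2] / ms
        for k in range(nmot):
            invm = half / mmass[k]
            mvel[k, 0] += invm * fmot[k, 0]
            mvel[k, 1] += invm * fmot[k, 1]
            mvel[k, 2] += invm * fmot[k, 2]
    return utot, zone1, zone2, anycut, overlap


@nb.njit(cache=True)
def solvent_bead_forces(spos, sspecies, cand, bpos, bspecies, eps,
                        sigma2_by_type, rc2_by_type, rrxn2_by_type,
                        box, edge, ncx, ncy, ncz, cellstart, cellorder):
    """WCA forces between candidate solvent particles and beads.

    Parameters are arrays indexed as follows: ``bspecies`` in {1, 2, 3}
    (E0/E1/E2); ``eps`` is the (3 solvent, 3 bead) well-depth table;
    ``*_by_type`` are squared radii indexed by bead type - 1.

    Returns per-candidate solvent forces, per-bead forces, the total pair
    potential energy, and per-candidate flags: inside an E1 reaction
    zone, inside an E2 reaction zone, inside any WCA cutoff, and an
    overlap error flag (solvent essentially on top of a bead).
    """
    ncand = cand.shape[0]
    fs = np.zeros((ncand, 3))
    fb = np.zeros((bpos.shape[0], 3))
    zone1 = np.zeros(ncand, dtype=np.uint8)
    zone2 = np.zeros(ncand, dtype=np.uint8)
    anycut = np.zeros(ncand, dtype=np.uint8)
    utot = 0.0
    overlap = -1
    hx, hy, hz = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    for a in range(ncand):
        i = cand[a]
        x, y, z = spos[i, 0], spos[i, 1], spos[i, 2]
        cx = int(x / edge)
        cy = int(y / edge)
        cz = int(z / edge)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        si = sspecies[i]
        for ox in range(-1, 2):
            gx = cx + ox
            if gx < 0:
                gx += ncx
            elif gx >= ncx:
                gx -= ncx
            for oy in range(-1, 2):
                gy = cy + oy
                if gy < 0:
                    gy += ncy
                elif gy >= ncy:
                    gy -= ncy
                for oz in range(-1, 2):
                    gz = cz + oz
                    if gz < 0:
                        gz += ncz
                    elif gz >= ncz:
                        gz -= ncz
                    cc = (gx * ncy + gy) * ncz + gz
                    for p in range(cellstart[cc], cellstart[cc + 1]):
                        j = cellorder[p]
                        dx = x - bpos[j, 0]
                        dy = y - bpos[j, 1]
                        dz = z - bpos[j, 2]
                        if dx > hx:
                            dx -= box[0]
                        elif dx < -hx:
                            dx += box[0]
                        if dy > hy:
                            dy -= box[1]
                        elif dy < -hy:
                            dy += box[1]
                        if dz > hz:
                            dz -= box[2]
                        elif dz < -hz:
                            dz += box[2]
                        r2 = dx * dx + dy * dy + dz * dz
                        bt = bspecies[j] - 1
                        if bt == 1 and r2 < rrxn2_by_type[1]:
                            zone1[a] = 1
                        elif bt == 2 and r2 < rrxn2_by_type[2]:
                            zone2[a] = 1
                        if r2 < rc2_by_type[bt]:
                            anycut[a] = 1
                            if r2 < 1e-12:
                                overlap = i
                                continue
                            e = eps[si, bt]
                            s2 = sigma2_by_type[bt] / r2
                            s6 = s2 * s2 * s2
                            s12 = s6 * s6
                            utot += 4.0 * e * (s12 - s6 + 0.25)
                            fr = 24.0 * e * (2.0 * s12 - s6) / r2
                            fs[a, 0] += fr * dx
                            fs[a, 1] += fr * dy
                            fs[a, 2] += fr * dz
                            fb[j, 0] -= fr * dx
                            fb[j, 1] -= fr * dy
                            fb[j, 2] -= fr * dz
    return fs, fb, utot, zone1, zone2, anycut, overlap
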