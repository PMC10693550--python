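"""Numba kernels: neighbor lists, pair/bonded forces, Langevin integration.

Everything here operates on the flat arrays of
:class:`ccphase.topology.SystemTopology`.  Units follow the GROMACS
convention (nm, ps, kJ/mol, amu, K), which is internally consistent:
1 kJ/mol == 1 amu nm^2/ps^2.

Coordinates are kept *unwrapped* (they may wander outside the box); all
distances use the minimum-image convention, and wrapping happens only when
binning beads into cells.  Saved frames therefore carry continuous
coordinates, which analysis can wrap or difference as needed.

Two Verlet lists are kept.  The sticky list is a distance filter over the
*statically complementary* bead pairs (matrix-attractive types with
matching registries on distinct segments — the only pairs that can ever
feel the sticky attraction), which the caller enumerates once per topology.
The WCA list comes from a short-cutoff cell scan over everything else.
Both potentials switch to a constant-force linear continuation below a
floor distance, so deep overlaps from packing relax under bounded forces.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KB = 0.0083144621  # kJ/mol/K


# ---------------------------------------------------------------------------
# neighbor lists
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _is_complementary(i, j, type_id, registry, coil_len, coil_seg, rule):
    t1 = type_id[i]
    t2 = type_id[j]
    if t1 < 0 or t2 < 0:
        return False
    o = rule[t1, t2]
    if o == 0 or coil_seg[i] == coil_seg[j]:
        return False
    if o == 1:
        return registry[i] == registry[j]
    return coil_len[i] == coil_len[j] and registry[j] == coil_len[i] + 1 - registry[i]


@njit(cache=True)
def wrap_into_box(pos, box, wpos):
    for i in range(pos.shape[0]):
        wpos[i, 0] = pos[i, 0] - box[0] * math.floor(pos[i, 0] / box[0])
        wpos[i, 1] = pos[i, 1] - box[1] * math.floor(pos[i, 1] / box[1])
        wpos[i, 2] = pos[i, 2] - box[2] * math.floor(pos[i, 2] / box[2])


@njit(cache=True)
def filter_sticky_pairs(wpos, box, static_pairs, cutoff, pairs_s):
    """Static complementary pairs currently within ``cutoff`` (min image)."""
    c2 = cutoff * cutoff
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    m = 0
    for p in range(static_pairs.shape[0]):
        i = static_pairs[p, 0]
        j = static_pairs[p, 1]
        dx = wpos[i, 0] - wpos[j, 0]
        dy = wpos[i, 1] - wpos[j, 1]
        dz = wpos[i, 2] - wpos[j, 2]
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
        if dx * dx + dy * dy + dz * dz < c2:
            pairs_s[m, 0] = i
            pairs_s[m, 1] = j
            m += 1
    return m


@njit(cache=True)
def build_wca_pairs(
    wpos,
    box,
    cutoff,
    chain_id,
    type_id,
    registry,
    coil_len,
    coil_seg,
    rule,
    pairs_w,
):
    """Cell/all-pairs scan for repulsive-core pairs within ``cutoff``.

    Excludes bonded 1-2/1-3 intra-chain pairs and statically complementary
    pairs (those live on the sticky list, which carries its own repulsion).
    Returns the count, or -1 on capacity overflow.
    """
    n = wpos.shape[0]
    cap = pairs_w.shape[0]
    c2 = cutoff * cutoff
    m = 0
    ncx = int(box[0] / cutoff)
    ncy = int(box[1] / cutoff)
    ncz = int(box[2] / cutoff)
    use_cells = (
        ncx >= 3 and ncy >= 3 and ncz >= 3 and n >= 200
        and ncx * ncy * ncz <= 16 * n
    )

    if not use_cells:
        hx = 0.5 * box[0]
        hy = 0.5 * box[1]
        hz = 0.5 * box[2]
        for i in range(n):
            for j in range(i + 1, n):
                dx = wpos[i, 0] - wpos[j, 0]
                dy = wpos[i, 1] - wpos[j, 1]
                dz = wpos[i, 2] - wpos[j, 2]
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
                if dx * dx + dy * dy + dz * dz >= c2:
                    continue
                if chain_id[i] == chain_id[j] and j - i <= 2:
                    continue
                if _is_complementary(i, j, type_id, registry, coil_len, coil_seg, rule):
                    continue
                if m >= cap:
                    return -1
                pairs_w[m, 0] = i
                pairs_w[m, 1] = j
                m += 1
        return m

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int32)
    nxt = np.full(n, -1, dtype=np.int32)
    for i in range(n):
        ix = min(int(wpos[i, 0] / box[0] * ncx), ncx - 1)
        iy = min(int(wpos[i, 1] / box[1] * ncy), ncy - 1)
        iz = min(int(wpos[i, 2] / box[2] * ncz), ncz - 1)
        c = ix + ncx * (iy + ncy * iz)
        nxt[i] = head[c]
        head[c] = i

    for iz in range(ncz):
        for iy in range(ncy):
            for ix in range(ncx):
                c = ix + ncx * (iy + ncy * iz)
                if head[c] < 0:
                    continue
                for dz in range(0, 2):
                    for dy in range(-1, 2):
                        for dx in range(-1, 2):
                            if dz == 0 and dy < 0:
                                continue
                            if dz == 0 and dy == 0 and dx < 0:
                                continue
                            jxr = ix + dx
                            jyr = iy + dy
                            jzr = iz + dz
                            sx = 0.0
                            sy = 0.0
                            sz = 0.0
                            if jxr == ncx:
                                jxr = 0
                                sx = box[0]
                            elif jxr < 0:
                                jxr = ncx - 1
                                sx = -box[0]
                            if jyr == ncy:
                                jyr = 0
                                sy = box[1]
                            elif jyr < 0:
                                jyr = ncy - 1
                                sy = -box[1]
                            if jzr == ncz:
                                jzr = 0
                                sz = box[2]
                            cc = jxr + ncx * (jyr + ncy * jzr)
                            same = cc == c
                            i = head[c]
                            while i >= 0:
                                j = head[cc] if not same else nxt[i]
                                while j >= 0:
                                    ddx = wpos[i, 0] - wpos[j, 0] - sx
                                    ddy = wpos[i, 1] - wpos[j, 1] - sy
                                    ddz = wpos[i, 2] - wpos[j, 2] - sz
                                    r2 = ddx * ddx + ddy * ddy + ddz * ddz
                                    if r2 < c2:
                                        a = i if i < j else j
                                        b = j if i < j else i
                                        if not (
                                            chain_id[a] == chain_id[b] and b - a <= 2
                                        ) and not _is_complementary(
                                            a, b, type_id, registry, coil_len,
                                            coil_seg, rule,
                                        ):
                                            if m >= cap:
                                                return -1
                                            pairs_w[m, 0] = a
                                            pairs_w[m, 1] = b
                                            m += 1
                                    j = nxt[j]
                                i = nxt[i]
    return m


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


@njit(cache=True)
def coil_axes(pos, box, seg_start, seg_len, axes):
    """End-to-end unit vector of every coil segment (min-image bond sums)."""
    for s in range(seg_start.shape[0]):
        a0 = seg_start[s]
        L = seg_len[s]
        vx = 0.0
        vy = 0.0
        vz = 0.0
        for k in range(L - 1):
            dx = pos[a0 + k + 1, 0] - pos[a0 + k, 0]
            dy = pos[a0 + k + 1, 1] - pos[a0 + k, 1]
            dz = pos[a0 + k + 1, 2] - pos[a0 + k, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            vx += dx
            vy += dy
            vz += dz
        norm = math.sqrt(vx * vx + vy * vy + vz * vz)
        if norm < 1e-12:
            axes[s, 0] = 0.0
            axes[s, 1] = 0.0
            axes[s, 2] = 1.0
        else:
            axes[s, 0] = vx / norm
            axes[s, 1] = vy / norm
            axes[s, 2] = vz / norm


@njit(cache=True, inline="always")
def _lj_capped(r2, sigma, eps, shift, r_floor):
    """Truncated-shifted 12-6 with constant-force continuation below r_floor.

    Returns (energy, fmag) with force vector = fmag * dx.
    """
    r = math.sqrt(r2)
    if r < r_floor:
        x = sigma / r_floor
        x6 = x ** 6
        x12 = x6 * x6
        u_f = 4.0 * eps * (x12 - x6) - shift
        frad = 24.0 * eps * (2.0 * x12 - x6) / r_floor
        rr = r if r > 1e-6 else 1e-6
        return u_f + frad * (r_floor - r), frad / rr
    x = sigma / r
    x6 = x ** 6
    x12 = x6 * x6
    return 4.0 * eps * (x12 - x6) - shift, 24.0 * eps * (2.0 * x12 - x6) / r2


@njit(cache=True)
def compute_forces(
    pos,
    box,
    pairs_s,
    ns,
    pairs_w,
    nw,
    type_id,
    coil_seg,
    seg_start,
    seg_len,
    axes,
    rule,
    eps_mat,
    sigma_s,
    cut_s,
    sigma_r,
    eps_r,
    gate_cos,
    r_floor_s,
    r_floor_r,
    bonds,
    bond_r0,
    bond_k,
    angles,
    angle_k,
    forces,
):
    """Total potential energy; forces (negative gradient) into ``forces``."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    coil_axes(pos, box, seg_start, seg_len, axes)

    energy = 0.0
    cut_s2 = cut_s * cut_s
    cut_r = 2.0 ** (1.0 / 6.0) * sigma_r
    cut_r2 = cut_r * cut_r
    xc = sigma_s / cut_s
    xc6 = xc ** 6
    sf_unit = 4.0 * (xc6 * xc6 - xc6)  # shift at cutoff, per unit epsilon

    # Sticky candidates: orientation-gated 12-6 attraction with 1:1 valence
    # saturation — a bead attracts only its nearest gated complementary bead,
    # and only if the choice is mutual (coiled-coil pairing is exclusive, so
    # a satisfied interface must not keep attracting third chains).  Pairs
    # that fail the gate or the matching fall back to plain WCA repulsion.
    pr2 = np.empty(ns)
    pgate = np.empty(ns, dtype=np.uint8)
    pdx = np.empty(ns)
    pdy = np.empty(ns)
    pdz = np.empty(ns)
    best_d2 = np.full(n, 1e30)
    best_j = np.full(n, -1, dtype=np.int64)
    for p in range(ns):
        i = pairs_s[p, 0]
        j = pairs_s[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        pdx[p] = dx
        pdy[p] = dy
        pdz[p] = dz
        pr2[p] = r2
        si = coil_seg[i]
        sj = coil_seg[j]
        o = rule[type_id[i], type_id[j]]
        d = (
            axes[si, 0] * axes[sj, 0]
            + axes[si, 1] * axes[sj, 1]
            + axes[si, 2] * axes[sj, 2]
        )
        gated = (o == 1 and d >= gate_cos) or (o == 2 and d <= -gate_cos)
        pgate[p] = 1 if gated else 0
        if gated and r2 < cut_s2:
            if r2 < best_d2[i]:
                best_d2[i] = r2
                best_j[i] = j
            if r2 < best_d2[j]:
                best_d2[j] = r2
                best_j[j] = i
    for p in range(ns):
        i = pairs_s[p, 0]
        j = pairs_s[p, 1]
        r2 = pr2[p]
        if pgate[p] == 1 and r2 < cut_s2 and best_j[i] == j and best_j[j] == i:
            eps = eps_mat[type_id[i], type_id[j]]
            u, fmag = _lj_capped(r2, sigma_s, eps, eps * sf_unit, r_floor_s)
        elif r2 < cut_r2:
            u, fmag = _lj_capped(r2, sigma_r, eps_r, -eps_r, r_floor_r)
        else:
            continue
        dx = pdx[p]
        dy = pdy[p]
        dz = pdz[p]
        energy += u
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # plain WCA core
    for p in range(nw):
        i = pairs_w[p, 0]
        j = pairs_w[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < cut_r2:
            u, fmag = _lj_capped(r2, sigma_r, eps_r, -eps_r, r_floor_r)
            energy += u
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz

    # harmonic bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        dr = r - bond_r0
        energy += 0.5 * bond_k * dr * dr
        fmag = -bond_k * dr / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # cosine bending on coil-internal triplets, minimum at 180 degrees
    for a in range(angles.shape[0]):
        ii = angles[a, 0]
        jj = angles[a, 1]
        kk = angles[a, 2]
        ux = pos[ii, 0] - pos[jj, 0]
        uy = pos[ii, 1] - pos[jj, 1]
        uz = pos[ii, 2] - pos[jj, 2]
        vx = pos[kk, 0] - pos[jj, 0]
        vy = pos[kk, 1] - pos[jj, 1]
        vz = pos[kk, 2] - pos[jj, 2]
        ux -= box[0] * round(ux / box[0])
        uy -= box[1] * round(uy / box[1])
        uz -= box[2] * round(uz / box[2])
        vx -= box[0] * round(vx / box[0])
        vy -= box[1] * round(vy / box[1])
        vz -= box[2] * round(vz / box[2])
        lu = math.sqrt(ux * ux + uy * uy + uz * uz)
        lv = math.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        nux = ux / lu
        nuy = uy / lu
        nuz = uz / lu
        nvx = vx / lv
        nvy = vy / lv
        nvz = vz / lv
        c = nux * nvx + nuy * nvy + nuz * nvz
        energy += angle_k * (1.0 + c)
        gux = (nvx - c * nux) / lu
        guy = (nvy - c * nuy) / lu
        guz = (nvz - c * nuz) / lu
        gvx = (nux - c * nvx) / lv
        gvy = (nuy - c * nvy) / lv
        gvz = (nuz - c * nvz) / lv
        forces[ii, 0] -= angle_k * gux
        forces[ii, 1] -= angle_k * guy
        forces[ii, 2] -= angle_k * guz
        forces[kk, 0] -= angle_k * gvx
        forces[kk, 1] -= angle_k * gvy
        forces[kk, 2] -= angle_k * gvz
        forces[jj, 0] += angle_k * (gux + gvx)
        forces[jj, 1] += angle_k * (guy + gvy)
        forces[jj, 2] += angle_k * (guz + gvz)

    return energy


@njit(cache=True)
def energy_forces_fresh(
    pos,
    box,
    chain_id,
    type_id,
    registry,
    coil_len,
    coil_seg,
    seg_start,
    seg_len,
    static_pairs,
    rule,
    eps_mat,
    sigma_s,
    cut_s,
    sigma_r,
    eps_r,
    gate_cos,
    r_floor_s,
    r_floor_r,
    bonds,
    bond_r0,
    bond_k,
    angles,
    angle_k,
    list_cut_s,
    list_cut_w,
):
    """Energy/forces with freshly built pair lists."""
    n = pos.shape[0]
    wpos = np.empty((n, 3))
    wrap_into_box(pos, box, wpos)
    pairs_s = np.empty((max(1, static_pairs.shape[0]), 2), dtype=np.int32)
    ms = filter_sticky_pairs(wpos, box, static_pairs, list_cut_s, pairs_s)
    cap_w = 32 * n + 1024
    while True:
        pairs_w = np.empty((cap_w, 2), dtype=np.int32)
        mw = build_wca_pairs(
            wpos, box, list_cut_w, chain_id, type_id, registry, coil_len,
            coil_seg, rule, pairs_w,
        )
        if mw >= 0:
            break
        cap_w *= 2
    forces = np.empty((n, 3), dtype=np.float64)
    axes = np.empty((seg_start.shape[0], 3), dtype=np.float64)
    e = compute_forces(
        pos, box, pairs_s, ms, pairs_w, mw, type_id, coil_seg, seg_start,
        seg_len, axes, rule, eps_mat, sigma_s, cut_s, sigma_r, eps_r,
        gate_cos, r_floor_s, r_floor_r, bonds, bond_r0, bond_k, angles,
        angle_k, forces,
    )
    return e, forces


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_langevin(
    pos,
    vel,
    box,
    masses,
    n_steps,
    dt,
    gamma,
    kT,
    save_every,
    seed,
    chain_id,
    type_id,
    registry,
    coil_len,
    coil_seg,
    seg_start,
    seg_len,
    static_pairs,
    rule,
    eps_mat,
    sigma_s,
    cut_s,
    sigma_r,
    eps_r,
    gate_cos,
    r_floor_s,
    r_floor_r,
    bonds,
    bond_r0,
    bond_k,
    angles,
    angle_k,
    skin,
    com_every,
    thermo_every,
):
    """Langevin integration (velocity Verlet + OU thermostat kick every
    ``thermo_every`` steps; BAOAB at ``thermo_every=1``, NVE at gamma=0).

    Returns (frames, frame_times, kinetic_temperatures, status); status 0 on
    success, 1 if a per-step displacement exceeded a quarter box (blow-up).
    Positions in ``pos``/frames are unwrapped.
    """
    n = pos.shape[0]
    np.random.seed(seed)
    thermo = gamma > 0.0 and thermo_every > 0
    if thermo:
        c1 = math.exp(-gamma * dt * thermo_every)
        c2 = math.sqrt(1.0 - c1 * c1)
    else:
        c1 = 1.0
        c2 = 0.0

    n_frames = n_steps // save_every
    frames = np.empty((n_frames, n, 3), dtype=np.float64)
    times = np.empty(n_frames, dtype=np.float64)
    kin_temp = np.empty(n_frames, dtype=np.float64)

    cut_wca = 2.0 ** (1.0 / 6.0) * sigma_r
    list_cut_s = cut_s + skin
    list_cut_w = cut_wca + skin
    wpos = np.empty((n, 3))
    pairs_s = np.empty((max(1, static_pairs.shape[0]), 2), dtype=np.int32)
    cap_w = 32 * n + 1024
    pairs_w = np.empty((cap_w, 2), dtype=np.int32)

    wrap_into_box(pos, box, wpos)
    ms = filter_sticky_pairs(wpos, box, static_pairs, list_cut_s, pairs_s)
    mw = build_wca_pairs(
        wpos, box, list_cut_w, chain_id, type_id, registry, coil_len,
        coil_seg, rule, pairs_w,
    )
    while mw < 0:
        cap_w *= 2
        pairs_w = np.empty((cap_w, 2), dtype=np.int32)
        mw = build_wca_pairs(
            wpos, box, list_cut_w, chain_id, type_id, registry, coil_len,
            coil_seg, rule, pairs_w,
        )
    ref = pos.copy()
    skin2 = (0.5 * skin) * (0.5 * skin)

    forces = np.empty((n, 3), dtype=np.float64)
    axes = np.empty((seg_start.shape[0], 3), dtype=np.float64)
    compute_forces(
        pos, box, pairs_s, ms, pairs_w, mw, type_id, coil_seg, seg_start,
        seg_len, axes, rule, eps_mat, sigma_s, cut_s, sigma_r, eps_r,
        gate_cos, r_floor_s, r_floor_r, bonds, bond_r0, bond_k, angles,
        angle_k, forces,
    )

    half = 0.5 * dt
    blow2 = (0.25 * min(box[0], min(box[1], box[2]))) ** 2
    frame = 0
    for step in range(n_steps):
        kick = thermo and step % thermo_every == 0
        if kick:
            noise = np.random.standard_normal((n, 3))
        maxd2 = 0.0
        for i in range(n):
            im = 1.0 / masses[i]
            vx = vel[i, 0] + half * forces[i, 0] * im
            vy = vel[i, 1] + half * forces[i, 1] * im
            vz = vel[i, 2] + half * forces[i, 2] * im
            x0 = pos[i, 0]
            y0 = pos[i, 1]
            z0 = pos[i, 2]
            x = x0 + half * vx
            y = y0 + half * vy
            z = z0 + half * vz
            if kick:
                s = math.sqrt(kT * im)
                vx = c1 * vx + c2 * s * noise[i, 0]
                vy = c1 * vy + c2 * s * noise[i, 1]
                vz = c1 * vz + c2 * s * noise[i, 2]
            x += half * vx
            y += half * vy
            z += half * vz
            dx = x - x0
            dy = y - y0
            dz = z - z0
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz
        if maxd2 > blow2:
            return frames[:frame], times[:frame], kin_temp[:frame], 1

        # refresh pair lists when any bead moved half the skin
        need = False
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            if dx * dx + dy * dy + dz * dz > skin2:
                need = True
                break
        if need:
            wrap_into_box(pos, box, wpos)
            ms = filter_sticky_pairs(wpos, box, static_pairs, list_cut_s, pairs_s)
            mw = build_wca_pairs(
                wpos, box, list_cut_w, chain_id, type_id, registry, coil_len,
                coil_seg, rule, pairs_w,
            )
            while mw < 0:
                cap_w *= 2
                pairs_w = np.empty((cap_w, 2), dtype=np.int32)
                mw = build_wca_pairs(
                    wpos, box, list_cut_w, chain_id, type_id, registry,
                    coil_len, coil_seg, rule, pairs_w,
                )
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]

        compute_forces(
            pos, box, pairs_s, ms, pairs_w, mw, type_id, coil_seg, seg_start,
            seg_len, axes, rule, eps_mat, sigma_s, cut_s, sigma_r, eps_r,
            gate_cos, r_floor_s, r_floor_r, bonds, bond_r0, bond_k, angles,
            angle_k, forces,
        )
        for i in range(n):
            im = 1.0 / masses[i]
            vel[i, 0] += half * forces[i, 0] * im
            vel[i, 1] += half * forces[i, 1] * im
            vel[i, 2] += half * forces[i, 2] * im

        if com_every > 0 and (step + 1) % com_every == 0:
            mtot = 0.0
            px = 0.0
            py = 0.0
            pz = 0.0
            for i in range(n):
                mtot += masses[i]
                px += masses[i] * vel[i, 0]
                py += masses[i] * vel[i, 1]
                pz += masses[i] * vel[i, 2]
            px /= mtot
            py /= mtot
            pz /= mtot
            for i in range(n):
                vel[i, 0] -= px
                vel[i, 1] -= py
                vel[i, 2] -= pz

        if (step + 1) % save_every == 0:
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (
                    vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                )
            kin_temp[frame] = 2.0 * ke / (3.0 * n * KB)
            times[frame] = (step + 1) * dt
            for i in range(n):
                frames[frame, i, 0] = pos[i, 0]
                frames[frame, i, 1] = pos[i, 1]
                frames[frame, i, 2] = pos[i, 2]
            frame += 1

    return frames, times, kin_temp, 0
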