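"""Numba kernels for canonical sampling of compiled CG models.

The compiled representation reduces every model to flat arrays:

* per-bead interaction-type indices into a dense (T, T, G) grid of
  composite nonbonded pair tables (tabulated short-range + shifted-cutoff
  Coulomb + excluded volume, pre-summed on a fine uniform grid),
* sorted 1-2/1-3 exclusion keys (i*N + j with i < j),
* harmonic and tabulated bonds, tabulated angles (CSR adjacency per bead
  for O(1) lookup during single-bead Monte Carlo moves),
* optional isotropic harmonic tethers to fixed points.

Energies are in kT at the model reference temperature; the Langevin
integrator converts to kJ/mol internally so masses in amu and times in ps
are consistent.
"""

import numpy as np
from numba import njit

DEG = 180.0 / np.pi


@njit(cache=True)
def _excluded(i, j, n, excl_keys):
    if i > j:
        i, j = j, i
    key = i * n + j
    lo, hi = 0, excl_keys.size
    while lo < hi:
        mid = (lo + hi) // 2
        if excl_keys[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < excl_keys.size and excl_keys[lo] == key


@njit(cache=True)
def _pair_u(ti, tj, r, u_pair, g_lo, g_dr, cutoff):
    if r >= cutoff:
        return 0.0
    x = (r - g_lo) / g_dr
    ng = u_pair.shape[2]
    if x <= 0.0:
        slope = (u_pair[ti, tj, 1] - u_pair[ti, tj, 0]) / g_dr
        return u_pair[ti, tj, 0] + slope * (r - g_lo)
    seg = int(x)
    if seg >= ng - 1:
        seg = ng - 2
    frac = x - seg
    return u_pair[ti, tj, seg] * (1.0 - frac) + u_pair[ti, tj, seg + 1] * frac


@njit(cache=True)
def _pair_f(ti, tj, r, u_pair, g_lo, g_dr, cutoff):
    """Force = -dU/dr of the linearly interpolated energy table: the
    (piecewise-constant) segment slope, so forces are exactly consistent
    with the energies the MC path sees."""
    if r >= cutoff:
        return 0.0
    x = (r - g_lo) / g_dr
    ng = u_pair.shape[2]
    seg = int(x)
    if x <= 0.0:
        seg = 0
    elif seg >= ng - 1:
        seg = ng - 2
    return -(u_pair[ti, tj, seg + 1] - u_pair[ti, tj, seg]) / g_dr


@njit(cache=True)
def _table_u(tab, t_lo, t_dr, x):
    """1-D table with linear extrapolation at both ends (bond/angle)."""
    ng = tab.size
    y = (x - t_lo) / t_dr
    if y <= 0.0:
        slope = (tab[1] - tab[0]) / t_dr
        return tab[0] + slope * (x - t_lo)
    seg = int(y)
    if seg >= ng - 1:
        slope = (tab[ng - 1] - tab[ng - 2]) / t_dr
        return tab[ng - 1] + slope * (x - (t_lo + (ng - 1) * t_dr))
    frac = y - seg
    return tab[seg] * (1.0 - frac) + tab[seg + 1] * frac


@njit(cache=True)
def _table_f(tab, t_lo, t_dr, x):
    ng = tab.size
    y = (x - t_lo) / t_dr
    if y <= 0.0:
        return -(tab[1] - tab[0]) / t_dr
    seg = int(y)
    if seg >= ng - 1:
        return -(tab[ng - 1] - tab[ng - 2]) / t_dr
    return -(tab[seg + 1] - tab[seg]) / t_dr


@njit(cache=True)
def _mi(d, box):
    out = np.empty(3)
    for a in range(3):
        out[a] = d[a] - box[a] * np.rint(d[a] / box[a])
    return out


@njit(cache=True)
def _dist(pos_i, pos_j, box):
    r2 = 0.0
    for a in range(3):
        d = pos_i[a] - pos_j[a]
        d -= box[a] * np.rint(d / box[a])
        r2 += d * d
    return np.sqrt(r2)


@njit(cache=True)
def _angle_deg(pos, i, j, k, box):
    v1 = _mi(pos[i] - pos[j], box)
    v2 = _mi(pos[k] - pos[j], box)
    r1 = np.sqrt(v1[0] ** 2 + v1[1] ** 2 + v1[2] ** 2)
    r2 = np.sqrt(v2[0] ** 2 + v2[1] ** 2 + v2[2] ** 2)
    c = (v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]) / (r1 * r2)
    if c > 1.0:
        c = 1.0
    if c < -1.0:
        c = -1.0
    return np.arccos(c) * DEG


@njit(cache=True)
def particle_energy(p, ppos, pos, box, itype, n,
                    u_pair, g_lo, g_dr, cutoff, excl_keys,
                    hb_i, hb_j, hb_r0, hb_k, pb_off, pb_idx,
                    tb_i, tb_j, tb_t, u_bond, b_lo, b_dr, ptb_off, ptb_idx,
                    ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr,
                    pa_off, pa_idx,
                    teth_k, teth_pos):
    """Energy of particle p located at ppos (other particles at pos)."""
    e = 0.0
    ti = itype[p]
    for q in range(n):
        if q == p:
            continue
        if excl_keys.size > 0 and _excluded(p, q, n, excl_keys):
            continue
        r = _dist(ppos, pos[q], box)
        e += _pair_u(ti, itype[q], r, u_pair, g_lo, g_dr, cutoff)
    for m in range(pb_off[p], pb_off[p + 1]):
        b = pb_idx[m]
        other = hb_j[b] if hb_i[b] == p else hb_i[b]
        r = _dist(ppos, pos[other], box)
        e += 0.5 * hb_k[b] * (r - hb_r0[b]) ** 2
    for m in range(ptb_off[p], ptb_off[p + 1]):
        b = ptb_idx[m]
        other = tb_j[b] if tb_i[b] == p else tb_i[b]
        r = _dist(ppos, pos[other], box)
        e += _table_u(u_bond[tb_t[b]], b_lo, b_dr, r)
    if pa_off[p + 1] > pa_off[p]:
        old = pos[p].copy()
        pos[p] = ppos
        for m in range(pa_off[p], pa_off[p + 1]):
            a = pa_idx[m]
            th = _angle_deg(pos, ang_i[a], ang_j[a], ang_k[a], box)
            e += _table_u(u_ang[ang_t[a]], a_lo, a_dr, th)
        pos[p] = old
    if teth_k[p] > 0.0:
        dx = ppos[0] - teth_pos[p, 0]
        dy = ppos[1] - teth_pos[p, 1]
        dz = ppos[2] - teth_pos[p, 2]
        e += 0.5 * teth_k[p] * (dx * dx + dy * dy + dz * dz)
    return e


@njit(cache=True)
def total_energy_kernel(pos, box, itype,
                        u_pair, g_lo, g_dr, cutoff, excl_keys,
                        hb_i, hb_j, hb_r0, hb_k,
                        tb_i, tb_j, tb_t, u_bond, b_lo, b_dr,
                        ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr,
                        teth_k, teth_pos):
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if excl_keys.size > 0 and _excluded(i, j, n, excl_keys):
                continue
            r = _dist(pos[i], pos[j], box)
            e += _pair_u(itype[i], itype[j], r, u_pair, g_lo, g_dr, cutoff)
    for b in range(hb_i.size):
        r = _dist(pos[hb_i[b]], pos[hb_j[b]], box)
        e += 0.5 * hb_k[b] * (r - hb_r0[b]) ** 2
    for b in range(tb_i.size):
        r = _dist(pos[tb_i[b]], pos[tb_j[b]], box)
        e += _table_u(u_bond[tb_t[b]], b_lo, b_dr, r)
    for a in range(ang_i.size):
        th = _angle_deg(pos, ang_i[a], ang_j[a], ang_k[a], box)
        e += _table_u(u_ang[ang_t[a]], a_lo, a_dr, th)
    for p in range(n):
        if teth_k[p] > 0.0:
            dx = pos[p, 0] - teth_pos[p, 0]
            dy = pos[p, 1] - teth_pos[p, 1]
            dz = pos[p, 2] - teth_pos[p, 2]
            e += 0.5 * teth_k[p] * (dx * dx + dy * dy + dz * dz)
    return e


@njit(cache=True)
def forces_kernel(pos, box, itype,
                  f_pair, g_lo, g_dr, cutoff, excl_keys,
                  hb_i, hb_j, hb_r0, hb_k,
                  tb_i, tb_j, tb_t, u_bond, b_lo, b_dr,
                  ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr,
                  teth_k, teth_pos):
    n = pos.shape[0]
    f = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            if excl_keys.size > 0 and _excluded(i, j, n, excl_keys):
                continue
            d = _mi(pos[i] - pos[j], box)
            r = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
            if r >= cutoff or r == 0.0:
                continue
            fm = _pair_f(itype[i], itype[j], r, f_pair, g_lo, g_dr, cutoff)
            for a in range(3):
                f[i, a] += fm * d[a] / r
                f[j, a] -= fm * d[a] / r
    for b in range(hb_i.size):
        i, j = hb_i[b], hb_j[b]
        d = _mi(pos[j] - pos[i], box)
        r = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        fm = -hb_k[b] * (r - hb_r0[b])
        for a in range(3):
            f[j, a] += fm * d[a] / r
            f[i, a] -= fm * d[a] / r
    for b in range(tb_i.size):
        i, j = tb_i[b], tb_j[b]
        d = _mi(pos[j] - pos[i], box)
        r = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        fm = _table_f(u_bond[tb_t[b]], b_lo, b_dr, r)
        for a in range(3):
            f[j, a] += fm * d[a] / r
            f[i, a] -= fm * d[a] / r
    for m in range(ang_i.size):
        i, j, k = ang_i[m], ang_j[m], ang_k[m]
        v1 = _mi(pos[i] - pos[j], box)
        v2 = _mi(pos[k] - pos[j], box)
        r1 = np.sqrt(v1[0] ** 2 + v1[1] ** 2 + v1[2] ** 2)
        r2 = np.sqrt(v2[0] ** 2 + v2[1] ** 2 + v2[2] ** 2)
        c = (v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]) / (r1 * r2)
        if c > 1.0 - 1e-12:
            c = 1.0 - 1e-12
        if c < -1.0 + 1e-12:
            c = -1.0 + 1e-12
        th = np.arccos(c) * DEG
        du = -_table_f(u_ang[ang_t[m]], a_lo, a_dr, th)  # dU/dtheta, kT/deg
        du_rad = du * DEG
        s = np.sqrt(1.0 - c * c)
        for a in range(3):
            dth_di = -(v2[a] / (r1 * r2) - c * v1[a] / r1 ** 2) / s
            dth_dk = -(v1[a] / (r1 * r2) - c * v2[a] / r2 ** 2) / s
            f[i, a] -= du_rad * dth_di
            f[k, a] -= du_rad * dth_dk
            f[j, a] += du_rad * (dth_di + dth_dk)
    for p in range(n):
        if teth_k[p] > 0.0:
            for a in range(3):
                f[p, a] -= teth_k[p] * (pos[p, a] - teth_pos[p, a])
    return f


@njit(cache=True)
def mc_run(pos, box, itype, mobile_idx,
           u_pair, g_lo, g_dr, cutoff, excl_keys,
           hb_i, hb_j, hb_r0, hb_k, pb_off, pb_idx,
           tb_i, tb_j, tb_t, u_bond, b_lo, b_dr, ptb_off, ptb_idx,
           ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr, pa_off, pa_idx,
           teth_k, teth_pos,
           beta, max_disp, n_steps, sample_every, seed):
    """Metropolis Monte Carlo with single-bead displacement moves.

    Returns (trajectory frames sampled every ``sample_every`` steps,
    number of accepted moves).  Bitwise reproducible for a given seed.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_mob = mobile_idx.size
    n_samples = n_steps // sample_every
    traj = np.empty((n_samples, n, 3))
    n_acc = 0
    trial = np.empty(3)
    s = 0
    for step in range(n_steps):
        p = mobile_idx[np.random.randint(n_mob)]
        for a in range(3):
            trial[a] = pos[p, a] + max_disp * (2.0 * np.random.random() - 1.0)
        e_old = particle_energy(
            p, pos[p], pos, box, itype, n,
            u_pair, g_lo, g_dr, cutoff, excl_keys,
            hb_i, hb_j, hb_r0, hb_k, pb_off, pb_idx,
            tb_i, tb_j, tb_t, u_bond, b_lo, b_dr, ptb_off, ptb_idx,
            ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr, pa_off, pa_idx,
            teth_k, teth_pos)
        e_new = particle_energy(
            p, trial, pos, box, itype, n,
            u_pair, g_lo, g_dr, cutoff, excl_keys,
            hb_i, hb_j, hb_r0, hb_k, pb_off, pb_idx,
            tb_i, tb_j, tb_t, u_bond, b_lo, b_dr, ptb_off, ptb_idx,
            ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr, pa_off, pa_idx,
            teth_k, teth_pos)
        de = e_new - e_old
        if not np.isfinite(de):
            raise ValueError("non-finite energy change in MC move")
        if de <= 0.0 or np.random.random() < np.exp(-beta * de):
            for a in range(3):
                pos[p, a] = trial[a]
            n_acc += 1
        if (step + 1) % sample_every == 0:
            for i in range(n):
                for a in range(3):
                    traj[s, i, a] = pos[i, a]
            s += 1
    return traj, n_acc


@njit(cache=True)
def ld_run(pos, vel, mass, mobile, box, itype,
           f_pair, g_lo, g_dr, cutoff, excl_keys,
           hb_i, hb_j, hb_r0, hb_k,
           tb_i, tb_j, tb_t, u_bond, b_lo, b_dr,
           ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr,
           teth_k, teth_pos,
           kt_sched_kjmol, e_scale_kjmol, dt, gamma,
           n_steps, sample_every, seed, max_force):
    """BAOAB Langevin dynamics.

    Potential tables are in kT-at-reference units; ``e_scale_kjmol``
    converts them to kJ/mol so that (nm, ps, amu) kinematics is
    consistent.  ``kt_sched_kjmol`` holds the thermostat kT per step
    (piecewise profiles implement simulated annealing); gamma in 1/ps.
    Zero gamma reduces to velocity Verlet.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_samples = n_steps // sample_every
    traj = np.empty((n_samples, n, 3))
    kin = np.empty(n_samples)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    f = forces_kernel(pos, box, itype, f_pair, g_lo, g_dr, cutoff,
                      excl_keys, hb_i, hb_j, hb_r0, hb_k,
                      tb_i, tb_j, tb_t, u_bond, b_lo, b_dr,
                      ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr,
                      teth_k, teth_pos)
    s = 0
    for step in range(n_steps):
        kt = kt_sched_kjmol[step]
        for p in range(n):
            if not mobile[p]:
                continue
            for a in range(3):
                vel[p, a] += 0.5 * dt * f[p, a] * e_scale_kjmol / mass[p]
                pos[p, a] += 0.5 * dt * vel[p, a]
        if gamma > 0.0:
            for p in range(n):
                if not mobile[p]:
                    continue
                sd = np.sqrt(kt / mass[p])
                for a in range(3):
                    vel[p, a] = (c1 * vel[p, a]
                                 + c2 * sd * np.random.standard_normal())
        for p in range(n):
            if not mobile[p]:
                continue
            for a in range(3):
                pos[p, a] += 0.5 * dt * vel[p, a]
        f = forces_kernel(pos, box, itype, f_pair, g_lo, g_dr, cutoff,
                          excl_keys, hb_i, hb_j, hb_r0, hb_k,
                          tb_i, tb_j, tb_t, u_bond, b_lo, b_dr,
                          ang_i, ang_j, ang_k, ang_t, u_ang, a_lo, a_dr,
                          teth_k, teth_pos)
        fmax = 0.0
        for p in range(n):
            for a in range(3):
                af = abs(f[p, a])
                if af > fmax:
                    fmax = af
        if not np.isfinite(fmax) or fmax * e_scale_kjmol > max_force:
            raise ValueError("force blow-up in Langevin dynamics")
        for p in range(n):
            if not mobile[p]:
                continue
            for a in range(3):
                vel[p, a] += 0.5 * dt * f[p, a] * e_scale_kjmol / mass[p]
        if (step + 1) % sample_every == 0:
            ke = 0.0
            for p in range(n):
                ke += 0.5 * mass[p] * (vel[p, 0] ** 2 + vel[p, 1] ** 2
                                       + vel[p, 2] ** 2)
            kin[s] = ke
            for i in range(n):
                for a in range(3):
                    traj[s, i, a] = pos[i, a]
            s += 1
    return traj, kin


@njit(cache=True)
def pair_hist_frames(traj, box, itype, pair_block, n_blocks,
                     excl_keys, h_lo, h_dr, n_bins):
    """Per-frame pair-distance histograms, one block of ``n_bins`` per
    tracked type pair (``pair_block[ti, tj]`` = block index or -1).
    These are the S_alpha observables of inverse Monte Carlo."""
    nf = traj.shape[0]
    n = traj.shape[1]
    s = np.zeros((nf, n_blocks * n_bins))
    for t in range(nf):
        for i in range(n):
            for j in range(i + 1, n):
                blk = pair_block[itype[i], itype[j]]
                if blk < 0:
                    continue
                if excl_keys.size > 0 and _excluded(i, j, n, excl_keys):
                    continue
                r = _dist(traj[t, i], traj[t, j], box)
                x = (r - h_lo) / h_dr
                if x < 0.0:
                    continue
                b = int(x)
                if b < n_bins:
                    s[t, blk * n_bins + b] += 1.0
    return s
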