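"""Compilation of CG models into a flat array form for fast sampling.

An interaction type is a (bead type, group) pair; beads sharing both are
interchangeable for nonbonded purposes.  For every interaction-type pair
the composite nonbonded potential is pre-summed onto one fine uniform
grid:

* the assigned tabulated short-range potential, except between two
  histone-core beads, whose short-range interaction is excluded volume
  only (the core's internal structure is ruled by the elastic network),
* otherwise the excluded-volume (WCA) term where it applies,
* the shifted-cutoff Coulomb term for charged pairs.

During canonical sampling the electrostatics is always the real-space
shifted-cutoff form; the Ewald path in :mod:`ncpcg.potentials` serves
quantitative single-point energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .potentials import InteractionSet

__all__ = ["CompiledModel"]


def _csr(n, items):
    """items: list of (particle, term_index) -> CSR offsets/indices."""
    counts = np.zeros(n + 1, dtype=np.int64)
    for p, _ in items:
        counts[p + 1] += 1
    off = np.cumsum(counts)
    idx = np.zeros(off[-1], dtype=np.int64)
    cursor = off[:-1].copy()
    for p, t in items:
        idx[cursor[p]] = t
        cursor[p] += 1
    return off, idx


@dataclass
class CompiledModel:
    box: np.ndarray
    itype: np.ndarray                 # per-bead interaction-type index
    type_labels: list                 # index -> (type, group)
    charges: np.ndarray
    masses: np.ndarray
    u_pair: np.ndarray                # (T, T, G)
    f_pair: np.ndarray
    g_lo: float
    g_dr: float
    cutoff: float
    excl_keys: np.ndarray
    hb_i: np.ndarray
    hb_j: np.ndarray
    hb_r0: np.ndarray
    hb_k: np.ndarray
    tb_i: np.ndarray
    tb_j: np.ndarray
    tb_t: np.ndarray
    u_bond: np.ndarray                # (n bond tables, Gb)
    b_lo: float
    b_dr: float
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_t: np.ndarray
    u_ang: np.ndarray
    a_lo: float
    a_dr: float
    teth_k: np.ndarray
    teth_pos: np.ndarray
    mobile: np.ndarray
    pb_off: np.ndarray = field(default=None)
    pb_idx: np.ndarray = field(default=None)
    ptb_off: np.ndarray = field(default=None)
    ptb_idx: np.ndarray = field(default=None)
    pa_off: np.ndarray = field(default=None)
    pa_idx: np.ndarray = field(default=None)

    # ------------------------------------------------------------------
    @classmethod
    def compile(cls, topology, terms: InteractionSet, box=None,
                grid_dr=0.002, grid_lo=0.02, cutoff=None,
                tethers=None, mobile=None):
        box = np.asarray(box if box is not None else topology.box,
                         dtype=float)
        if box is None or box.size != 3:
            raise ValueError("an orthorhombic box is required")
        n = topology.n_beads
        types = topology.types
        groups = topology.groups
        q = topology.charges
        masses = topology.masses.astype(float)
        masses[masses <= 0] = 1.0

        keys = sorted({(t, g) for t, g in zip(types, groups)})
        key_index = {k: i for i, k in enumerate(keys)}
        itype = np.array([key_index[(t, g)] for t, g in zip(types, groups)],
                         dtype=np.int64)
        ntyp = len(keys)
        type_q = np.zeros(ntyp)
        q_seen = np.zeros(ntyp, dtype=bool)
        for b in range(n):
            ti = itype[b]
            if q_seen[ti] and type_q[ti] != q[b]:
                raise ValueError(
                    f"beads of interaction type {keys[ti]} carry different "
                    f"charges; charge must be a function of (type, group)")
            type_q[ti] = q[b]
            q_seen[ti] = True

        # cutoff: largest of table cutoffs, coulomb cutoff, EV walls
        cut = 0.0
        for tab in terms.pair_tables.values():
            cut = max(cut, tab.cutoff)
        if terms.coulomb is not None and np.any(q != 0):
            cut = max(cut, terms.coulomb.cutoff)
        if terms.excluded_volume is not None and terms.excluded_volume.sigma:
            smax = max(terms.excluded_volume.sigma.get(t, 0.0)
                       for t in set(types))
            cut = max(cut, 2.0 ** (1.0 / 6.0) * smax)
        if cutoff is not None:
            cut = cutoff
        if cut <= grid_lo:
            cut = grid_lo + 10 * grid_dr
        ng = int(np.ceil((cut - grid_lo) / grid_dr)) + 1
        r_grid = np.linspace(grid_lo, cut, ng)
        g_dr = float(r_grid[1] - r_grid[0])

        u_pair = np.zeros((ntyp, ntyp, ng))
        ev = terms.excluded_volume
        for a in range(ntyp):
            ta, ga = keys[a]
            for b in range(a, ntyp):
                tb, gb = keys[b]
                both_core = ga == gb == "histone_core"
                u = np.zeros(ng)
                tab = None if both_core else terms.pair_table(ta, tb)
                if tab is not None:
                    u += tab.evaluate(r_grid)[0]
                elif (ev is not None and ev.applies(ga, gb)
                        and ta in ev.sigma and tb in ev.sigma):
                    u += ev.pair_energy(ev.sigma_ij(ta, tb), r_grid)
                if (terms.coulomb is not None
                        and terms.coulomb.method != "none"
                        and type_q[a] * type_q[b] != 0.0):
                    u += terms.coulomb.pair_energy(type_q[a], type_q[b],
                                                   r_grid)
                u_pair[a, b] = u_pair[b, a] = u
        # kernel forces are the segment slopes of the energy table, so a
        # separate force table is just an alias for the energy table
        f_pair = u_pair

        excl = sorted(topology.exclusions())
        excl_keys = np.array([i * n + j for i, j in excl], dtype=np.int64)

        hb = [bd for bd in topology.bonds if bd.style == "harmonic"]
        tb = [bd for bd in topology.bonds if bd.style == "table"]
        hb_i = np.array([bd.i for bd in hb], dtype=np.int64)
        hb_j = np.array([bd.j for bd in hb], dtype=np.int64)
        hb_r0 = np.array([bd.r0 for bd in hb], dtype=float)
        hb_k = np.array([bd.k for bd in hb], dtype=float)

        bond_ids = sorted({bd.potential for bd in tb})
        if bond_ids:
            tabs = [terms.bond_tables[bid] for bid in bond_ids]
            for bid in bond_ids:
                if bid not in terms.bond_tables:
                    raise KeyError(f"missing bond table {bid!r}")
            b_lo = min(t.r[0] for t in tabs)
            b_hi = max(t.r[-1] for t in tabs)
            b_dr = min(t.dr for t in tabs)
            gb = int(np.round((b_hi - b_lo) / b_dr)) + 1
            grid_b = np.linspace(b_lo, b_hi, gb)
            b_dr = float(grid_b[1] - grid_b[0])
            u_bond = np.stack([t.evaluate(grid_b)[0] for t in tabs])
        else:
            b_lo, b_dr = 0.0, 1.0
            u_bond = np.zeros((1, 2))
        bond_id_index = {bid: i for i, bid in enumerate(bond_ids)}
        tb_i = np.array([bd.i for bd in tb], dtype=np.int64)
        tb_j = np.array([bd.j for bd in tb], dtype=np.int64)
        tb_t = np.array([bond_id_index[bd.potential] for bd in tb],
                        dtype=np.int64)

        ang = topology.angles
        ang_ids = sorted({a_.potential for a_ in ang})
        if ang_ids:
            for aid in ang_ids:
                if aid not in terms.angle_tables:
                    raise KeyError(f"missing angle table {aid!r}")
            tabs = [terms.angle_tables[aid] for aid in ang_ids]
            a_lo = min(t.r[0] for t in tabs)
            a_hi = max(t.r[-1] for t in tabs)
            a_dr = min(t.dr for t in tabs)
            ga_ = int(np.round((a_hi - a_lo) / a_dr)) + 1
            grid_a = np.linspace(a_lo, a_hi, ga_)
            a_dr = float(grid_a[1] - grid_a[0])
            u_ang = np.stack([t.evaluate(grid_a)[0] for t in tabs])
        else:
            a_lo, a_dr = 0.0, 1.0
            u_ang = np.zeros((1, 2))
        ang_id_index = {aid: i for i, aid in enumerate(ang_ids)}
        ang_i = np.array([a_.i for a_ in ang], dtype=np.int64)
        ang_j = np.array([a_.j for a_ in ang], dtype=np.int64)
        ang_k = np.array([a_.k for a_ in ang], dtype=np.int64)
        ang_t = np.array([ang_id_index[a_.potential] for a_ in ang],
                         dtype=np.int64)

        teth_k = np.zeros(n)
        teth_pos = np.zeros((n, 3))
        if tethers:
            for p, (k_, r_) in tethers.items():
                teth_k[p] = k_
                teth_pos[p] = np.asarray(r_, dtype=float)
        mob = np.ones(n, dtype=np.bool_)
        if mobile is not None:
            mob[:] = False
            mob[np.asarray(mobile, dtype=int)] = True

        model = cls(box=box, itype=itype, type_labels=keys,
                    charges=q.astype(float), masses=masses,
                    u_pair=u_pair, f_pair=f_pair, g_lo=float(grid_lo),
                    g_dr=g_dr, cutoff=float(cut), excl_keys=excl_keys,
                    hb_i=hb_i, hb_j=hb_j, hb_r0=hb_r0, hb_k=hb_k,
                    tb_i=tb_i, tb_j=tb_j, tb_t=tb_t, u_bond=u_bond,
                    b_lo=float(b_lo), b_dr=float(b_dr),
                    ang_i=ang_i, ang_j=ang_j, ang_k=ang_k, ang_t=ang_t,
                    u_ang=u_ang, a_lo=float(a_lo), a_dr=float(a_dr),
                    teth_k=teth_k, teth_pos=teth_pos, mobile=mob)
        model._build_adjacency(n)
        return model

    def _build_adjacency(self, n):
        hb_items = []
        for t, (i, j) in enumerate(zip(self.hb_i, self.hb_j)):
            hb_items += [(int(i), t), (int(j), t)]
        self.pb_off, self.pb_idx = _csr(n, hb_items)
        tb_items = []
        for t, (i, j) in enumerate(zip(self.tb_i, self.tb_j)):
            tb_items += [(int(i), t), (int(j), t)]
        self.ptb_off, self.ptb_idx = _csr(n, tb_items)
        ang_items = []
        for t, (i, j, k) in enumerate(zip(self.ang_i, self.ang_j,
                                          self.ang_k)):
            ang_items += [(int(i), t), (int(j), t), (int(k), t)]
        self.pa_off, self.pa_idx = _csr(n, ang_items)

    # ------------------------------------------------------------------
    @property
    def n_beads(self):
        return self.itype.size

    @property
    def mobile_idx(self):
        return np.nonzero(self.mobile)[0].astype(np.int64)

    def type_index(self, type_label, group=None):
        """Interaction-type index for a bead type (optionally a specific
        group); raises if the label is ambiguous across groups."""
        hits = [i for i, (t, g) in enumerate(self.type_labels)
                if t == type_label and (group is None or g == group)]
        if not hits:
            raise KeyError(f"no interaction type {type_label!r}")
        if len(hits) > 1:
            raise KeyError(f"type {type_label!r} appears in several groups; "
                           f"specify the group")
        return hits[0]

    def energy(self, positions):
        return float(_kernels.total_energy_kernel(
            np.ascontiguousarray(positions, dtype=float), self.box,
            self.itype, self.u_pair, self.g_lo, self.g_dr, self.cutoff,
            self.excl_keys, self.hb_i, self.hb_j, self.hb_r0, self.hb_k,
            self.tb_i, self.tb_j, self.tb_t, self.u_bond, self.b_lo,
            self.b_dr, self.ang_i, self.ang_j, self.ang_k, self.ang_t,
            self.u_ang, self.a_lo, self.a_dr, self.teth_k, self.teth_pos))

    def forces(self, positions):
        return _kernels.forces_kernel(
            np.ascontiguousarray(positions, dtype=float), self.box,
            self.itype, self.f_pair, self.g_lo, self.g_dr, self.cutoff,
            self.excl_keys, self.hb_i, self.hb_j, self.hb_r0, self.hb_k,
            self.tb_i, self.tb_j, self.tb_t, self.u_bond, self.b_lo,
            self.b_dr, self.ang_i, self.ang_j, self.ang_k, self.ang_t,
            self.u_ang, self.a_lo, self.a_dr, self.teth_k, self.teth_pos)

    def pair_block_map(self, tracked_pairs):
        """(T, T) block-index map for the tracked type-label pairs (used
        by the pair-count observable histograms); -1 marks untracked."""
        blocks = np.full((len(self.type_labels), len(self.type_labels)),
                         -1, dtype=np.int64)
        for blk, (ta, tb) in enumerate(tracked_pairs):
            ia = [i for i, (t, _) in enumerate(self.type_labels) if t == ta]
            ib = [i for i, (t, _) in enumerate(self.type_labels) if t == tb]
            for i in ia:
                for j in ib:
                    blocks[i, j] = blocks[j, i] = blk
        return blocks
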