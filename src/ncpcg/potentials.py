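"""Energy and force evaluation for the composite CG model.

The total potential energy is a sum of four classes:

* bonded terms: harmonic bonds (elastic network, DNA-core restraints) and
  tabulated bond potentials,
* angle terms: tabulated X-AA-X angle potentials,
* electrostatics: Coulomb's law with a uniform relative permittivity
  (default 78), evaluated either with a shifted real-space cutoff or by
  Ewald summation in periodic boundaries,
* short-range nonbonded terms: tabulated pair potentials per bead-type
  pair, plus a purely repulsive excluded-volume term (the
  Weeks-Chandler-Andersen split of the Lennard-Jones potential, i.e. LJ
  truncated at its minimum 2^(1/6) sigma_ij and shifted up by epsilon)
  with the combining rule sigma_ij = (sigma_i + sigma_j)/2 and
  epsilon = 1 kT.

1-2 and 1-3 bonded neighbours are excluded from both electrostatic and
short-range classes.  All energies are in k_B*T at the model temperature;
distances in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, erfc

from .distributions import minimum_image
from .tables import TabulatedPotential
from .units import (EPSILON_R_DEFAULT, KE_KJMOL_NM, T_DEFAULT,
                    bjerrum_length)

__all__ = [
    "CoulombTerm", "ExcludedVolumeTerm", "HarmonicBondTerm",
    "InteractionSet", "coulomb_energy", "ewald_energy", "total_energy",
    "forces", "eval_tabulated",
]


def eval_tabulated(pot: TabulatedPotential, r):
    """Energy (kT) and force (kT/nm) of a tabulated potential at ``r``."""
    return pot.evaluate(r)


# ---------------------------------------------------------------------------
# term definitions
# ---------------------------------------------------------------------------

@dataclass
class CoulombTerm:
    """Coulomb's law U = l_B q_i q_j / r in kT units, with l_B the Bjerrum
    length at (temperature, epsilon_r)."""
    epsilon_r: float = EPSILON_R_DEFAULT
    temperature: float = T_DEFAULT
    method: str = "cutoff"        # "cutoff" (shifted) | "ewald"
    cutoff: float = 2.5           # nm, real-space cutoff
    accuracy: float = 1e-5        # Ewald accuracy target
    alpha: float | None = None    # Ewald splitting parameter override

    def __post_init__(self):
        if self.epsilon_r <= 0:
            raise ValueError("relative permittivity must be positive")
        if self.method not in ("cutoff", "ewald"):
            raise ValueError(f"unknown electrostatics method {self.method!r}")

    @property
    def bjerrum(self) -> float:
        return bjerrum_length(self.temperature, self.epsilon_r)

    def pair_energy(self, q1, q2, r):
        """Shifted-cutoff pair energy in kT (zero at and beyond cutoff)."""
        r = np.asarray(r, dtype=float)
        u = np.where(r < self.cutoff,
                     self.bjerrum * q1 * q2 * (1.0 / r - 1.0 / self.cutoff),
                     0.0)
        return u

    def pair_force(self, q1, q2, r):
        r = np.asarray(r, dtype=float)
        return np.where(r < self.cutoff,
                        self.bjerrum * q1 * q2 / r ** 2, 0.0)


@dataclass
class ExcludedVolumeTerm:
    """Repulsive-only (WCA) part of the Lennard-Jones potential:
    U = 4*eps*((s/r)^12 - (s/r)^6) + eps for r < 2^(1/6)*s, else 0,
    with s = (sigma_i + sigma_j)/2 and eps = 1 kT."""
    sigma: dict = field(default_factory=dict)   # type label -> sigma_i (nm)
    epsilon: float = 1.0                        # kT
    groups: tuple | None = None   # restrict to these (group, group) pairs

    def sigma_ij(self, type_i: str, type_j: str) -> float:
        return 0.5 * (self.sigma[type_i] + self.sigma[type_j])

    def applies(self, group_i: str, group_j: str) -> bool:
        if self.groups is None:
            return True
        return (tuple(sorted((group_i, group_j)))
                in {tuple(sorted(g)) for g in self.groups})

    def pair_energy(self, s, r):
        r = np.asarray(r, dtype=float)
        rc = 2.0 ** (1.0 / 6.0) * s
        sr6 = (s / np.minimum(r, rc)) ** 6
        u = 4.0 * self.epsilon * (sr6 ** 2 - sr6) + self.epsilon
        return np.where(r < rc, u, 0.0)

    def pair_force(self, s, r):
        r = np.asarray(r, dtype=float)
        rc = 2.0 ** (1.0 / 6.0) * s
        sr6 = (s / r) ** 6
        f = 24.0 * self.epsilon * (2.0 * sr6 ** 2 - sr6) / r
        return np.where(r < rc, f, 0.0)


@dataclass
class HarmonicBondTerm:
    """U = (k/2)(r - r0)^2, k in kT/nm^2."""
    k: float = 500.0   # 5 kT/A^2
    r0: float = 0.0

    def energy(self, r):
        return 0.5 * self.k * (np.asarray(r, dtype=float) - self.r0) ** 2

    def force(self, r):
        """Scalar force magnitude along the bond: -dU/dr."""
        return -self.k * (np.asarray(r, dtype=float) - self.r0)


@dataclass
class InteractionSet:
    """All interaction terms of a model, resolved by id/type-pair."""
    pair_tables: dict = field(default_factory=dict)   # (ta, tb) -> table
    bond_tables: dict = field(default_factory=dict)   # pot id -> table
    angle_tables: dict = field(default_factory=dict)  # pot id -> table
    coulomb: CoulombTerm | None = None
    excluded_volume: ExcludedVolumeTerm | None = None

    def pair_table(self, ta: str, tb: str):
        key = tuple(sorted((ta, tb)))
        tab = self.pair_tables.get(key)
        if tab is None:
            tab = self.pair_tables.get((key[1], key[0]))
        return tab


# ---------------------------------------------------------------------------
# direct Coulomb and Ewald
# ---------------------------------------------------------------------------

def coulomb_energy(q1, q2, r, epsilon_r=EPSILON_R_DEFAULT):
    """Bare Coulomb pair energy k_e q1 q2 / (eps_r r) in kJ/mol
    (q in e, r in nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    return KE_KJMOL_NM * q1 * q2 / (epsilon_r * r)


def _ewald_parameters(box, accuracy, alpha=None, r_cut=None):
    box = np.asarray(box, dtype=float)
    p = max(-np.log(accuracy), 2.0)
    if r_cut is None:
        r_cut = float(box.min()) / 2.0
    if alpha is None:
        alpha = np.sqrt(p) / r_cut
    kmax = np.ceil(alpha * box * np.sqrt(p) / np.pi).astype(int)
    return alpha, r_cut, kmax


def ewald_energy(positions, charges, box, epsilon_r=EPSILON_R_DEFAULT,
                 temperature=T_DEFAULT, accuracy=1e-6, alpha=None,
                 exclusions=(), allow_net_charge=False):
    """Electrostatic energy of a periodic system by Ewald summation, in kT.

    Real-space part with minimum image (the real cutoff is half the
    shortest box edge), reciprocal sum over a k-shell chosen from the
    accuracy target, self term, and (for excluded bonded pairs) removal of
    the full pair interaction.  Non-neutral systems raise unless
    ``allow_net_charge`` adds the uniform-background correction.
    """
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    box = np.asarray(box, dtype=float)
    net = q.sum()
    if abs(net) > 1e-9 and not allow_net_charge:
        raise ValueError(f"system has net charge {net:+.3g}e; pass "
                         "allow_net_charge=True for a background correction")
    alpha, r_cut, kmax = _ewald_parameters(box, accuracy, alpha)
    n = len(q)
    volume = float(np.prod(box))

    # real space (minimum image, i<j)
    iu = np.triu_indices(n, k=1)
    d = minimum_image(pos[iu[0]] - pos[iu[1]], box)
    r = np.linalg.norm(d, axis=1)
    qq = q[iu[0]] * q[iu[1]]
    excl = {tuple(sorted(p)) for p in exclusions}
    if excl:
        mask = np.array([tuple(sorted((int(a), int(b)))) not in excl
                         for a, b in zip(*iu)])
    else:
        mask = np.ones(r.size, dtype=bool)
    in_cut = mask & (r < r_cut)
    e_real = np.sum(qq[in_cut] * erfc(alpha * r[in_cut]) / r[in_cut])

    # reciprocal space
    nx, ny, nz = (np.arange(-m, m + 1) for m in kmax)
    gx, gy, gz = np.meshgrid(nx, ny, nz, indexing="ij")
    nvec = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    nvec = nvec[np.any(nvec != 0, axis=1)]
    kvec = 2.0 * np.pi * nvec / box
    k2 = np.einsum("ij,ij->i", kvec, kvec)
    keep = k2 <= (2.0 * alpha * np.sqrt(max(-np.log(accuracy), 2.0))) ** 2
    kvec, k2 = kvec[keep], k2[keep]
    phase = kvec @ pos.T                       # (K, N)
    s_re = np.cos(phase) @ q
    s_im = np.sin(phase) @ q
    e_recip = (2.0 * np.pi / volume) * np.sum(
        np.exp(-k2 / (4.0 * alpha ** 2)) / k2 * (s_re ** 2 + s_im ** 2))

    e_self = -alpha / np.sqrt(np.pi) * np.sum(q ** 2)

    e_excl = 0.0
    if excl:
        # remove the erf part the reciprocal sum contributed for excluded
        # pairs (the erfc part was already skipped in real space)
        dd = d[~mask]
        rr = r[~mask]
        e_excl = -np.sum(qq[~mask] * erf(alpha * rr) / rr)
        del dd

    e_background = 0.0
    if abs(net) > 1e-9:
        e_background = -np.pi * net ** 2 / (2.0 * alpha ** 2 * volume)

    lb = bjerrum_length(temperature, epsilon_r)
    return lb * (e_real + e_recip + e_self + e_excl + e_background)


# ---------------------------------------------------------------------------
# full-system energy breakdown and forces
# ---------------------------------------------------------------------------

_CLASSES = ("bond", "angle", "coulomb", "short_range", "excluded_volume")


def _nonbonded_pairs(topology, box):
    """Index pairs (i<j), minimum-image vectors and distances, with the
    1-2/1-3 exclusion mask applied."""
    pos = topology.positions
    n = len(pos)
    iu = np.triu_indices(n, k=1)
    d = pos[iu[0]] - pos[iu[1]]
    if box is not None:
        d = minimum_image(d, np.asarray(box, dtype=float))
    r = np.linalg.norm(d, axis=1)
    excl = topology.exclusions()
    if excl:
        mask = np.array([(int(a), int(b)) not in excl
                         for a, b in zip(*iu)])
    else:
        mask = np.ones(r.size, dtype=bool)
    return iu[0][mask], iu[1][mask], d[mask], r[mask]


def total_energy(topology, terms: InteractionSet, positions=None, box=None,
                 classes=None):
    """Per-class energy breakdown (kT).  Returns a dict with one entry per
    interaction class plus ``"total"``; the breakdown is strictly
    additive."""
    from dataclasses import replace as _replace
    if positions is not None:
        beads = [
            _replace(b, position=np.asarray(p, dtype=float))
            for b, p in zip(topology.beads, positions)]
        topology = _replace(topology, beads=beads)
    box = box if box is not None else topology.box
    wanted = set(classes or _CLASSES)
    out = {c: 0.0 for c in wanted}

    pos = topology.positions
    types = topology.types
    groups = topology.groups
    q = topology.charges

    if "bond" in wanted:
        e = 0.0
        for bd in topology.bonds:
            dv = pos[bd.j] - pos[bd.i]
            if box is not None:
                dv = minimum_image(dv, np.asarray(box, dtype=float))
            r = float(np.linalg.norm(dv))
            if bd.style == "harmonic":
                e += 0.5 * bd.k * (r - bd.r0) ** 2
            else:
                tab = terms.bond_tables.get(bd.potential)
                if tab is None:
                    raise KeyError(f"no bond table {bd.potential!r}")
                e += tab.evaluate(r)[0]
        out["bond"] = e

    if "angle" in wanted:
        e = 0.0
        for an in topology.angles:
            v1 = pos[an.i] - pos[an.j]
            v2 = pos[an.k] - pos[an.j]
            if box is not None:
                v1 = minimum_image(v1, np.asarray(box, dtype=float))
                v2 = minimum_image(v2, np.asarray(box, dtype=float))
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
            tab = terms.angle_tables.get(an.potential)
            if tab is None:
                raise KeyError(f"no angle table {an.potential!r}")
            e += tab.evaluate(theta)[0]
        out["angle"] = e

    need_pairs = wanted & {"coulomb", "short_range", "excluded_volume"}
    if need_pairs and len(pos) > 1:
        ii, jj, dvec, r = _nonbonded_pairs(topology, box)
        if "coulomb" in wanted and terms.coulomb is not None:
            qq = q[ii] * q[jj]
            nz = qq != 0
            if terms.coulomb.method == "ewald":
                if box is None:
                    raise ValueError("Ewald needs a periodic box")
                out["coulomb"] = float(ewald_energy(
                    pos, q, box,
                    epsilon_r=terms.coulomb.epsilon_r,
                    temperature=terms.coulomb.temperature,
                    accuracy=terms.coulomb.accuracy,
                    alpha=terms.coulomb.alpha,
                    exclusions=topology.exclusions()))
            else:
                out["coulomb"] = float(np.sum(terms.coulomb.pair_energy(
                    q[ii][nz], q[jj][nz], r[nz])))
        if "short_range" in wanted and terms.pair_tables:
            e = 0.0
            for a, b, rr in zip(ii, jj, r):
                tab = terms.pair_table(types[a], types[b])
                if tab is not None:
                    e += tab.evaluate(rr)[0]
            out["short_range"] = e
        if "excluded_volume" in wanted and terms.excluded_volume is not None:
            ev = terms.excluded_volume
            e = 0.0
            for a, b, rr in zip(ii, jj, r):
                if ev.applies(groups[a], groups[b]):
                    e += float(ev.pair_energy(ev.sigma_ij(types[a],
                                                          types[b]), rr))
            out["excluded_volume"] = e

    out["total"] = float(sum(out[c] for c in wanted))
    return out


def forces(topology, terms: InteractionSet, positions=None, box=None,
           classes=None):
    """Analytic forces (kT/nm), summed over the requested interaction
    classes.  Ewald electrostatics is energy-only; use the cutoff method
    for force evaluation."""
    pos = np.asarray(positions if positions is not None
                     else topology.positions, dtype=float)
    box_arr = np.asarray(box if box is not None else topology.box,
                         dtype=float) if (box is not None or
                                          topology.box is not None) else None
    wanted = set(classes or _CLASSES)
    f = np.zeros_like(pos)
    types = topology.types
    groups = topology.groups
    q = topology.charges

    def mi(v):
        return minimum_image(v, box_arr) if box_arr is not None else v

    if "bond" in wanted:
        for bd in topology.bonds:
            dv = mi(pos[bd.j] - pos[bd.i])
            r = float(np.linalg.norm(dv))
            u = dv / r
            if bd.style == "harmonic":
                fmag = -bd.k * (r - bd.r0)
            else:
                fmag = terms.bond_tables[bd.potential].evaluate(r)[1]
            f[bd.j] += fmag * u
            f[bd.i] -= fmag * u

    if "angle" in wanted:
        for an in topology.angles:
            v1 = mi(pos[an.i] - pos[an.j])
            v2 = mi(pos[an.k] - pos[an.j])
            r1 = np.linalg.norm(v1)
            r2 = np.linalg.norm(v2)
            c = float(np.dot(v1, v2) / (r1 * r2))
            c = np.clip(c, -1.0 + 1e-12, 1.0 - 1e-12)
            theta = np.degrees(np.arccos(c))
            # dU/dtheta in kT/deg -> kT/rad
            du_dtheta = -terms.angle_tables[an.potential].evaluate(theta)[1]
            du_dtheta_rad = du_dtheta * 180.0 / np.pi
            s = np.sqrt(1.0 - c * c)
            dtheta_di = -(v2 / (r1 * r2) - c * v1 / r1 ** 2) / s
            dtheta_dk = -(v1 / (r1 * r2) - c * v2 / r2 ** 2) / s
            f[an.i] -= du_dtheta_rad * dtheta_di
            f[an.k] -= du_dtheta_rad * dtheta_dk
            f[an.j] += du_dtheta_rad * (dtheta_di + dtheta_dk)

    need_pairs = wanted & {"coulomb", "short_range", "excluded_volume"}
    if need_pairs and len(pos) > 1:
        from dataclasses import replace as _replace
        beads = [_replace(b, position=p) for b, p in
                 zip(topology.beads, pos)]
        top = _replace(topology, beads=beads)
        ii, jj, dvec, r = _nonbonded_pairs(top, box_arr)
        unit = dvec / r[:, None]
        fmag = np.zeros_like(r)
        if "coulomb" in wanted and terms.coulomb is not None:
            fmag += terms.coulomb.pair_force(q[ii], q[jj], r)
        if "short_range" in wanted and terms.pair_tables:
            for n_, (a, b, rr) in enumerate(zip(ii, jj, r)):
                tab = terms.pair_table(types[a], types[b])
                if tab is not None:
                    fmag[n_] += tab.evaluate(rr)[1]
        if "excluded_volume" in wanted and terms.excluded_volume is not None:
            ev = terms.excluded_volume
            for n_, (a, b, rr) in enumerate(zip(ii, jj, r)):
                if ev.applies(groups[a], groups[b]):
                    fmag[n_] += float(ev.pair_force(
                        ev.sigma_ij(types[a], types[b]), rr))
        np.add.at(f, ii, fmag[:, None] * unit)
        np.add.at(f, jj, -fmag[:, None] * unit)
    return f
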