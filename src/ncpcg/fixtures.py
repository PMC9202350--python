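"""Synthetic systems for building and testing the toolkit end to end.

Nothing here emulates a real force field; each fixture guarantees only
the statistical structure the corresponding pipeline stage assumes:

* toy fluids with known ground-truth tabulated pair potentials, whose
  sampled RDFs serve as inversion-recovery targets;
* harmonic/tabulated bonded dimers and chains for bonded inversion;
* miniature NCP-like particles (a wedge of two stacked discs of
  differing radius, flexible charged tails, a wrapped charged chain of
  P/D units, explicit ions) at roughly quarter scale so elastic-network,
  geometry, valency and SDF tests finish quickly;
* deterministic multi-particle arrangements (gas, stack, side-by-side,
  perpendicular) realising the particle-particle binding modes used by
  the aggregation analyses.

All fixtures are bitwise reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CompiledModel
from .potentials import CoulombTerm, ExcludedVolumeTerm, InteractionSet
from .sampler import SamplerConfig, rdf_from_traj, run_mc
from .tables import TabulatedPotential
from .topology import (Angle, BeadTypeTable, Bond, CGBead, CGTopology,
                       assign_angles, build_dna_core_restraints,
                       build_elastic_network)

__all__ = ["ToyFluidSpec", "ToyFluid", "make_toy_fluid",
           "MiniNCPSpec", "MiniNCP", "make_mini_ncp",
           "make_aggregate_configuration", "lj_table", "harmonic_table"]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def lj_table(sigma=0.35, epsilon=0.7, r_min=0.2, r_cut=1.2, n=201,
             name="LJ") -> TabulatedPotential:
    """Truncated-and-shifted Lennard-Jones as a ground-truth table
    (energies in kT)."""
    r = np.linspace(r_min, r_cut, n)
    u = 4.0 * epsilon * ((sigma / r) ** 12 - (sigma / r) ** 6)
    return TabulatedPotential(r, u - u[-1], kind="pair", name=name)


def harmonic_table(k, x0, lo, hi, n=201, kind="bond",
                   name="harm") -> TabulatedPotential:
    x = np.linspace(lo, hi, n)
    return TabulatedPotential(x, 0.5 * k * (x - x0) ** 2, kind=kind,
                              name=name)


# ---------------------------------------------------------------------------
# toy fluids
# ---------------------------------------------------------------------------

@dataclass
class ToyFluidSpec:
    composition: dict = field(default_factory=lambda: {"A": 100})
    box_length: float = 3.0             # nm
    potentials: dict | None = None      # (ta, tb) -> TabulatedPotential
    charges: dict = field(default_factory=dict)   # type -> e
    seed: int = 0
    burn_in: int = 30_000               # MC moves
    n_steps: int = 600_000
    sample_every: int = 600
    mc_max_disp: float = 0.35           # nm
    rdf_edges: np.ndarray | None = None

    def __post_init__(self):
        if self.potentials is None:
            self.potentials = {("A", "A"): lj_table()}
        if self.rdf_edges is None:
            cut = max(t.cutoff for t in self.potentials.values())
            self.rdf_edges = np.arange(0.2, cut + 1e-9, 0.025)
        cut = max(t.cutoff for t in self.potentials.values())
        if cut > self.box_length / 2:
            raise ValueError(
                f"interaction cutoff {cut} nm exceeds half the box "
                f"({self.box_length / 2} nm): density/box infeasible")

    @property
    def pairs(self):
        return sorted(self.potentials.keys())

    @property
    def n_particles(self):
        return sum(self.composition.values())


@dataclass
class ToyFluid:
    spec: ToyFluidSpec
    topology: CGTopology
    terms: InteractionSet
    model: CompiledModel
    ground_truth: dict
    reference_rdfs: dict
    frames: np.ndarray
    initial_positions: np.ndarray

    def rebuild(self, trial_potentials):
        """Compile the same system under trial pair potentials (the
        ground truth stays untouched); used by inversion loops."""
        terms = InteractionSet(pair_tables=dict(trial_potentials),
                               coulomb=self.terms.coulomb)
        model = CompiledModel.compile(self.topology, terms, grid_dr=0.005)
        return model, self.initial_positions.copy()


def make_toy_fluid(spec: ToyFluidSpec) -> ToyFluid:
    """Build a periodic fluid under the ground-truth potentials and
    sample its reference RDFs with the MC backend."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_particles
    pos0 = rng.uniform(0.0, spec.box_length, (n, 3))
    beads = []
    i = 0
    for label, count in sorted(spec.composition.items()):
        q = float(spec.charges.get(label, 0.0))
        for _ in range(count):
            beads.append(CGBead(i, label, q, 1.0, pos0[i], "ion"))
            i += 1
    top = CGTopology(beads=beads,
                     box=np.array([spec.box_length] * 3))
    coulomb = None
    if any(spec.charges.values()):
        coulomb = CoulombTerm(cutoff=min(1.45, spec.box_length / 2))
    terms = InteractionSet(pair_tables=dict(spec.potentials),
                           coulomb=coulomb)
    model = CompiledModel.compile(top, terms, grid_dr=0.005)
    cfg_burn = SamplerConfig(mode="MC", n_steps=spec.burn_in,
                             sample_every=spec.burn_in,
                             mc_max_disp=spec.mc_max_disp, seed=spec.seed)
    burn = run_mc(model, pos0, cfg_burn)
    cfg = SamplerConfig(mode="MC", n_steps=spec.n_steps,
                        sample_every=spec.sample_every,
                        mc_max_disp=spec.mc_max_disp, seed=spec.seed + 1)
    prod = run_mc(model, burn.final_positions, cfg)
    rdfs = rdf_from_traj(model, prod.frames, spec.pairs, spec.rdf_edges)
    return ToyFluid(spec=spec, topology=top, terms=terms, model=model,
                    ground_truth=dict(spec.potentials),
                    reference_rdfs=dict(zip(spec.pairs, rdfs)),
                    frames=prod.frames, initial_positions=pos0)


# ---------------------------------------------------------------------------
# miniature NCP-like particles
# ---------------------------------------------------------------------------

@dataclass
class MiniNCPSpec:
    disc_radii: tuple = (1.6, 1.1)      # nm, wedge = two unequal discs
    disc_z: tuple = (-0.25, 0.25)
    core_spacing: float = 0.32          # nm, in-plane bead spacing
    core_pattern: tuple = ("LYS", "SER", "ALA", "GLU", "LEU",
                           "ARG", "THR", "ASP")
    n_tails: int = 4
    tail_residues: tuple = ("ARG", "GLY", "LYS", "PRO", "SER")
    tail_bond_length: float = 0.38      # nm
    chain_units: int = 20               # wrapped-chain 2-bp-like units
    chain_radius: float = 2.05          # nm
    chain_z_span: float = 0.5
    chain_turns: float = 1.3
    p_offset: float = 0.25              # nm, P beads around each D bead
    ions: dict = field(default_factory=dict)   # extra ions, e.g. {"CoHex": 4}
    neutralize: bool = True
    box_length: float = 12.0
    seed: int = 0
    elastic_cutoff: float = 0.7
    k_elastic: float = 500.0
    dna_end_exempt: int = 2

    def __post_init__(self):
        if self.chain_units < 5:
            raise ValueError("need at least 5 chain units")


@dataclass
class MiniNCP:
    spec: MiniNCPSpec
    topology: CGTopology
    terms: InteractionSet
    reference_positions: np.ndarray
    core_indices: np.ndarray
    tail_indices: np.ndarray
    dna_indices: np.ndarray
    ion_indices: np.ndarray
    dna_end_indices: np.ndarray        # first/last D beads (defines +x)

    @property
    def contact_indices(self):
        """Beads entering the minimum-distance contact criterion:
        core + DNA, histone tails excluded."""
        return np.concatenate([self.core_indices, self.dna_indices])


def _disc_points(radius, spacing, z):
    n = max(int(np.pi * radius ** 2 / spacing ** 2), 7)
    k = np.arange(1, n + 1)
    r = radius * np.sqrt((k - 0.5) / n)
    th = k * GOLDEN_ANGLE
    return np.stack([r * np.cos(th), r * np.sin(th),
                     np.full(n, float(z))], axis=1)


def make_mini_ncp(spec: MiniNCPSpec,
                  type_table: BeadTypeTable | None = None) -> MiniNCP:
    """Assemble a quarter-scale NCP-like particle: wedge core with
    elastic network, charged flexible tails with typed angles, a wrapped
    P/D chain restrained to the core, and explicit ions."""
    table = type_table or BeadTypeTable()
    rng = np.random.default_rng(spec.seed)
    center = np.full(3, spec.box_length / 2.0)
    beads = []
    bonds = []
    angles = []

    def add_bead(type_, group, pos, resname="", mass=1.0, chain=""):
        q = table.charge_of(type_)
        b = CGBead(len(beads), type_, q, mass, np.asarray(pos) + center,
                   group, chain=chain, resname=resname, resid=len(beads))
        beads.append(b)
        return b

    # --- wedge core: two stacked discs of differing radius
    core = []
    pat = spec.core_pattern
    k = 0
    for radius, z in zip(spec.disc_radii, spec.disc_z):
        for p in _disc_points(radius, spec.core_spacing, z):
            code = pat[k % len(pat)]
            core.append(add_bead(table.aa_type(code), "histone_core", p,
                                 resname=code, mass=110.0, chain="CORE"))
            k += 1
    core_idx = np.array([b.index for b in core])

    # --- flexible tails anchored at the rim of the larger disc
    tails = []
    rim = [b for b in core
           if np.linalg.norm((b.position - center)[:2])
           > spec.disc_radii[0] - 2 * spec.core_spacing
           and abs(b.position[2] - center[2] - spec.disc_z[0]) < 1e-9]
    anchors = rim[:: max(len(rim) // max(spec.n_tails, 1), 1)][:spec.n_tails]
    for t, anchor in enumerate(anchors):
        direction = anchor.position - center
        direction[2] = 0.0
        direction /= np.linalg.norm(direction)
        chain_beads = [anchor]
        for s, code in enumerate(spec.tail_residues):
            pos = (anchor.position - center
                   + direction * spec.tail_bond_length * (s + 1))
            # slight out-of-plane kink so angles are well-defined
            pos = pos + np.array([0.0, 0.0, 0.05 * ((s % 2) * 2 - 1)])
            b = add_bead(table.aa_type(code), "histone_tail", pos,
                         resname=code, mass=110.0, chain=f"TAIL{t}")
            bonds.append(Bond(chain_beads[-1].index, b.index, "table",
                              "Bond_AA"))
            chain_beads.append(b)
            tails.append(b)
        angles.extend(assign_angles(chain_beads))
    tail_idx = np.array(sorted(b.index for b in tails), dtype=int)

    # --- wrapped charged chain (P/D units) around the core
    d_beads = []
    p_beads = []
    nu = spec.chain_units
    theta = np.linspace(0.0, 2.0 * np.pi * spec.chain_turns, nu)
    zline = np.linspace(-spec.chain_z_span / 2, spec.chain_z_span / 2, nu)
    for u in range(nu):
        c, s = np.cos(theta[u]), np.sin(theta[u])
        radial = np.array([c, s, 0.0])
        tangent = np.array([-s, c, 0.0])
        d_pos = spec.chain_radius * radial + np.array([0, 0, zline[u]])
        d = add_bead("D", "dna", d_pos, resname="D", mass=400.0,
                     chain="DNA")
        d_beads.append(d)
        for sign_t in (-1.0, 1.0):
            for sign_z in (-1.0, 1.0):
                off = (0.6 * spec.p_offset * sign_t * tangent
                       + spec.p_offset * radial
                       + np.array([0, 0, 0.6 * spec.p_offset * sign_z]))
                p = add_bead("P", "dna", d_pos + off, resname="P",
                             mass=95.0, chain="DNA")
                p_beads.append(p)
                bonds.append(Bond(d.index, p.index, "table", "Bond_PD"))
    for d1, d2 in zip(d_beads, d_beads[1:]):
        bonds.append(Bond(d1.index, d2.index, "table", "Bond_DD"))
    for d1, d2, d3 in zip(d_beads, d_beads[1:], d_beads[2:]):
        angles.append(Angle(d1.index, d2.index, d3.index, "Angle_DDD"))
    dna_idx = np.array(sorted(b.index for b in d_beads + p_beads),
                       dtype=int)
    dna_end_idx = np.array([d_beads[0].index, d_beads[-1].index])

    # --- elastic network and DNA-core restraints from the reference
    ref = np.array([b.position for b in beads])
    bonds.extend(build_elastic_network(core, ref[core_idx],
                                       cutoff=spec.elastic_cutoff,
                                       k_b=spec.k_elastic))
    bonds.extend(build_dna_core_restraints(
        d_beads, core, ref, k_b=spec.k_elastic,
        end_exempt=spec.dna_end_exempt))

    # --- explicit ions: neutralizing K+ plus any requested species
    particle_charge = sum(b.charge for b in beads)
    ions = dict(spec.ions)
    if spec.neutralize:
        extra = sum(table.charge_of(t) * c for t, c in ions.items())
        need = -(particle_charge + extra)
        if need < 0 or need != int(need):
            ions["Cl"] = ions.get("Cl", 0) + int(np.ceil(max(-need, 0)))
            need = -(particle_charge
                     + sum(table.charge_of(t) * c for t, c in ions.items()))
        ions["K"] = ions.get("K", 0) + int(round(need))
    ion_list = []
    occupied = np.array([b.position for b in beads])
    for label in sorted(ions):
        for _ in range(int(ions[label])):
            for _attempt in range(200):
                pos = rng.uniform(0.8, spec.box_length - 0.8, 3)
                if np.min(np.linalg.norm(occupied - pos, axis=1)) > 0.8:
                    break
            else:
                raise ValueError("cannot place ions without overlap")
            b = CGBead(len(beads), label, table.charge_of(label), 40.0,
                       pos, "ion", chain="ION", resname=label,
                       resid=len(beads))
            beads.append(b)
            ion_list.append(b)
            occupied = np.vstack([occupied, pos])
    ion_idx = np.array(sorted(b.index for b in ion_list), dtype=int)

    top = CGTopology(beads=beads, bonds=bonds, angles=angles,
                     box=np.array([spec.box_length] * 3))
    top.validate()

    # overlap sanity: non-bonded beads must not interpenetrate badly
    ref = top.positions
    from scipy.spatial.distance import pdist, squareform
    dmat = squareform(pdist(ref))
    np.fill_diagonal(dmat, np.inf)
    excl = top.exclusions()
    for i, j in zip(*np.nonzero(dmat < 0.12)):
        if i < j and (int(i), int(j)) not in excl:
            raise ValueError(f"geometric overlap between beads {i} and "
                             f"{j}: {dmat[i, j]:.3f} nm")

    terms = _mini_ncp_interactions(top, table)
    return MiniNCP(spec=spec, topology=top, terms=terms,
                   reference_positions=top.positions,
                   core_indices=core_idx, tail_indices=tail_idx,
                   dna_indices=dna_idx, ion_indices=ion_idx,
                   dna_end_indices=dna_end_idx)


def _mini_ncp_interactions(top: CGTopology, table: BeadTypeTable
                           ) -> InteractionSet:
    """Default interaction set for mini-NCP sampling: excluded volume on
    every pair, shifted-cutoff Coulomb, harmonic-shaped bond/angle
    tables."""
    sigma = {t: table.radius_of(t) for t in set(top.types)}
    ev = ExcludedVolumeTerm(sigma=sigma, groups=None)
    bond_tables = {
        "Bond_AA": harmonic_table(300.0, 0.38, 0.1, 1.0, name="Bond_AA"),
        "Bond_PD": harmonic_table(300.0, 0.42, 0.1, 1.2, name="Bond_PD"),
        "Bond_DD": harmonic_table(300.0, 0.5, 0.1, 1.4, name="Bond_DD"),
    }
    angle_tables = {
        "Angle_PRO": harmonic_table(0.006, 95.0, 0.0, 180.0, kind="angle",
                                    name="Angle_PRO"),
        "Angle_GLY": harmonic_table(0.003, 130.0, 0.0, 180.0, kind="angle",
                                    name="Angle_GLY"),
        "Angle_Other": harmonic_table(0.004, 120.0, 0.0, 180.0,
                                      kind="angle", name="Angle_Other"),
        "Angle_DDD": harmonic_table(0.01, 160.0, 0.0, 180.0, kind="angle",
                                    name="Angle_DDD"),
    }
    return InteractionSet(bond_tables=bond_tables,
                          angle_tables=angle_tables,
                          coulomb=CoulombTerm(cutoff=2.5),
                          excluded_volume=ev)


# ---------------------------------------------------------------------------
# multi-particle arrangements
# ---------------------------------------------------------------------------

def _rotation_x(deg):
    a = np.radians(deg)
    return np.array([[1, 0, 0],
                     [0, np.cos(a), -np.sin(a)],
                     [0, np.sin(a), np.cos(a)]])


def make_aggregate_configuration(n_particles, arrangement, spacing,
                                 spec: MiniNCPSpec | None = None,
                                 seed=0, box_length=None):
    """Deterministic multi-particle configurations realising the named
    binding modes: "stack" (translated along the cylinder axis),
    "side_by_side" (translated in-plane), "perpendicular" (alternating
    90-degree rotation about x), "gas" (dilute jittered lattice).

    Returns ``(frame (N, 3), particles, box)`` where ``particles`` is a
    list of dicts with per-particle core/dna/tail/contact index arrays.
    """
    spec = spec or MiniNCPSpec()
    single = make_mini_ncp(spec)
    base = single.reference_positions.copy()
    center = base[single.core_indices].mean(axis=0)
    base -= center
    n_beads = base.shape[0]

    if arrangement in ("stack", "side_by_side", "perpendicular"):
        if box_length is None:
            box_length = max(spec.box_length,
                             (n_particles + 1) * spacing + 6.0)
        mid = np.full(3, box_length / 2.0)
        offsets, rots = [], []
        axis = np.array([0, 0, 1.0]) if arrangement == "stack" \
            else np.array([1.0, 0, 0])
        for p in range(n_particles):
            shift = (p - (n_particles - 1) / 2.0) * spacing * axis
            offsets.append(mid + shift)
            if arrangement == "perpendicular" and p % 2 == 1:
                rots.append(_rotation_x(90.0))
            else:
                rots.append(np.eye(3))
        min_allowed = {"stack": 0.45, "side_by_side": 2 * spec.disc_radii[0],
                       "perpendicular": 0.45}[arrangement]
        if spacing < min_allowed:
            raise ValueError(f"spacing {spacing} nm overlaps particles in "
                             f"the {arrangement} arrangement")
    elif arrangement == "gas":
        if box_length is None:
            box_length = n_particles * 9.0
        rng = np.random.default_rng(seed)
        side = int(np.ceil(n_particles ** (1 / 3)))
        pitch = box_length / side
        if pitch < 2 * spec.chain_radius + 1.0:
            raise ValueError("box too small for a non-contacting gas")
        cells = [(i, j, k) for i in range(side) for j in range(side)
                 for k in range(side)][:n_particles]
        offsets = [(np.array(c) + 0.5) * pitch
                   + rng.uniform(-0.5, 0.5, 3) for c in cells]
        rots = [_random_rotation(rng) for _ in range(n_particles)]
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    frame = np.concatenate([base @ r.T + off
                            for r, off in zip(rots, offsets)])
    particles = []
    for p in range(n_particles):
        off = p * n_beads
        particles.append({
            "core": single.core_indices + off,
            "dna": single.dna_indices + off,
            "tails": single.tail_indices + off,
            "contact": single.contact_indices + off,
            "dna_ends": single.dna_end_indices + off,
        })
    return frame, particles, np.array([box_length] * 3)


def _random_rotation(rng):
    """Uniform random rotation matrix (seeded)."""
    from scipy.spatial.transform import Rotation as R
    return R.random(rng=rng).as_matrix()
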