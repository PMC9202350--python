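"""CG topology construction for nucleosome-like systems.

The coarse-grained representation follows a one-bead-per-amino-acid mapping
for protein (bead at the residue centre of mass, grouped into five types:
polar POL, nonpolar NPL, positive POS, negative NEG, and glycine GLY), a
five-beads-per-two-base-pairs mapping for DNA (four phosphate P beads at
-1e each plus one central D bead at the centre of mass of everything else),
and one bead per explicit ion.

The structured histone core is held together by an elastic network: every
core bead pair closer than a cutoff (default 7 A) in the reference
structure is connected by a harmonic bond with the reference distance as
equilibrium length.  The wrapped DNA is localised on the core by harmonic
restraints from each central D bead (except the two at each DNA end, which
are left free to breathe) to its nearest core bead.

1-2 and 1-3 bonded neighbours are excluded from all nonbonded
interactions; 1-4 and beyond interact as ordinary nonbonded pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BeadTypeTable", "CGBead", "Bond", "Angle", "CGTopology",
    "map_protein", "map_dna", "DNAUnit", "assign_angles",
    "build_elastic_network", "build_dna_core_restraints",
    "build_peptide_chain", "compute_exclusions",
    "write_topology", "read_topology", "load_pdb_residues",
]

# default stiffness of core elastic-network and DNA-core bonds:
# 5 kT/A^2 = 500 kT/nm^2
K_ELASTIC_DEFAULT = 500.0
ELASTIC_CUTOFF_DEFAULT = 0.7  # nm

GROUPS = ("histone_core", "histone_tail", "dna", "ion")

_DEFAULT_AA_TYPES = {
    # positive / negative
    "LYS": "POS", "ARG": "POS",
    "ASP": "NEG", "GLU": "NEG",
    # glycine gets its own type (small size, extra backbone freedom)
    "GLY": "GLY",
    # nonpolar
    "ALA": "NPL", "VAL": "NPL", "LEU": "NPL", "ILE": "NPL", "PRO": "NPL",
    "PHE": "NPL", "MET": "NPL", "TRP": "NPL", "CYS": "NPL",
    # polar (His kept neutral: POS beads carry a full +e and His is
    # predominantly uncharged at pH 7)
    "SER": "POL", "THR": "POL", "ASN": "POL", "GLN": "POL",
    "TYR": "POL", "HIS": "POL",
}

_DEFAULT_TYPE_CHARGE = {"POL": 0.0, "NPL": 0.0, "POS": 1.0, "NEG": -1.0,
                        "GLY": 0.0}

# effective LJ sigma_i per bead type (nm) for the excluded-volume term;
# chosen so the repulsive wall sits just inside typical bonded CG bead
# spacings (~0.38 nm residue-residue); config-overridable stand-ins
_DEFAULT_TYPE_RADIUS = {"POL": 0.28, "NPL": 0.30, "POS": 0.32, "NEG": 0.30,
                        "GLY": 0.22, "P": 0.20, "D": 0.40}

_DEFAULT_ION_CHARGE = {"K": 1, "Na": 1, "Cl": -1, "MgW6": 2, "CoHex": 3}
_DEFAULT_ION_RADIUS = {"K": 0.15, "Na": 0.12, "Cl": 0.18, "MgW6": 0.25,
                       "CoHex": 0.30}


@dataclass
class BeadTypeTable:
    """Bead-type assignment and per-type parameters.

    Five amino-acid types (POL, NPL, POS, NEG, GLY), two DNA types
    (P at -1e, D neutral) and explicit ion types with integer charges.
    ``type_radius`` holds the effective diameter sigma_i (nm) entering the
    excluded-volume combining rule sigma_ij = (sigma_i + sigma_j)/2.
    """

    amino_acid_to_type: dict = field(
        default_factory=lambda: dict(_DEFAULT_AA_TYPES))
    type_charge: dict = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_CHARGE))
    type_radius: dict = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_RADIUS))
    ion_charge: dict = field(
        default_factory=lambda: dict(_DEFAULT_ION_CHARGE))
    ion_radius: dict = field(
        default_factory=lambda: dict(_DEFAULT_ION_RADIUS))

    AA_TYPES = ("POL", "NPL", "POS", "NEG", "GLY")
    DNA_CHARGE = {"P": -1.0, "D": 0.0}

    def __post_init__(self):
        self.validate()

    def validate(self):
        types = set(self.amino_acid_to_type.values())
        if types != set(self.AA_TYPES):
            raise ValueError(
                f"amino-acid mapping must use exactly the five types "
                f"{self.AA_TYPES}, got {sorted(types)}")
        if self.type_charge["POS"] != 1.0 or self.type_charge["NEG"] != -1.0:
            raise ValueError("POS must carry +1e and NEG -1e")
        for t in ("POL", "NPL", "GLY"):
            if self.type_charge[t] != 0.0:
                raise ValueError(f"{t} beads must be neutral")
        for t, r in self.type_radius.items():
            if r <= 0:
                raise ValueError(f"non-positive radius for type {t}")
        for ion, q in self.ion_charge.items():
            if q != int(q):
                raise ValueError(f"ion {ion} must carry an integer charge")

    def aa_type(self, code: str) -> str:
        try:
            return self.amino_acid_to_type[code.upper()]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}; add it to the "
                           f"bead-type table") from None

    def charge_of(self, type_label: str) -> float:
        if type_label in self.type_charge:
            return self.type_charge[type_label]
        if type_label in self.DNA_CHARGE:
            return self.DNA_CHARGE[type_label]
        if type_label in self.ion_charge:
            return float(self.ion_charge[type_label])
        raise KeyError(f"unknown bead type {type_label!r}")

    def radius_of(self, type_label: str) -> float:
        if type_label in self.type_radius:
            return self.type_radius[type_label]
        if type_label in self.ion_radius:
            return self.ion_radius[type_label]
        raise KeyError(f"no radius for bead type {type_label!r}")


@dataclass
class CGBead:
    index: int
    type: str
    charge: float
    mass: float
    position: np.ndarray       # nm
    group: str                 # histone_core | histone_tail | dna | ion
    chain: str = ""
    resname: str = ""
    resid: int = -1

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class Bond:
    i: int
    j: int
    style: str            # "harmonic" | "table"
    potential: str        # potential id (table name) or bond class
    r0: float | None = None   # nm, harmonic only
    k: float | None = None    # kT/nm^2, harmonic only

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-bond")
        if self.i > self.j:
            self.i, self.j = self.j, self.i

    @property
    def pair(self):
        return (self.i, self.j)


@dataclass
class Angle:
    i: int
    j: int   # central bead
    k: int
    potential: str   # Angle_PRO | Angle_GLY | Angle_Other | table id

    def __post_init__(self):
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle needs three distinct beads")


@dataclass
class CGTopology:
    beads: list
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    box: np.ndarray | None = None   # orthorhombic edge lengths, nm

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        seen = [b.index for b in self.beads]
        if len(set(seen)) != len(seen):
            raise ValueError("duplicate bead indices")

    # -- array views -----------------------------------------------------
    @property
    def n_beads(self):
        return len(self.beads)

    @property
    def positions(self):
        return np.array([b.position for b in self.beads])

    @property
    def charges(self):
        return np.array([b.charge for b in self.beads])

    @property
    def masses(self):
        return np.array([b.mass for b in self.beads])

    @property
    def types(self):
        return [b.type for b in self.beads]

    @property
    def groups(self):
        return [b.group for b in self.beads]

    def indices_of_group(self, group: str) -> np.ndarray:
        return np.array([b.index for b in self.beads if b.group == group],
                        dtype=int)

    def total_charge(self) -> float:
        return float(sum(b.charge for b in self.beads))

    def exclusions(self) -> set:
        """1-2 and 1-3 excluded pairs derived from the full bond graph."""
        return compute_exclusions(self.bonds)

    def validate(self):
        n = self.n_beads
        idx = {b.index for b in self.beads}
        if idx != set(range(n)):
            raise ValueError("bead indices must be 0..n-1")
        for bd in self.bonds:
            if bd.i not in idx or bd.j not in idx:
                raise ValueError(f"bond {bd.pair} references unknown bead")
        for an in self.angles:
            for m in (an.i, an.j, an.k):
                if m not in idx:
                    raise ValueError(f"angle references unknown bead {m}")
        groups = self.groups
        for bd in self.bonds:
            if bd.potential == "elastic":
                if not (groups[bd.i] == groups[bd.j] == "histone_core"):
                    raise ValueError(
                        f"elastic bond {bd.pair} outside the histone core")
        return True


# ---------------------------------------------------------------------------
# mapping operations
# ---------------------------------------------------------------------------

def _com(positions, masses):
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if positions.ndim != 2 or positions.shape[0] == 0:
        raise ValueError("empty atom set")
    if np.any(masses <= 0):
        raise ValueError("non-positive atom mass")
    return masses @ positions / masses.sum()


def map_protein(residues, type_table: BeadTypeTable, group="histone_tail",
                chain="A", start_index=0, start_resid=0):
    """Map residues to one CG bead each at the residue centre of mass.

    ``residues`` is a sequence of ``(code, atom_positions, atom_masses)``
    with positions in nm.  Type and charge come from the bead-type table.
    """
    beads = []
    for n, (code, pos, masses) in enumerate(residues):
        t = type_table.aa_type(code)
        beads.append(CGBead(
            index=start_index + n,
            type=t,
            charge=type_table.charge_of(t),
            mass=float(np.sum(masses)),
            position=_com(pos, masses),
            group=group,
            chain=chain,
            resname=code.upper(),
            resid=start_resid + n,
        ))
    return beads


@dataclass
class DNAUnit:
    """A two-base-pair DNA unit: four phosphate groups plus everything else.

    ``phosphates`` is a sequence of four ``(positions, masses)`` atom sets
    (one per phosphate group); ``rest_positions``/``rest_masses`` hold all
    remaining atoms of the two base pairs.
    """
    phosphates: list
    rest_positions: np.ndarray
    rest_masses: np.ndarray


def map_dna(units, chain="DNA", start_index=0):
    """Map pre-partitioned 2-bp units to CG beads: four P beads (-1e each)
    at the phosphate-group centres of mass plus one neutral D bead at the
    centre of mass of all remaining atoms (5 beads, -4e per unit)."""
    beads = []
    idx = start_index
    for u_n, unit in enumerate(units):
        if len(unit.phosphates) != 4:
            raise ValueError(
                f"DNA unit {u_n} has {len(unit.phosphates)} phosphate "
                f"groups, expected 4")
        for pos, masses in unit.phosphates:
            beads.append(CGBead(idx, "P", -1.0, float(np.sum(masses)),
                                _com(pos, masses), "dna", chain=chain,
                                resname="P", resid=u_n))
            idx += 1
        beads.append(CGBead(idx, "D", 0.0, float(np.sum(unit.rest_masses)),
                            _com(unit.rest_positions, unit.rest_masses),
                            "dna", chain=chain, resname="D", resid=u_n))
        idx += 1
    return beads


def n_dna_units(n_base_pairs: int) -> int:
    """Number of 2-bp units for a duplex: floor(N/2); an odd final base
    pair is merged into the last unit's central bead."""
    if n_base_pairs < 2:
        raise ValueError("need at least 2 base pairs")
    return n_base_pairs // 2


def assign_angles(chain_beads, potential_prefix="Angle"):
    """One angle per interior bead of a chain, typed on the central
    residue: Angle_PRO at proline, Angle_GLY at glycine, Angle_Other
    elsewhere.  Angles lying entirely inside the histone core are omitted
    (the core is ruled by the elastic network instead).  Chains shorter
    than 3 beads yield no angles."""
    angles = []
    for a, b, c in zip(chain_beads, chain_beads[1:], chain_beads[2:]):
        if a.group == b.group == c.group == "histone_core":
            continue
        if b.resname == "PRO":
            pot = f"{potential_prefix}_PRO"
        elif b.resname == "GLY":
            pot = f"{potential_prefix}_GLY"
        else:
            pot = f"{potential_prefix}_Other"
        angles.append(Angle(a.index, b.index, c.index, pot))
    return angles


def build_peptide_chain(residues, type_table: BeadTypeTable,
                        group="histone_tail", chain="A", start_index=0,
                        bond_potential="Bond_AA"):
    """Convenience builder: map a peptide and wire consecutive 1-2 bonds
    plus X-AA-X angles."""
    beads = map_protein(residues, type_table, group=group, chain=chain,
                        start_index=start_index)
    bonds = [Bond(b1.index, b2.index, "table", bond_potential)
             for b1, b2 in zip(beads, beads[1:])]
    angles = assign_angles(beads)
    return beads, bonds, angles


def build_elastic_network(core_beads, reference_positions,
                          cutoff=ELASTIC_CUTOFF_DEFAULT,
                          k_b=K_ELASTIC_DEFAULT, existing_bonds=()):
    """Harmonic bonds between every pair of core beads strictly closer
    than ``cutoff`` (nm) in the reference structure; equilibrium length is
    the reference distance, stiffness ``k_b`` (kT/nm^2) uniform.  Pairs
    already bonded 1-2 are not duplicated."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ref = np.asarray(reference_positions, dtype=float)
    if not np.all(np.isfinite(ref)):
        raise ValueError("non-finite reference positions")
    idx = np.array([b.index for b in core_beads], dtype=int)
    if ref.shape[0] != idx.size:
        raise ValueError("reference positions do not match core beads")
    existing = {tuple(sorted(p)) for p in
                (bd.pair if isinstance(bd, Bond) else tuple(bd)
                 for bd in existing_bonds)}
    bonds = []
    d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    for a in range(idx.size):
        for b in range(a + 1, idx.size):
            if d[a, b] < cutoff:   # strict: exactly-at-cutoff excluded
                pair = tuple(sorted((int(idx[a]), int(idx[b]))))
                if pair in existing:
                    continue
                bonds.append(Bond(pair[0], pair[1], "harmonic", "elastic",
                                  r0=float(d[a, b]), k=k_b))
    return bonds


def build_dna_core_restraints(d_beads, core_beads, reference_positions,
                              k_b=K_ELASTIC_DEFAULT, end_exempt=2):
    """Harmonic restraints from each central DNA (D) bead to its nearest
    histone-core bead, exempting ``end_exempt`` beads at each DNA end so
    the DNA termini can breathe (default 2; pass 4 for the reduced-bond
    variant with two fewer bonds at each end).  Stiffness matches the
    elastic network.  Ties in the nearest-core search break to the lowest
    core bead index."""
    d_beads = list(d_beads)
    core_beads = list(core_beads)
    if len(d_beads) <= 2 * end_exempt or len(d_beads) < 5:
        raise ValueError(
            f"need more than {max(2 * end_exempt, 4)} D beads to place "
            f"restraints, got {len(d_beads)}")
    if not core_beads:
        raise ValueError("empty histone core")
    ref = np.asarray(reference_positions, dtype=float)
    core_idx = np.array([b.index for b in core_beads], dtype=int)
    order = np.argsort(core_idx)           # tie-break: lowest bead index
    core_idx = core_idx[order]
    core_pos = ref[core_idx]
    bonds = []
    for d_bead in d_beads[end_exempt:len(d_beads) - end_exempt]:
        dists = np.linalg.norm(core_pos - ref[d_bead.index], axis=1)
        nearest = int(np.argmin(dists))    # argmin returns first == lowest
        bonds.append(Bond(int(d_bead.index), int(core_idx[nearest]),
                          "harmonic", "dna_core",
                          r0=float(dists[nearest]), k=k_b))
    return bonds


def compute_exclusions(bonds) -> set:
    """All 1-2 and 1-3 neighbour pairs implied by a bond list, as a set of
    sorted index tuples."""
    neighbours = {}
    for bd in bonds:
        neighbours.setdefault(bd.i, set()).add(bd.j)
        neighbours.setdefault(bd.j, set()).add(bd.i)
    excl = set()
    for i, nbrs in neighbours.items():
        for j in nbrs:
            excl.add(tuple(sorted((i, j))))            # 1-2
            for k in neighbours.get(j, ()):            # 1-3 via j
                if k != i:
                    excl.add(tuple(sorted((i, k))))
    return excl


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_topology(top: CGTopology, path):
    """Serialize a topology to a sectioned plain-text format."""
    lines = ["# ncpcg topology; units nm, e, amu, kT"]
    if top.box is not None:
        lines.append("[box]")
        lines.append(" ".join(f"{x:.10g}" for x in top.box))
    lines.append("[beads]")
    lines.append("# index type charge mass x y z group chain resname resid")
    for b in top.beads:
        x, y, z = b.position
        lines.append(f"{b.index} {b.type} {b.charge:.10g} {b.mass:.10g} "
                     f"{x:.10g} {y:.10g} {z:.10g} {b.group} "
                     f"{b.chain or '-'} {b.resname or '-'} {b.resid}")
    lines.append("[bonds]")
    lines.append("# i j style potential r0 k")
    for bd in top.bonds:
        r0 = "nan" if bd.r0 is None else f"{bd.r0:.10g}"
        k = "nan" if bd.k is None else f"{bd.k:.10g}"
        lines.append(f"{bd.i} {bd.j} {bd.style} {bd.potential} {r0} {k}")
    lines.append("[angles]")
    lines.append("# i j k potential")
    for an in top.angles:
        lines.append(f"{an.i} {an.j} {an.k} {an.potential}")
    lines.append("[exclusions]")
    for i, j in sorted(top.exclusions()):
        lines.append(f"{i} {j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path) -> CGTopology:
    section = None
    box = None
    beads, bonds, angles = [], [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        parts = line.split()
        if section == "box":
            box = np.array([float(x) for x in parts])
        elif section == "beads":
            idx, typ, q, m, x, y, z, group, chain, resname, resid = parts
            beads.append(CGBead(int(idx), typ, float(q), float(m),
                                np.array([float(x), float(y), float(z)]),
                                group,
                                chain="" if chain == "-" else chain,
                                resname="" if resname == "-" else resname,
                                resid=int(resid)))
        elif section == "bonds":
            i, j, style, pot, r0, k = parts
            bonds.append(Bond(int(i), int(j), style, pot,
                              r0=None if r0 == "nan" else float(r0),
                              k=None if k == "nan" else float(k)))
        elif section == "angles":
            i, j, k, pot = parts
            angles.append(Angle(int(i), int(j), int(k), pot))
        elif section == "exclusions":
            pass   # recomputed from bonds
    return CGTopology(beads=beads, bonds=bonds, angles=angles, box=box)


def load_pdb_residues(path, unit="angstrom"):
    """Read an atomistic PDB and return per-residue
    ``(code, positions_nm, masses)`` tuples grouped by chain, ready for
    :func:`map_protein`.  Returns ``{chain_id: [residue, ...]}``."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
        u = mda.Universe(str(path))
    scale = 0.1 if unit == "angstrom" else 1.0
    chains = {}
    for res in u.residues:
        seg = str(res.segid or getattr(res, "chainID", "A")).strip() or "A"
        pos = res.atoms.positions * scale
        try:
            masses = res.atoms.masses.copy()
            if np.any(masses <= 0):
                raise ValueError
        except Exception:
            masses = np.ones(len(res.atoms))
        chains.setdefault(seg, []).append((str(res.resname), pos, masses))
    return chains
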