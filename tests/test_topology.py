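"""CG mapping, elastic network, DNA-core restraints, exclusions and
topology serialization."""

import numpy as np
import pytest

from ncpcg.topology import (Angle, BeadTypeTable, Bond, CGBead,
                            DNAUnit, assign_angles, build_dna_core_restraints,
                            build_elastic_network, build_peptide_chain,
                            compute_exclusions, map_dna, map_protein,
                            n_dna_units, read_topology, write_topology)


@pytest.fixture
def table():
    return BeadTypeTable()


def _residue(code, positions, masses=None):
    positions = np.asarray(positions, dtype=float)
    if masses is None:
        masses = np.ones(len(positions))
    return (code, positions, masses)


class TestBeadTypeTable:
    def test_five_types_and_charges(self, table):
        assert set(table.amino_acid_to_type.values()) == \
            {"POL", "NPL", "POS", "NEG", "GLY"}
        assert table.charge_of("POS") == 1.0
        assert table.charge_of("NEG") == -1.0
        for t in ("POL", "NPL", "GLY"):
            assert table.charge_of(t) == 0.0

    def test_every_standard_amino_acid_maps(self, table):
        standard = ("ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET "
                    "PHE PRO SER THR TRP TYR VAL").split()
        assert sorted(table.amino_acid_to_type) == sorted(standard)

    def test_dna_and_ion_charges(self, table):
        assert table.charge_of("P") == -1.0
        assert table.charge_of("D") == 0.0
        assert table.charge_of("MgW6") == 2
        assert table.charge_of("CoHex") == 3

    def test_rejects_wrong_pos_charge(self):
        with pytest.raises(ValueError):
            BeadTypeTable(type_charge={"POL": 0, "NPL": 0, "POS": 2.0,
                                       "NEG": -1.0, "GLY": 0})


class TestMapProtein:
    def test_com_of_symmetric_pair(self, table):
        beads = map_protein([_residue("LYS", [[0, 0, 0], [1, 0, 0]])],
                            table)
        assert beads[0].type == "POS"
        assert beads[0].charge == 1.0
        assert np.allclose(beads[0].position, [0.5, 0, 0])

    def test_mass_weighted_com(self, table):
        beads = map_protein(
            [_residue("SER", [[0, 0, 0], [1, 0, 0]], [3.0, 1.0])], table)
        assert np.allclose(beads[0].position, [0.25, 0, 0])

    def test_glycine_gets_dedicated_type(self, table):
        beads = map_protein([_residue("GLY", [[0, 0, 0]])], table)
        assert beads[0].type == "GLY" and beads[0].charge == 0.0

    def test_unknown_code_raises_with_name(self, table):
        with pytest.raises(KeyError, match="XYZ"):
            map_protein([_residue("XYZ", [[0, 0, 0]])], table)

    def test_empty_residue_raises(self, table):
        with pytest.raises(ValueError):
            map_protein([("ALA", np.zeros((0, 3)), np.zeros(0))], table)

    def test_provenance_reconstructs_partition(self, table):
        codes = ["ALA", "GLY", "LYS", "PRO"]
        residues = [_residue(c, [[i, 0, 0]]) for i, c in enumerate(codes)]
        beads = map_protein(residues, table, chain="H3")
        assert [b.resname for b in beads] == codes
        assert [b.resid for b in beads] == list(range(4))
        assert all(b.chain == "H3" for b in beads)

    def test_eight_residue_chain_bonds_and_angles(self, table):
        codes = ["ALA"] * 8
        residues = [_residue(c, [[0.38 * i, 0, 0.01 * (i % 2)]])
                    for i, c in enumerate(codes)]
        beads, bonds, angles = build_peptide_chain(residues, table)
        assert len(beads) == 8
        assert len(bonds) == 7
        assert len(angles) == 6


class TestMapDNA:
    def _unit(self, shift=0.0):
        phosphates = [(np.array([[shift + 0.1 * k, 0, 0]]),
                       np.array([95.0])) for k in range(4)]
        rest = np.array([[shift, 0.5, 0], [shift, -0.5, 0]])
        return DNAUnit(phosphates, rest, np.array([200.0, 200.0]))

    def test_unit_yields_five_beads_minus_four_charges(self):
        beads = map_dna([self._unit()])
        assert len(beads) == 5
        assert sum(b.type == "P" for b in beads) == 4
        assert sum(b.type == "D" for b in beads) == 1
        assert sum(b.charge for b in beads) == -4.0

    def test_36_bp_duplex_counts(self):
        units = [self._unit(shift=u) for u in range(n_dna_units(36))]
        beads = map_dna(units)
        assert len(units) == 18
        assert len(beads) == 90
        assert sum(b.charge for b in beads) == -72.0

    def test_146_bp_floor_rule(self):
        assert n_dna_units(146) == 73
        assert 5 * n_dna_units(146) == 365

    def test_d_bead_at_com_of_rest_atoms(self):
        unit = DNAUnit([(np.array([[1.0, 1, 1]]), np.array([95.0]))] * 4,
                       np.zeros((3, 3)), np.ones(3))
        d = [b for b in map_dna([unit]) if b.type == "D"][0]
        assert np.allclose(d.position, 0.0)

    def test_wrong_phosphate_count_identifies_unit(self):
        bad = DNAUnit([(np.zeros((1, 3)), np.ones(1))] * 3,
                      np.zeros((1, 3)), np.ones(1))
        with pytest.raises(ValueError, match="unit 0"):
            map_dna([bad])


class TestAssignAngles:
    def _chain(self, codes, group="histone_tail"):
        return [CGBead(i, "NPL", 0, 1, [0.4 * i, 0, 0], group, resname=c)
                for i, c in enumerate(codes)]

    def test_proline_center_gives_angle_pro(self):
        angles = assign_angles(self._chain(["ALA", "PRO", "ALA"]))
        assert len(angles) == 1
        assert angles[0].potential == "Angle_PRO"

    def test_glycine_and_other_types(self):
        angles = assign_angles(self._chain(["ALA", "GLY", "LYS", "SER"]))
        assert [a.potential for a in angles] == ["Angle_GLY",
                                                 "Angle_Other"]

    def test_core_region_has_no_angles(self):
        angles = assign_angles(self._chain(["ALA", "ALA", "ALA"],
                                           group="histone_core"))
        assert angles == []

    def test_interior_count_is_n_minus_2(self):
        assert len(assign_angles(self._chain(["ALA"] * 5))) == 3

    def test_short_chain_returns_empty(self):
        assert assign_angles(self._chain(["ALA", "GLY"])) == []


class TestElasticNetwork:
    def _core(self, xs):
        return [CGBead(i, "POL", 0, 1, [x, 0, 0], "histone_core")
                for i, x in enumerate(xs)]

    def test_line_fixture_strict_cutoff(self):
        # 0, 0.5, 1.2 nm with 0.7 nm cutoff: only the 0.5 nm pair binds;
        # the 0.7 nm pair (beads 1-2) is exactly at cutoff and excluded
        core = self._core([0.0, 0.5, 1.2])
        bonds = build_elastic_network(core, [[0, 0, 0], [0.5, 0, 0],
                                             [1.2, 0, 0]], cutoff=0.7)
        assert len(bonds) == 1
        assert bonds[0].pair == (0, 1)
        assert bonds[0].r0 == pytest.approx(0.5)

    def test_exactly_at_cutoff_is_excluded(self):
        core = self._core([0.0, 0.7])
        assert build_elastic_network(core, [[0, 0, 0], [0.7, 0, 0]],
                                     cutoff=0.7) == []

    def test_default_stiffness_is_5kt_per_angstrom2(self):
        core = self._core([0.0, 0.5])
        bonds = build_elastic_network(core, [[0, 0, 0], [0.5, 0, 0]])
        # 5 kT/A^2 == 500 kT/nm^2
        assert bonds[0].k == pytest.approx(500.0)

    def test_energy_zero_at_reference(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 1.2, (20, 3))
        core = [CGBead(i, "POL", 0, 1, ref[i], "histone_core")
                for i in range(20)]
        bonds = build_elastic_network(core, ref)
        e = sum(0.5 * b.k * (np.linalg.norm(ref[b.j] - ref[b.i])
                             - b.r0) ** 2 for b in bonds)
        assert e == pytest.approx(0.0, abs=1e-20)

    def test_count_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 1.5, (30, 3))
        core = [CGBead(i, "POL", 0, 1, ref[i], "histone_core")
                for i in range(30)]
        n0 = len(build_elastic_network(core, ref))
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [0.5, -1.0, 2.2]).as_matrix()
        moved = ref @ rot.T + np.array([3.0, -1.0, 0.5])
        assert len(build_elastic_network(core, moved)) == n0

    def test_existing_12_bonds_not_duplicated(self):
        core = self._core([0.0, 0.5])
        bonds = build_elastic_network(core, [[0, 0, 0], [0.5, 0, 0]],
                                      existing_bonds=[(0, 1)])
        assert bonds == []

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            build_elastic_network(self._core([0.0]), [[0, 0, 0]],
                                  cutoff=0.0)


class TestDNACoreRestraints:
    def _setup(self, n_d=10):
        d_beads = [CGBead(i, "D", 0, 1, [0.5 * i, 1.0, 0], "dna")
                   for i in range(n_d)]
        core = [CGBead(100 + i, "POL", 0, 1, [0.5 * i, 0, 0],
                       "histone_core") for i in range(n_d)]
        ref = np.zeros((200, 3))
        for b in d_beads + core:
            ref[b.index] = b.position
        return d_beads, core, ref

    def test_ten_d_beads_give_six_restraints(self):
        d_beads, core, ref = self._setup()
        bonds = build_dna_core_restraints(d_beads, core, ref)
        assert len(bonds) == 6
        restrained = {b.i for b in bonds}
        assert restrained == {2, 3, 4, 5, 6, 7}   # 2 exempt at each end

    def test_reduced_variant_two_fewer_bonds_per_end(self):
        d_beads, core, ref = self._setup()
        bonds = build_dna_core_restraints(d_beads, core, ref, end_exempt=4)
        assert len(bonds) == 2

    def test_equilibrium_is_reference_distance(self):
        d_beads, core, ref = self._setup()
        for b in build_dna_core_restraints(d_beads, core, ref):
            assert b.r0 == pytest.approx(1.0)
            assert b.k == pytest.approx(500.0)

    def test_tie_breaks_to_lowest_core_index(self):
        d_beads = [CGBead(i, "D", 0, 1, [float(i), 1.0, 0], "dna")
                   for i in range(5)]
        # two equidistant core beads for the single interior D bead
        core = [CGBead(10, "POL", 0, 1, [2.0, 0, 0], "histone_core"),
                CGBead(11, "POL", 0, 1, [2.0, 2.0, 0], "histone_core")]
        ref = np.zeros((12, 3))
        for b in d_beads + core:
            ref[b.index] = b.position
        bonds = build_dna_core_restraints(d_beads, core, ref)
        assert all(b.j == 10 for b in bonds)

    def test_too_few_d_beads_raise(self):
        d_beads, core, ref = self._setup(n_d=4)
        with pytest.raises(ValueError):
            build_dna_core_restraints(d_beads, core, ref)


class TestExclusions:
    def test_matches_brute_force_on_random_chains(self):
        import networkx as nx
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 12
            edges = set()
            while len(edges) < 14:
                i, j = sorted(rng.integers(0, n, 2))
                if i != j:
                    edges.add((int(i), int(j)))
            bonds = [Bond(i, j, "harmonic", "b", r0=0.1, k=1.0)
                     for i, j in edges]
            got = compute_exclusions(bonds)
            g = nx.Graph(list(edges))
            expected = set()
            for i in g.nodes:
                for j, dist in nx.single_source_shortest_path_length(
                        g, i, cutoff=2).items():
                    if j != i and dist <= 2:
                        expected.add(tuple(sorted((i, j))))
            assert got == expected

    def test_linear_chain_12_and_13_only(self):
        bonds = [Bond(i, i + 1, "table", "b") for i in range(4)]
        excl = compute_exclusions(bonds)
        assert excl == {(0, 1), (1, 2), (2, 3), (3, 4),
                        (0, 2), (1, 3), (2, 4)}


class TestTopologySerialization:
    def test_round_trip(self, tmp_path, mini_ncp):
        path = tmp_path / "topology.txt"
        write_topology(mini_ncp.topology, path)
        back = read_topology(path)
        top = mini_ncp.topology
        assert back.n_beads == top.n_beads
        assert np.allclose(back.positions, top.positions)
        assert np.allclose(back.charges, top.charges)
        assert back.types == top.types
        assert len(back.bonds) == len(top.bonds)
        assert len(back.angles) == len(top.angles)
        assert back.exclusions() == top.exclusions()
        assert np.allclose(back.box, top.box)


def test_neutral_system_total_charge(mini_ncp):
    assert abs(mini_ncp.topology.total_charge()) < 1e-12


def test_elastic_bonds_connect_only_core(mini_ncp):
    groups = mini_ncp.topology.groups
    for bd in mini_ncp.topology.bonds:
        if bd.potential == "elastic":
            assert groups[bd.i] == groups[bd.j] == "histone_core"
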