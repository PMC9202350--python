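"""Energy/force terms: Coulomb (direct and Ewald), excluded volume,
harmonic bonds, per-class breakdown and force-gradient consistency."""

import numpy as np
import pytest

from ncpcg.fixtures import harmonic_table, lj_table
from ncpcg.potentials import (CoulombTerm, ExcludedVolumeTerm,
                              HarmonicBondTerm, InteractionSet,
                              coulomb_energy, ewald_energy, forces,
                              total_energy)
from ncpcg.topology import Angle, Bond, CGBead, CGTopology
from ncpcg.units import bjerrum_length


class TestCoulomb:
    def test_zero_charge_gives_zero(self):
        assert coulomb_energy(0.0, 1.0, 0.5) == 0.0

    def test_unit_charges_one_nm_vacuum(self):
        # k_e in molar units: ~138.935 kJ/mol for e^2/nm
        assert coulomb_energy(1, 1, 1.0, epsilon_r=1.0) == \
            pytest.approx(138.935, rel=1e-3)

    def test_linearity_in_inverse_permittivity(self):
        e1 = coulomb_energy(1, 1, 1.0, epsilon_r=1.0)
        e78 = coulomb_energy(1, 1, 1.0, epsilon_r=78.0)
        assert e78 == pytest.approx(e1 / 78.0)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            coulomb_energy(1, 1, 0.0)

    def test_shifted_cutoff_vanishes_at_cutoff(self):
        term = CoulombTerm(cutoff=2.0)
        assert term.pair_energy(1, 1, 2.0) == 0.0
        assert term.pair_energy(1, 1, 2.5) == 0.0
        assert term.pair_energy(1, -1, 1.0) < 0

    def test_symmetry_and_charge_scaling(self):
        term = CoulombTerm()
        assert term.pair_energy(2, -1, 0.8) == term.pair_energy(-1, 2, 0.8)
        assert term.pair_energy(2, 2, 0.8) == \
            pytest.approx(4 * term.pair_energy(1, 1, 0.8))


class TestEwald:
    def test_isolated_pair_large_box_limit(self):
        # a +-e pair in a huge box: periodic images negligible, the
        # energy approaches the bare Coulomb value
        box = np.array([40.0] * 3)
        pos = np.array([[20.0, 20, 20], [21.0, 20, 20]])
        q = np.array([1.0, -1.0])
        e = ewald_energy(pos, q, box, epsilon_r=78.0, accuracy=1e-7)
        lb = bjerrum_length(310.0, 78.0)
        assert e == pytest.approx(-lb / 1.0, rel=1e-3)

    def test_splitting_parameter_invariance(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 3.0, (10, 3))
        q = np.array([1.0, -1.0] * 5)
        box = np.array([3.0] * 3)
        e1 = ewald_energy(pos, q, box, accuracy=1e-7)
        e2 = ewald_energy(pos, q, box, accuracy=1e-7, alpha=2.5)
        assert e1 == pytest.approx(e2, rel=1e-5)

    def test_rock_salt_madelung_energy(self):
        # 8-ion NaCl-type cell: E_total = N * (-M * l_B / d) / 2 with the
        # literature Madelung constant M = 1.7475645946
        d = 0.3
        pos, q = [], []
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    pos.append([i * d, j * d, k * d])
                    q.append((-1.0) ** (i + j + k))
        e = ewald_energy(np.array(pos), np.array(q),
                         np.array([2 * d] * 3), epsilon_r=1.0,
                         accuracy=1e-8)
        lb = bjerrum_length(310.0, 1.0)
        e_ref = 8 * (-1.7475645946 * lb / d) / 2
        assert e == pytest.approx(e_ref, rel=1e-3)

    def test_direct_evjen_lattice_sum_agrees(self):
        # independent oracle: direct lattice sum with Evjen fractional
        # weights on the boundary of a (2m)^3-image block
        d = 0.3
        m = 6
        total = 0.0
        for i in range(-m, m + 1):
            for j in range(-m, m + 1):
                for k in range(-m, m + 1):
                    if i == j == k == 0:
                        continue
                    w = 1.0
                    for c in (i, j, k):
                        if abs(c) == m:
                            w *= 0.5
                    total += w * (-1.0) ** (i + j + k) / (
                        d * np.sqrt(i * i + j * j + k * k))
        lb = bjerrum_length(310.0, 1.0)
        e_direct_per_ion = lb * total / 2 * 2   # site energy * q_i / 2
        pos, q = [], []
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    pos.append([i * d, j * d, k * d])
                    q.append((-1.0) ** (i + j + k))
        e = ewald_energy(np.array(pos), np.array(q),
                         np.array([2 * d] * 3), epsilon_r=1.0,
                         accuracy=1e-8)
        assert e / 8 == pytest.approx(e_direct_per_ion / 2, rel=1e-3)

    def test_net_charge_requires_flag(self):
        pos = np.array([[0.5, 0.5, 0.5]])
        with pytest.raises(ValueError, match="net charge"):
            ewald_energy(pos, np.array([1.0]), np.array([3.0] * 3))
        e = ewald_energy(pos, np.array([1.0]), np.array([3.0] * 3),
                         allow_net_charge=True)
        assert np.isfinite(e)


class TestExcludedVolume:
    def setup_method(self):
        self.term = ExcludedVolumeTerm(sigma={"A": 0.3, "B": 0.5})

    def test_combining_rule(self):
        assert self.term.sigma_ij("A", "B") == pytest.approx(0.4)

    def test_non_negative_and_zero_beyond_minimum(self):
        s = 0.4
        r = np.linspace(0.2, 1.0, 200)
        u = self.term.pair_energy(s, r)
        assert np.all(u >= 0)
        assert np.all(u[r >= 2 ** (1 / 6) * s] == 0)

    def test_strictly_decreasing_below_truncation(self):
        s = 0.4
        r = np.linspace(0.2, 2 ** (1 / 6) * s - 1e-4, 100)
        u = self.term.pair_energy(s, r)
        assert np.all(np.diff(u) < 0)

    def test_continuous_at_truncation(self):
        s = 0.4
        rc = 2 ** (1 / 6) * s
        assert self.term.pair_energy(s, rc - 1e-9) == \
            pytest.approx(0.0, abs=1e-6)


class TestHarmonicBond:
    def test_zero_at_equilibrium_and_symmetry(self):
        term = HarmonicBondTerm(k=500.0, r0=0.4)
        assert term.energy(0.4) == 0.0
        assert term.energy(0.45) == pytest.approx(term.energy(0.35))
        assert term.force(0.45) == pytest.approx(-500.0 * 0.05)


def _toy_system():
    """Charged 4-bead chain plus a free ion, with every term class."""
    beads = [
        CGBead(0, "POS", 1.0, 100.0, [1.0, 1.0, 1.0], "histone_tail"),
        CGBead(1, "GLY", 0.0, 60.0, [1.4, 1.0, 1.0], "histone_tail"),
        CGBead(2, "NEG", -1.0, 100.0, [1.8, 1.05, 1.0], "histone_tail"),
        CGBead(3, "POL", 0.0, 90.0, [2.2, 1.1, 1.05], "histone_tail"),
        CGBead(4, "Cl", -1.0, 35.0, [2.0, 2.0, 2.0], "ion"),
        CGBead(5, "K", 1.0, 39.0, [0.6, 2.2, 1.4], "ion"),
    ]
    bonds = [Bond(0, 1, "harmonic", "elastic0", r0=0.4, k=400.0),
             Bond(1, 2, "table", "Bond_AA"),
             Bond(2, 3, "table", "Bond_AA")]
    angles = [Angle(1, 2, 3, "Angle_Other")]
    top = CGTopology(beads=beads, bonds=bonds, angles=angles,
                     box=np.array([4.0, 4.0, 4.0]))
    terms = InteractionSet(
        pair_tables={("Cl", "K"): lj_table(sigma=0.3, epsilon=0.5,
                                           r_min=0.15, r_cut=1.4)},
        bond_tables={"Bond_AA": harmonic_table(300.0, 0.4, 0.1, 1.0)},
        angle_tables={"Angle_Other": harmonic_table(
            0.004, 120.0, 0.0, 180.0, kind="angle")},
        coulomb=CoulombTerm(cutoff=1.8),
        excluded_volume=ExcludedVolumeTerm(
            sigma={"POS": 0.32, "GLY": 0.22, "NEG": 0.3, "POL": 0.28,
                   "Cl": 0.18, "K": 0.15}))
    return top, terms


class TestTotalEnergy:
    def test_single_bead_all_zero(self):
        top = CGTopology(beads=[CGBead(0, "K", 1.0, 39.0, [1, 1, 1],
                                       "ion")], box=np.array([4.0] * 3))
        out = total_energy(top, InteractionSet(coulomb=CoulombTerm()))
        assert out["total"] == 0.0

    def test_breakdown_is_additive(self):
        top, terms = _toy_system()
        out = total_energy(top, terms)
        parts = sum(v for k, v in out.items() if k != "total")
        assert parts == pytest.approx(out["total"], rel=1e-12)

    def test_toggling_one_class_changes_total_by_that_class(self):
        top, terms = _toy_system()
        full = total_energy(top, terms)
        wanted = [c for c in full if c != "total" and c != "coulomb"]
        partial = total_energy(top, terms, classes=wanted)
        assert full["total"] - partial["total"] == \
            pytest.approx(full["coulomb"], rel=1e-9)

    def test_elastic_only_core_zero_at_reference(self):
        rng = np.random.default_rng(4)
        ref = 1.0 + rng.uniform(0, 1.0, (15, 3))
        from ncpcg.topology import build_elastic_network
        beads = [CGBead(i, "POL", 0, 100.0, ref[i], "histone_core")
                 for i in range(15)]
        bonds = build_elastic_network(beads, ref)
        top = CGTopology(beads=beads, bonds=bonds,
                         box=np.array([6.0] * 3))
        out = total_energy(top, InteractionSet(), classes=["bond"])
        assert out["bond"] == pytest.approx(0.0, abs=1e-18)

    def test_13_neighbors_excluded_from_nonbonded(self):
        # 3-bead chain: beads 0-2 are 1-3 neighbours; only the ion pairs
        # remain for Coulomb.  Hand-computed over remaining pairs.
        beads = [CGBead(0, "POS", 1.0, 1, [1.0, 1, 1], "histone_tail"),
                 CGBead(1, "GLY", 0.0, 1, [1.4, 1, 1], "histone_tail"),
                 CGBead(2, "NEG", -1.0, 1, [1.8, 1, 1], "histone_tail")]
        bonds = [Bond(0, 1, "harmonic", "b", r0=0.4, k=1.0),
                 Bond(1, 2, "harmonic", "b", r0=0.4, k=1.0)]
        top = CGTopology(beads=beads, bonds=bonds,
                         box=np.array([4.0] * 3))
        term = CoulombTerm(cutoff=1.8)
        out = total_energy(top, InteractionSet(coulomb=term))
        assert out["coulomb"] == pytest.approx(0.0, abs=1e-15)

    def test_missing_angle_table_reported(self):
        top, terms = _toy_system()
        terms.angle_tables.clear()
        with pytest.raises(KeyError, match="Angle_Other"):
            total_energy(top, terms)


class TestForceConsistency:
    @pytest.mark.parametrize("cls", ["bond", "angle", "coulomb",
                                     "short_range", "excluded_volume"])
    def test_forces_match_numerical_gradient(self, cls):
        top, terms = _toy_system()
        rng = np.random.default_rng(17)
        h = 1e-6
        worst = 0.0
        for rep in range(20):
            pos = top.positions + rng.normal(0, 0.03,
                                             top.positions.shape)
            f = forces(top, terms, positions=pos, classes=[cls])
            i = int(rng.integers(0, top.n_beads))
            a = int(rng.integers(0, 3))
            for sign in (1,):
                pp = pos.copy()
                pp[i, a] += h
                ep = total_energy(top, terms, positions=pp,
                                  classes=[cls])["total"]
                pm = pos.copy()
                pm[i, a] -= h
                em = total_energy(top, terms, positions=pm,
                                  classes=[cls])["total"]
                num = -(ep - em) / (2 * h)
                denom = max(abs(num), abs(f[i, a]), 1e-4)
                worst = max(worst, abs(num - f[i, a]) / denom)
        assert worst < 1e-4

    def test_translation_invariance(self):
        top, terms = _toy_system()
        e0 = total_energy(top, terms)["total"]
        e1 = total_energy(top, terms,
                          positions=top.positions + 1.234)["total"]
        assert e1 == pytest.approx(e0, rel=1e-9)
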