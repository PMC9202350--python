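"""Structural and aggregation observables: RMSD, Rg/Dmax, core-core
RDF, valency, body frames and SDFs, effective pair potential."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ncpcg.analysis import (BodyFrame, core_com_rdf,
                            effective_pair_potential, rg_dmax,
                            rmsd_to_reference, sdf, valency, write_sdf_dx)
from ncpcg.fixtures import MiniNCPSpec, make_aggregate_configuration


class TestRMSD:
    def test_identical_structures_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3))
        assert rmsd_to_reference(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        rot = Rotation.from_euler("zyx", [1.2, -0.4, 2.8]).as_matrix()
        moved = x @ rot.T + np.array([5.0, -3.0, 1.0])
        assert rmsd_to_reference(moved, x) == pytest.approx(0.0,
                                                            abs=1e-9)

    def test_matches_brute_force_rotation_search(self):
        """Oracle: exhaustive search over a fine Euler-angle grid for a
        4-bead toy pair."""
        a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        rng = np.random.default_rng(2)
        b = a + rng.normal(0, 0.1, a.shape)
        got = rmsd_to_reference(b, a)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        best = np.inf
        grid = np.arange(0.0, 2 * np.pi, 0.05)
        half = np.arange(0.0, np.pi, 0.05)
        for alpha in grid:
            for beta in half:
                for gamma in grid:
                    rot = Rotation.from_euler(
                        "zyz", [alpha, beta, gamma]).as_matrix()
                    val = np.sqrt(np.mean(
                        np.sum((bc @ rot.T - ac) ** 2, axis=1)))
                    if val < best:
                        best = val
        assert got <= best + 1e-9
        assert got == pytest.approx(best, abs=2e-3)

    def test_superposed_never_exceeds_unsuperposed(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=(15, 3))
            b = rng.normal(size=(15, 3))
            assert rmsd_to_reference(b, a) <= \
                rmsd_to_reference(b, a, superpose=False) + 1e-12

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd_to_reference(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_selection_restricts_comparison(self):
        a = np.zeros((4, 3))
        b = np.zeros((4, 3))
        b[3] = [9.0, 9, 9]
        assert rmsd_to_reference(b, a, selection=[0, 1, 2]) == \
            pytest.approx(0.0, abs=1e-12)


class TestRgDmax:
    def test_unit_mass_dimer(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        rg, dmax = rg_dmax(pos)
        assert rg == pytest.approx(0.5)
        assert dmax == pytest.approx(1.0)

    def test_uniform_ring_closed_form(self):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        ring = np.stack([2.0 * np.cos(theta), 2.0 * np.sin(theta),
                         np.zeros_like(theta)], axis=1)
        rg, dmax = rg_dmax(ring)
        assert rg == pytest.approx(2.0, rel=1e-6)
        assert dmax == pytest.approx(4.0, rel=1e-3)

    def test_mass_weighting(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        rg, _ = rg_dmax(pos, masses=[3.0, 1.0])
        # COM at 0.25; Rg = sqrt((3*0.0625 + 1*0.5625)/4)
        assert rg == pytest.approx(np.sqrt(0.1875))

    def test_single_bead_policy(self):
        with pytest.raises(ValueError):
            rg_dmax(np.zeros((1, 3)))
        assert rg_dmax(np.zeros((1, 3)), allow_single=True) == (0.0, 0.0)

    def test_wrapped_molecule_detected(self):
        pos = np.array([[0.1, 0, 0], [3.9, 0, 0]])
        with pytest.raises(ValueError, match="wrap"):
            rg_dmax(pos, box=[4.0, 4.0, 4.0], bonds=[(0, 1)])


class TestCoreComRDF:
    def test_two_fixed_particles_single_peak(self):
        frames = np.zeros((1, 4, 3))
        frames[0] = [[5, 5, 5], [5, 5, 5.2], [5, 5, 11.43],
                     [5, 5, 11.65]]
        box = np.array([30.0] * 3)
        edges = np.arange(0.0, 10.0, 0.1)
        rdf = core_com_rdf(frames, [[0, 1], [2, 3]], box, edges)
        nz = np.nonzero(rdf.g)[0]
        assert len(nz) == 1
        assert rdf.edges[nz[0]] <= 6.44 <= rdf.edges[nz[0] + 1]

    def test_three_particle_stack_weights(self):
        # spacings 6, 6, 12 -> distances {6, 6, 12}: 2:1 bin weights
        frames = np.zeros((1, 3, 3))
        frames[0, :, 2] = [5.0, 11.0, 17.0]
        frames[0, :, 0] = frames[0, :, 1] = 20.0
        box = np.array([40.0] * 3)
        edges = np.arange(0.0, 15.0, 0.5)
        rdf = core_com_rdf(frames, [[0], [1], [2]], box, edges)
        counts = rdf.meta["counts"]
        b6 = np.searchsorted(edges, 6.0, side="right") - 1
        b12 = np.searchsorted(edges, 12.0, side="right") - 1
        assert counts[b6] == 2 and counts[b12] == 1

    def test_single_particle_rejected(self):
        with pytest.raises(ValueError):
            core_com_rdf(np.zeros((1, 2, 3)), [[0, 1]],
                         np.array([4.0] * 3), np.arange(0, 2, 0.1))


class TestValency:
    def _frames(self, *particles):
        n = sum(len(p) for p in particles)
        frame = np.concatenate([np.asarray(p, dtype=float)
                                for p in particles])
        idx = []
        start = 0
        for p in particles:
            idx.append(np.arange(start, start + len(p)))
            start += len(p)
        return frame[None], idx

    def test_contacting_pair_has_valency_one(self):
        frames, idx = self._frames([[0, 0, 0.0]], [[0.5, 0, 0]])
        assert valency(frames, idx, cutoff=1.0).mean == 1.0

    def test_mutual_triplet_has_valency_two(self):
        # equilateral triangle, all pairs in contact: 6 ordered contacts
        # over 3 particles
        frames, idx = self._frames([[0, 0, 0.0]], [[0.8, 0, 0]],
                                   [[0.4, 0.7, 0]])
        assert valency(frames, idx, cutoff=1.0).mean == 2.0

    def test_dilute_gas_near_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (10, 1, 3))
        frames = pts.reshape(1, 10, 3)
        idx = [np.array([i]) for i in range(10)]
        assert valency(frames, idx, cutoff=1.0).mean == 0.0

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 5, (3, 8, 3))
        idx = [np.array([i]) for i in range(8)]
        means = [valency(frames, idx, cutoff=c).mean
                 for c in (0.5, 1.0, 2.0, 4.0)]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 3, (2, 6, 3))
        idx = [np.array([i, i + 3]) for i in range(3)]
        v1 = valency(frames, idx, cutoff=1.5).mean
        v2 = valency(frames, idx[::-1], cutoff=1.5).mean
        assert v1 == v2

    def test_contact_record_fields(self):
        frames, idx = self._frames([[0, 0, 0.0]], [[0.5, 0, 0]])
        res = valency(frames, idx, cutoff=1.0, keep_contacts=True)
        (rec,) = res.contacts
        assert rec.pair == (0, 1)
        assert rec.min_distance == pytest.approx(0.5)
        assert rec.in_contact

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            valency(np.zeros((0, 2, 3)), [[0], [1]], cutoff=1.0)


class TestBodyFrame:
    def _wedge(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        th = rng.uniform(0, 2 * np.pi, n)
        r = np.empty(n)
        z = np.empty(n)
        half = n // 2
        r[:half] = 1.6 * np.sqrt(rng.random(half))
        z[:half] = -0.25
        r[half:] = 1.0 * np.sqrt(rng.random(n - half))
        z[half:] = 0.25
        return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)

    def test_axes_orthonormal_and_right_handed(self):
        pos = self._wedge()
        bf = BodyFrame.from_positions(pos, x_reference=pos[0])
        assert np.allclose(bf.axes @ bf.axes.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(bf.axes) == pytest.approx(1.0)

    def test_deterministic_and_body_attached(self):
        pos = self._wedge()
        bf1 = BodyFrame.from_positions(pos, x_reference=pos[3])
        rot = Rotation.from_euler("xyz", [0.7, -1.1, 0.3]).as_matrix()
        moved = pos @ rot.T + np.array([2.0, 1.0, -4.0])
        bf2 = BodyFrame.from_positions(moved, x_reference=moved[3])
        # body coordinates of every bead are preserved
        assert np.allclose(bf1.to_body(pos), bf2.to_body(moved),
                           atol=1e-9)

    def test_spherical_cloud_rejected(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(size=(4000, 3))
        with pytest.raises(ValueError, match="degenerate|symmetric"):
            BodyFrame.from_positions(pos, x_reference=pos[0],
                                     degeneracy_tol=0.2)


class TestSDF:
    def _stack(self, spacing=1.2):
        spec = MiniNCPSpec()
        frame, parts, box = make_aggregate_configuration(2, "stack",
                                                         spacing, spec)
        return frame, parts, box

    def test_probability_normalization(self):
        frame, parts, _ = self._stack()
        edges = [np.linspace(-6, 6, 13)] * 3
        grid = sdf([frame], parts[0]["core"], parts[1]["dna"], edges,
                   x_reference_indices=parts[0]["dna_ends"])
        assert grid.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(grid.density >= 0)

    def test_stacked_neighbour_mass_is_axial(self):
        frame, parts, _ = self._stack()
        edges = [np.linspace(-6, 6, 13)] * 3
        grid = sdf([frame], parts[0]["core"], parts[1]["dna"], edges,
                   x_reference_indices=parts[0]["dna_ends"])
        z_profile = grid.density.sum(axis=(0, 1))
        lateral = grid.density.sum(axis=2)
        centers_z = grid.centers[2]
        axial_mass = z_profile[np.abs(centers_z) >= 0.5].sum()
        assert axial_mass == pytest.approx(1.0, abs=1e-9)
        assert lateral[0, :].sum() == pytest.approx(0.0, abs=1e-12)

    def test_global_rotation_covariance(self):
        frame, parts, _ = self._stack()
        edges = [np.linspace(-6, 6, 13)] * 3
        g1 = sdf([frame], parts[0]["core"], parts[1]["dna"], edges,
                 x_reference_indices=parts[0]["dna_ends"])
        rot = Rotation.from_euler("xyz", [0.9, 0.2, -1.4]).as_matrix()
        g2 = sdf([frame @ rot.T], parts[0]["core"], parts[1]["dna"],
                 edges, x_reference_indices=parts[0]["dna_ends"])
        assert np.max(np.abs(g1.density - g2.density)) < 1e-9

    def test_stack_and_perpendicular_are_distinguishable(self):
        spec = MiniNCPSpec()
        edges = [np.linspace(-6, 6, 13)] * 3
        f1, p1, _ = make_aggregate_configuration(2, "stack", 1.2, spec)
        f2, p2, _ = make_aggregate_configuration(2, "perpendicular", 3.4,
                                                 spec)
        g1 = sdf([f1], p1[0]["core"], p1[1]["dna"], edges,
                 x_reference_indices=p1[0]["dna_ends"])
        g2 = sdf([f2], p2[0]["core"], p2[1]["dna"], edges,
                 x_reference_indices=p2[0]["dna_ends"])
        overlap = np.minimum(g1.density, g2.density).sum()
        assert overlap < 0.2

    def test_isotropic_targets_uniform(self):
        # targets uniform in a ball; the grid cube inscribed in the ball
        # is rotation-proof, so every voxel is equally likely
        rng = np.random.default_rng(7)
        core = self._wedge_cloud(rng)
        n_t = 40_000
        raw = rng.normal(size=(n_t, 3))
        raw /= np.linalg.norm(raw, axis=1)[:, None]
        target = raw * 3.0 * rng.random(n_t)[:, None] ** (1 / 3)
        frame = np.concatenate([core, target])
        half = 3.0 / np.sqrt(3.0)
        edges = [np.linspace(-half, half, 4)] * 3
        grid = sdf([frame], np.arange(len(core)),
                   len(core) + np.arange(n_t), edges,
                   x_reference_indices=[0], mode="probability")
        # in-grid target count from the body coordinates
        bf = BodyFrame.from_positions(core, x_reference=core[0])
        inside = np.all(np.abs(bf.to_body(target)) < half, axis=1)
        observed = grid.density * inside.sum()
        expected = inside.sum() / 27
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert chi2 < 27 + 4 * np.sqrt(2 * 27)

    @staticmethod
    def _wedge_cloud(rng, n=300):
        th = rng.uniform(0, 2 * np.pi, n)
        r = np.empty(n)
        z = np.empty(n)
        half = n // 2
        r[:half] = 1.2 * np.sqrt(rng.random(half))
        z[:half] = -0.2
        r[half:] = 0.7 * np.sqrt(rng.random(n - half))
        z[half:] = 0.2
        return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)

    def test_dx_output_well_formed(self, tmp_path):
        frame, parts, _ = self._stack()
        edges = [np.linspace(-6, 6, 7)] * 3
        grid = sdf([frame], parts[0]["core"], parts[1]["dna"], edges,
                   x_reference_indices=parts[0]["dna_ends"])
        path = tmp_path / "sdf.dx"
        write_sdf_dx(grid, path)
        text = path.read_text()
        assert "gridpositions counts 6 6 6" in text
        assert "items 216" in text


class TestEffectivePairPotential:
    def test_flat_rdf_gives_zero_potential(self):
        from ncpcg.distributions import RDF
        edges = np.arange(0.4, 2.4 + 1e-9, 0.1)
        g = RDF(pair=("NCP", "NCP"), edges=edges,
                g=np.ones(edges.size - 1), n_frames=1, density=0.02)
        pot, res = effective_pair_potential(g, density=0.02, seed=3,
                                            n_steps=120_000,
                                            sample_every=300)
        assert res.converged
        assert np.max(np.abs(pot.u)) < 0.1

    def test_dilute_limit_recovery(self, closure_report):
        """Inverting g = exp(-U*) at low density returns U* within
        0.2 kT, and the final sampled RDF matches the target within
        0.05."""
        assert closure_report["result"].converged
        assert closure_report["max_u_err"] < 0.2
        assert closure_report["max_g_dev"] < 0.05

    def test_range_exceeding_half_box_rejected(self):
        from ncpcg.distributions import RDF
        edges = np.arange(0.4, 8.0, 0.1)
        g = RDF(pair=("NCP", "NCP"), edges=edges,
                g=np.ones(edges.size - 1), n_frames=1, density=0.05)
        with pytest.raises(ValueError, match="half the box"):
            effective_pair_potential(g, density=0.05, n_particles=27)
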