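"""Self-contained validation benchmarks.

Each function builds its own synthetic inputs from a seed, runs one
pipeline stage end to end, and returns the measured quantities.  They
back both the test suite and the reproduction script, so the numbers
reported there are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .analysis import (effective_pair_potential, rg_dmax,
                       rmsd_to_reference, sdf, valency)
from .distributions import RDF, rdf_rmsf
from .engine import CompiledModel
from .fixtures import (MiniNCPSpec, ToyFluidSpec, harmonic_table, lj_table,
                       make_aggregate_configuration, make_toy_fluid)
from .inversion import (InversionProblem, boltzmann_invert, run_inversion)
from .potentials import (CoulombTerm, ExcludedVolumeTerm, InteractionSet,
                         ewald_energy, forces, total_energy)
from .sampler import (AnnealingSchedule, SamplerConfig, rdf_from_traj,
                      run_annealed, run_ld, run_mc)
from .tables import TabulatedPotential
from .topology import (Angle, Bond, CGBead, CGTopology,
                       build_dna_core_restraints, build_elastic_network)
from .units import bjerrum_length

MADELUNG_NACL = 1.7475645946331822


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def toy_fluid_bundle(seed=3):
    return make_toy_fluid(ToyFluidSpec(seed=seed))


def inversion_recovery(toy=None, seed=11):
    """IBI-then-IMC recovery of the toy-fluid potential from zero.
    Returns max |g - g_ref| at convergence and max |U - U*| (kT) where
    g_ref > 0.1, after shift alignment."""
    toy = toy or toy_fluid_bundle()
    cfg = SamplerConfig(mode="MC", n_steps=1_200_000, sample_every=800,
                        mc_max_disp=0.35, seed=seed)
    problem = InversionProblem(build=toy.rebuild,
                               target_rdfs=toy.reference_rdfs,
                               sampler_config=cfg, n_ibi=10,
                               max_iterations=40, tolerance=0.05)
    result = run_inversion(problem)
    ref = toy.reference_rdfs[("A", "A")]
    mask = ref.g > 0.1
    u_true = toy.ground_truth[("A", "A")].evaluate(ref.centers)[0]
    u_true -= u_true[-1]
    rec = result.potentials[("A", "A")]
    u_rec = rec.u - rec.u[-1]
    return {
        "result": result,
        "max_g_dev": result.log[-1]["max_dev"],
        "max_u_err": float(np.max(np.abs(u_rec[mask] - u_true[mask]))),
        "converged": result.converged,
        "iterations": result.iterations,
    }


def imc_jacobian_fraction(toy=None, seed=31):
    """Fraction of IMC Jacobian entries where -beta Cov(S_a, S_g)
    matches the central finite difference of <S_a> under +-0.05 kT
    per-bin perturbations, within 3 combined Monte-Carlo standard
    errors, on a 5-bin system."""
    from .inversion import IMCState
    toy = toy or toy_fluid_bundle()
    edges = np.arange(0.3, 0.8 + 1e-9, 0.1)
    fine_r = np.arange(0.3, 1.2 + 1e-9, 0.005)
    base_u = toy.ground_truth[("A", "A")].resampled(fine_r)
    cfg = dict(mode="MC", n_steps=900_000, sample_every=1500,
               mc_max_disp=0.35)

    def block_se(x, nb=20):
        cut = (x.shape[0] // nb) * nb
        b = x[:cut].reshape(nb, -1, x.shape[1]).mean(axis=1)
        return b.std(axis=0, ddof=1) / np.sqrt(nb)

    def sample_s(pot, s):
        model, pos0 = toy.rebuild({("A", "A"): pot})
        res = run_mc(model, pos0, SamplerConfig(**cfg, seed=s))
        _, sf = rdf_from_traj(model, res.frames[120:], [("A", "A")],
                              edges, return_observables=True)
        return sf

    s0 = sample_s(base_u, seed)
    state = IMCState(s0, s0.mean(axis=0))
    jac = -state.covariance
    nb_blocks = 20
    cut = (s0.shape[0] // nb_blocks) * nb_blocks
    cov_blocks = []
    for b in range(nb_blocks):
        blk = s0[:cut].reshape(nb_blocks, -1, s0.shape[1])[b]
        d = blk - blk.mean(axis=0)
        cov_blocks.append(d.T @ d / blk.shape[0])
    se_cov = np.std(cov_blocks, axis=0, ddof=1) / np.sqrt(nb_blocks)
    nb = edges.size - 1
    delta = 0.05
    hits = total = 0
    for g in range(nb):
        in_bin = (fine_r >= edges[g]) & (fine_r <= edges[g + 1])
        up, dn = base_u.u.copy(), base_u.u.copy()
        up[in_bin] += delta
        dn[in_bin] -= delta
        sp = sample_s(TabulatedPotential(fine_r, up), seed + 100 + g)
        sm = sample_s(TabulatedPotential(fine_r, dn), seed + 200 + g)
        fd = (sp.mean(axis=0) - sm.mean(axis=0)) / (2 * delta)
        se_fd = np.sqrt(block_se(sp) ** 2 + block_se(sm) ** 2) / (2 * delta)
        tol = 3.0 * np.sqrt(se_fd ** 2 + se_cov[:, g] ** 2)
        hits += int(np.sum(np.abs(fd - jac[:, g]) < tol))
        total += nb
    return hits / total


def bond_curvature_error(seed=0, k=500.0, r0=0.38):
    """Relative error of the harmonic stiffness recovered by Boltzmann
    inversion from samples of the closed-form bond-length density
    p(r) ~ r^2 exp(-k (r-r0)^2 / 2)."""
    from .distributions import BondedHistogram
    rng = np.random.default_rng(seed)
    sd = 1.0 / np.sqrt(k)
    r = rng.normal(r0, sd, 600_000)
    rmax = r0 + 5 * sd
    r = r[(r > 0) & (rng.random(r.size) < (r / rmax) ** 2)]
    edges = np.linspace(r0 - 4 * sd, r0 + 4 * sd, 61)
    dens, _ = np.histogram(r, bins=edges, density=True)
    hist = BondedHistogram("bond", "b", edges, dens, n_samples=r.size)
    pot = boltzmann_invert(hist)
    sel = np.abs(pot.r - r0) < 2.5 * sd
    k_fit = 2.0 * np.polyfit(pot.r[sel], pot.u[sel], 2)[0]
    return abs(k_fit - k) / k


def rmsf_two_bin_example():
    """Hand-checkable block-RMSF: g = (1, 2) against g_fin = (1, 1)
    gives sqrt(1/2); the reference window against itself gives 0."""
    edges = np.array([0.0, 0.1, 0.2])
    ref = RDF(("A", "A"), edges, np.array([1.0, 1.0]), 10, 1.0)
    blk = RDF(("A", "A"), edges, np.array([1.0, 2.0]), 10, 1.0)
    series = rdf_rmsf([blk, ref], ref)
    return {"two_bin": float(series.values[0]),
            "self": float(series.values[1])}


# ---------------------------------------------------------------------------
# bonded topology
# ---------------------------------------------------------------------------

def elastic_fixture_counts():
    """Elastic network and DNA-core restraints on deterministic line
    fixtures, against hand enumeration."""
    core = [CGBead(i, "POL", 0, 1, [x, 0, 0], "histone_core")
            for i, x in enumerate([0.0, 0.5, 1.2])]
    ref = np.array([[0.0, 0, 0], [0.5, 0, 0], [1.2, 0, 0]])
    line_bonds = build_elastic_network(core, ref, cutoff=0.7)

    d_beads = [CGBead(i, "D", 0, 1, [0.5 * i, 1.0, 0], "dna")
               for i in range(10)]
    core10 = [CGBead(100 + i, "POL", 0, 1, [0.5 * i, 0, 0],
                     "histone_core") for i in range(10)]
    ref2 = np.zeros((200, 3))
    for b in d_beads + core10:
        ref2[b.index] = b.position
    restraints = build_dna_core_restraints(d_beads, core10, ref2)
    reduced = build_dna_core_restraints(d_beads, core10, ref2,
                                        end_exempt=4)
    e_ref = sum(0.5 * bd.k * (np.linalg.norm(ref2[bd.j] - ref2[bd.i])
                              - bd.r0) ** 2 for bd in restraints)
    return {"line_bond_count": len(line_bonds),
            "line_bond_r0": line_bonds[0].r0,
            "restraint_count": len(restraints),
            "reduced_restraint_count": len(reduced),
            "energy_at_reference": float(e_ref)}


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------

def mixed_term_system():
    """Small system exercising every interaction class."""
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


def force_gradient_errors(seed=17, n_configs=100, h=1e-6):
    """Worst relative deviation between analytic forces and central
    finite differences, per interaction class, over random
    configurations."""
    top, terms = mixed_term_system()
    rng = np.random.default_rng(seed)
    classes = ["bond", "angle", "coulomb", "short_range",
               "excluded_volume"]
    worst = {c: 0.0 for c in classes}
    for _ in range(n_configs):
        pos = top.positions + rng.normal(0, 0.03, top.positions.shape)
        i = int(rng.integers(0, top.n_beads))
        a = int(rng.integers(0, 3))
        for cls in classes:
            f = forces(top, terms, positions=pos, classes=[cls])
            pp = pos.copy()
            pp[i, a] += h
            pm = pos.copy()
            pm[i, a] -= h
            num = -(total_energy(top, terms, positions=pp,
                                 classes=[cls])["total"]
                    - total_energy(top, terms, positions=pm,
                                   classes=[cls])["total"]) / (2 * h)
            denom = max(abs(num), abs(f[i, a]), 1e-4)
            worst[cls] = max(worst[cls], abs(num - f[i, a]) / denom)
    return worst


def madelung_check():
    """Ewald energy of the 8-ion rock-salt cell against the literature
    Madelung constant, plus splitting-parameter invariance."""
    d = 0.3
    pos, q = [], []
    for i in range(2):
        for j in range(2):
            for k in range(2):
                pos.append([i * d, j * d, k * d])
                q.append((-1.0) ** (i + j + k))
    pos, q = np.array(pos), np.array(q)
    box = np.array([2 * d] * 3)
    e = ewald_energy(pos, q, box, epsilon_r=1.0, accuracy=1e-8)
    e2 = ewald_energy(pos, q, box, epsilon_r=1.0, accuracy=1e-8,
                      alpha=9.0 / (2 * d))
    lb = bjerrum_length(310.0, 1.0)
    e_ref = 8 * (-MADELUNG_NACL * lb / d) / 2
    return {"relative_error": abs(e - e_ref) / abs(e_ref),
            "alpha_invariance": abs(e - e2) / abs(e)}


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def harmonic_variance_mc(seed=5, k=100.0):
    """MC positional variance of a tethered bead over kT/k (target 1)."""
    top = CGTopology(beads=[CGBead(0, "A", 0, 1.0, [5.0] * 3, "ion")],
                     box=np.array([10.0] * 3))
    model = CompiledModel.compile(top, InteractionSet(),
                                  tethers={0: (k, [5.0] * 3)})
    cfg = SamplerConfig(mode="MC", n_steps=1_000_000, sample_every=25,
                        mc_max_disp=0.25, seed=seed)
    res = run_mc(model, top.positions, cfg)
    var = res.frames[:, 0, :].var(axis=0).mean()
    return float(var * k)


def mc_ld_rdf_deviation(seed=11):
    """Max |g_MC - g_LD| for a small LJ fluid at matched sampling."""
    rng = np.random.default_rng(seed)
    n, box = 50, 2.5
    pos = rng.uniform(0, box, (n, 3))
    beads = [CGBead(i, "A", 0, 40.0, pos[i], "ion") for i in range(n)]
    top = CGTopology(beads=beads, box=np.array([box] * 3))
    terms = InteractionSet(pair_tables={("A", "A"): lj_table(
        sigma=0.35, epsilon=0.7, r_min=0.2, r_cut=1.2)})
    model = CompiledModel.compile(top, terms)
    edges = np.arange(0.2, 1.2 + 1e-9, 0.05)
    eq = run_mc(model, pos, SamplerConfig(mode="MC", n_steps=50_000,
                                          sample_every=50_000,
                                          mc_max_disp=0.3, seed=seed))
    mc = run_mc(model, eq.final_positions,
                SamplerConfig(mode="MC", n_steps=1_600_000,
                              sample_every=800, mc_max_disp=0.35,
                              seed=seed + 1))
    g_mc = rdf_from_traj(model, mc.frames[200:], [("A", "A")],
                         edges)[0].g
    ld = run_ld(model, eq.final_positions,
                SamplerConfig(mode="LD", n_steps=1_000_000,
                              sample_every=250, timestep_fs=4,
                              friction=5.0, seed=seed + 2))
    g_ld = rdf_from_traj(model, ld.frames[800:], [("A", "A")],
                         edges)[0].g
    return float(np.max(np.abs(g_mc - g_ld)))


def double_well_occupancies(seed=21, barrier=14.0, hot=2400.0):
    """Occupancy of the outer well of a radial double-well bond, for a
    short unannealed run versus an annealed run started in the inner
    well."""
    r = np.linspace(0.2, 2.4, 441)
    w1, w2 = 0.6, 1.5
    mid, half = (w1 + w2) / 2, (w2 - w1) / 2
    u = barrier * (((r - mid) ** 2 - half ** 2) ** 2) / half ** 4
    tab = TabulatedPotential(r, u, kind="bond", name="dwell")
    beads = [CGBead(0, "G", 0, 1.0, [4.0] * 3, "ion"),
             CGBead(1, "A", 0, 30.0, [4.6, 4.0, 4.0], "ion")]
    top = CGTopology(beads=beads, bonds=[Bond(0, 1, "table", "dwell")],
                     box=np.array([8.0] * 3))
    terms = InteractionSet(bond_tables={"dwell": tab})
    model = CompiledModel.compile(top, terms, mobile=[1])
    cfg = SamplerConfig(mode="LD", n_steps=96_000, sample_every=60,
                        timestep_fs=10, friction=2.0, seed=seed)
    plain = run_ld(model, top.positions, cfg)
    d_plain = np.linalg.norm(plain.frames[:, 1] - plain.frames[:, 0],
                             axis=1)
    sched = AnnealingSchedule(310.0, hot, 3000, 10_000, 3000, 16_000,
                              cycles=3)
    ann = run_annealed(model, top.positions, sched, cfg)
    d_ann = np.linalg.norm(ann.production_frames[:, 1]
                           - ann.production_frames[:, 0], axis=1)
    return {"plain": float((d_plain > 1.05).mean()),
            "annealed": float((d_ann > 1.05).mean())}


# ---------------------------------------------------------------------------
# aggregation analysis
# ---------------------------------------------------------------------------

def valency_suite():
    """Hand-countable valency fixtures: a stacked pair (V = 1), a
    mutually contacting triplet (V = 2), and a dilute gas (V = 0)."""
    spec = MiniNCPSpec()
    f2, p2, _ = make_aggregate_configuration(2, "stack", 1.2, spec)
    v_pair = valency([f2], [p["contact"] for p in p2], cutoff=1.0).mean
    f3, p3, _ = make_aggregate_configuration(3, "stack", 1.0, spec)
    v_tri = valency([f3], [p["contact"] for p in p3], cutoff=2.6).mean
    fg, pg, boxg = make_aggregate_configuration(8, "gas", 0.0, spec,
                                                seed=6)
    v_gas = valency([fg], [p["contact"] for p in pg], cutoff=1.0,
                    box=boxg).mean
    return {"pair": float(v_pair), "triplet": float(v_tri),
            "gas": float(v_gas)}


def geometry_suite(seed=2):
    """RMSD rigid-motion invariance, Rg/Dmax closed forms, SDF
    body-frame covariance and stack/perpendicular distinguishability."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(30, 3))
    rot = Rotation.from_euler("zyx", [1.2, -0.4, 2.8]).as_matrix()
    rmsd_rigid = rmsd_to_reference(x @ rot.T + np.array([5.0, -3, 1]), x)

    rg_d, dmax_d = rg_dmax(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    ring = np.stack([2 * np.cos(theta), 2 * np.sin(theta),
                     np.zeros_like(theta)], axis=1)
    rg_r, dmax_r = rg_dmax(ring)

    spec = MiniNCPSpec()
    edges = [np.linspace(-6, 6, 13)] * 3
    f1, p1, _ = make_aggregate_configuration(2, "stack", 1.2, spec)
    g1 = sdf([f1], p1[0]["core"], p1[1]["dna"], edges,
             x_reference_indices=p1[0]["dna_ends"])
    rot2 = Rotation.from_euler("xyz", [0.9, 0.2, -1.4]).as_matrix()
    g1r = sdf([f1 @ rot2.T], p1[0]["core"], p1[1]["dna"], edges,
              x_reference_indices=p1[0]["dna_ends"])
    f2, p2, _ = make_aggregate_configuration(2, "perpendicular", 3.4,
                                             spec)
    g2 = sdf([f2], p2[0]["core"], p2[1]["dna"], edges,
             x_reference_indices=p2[0]["dna_ends"])
    return {
        "rmsd_rigid_motion": float(rmsd_rigid),
        "rg_dimer_err": abs(rg_d - 0.5),
        "dmax_dimer_err": abs(dmax_d - 1.0),
        "rg_ring_err": abs(rg_r - 2.0),
        "dmax_ring_err": abs(dmax_r - 4.0),
        "sdf_rotation_dev": float(np.max(np.abs(g1.density
                                                - g1r.density))),
        "sdf_stack_perp_overlap": float(np.minimum(g1.density,
                                                   g2.density).sum()),
    }


def dilute_closure(seed=5):
    """Effective-pair-potential closure on a dilute-limit target
    g = exp(-U*): recovery error of U* and the final resampled RDF
    deviation."""
    edges = np.arange(0.5, 2.5 + 1e-9, 0.1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    u_true = (1.2 * np.exp(-((centers - 0.7) / 0.25) ** 2)
              - 0.8 * np.exp(-((centers - 1.35) / 0.3) ** 2))
    u_true -= u_true[-1]
    target = RDF(("NCP", "NCP"), edges, np.exp(-u_true), 1, 0.02)
    pot, result = effective_pair_potential(
        target, density=0.02, n_particles=150, seed=seed,
        tolerance=0.04, n_steps=4_000_000, sample_every=1000)
    u_rec = pot.u - pot.u[-1]
    g_fin = result.rdfs[("NCP", "NCP")].g
    return {"pot": pot, "result": result,
            "max_u_err": float(np.max(np.abs(u_rec - u_true))),
            "max_g_dev": float(np.max(np.abs(g_fin - target.g)))}


def assembly_suite(tmpdir, mini=None):
    """Precedence default on a multi-source DNA-DNA pair and bundle
    round-trip energy fidelity."""
    from .assembly import (PotentialLibrary, PrecedenceRules, assemble,
                           export_bundle, import_bundle)
    from .fixtures import make_mini_ncp
    mini = mini or make_mini_ncp(MiniNCPSpec(seed=0))
    lib = PotentialLibrary()
    types = sorted(set(mini.topology.types))
    for i, a in enumerate(types):
        for b in types[i:]:
            lib.add((a, b), "DNA-Peptide",
                    lj_table(sigma=0.3, epsilon=0.4, r_min=0.2,
                             r_cut=1.2, name=f"{a}-{b}"))
    for src in ("DNA-Mg", "DNA-Co"):
        lib.add(("P", "P"), src, lj_table(sigma=0.32, epsilon=0.5,
                                          r_min=0.2, r_cut=1.2,
                                          name=src))
    bundle = assemble(lib, PrecedenceRules(), mini.topology,
                      coulomb=mini.terms.coulomb,
                      excluded_volume=mini.terms.excluded_volume,
                      bond_tables=mini.terms.bond_tables,
                      angle_tables=mini.terms.angle_tables)
    export_bundle(bundle, tmpdir)
    back = import_bundle(tmpdir)
    m1 = CompiledModel.compile(bundle.topology,
                               bundle.interaction_set())
    m2 = CompiledModel.compile(back.topology, back.interaction_set())
    rng = np.random.default_rng(1)
    worst = 0.0
    for _ in range(100):
        pos = (mini.reference_positions
               + rng.normal(0, 0.02, mini.reference_positions.shape))
        e1 = m1.energy(pos)
        e2 = m2.energy(pos)
        worst = max(worst, abs(e2 - e1) / max(abs(e1), 1e-12))
    return {"dna_dna_source": bundle.pair_sources[("P", "P")],
            "roundtrip_max_rel_err": worst}
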