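# Methods

This note documents the models, numerical choices and limitations of
`ncpcg`. Energies are in units of k_BT at the reference temperature
(310 K unless stated), lengths in nm, masses in amu, times in ps,
charges in e.

## Coarse-grained representation

Proteins are mapped one bead per residue at the mass-weighted centre
of the residue's atoms. The twenty amino acids collapse to five bead
types — polar (POL), nonpolar (NPL), positive (POS, +1e), negative
(NEG, −1e) and glycine (GLY, set apart for its size and backbone
freedom). The default assignment is POS = {Lys, Arg},
NEG = {Asp, Glu}, GLY = {Gly}, NPL = {Ala, Val, Leu, Ile, Pro, Phe,
Met, Trp, Cys}, POL = {Ser, Thr, Asn, Gln, Tyr, His}; histidine is
kept neutral because the charged types carry a full ±e and His is
predominantly uncharged at pH 7. The assignment, per-type charges and
excluded-volume σ values are all configurable (`BeadTypeTable`); the
shipped σ values are stand-ins chosen so the repulsive wall sits just
inside typical bonded bead spacings (~0.38 nm residue–residue) and
tests never depend on them.

DNA is mapped five beads per two base pairs: four phosphate P beads
(−1e each) at the phosphate-group centres of mass and one neutral D
bead at the centre of mass of everything else, giving −2e per
represented base pair. Odd base-pair counts use floor(N/2) units with
the final unpaired base pair merged into the last unit's D bead, which
preserves the charge bookkeeping. The internal DNA bonded template
(D–D backbone bonds, P–D bonds within a unit, D–D–D angles) is
configurable, since different parameterisations of the underlying DNA
model wire it differently. Ions (K⁺, Na⁺, Cl⁻, Mg(H₂O)₆²⁺ as +2,
CoHex³⁺ as +3) are single beads.

Peptide-chain angles are typed on the central residue — Angle_PRO,
Angle_GLY, Angle_Other — reflecting the distinct X-Pro-X and X-Gly-X
angle statistics of flexible peptides. No angle terms exist inside the
histone core: an angle is dropped exactly when all three of its beads
belong to the core group, since the core's geometry is maintained by
the elastic network instead.

## Composite potential

The total energy is U_bond + U_angle + U_elec + U_sr.

* Bonded and angle terms are tabulated with exact linear interpolation
  between nodes (forces therefore piecewise constant). Bond/angle
  tables extrapolate linearly at both ends; pair tables vanish beyond
  the last node and continue with the inner-wall slope below the first
  node, giving a defined repulsive wall in never-sampled bins.
* The histone-core elastic network connects every core bead pair
  strictly closer than 0.7 nm in the reference structure with a
  harmonic bond at the reference distance, uniform k_b = 5 kT/Å²
  (500 kT/nm²). "Strictly" means a pair exactly at the cutoff is
  excluded.
* DNA–core restraints bond each central D bead to its nearest core
  bead (ties broken to the lowest bead index) at the reference
  distance with the same k_b; the two D beads at each DNA end are
  exempt so the DNA termini can breathe. A reduced variant exempts
  four per end.
* Electrostatics is Coulomb's law with uniform ε = 78. During
  sampling the real-space shifted-cutoff form (default 2.5 nm) is
  used; an Ewald summation (real + reciprocal + self terms, optional
  uniform-background correction for net-charged systems, excluded-pair
  removal) provides quantitative periodic energies and is validated
  against the rock-salt Madelung constant. Mesh methods (PME/PPPM) are
  out of scope at this problem size; exported tables remain consumable
  by engines that provide them.
* Excluded volume is the Weeks–Chandler–Andersen split of the
  Lennard-Jones potential — the repulsive branch truncated at the
  minimum 2^(1/6)σ_ij and shifted so it is non-negative and vanishes
  beyond the truncation — with σ_ij = (σ_i+σ_j)/2 and ε = 1 kT. The
  LJ split is not unique; WCA was chosen because it makes the term
  purely repulsive and exactly zero at the truncation, both testable
  properties. Short-range interactions between two histone-core beads
  are always excluded volume only, even where a table exists for the
  type pair.
* 1–2 and 1–3 bonded neighbours are excluded from the electrostatic
  and short-range classes; 1–4 and beyond interact as ordinary
  nonbonded pairs. The exclusion list is derived from the full bond
  graph, elastic network and restraints included.

For sampling, the per-(type, group) composite nonbonded potential —
assigned table or excluded volume, plus shifted Coulomb — is
pre-summed onto one uniform grid (default spacing 0.002 nm) consumed
by numba kernels; kernel forces are the segment slopes of that grid,
exactly consistent with the interpolated energies. The grid
discretisation error is bounded by the grid spacing and checked
against the reference per-class evaluation in the tests.

## Sampling

Metropolis Monte Carlo uses single-bead cube displacement moves
(symmetric, hence detailed balance), bitwise reproducible per seed; it
is the backend of the inversion loop, where only configurational
averages matter. Langevin dynamics uses the BAOAB splitting with
friction default 1–5 ps⁻¹. The production protocol this mirrors
thermostats Hamiltonian dynamics with velocity rescaling; a Langevin
thermostat samples the same configurational ensemble with a simpler
correctness contract, which is why it is used here — the two backends
are cross-validated on RDFs of the same fluid. At zero friction BAOAB
reduces to velocity Verlet (energy-conservation tests); the staged
timestep ramp (1 → 2 → 5 fs) of production protocols is a
configuration preset, not hard-coded.

Simulated annealing follows a piecewise-linear temperature profile per
cycle — ramp up, hold hot, ramp down, production hold at base — with
only the base-temperature production windows marked for analysis. The
elevated temperature is system-specific and therefore a required
schedule parameter. Spans quoted in ns in production protocols are
scaled down (default ×0.01) for desk-scale runs; the double-well
benchmark uses a 14 kT barrier crossed only at the elevated
temperature.

All pair evaluations are exact O(N²) loops; at the bead counts this
package targets (≤ a few thousand) a cell list buys little and the
brute-force path doubles as its own reference.

## Inversion

Bonded starting potentials come from direct Boltzmann inversion,
U = −kT ln(p/J) with J = r² for bonds and sin θ for angles, minimum
shifted to zero, empty bins bridged by linear interpolation. Nonbonded
potentials start from zero (or from the PMF −kT ln g_ref where that is
a good guess, e.g. dilute systems).

Each iteration samples the current model, measures RDFs and the
per-bin pair-count observables S_α, and corrects:

* IBI: U′ = U + λ kT ln(g_sim/g_ref) on bins where both are positive
  (λ default 0.5); unsampled core bins are continued linearly inward
  with the (repulsive) slope of the first sampled nodes.
* IMC: solves β Cov(S_α, S_γ) ΔU_γ = ⟨S_α⟩ − S_α^ref with
  truncated-SVD regularisation (singular values below 10⁻³ of the
  largest discarded) and damping λ = 0.3. The sign convention makes an
  over-populated bin more repulsive; the Jacobian identity
  ∂⟨S_α⟩/∂U_γ = −β Cov(S_α,S_γ) is verified against finite
  differences in the tests. Cross-correlations between type pairs are
  carried in the full covariance matrix. Bins that collect no samples
  are flagged and frozen.

The schedule runs 10 IBI iterations, then IMC, capped at 50
iterations. Because "agreement within statistical error" is the
operative convergence notion, the loop stops when either the hard
tolerance (default max|g−g_ref| < 0.05) is met or every bin deviates
by less than 3× the block-averaged standard error of the simulated g;
without the latter rule the Newton updates chase sampling noise. A
divergence guard halts after three consecutive deviation increases
beyond the noise floor. Fixed terms (electrostatics, excluded volume)
are never touched by the loop.

## Assembly

Effective potentials are state-point dependent, so the same type pair
derived from different reference subsystems differs. `PotentialLibrary`
keys tables by (pair, source subsystem); `PrecedenceRules` picks the
source closest to the target system: DNA–DNA and DNA–amino-acid pairs
from the DNA–peptide subsystem, pairs involving a multivalent cation
from that cation's subsystem, monovalent-ion pairs from any source
(flagged equivalent). All rules are overridable per class and per
pair; the provenance of every choice lands in the bundle manifest.
Bundles export to a directory of table-dialect files plus topology and
a checksummed JSON manifest; re-import is verified to reproduce
energies to 10⁻⁹ relative on random configurations, and a lint step
refuses incomplete bundles.

## Analysis

* RMSD uses Kabsch superposition (via scipy's `align_vectors`),
  optionally mass-weighted and restricted to selections (DNA, core,
  combined).
* R_g is the mass-weighted root-mean-square distance from the centre
  of mass; D_max the maximum bead-centre pairwise distance, with no
  radius inflation — SAXS-derived D_max values include scattering
  contrast effects and are expected to differ, particularly because
  flexible tails sample space far from the particle. Wrapped molecules
  (any bond longer than half the box) are rejected rather than
  silently unwrapped.
* The core–core RDF is the standard pair correlation of histone-core
  centres of mass. The effective particle–particle pair potential
  treats each particle as one site and inverts that RDF with the same
  IBI/IMC machinery, starting from the PMF; in the dilute limit it
  must approach −kT ln g_ref, which is the closure test.
* Valency counts ordered particle pairs whose minimum inter-bead
  distance (histone tails excluded from the bead sets) is below a
  cutoff, averaged over frames and particles. The literature does not
  fix the cutoff; it is mandatory in the interface (1.0 nm in the
  fixtures here) and reported with every result.
* SDFs accumulate target positions in a particle's body frame:
  origin at the core centre of mass; z the eigenvector of the largest
  principal inertia eigenvalue (the cylinder axis of a disc), its sign
  fixed by the third mass moment along z — well defined for a
  wedge-shaped core, with an explicit override required for symmetric
  shapes; x the in-plane direction to a body-attached reference (the
  DNA-end midpoint for an NCP); y = z × x. Normalisation is either
  probability (voxels sum to 1) or relative-to-bulk. "Equilibrated
  parts" of trajectories default to the production windows of the
  annealing schedule.

## Synthetic fixtures

The generators produce every input the pipeline needs: toy fluids with
known tabulated potentials (N = 100, box 3 nm, LJ-like σ = 0.35 nm,
ε = 0.7 kT by default) whose MC-sampled RDFs are inversion targets;
harmonic dimers/chains for bonded inversion; a quarter-scale NCP-like
particle (wedge of two stacked discs of radii 1.6/1.1 nm, ~115 core
beads, four 5-residue charged tails, a 20-unit wrapped P/D chain,
neutralising ions — ~300 beads total) that satisfies every topology
invariant; and deterministic aggregate configurations (stack,
side-by-side, perpendicular, gas) realising the binding modes the
aggregation analyses distinguish. Fixtures are bitwise reproducible
from (spec, seed).

What the fixtures do **not** emulate: real force-field energetics,
sequence-dependent DNA behaviour (deliberately out of scope),
solvent-mediated effects beyond what pairwise effective potentials can
carry, or production-scale systems (tens of NCPs, microsecond
sampling). Passing tests therefore demonstrate the correctness of the
machinery — mapping, inversion, sampling, analysis — not the accuracy
of any particular published model. Problem sizes (10²–10³ beads,
10⁵–10⁶ MC moves per inversion iteration, 20-bin RDF grids for the
dilute closure) were chosen so each stage has clear statistical
resolution for its acceptance margin.

## Known limitations

* Pairwise additivity throughout; no multibody terms.
* Orthorhombic periodic boxes only (minimum image).
* Charge must be a function of (bead type, group) for the compiled
  sampler; per-bead exotic charges require extra types.
* Kinetic observables from Langevin dynamics carry the usual
  finite-timestep bias (configurational averages are the validated
  quantity).
* The IMC covariance estimate needs decorrelated frames; the loop
  does not yet estimate integrated autocorrelation times itself —
  sampling strides are the user's responsibility (defaults are chosen
  generously for the shipped fixtures).
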