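"""Structural and aggregation observables for NCP-like particles.

Single-particle geometry: optimal-superposition RMSD against a reference
structure, radius of gyration and maximal dimension (the SAXS-comparable
size observables).  Aggregation structure: the radial distribution
function between histone-core centres of mass, the effective
particle-particle pair potential obtained by inverting that RDF, the
valency (mean number of particle-particle contacts per particle and
frame, from a minimum-distance criterion that excludes the flexible
tails), and spatial distribution functions (SDFs) of a selection in a
particle's body-fixed frame.

The body frame is built from the histone core's principal inertia axes:
z is the eigenvector of the largest inertia eigenvalue (the cylinder
axis of a disc-shaped core), its sign fixed by the third mass moment
along z (well-defined for a wedge-shaped core; an explicit reference
must be supplied for symmetric shapes), x is the in-plane projection of
a body-attached reference vector (for an NCP, core COM to the midpoint
of the DNA ends), and y = z cross x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .distributions import RDF, compute_rdf, minimum_image
from .tables import TabulatedPotential

__all__ = [
    "ContactRecord", "ValencyResult", "BodyFrame", "SDFGrid",
    "rmsd_to_reference", "rg_dmax", "core_com_rdf",
    "effective_pair_potential", "valency", "sdf", "write_sdf_dx",
]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def rmsd_to_reference(frame, reference, selection=None, weights=None,
                      superpose=True):
    """Root-mean-square deviation (nm) after optimal rigid superposition
    (rotation + translation, Kabsch).  ``selection`` restricts both
    structures to the given bead indices."""
    a = np.asarray(frame, dtype=float)
    b = np.asarray(reference, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        if sel.size == 0:
            raise ValueError("empty selection")
        a, b = a[sel], b[sel]
    if a.shape != b.shape:
        raise ValueError(f"bead count mismatch: {a.shape} vs {b.shape}")
    w = np.ones(len(a)) if weights is None else np.asarray(weights,
                                                           dtype=float)
    ac = a - np.average(a, axis=0, weights=w)
    bc = b - np.average(b, axis=0, weights=w)
    if superpose:
        rot, _ = Rotation.align_vectors(bc, ac, weights=w)
        ac = rot.apply(ac)
    return float(np.sqrt(np.average(np.sum((ac - bc) ** 2, axis=1),
                                    weights=w)))


def rg_dmax(positions, masses=None, box=None, bonds=None,
            allow_single=False):
    """Radius of gyration and maximal dimension (nm) of an unwrapped
    molecule.  If box and bonds are given, a bond longer than half the
    box flags a periodically wrapped molecule and raises."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2:
        raise ValueError("positions must be (N, 3)")
    if len(pos) < 2:
        if allow_single:
            return 0.0, 0.0
        raise ValueError("need at least 2 beads (or allow_single=True)")
    if box is not None and bonds is not None:
        half = np.asarray(box, dtype=float).min() / 2.0
        for bd in bonds:
            i, j = (bd.i, bd.j) if hasattr(bd, "i") else bd
            if np.linalg.norm(pos[j] - pos[i]) > half:
                raise ValueError(
                    f"bond {i}-{j} longer than half the box: the molecule "
                    "appears wrapped; unwrap before measuring Rg/Dmax")
    m = np.ones(len(pos)) if masses is None else np.asarray(masses,
                                                            dtype=float)
    com = np.average(pos, axis=0, weights=m)
    rg = float(np.sqrt(np.average(np.sum((pos - com) ** 2, axis=1),
                                  weights=m)))
    dmax = float(pdist(pos).max())
    return rg, dmax


# ---------------------------------------------------------------------------
# core-core RDF and effective pair potential
# ---------------------------------------------------------------------------

def particle_coms(frames, particle_indices, masses=None):
    """Centre of mass of each particle's bead set per frame ->
    (F, n_particles, 3)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    out = np.empty((frames.shape[0], len(particle_indices), 3))
    for p, idx in enumerate(particle_indices):
        idx = np.asarray(idx, dtype=int)
        w = None if masses is None else np.asarray(masses, dtype=float)[idx]
        if w is None:
            out[:, p] = frames[:, idx].mean(axis=1)
        else:
            out[:, p] = np.einsum("fia,i->fa", frames[:, idx],
                                  w / w.sum())
    return out


def core_com_rdf(frames, particle_indices, box, edges, masses=None) -> RDF:
    """RDF between histone-core centres of mass of the particles."""
    if len(particle_indices) < 2:
        raise ValueError("need at least two particles")
    coms = particle_coms(frames, particle_indices, masses)
    sel = np.arange(coms.shape[1])
    return compute_rdf(coms, box, sel, sel, edges,
                       pair_label=("core_COM", "core_COM"))


def effective_pair_potential(g_ref: RDF, density, n_particles=64,
                             seed=0, tolerance=0.05, n_ibi=10,
                             max_iterations=40, n_steps=250_000,
                             sample_every=250) -> tuple:
    """Effective single-site pair potential whose fluid reproduces a
    target centre-of-mass RDF.

    Each particle is reduced to one interaction site at density
    ``density`` (nm^-3); the iterative inversion (IBI then IMC) is run
    against ``g_ref``, starting from the potential of mean force
    -kT ln g_ref (exact in the dilute limit).  Returns
    ``(TabulatedPotential, InversionResult)`` with the shift-to-zero
    convention applied.
    """
    from .engine import CompiledModel
    from .inversion import InversionProblem, run_inversion
    from .potentials import InteractionSet
    from .sampler import SamplerConfig
    from .topology import CGBead, CGTopology

    length = (n_particles / density) ** (1.0 / 3.0)
    if g_ref.edges[-1] > length / 2:
        raise ValueError(
            f"target RDF range {g_ref.edges[-1]:.2f} nm exceeds half the "
            f"box ({length / 2:.2f} nm) at this density; reduce the range "
            "or raise n_particles")
    box = np.array([length] * 3)
    rng = np.random.default_rng(seed)
    pos0 = rng.uniform(0, length, (n_particles, 3))
    beads = [CGBead(i, "NCP", 0.0, 1.0, pos0[i], "ion")
             for i in range(n_particles)]
    top = CGTopology(beads=beads, box=box)

    def build(pots):
        terms = InteractionSet(pair_tables={("NCP", "NCP"):
                                            pots[("NCP", "NCP")]})
        model = CompiledModel.compile(top, terms, grid_dr=0.005)
        return model, pos0

    centers = g_ref.centers
    pmf = -np.log(np.clip(g_ref.g, np.exp(-8.0), None))
    initial = {("NCP", "NCP"): TabulatedPotential(
        centers, pmf - pmf[-1], kind="pair", name="NCP-NCP")}
    cfg = SamplerConfig(mode="MC", n_steps=n_steps,
                        sample_every=sample_every, mc_max_disp=0.6,
                        seed=seed)
    problem = InversionProblem(
        build=build, target_rdfs={("NCP", "NCP"): g_ref},
        sampler_config=cfg, n_ibi=n_ibi, max_iterations=max_iterations,
        tolerance=tolerance, initial_potentials=initial)
    result = run_inversion(problem)
    pot = result.potentials[("NCP", "NCP")].shifted_to_zero()
    return pot, result


# ---------------------------------------------------------------------------
# valency
# ---------------------------------------------------------------------------

@dataclass
class ContactRecord:
    frame: int
    pair: tuple
    min_distance: float     # nm, minimum inter-bead distance (tails excl.)
    cutoff: float
    in_contact: bool


@dataclass
class ValencyResult:
    mean: float
    per_frame: np.ndarray
    n_frames: int
    n_particles: int
    std: float
    cutoff: float
    contacts: list = field(default_factory=list)

    def __post_init__(self):
        if not (-1e-12 <= self.mean <= self.n_particles - 1 + 1e-12):
            raise ValueError("valency out of [0, N-1]")


def valency(frames, particle_indices, cutoff, box=None,
            keep_contacts=False) -> ValencyResult:
    """Mean number of particle-particle contacts per particle per frame:

        V = 1/(N_t N_n) * sum_t sum_{i != j} C_ij(t),

    where C_ij(t) = 1 iff the minimum distance between the bead sets of
    particles i and j (the caller passes tail-free selections) is below
    ``cutoff``.  Ordered pairs are counted, so one contact contributes to
    both partners."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("zero frames")
    n_n = len(particle_indices)
    per_frame = np.zeros(frames.shape[0])
    contacts = []
    for t, frame in enumerate(frames):
        n_contacts = 0
        for i in range(n_n):
            for j in range(i + 1, n_n):
                a = frame[np.asarray(particle_indices[i], dtype=int)]
                b = frame[np.asarray(particle_indices[j], dtype=int)]
                if box is not None:
                    d = a[:, None, :] - b[None, :, :]
                    d = minimum_image(d, np.asarray(box, dtype=float))
                    dmin = float(np.linalg.norm(d, axis=-1).min())
                else:
                    dmin = float(cdist(a, b).min())
                hit = dmin < cutoff
                n_contacts += 2 * hit        # ordered pairs
                if keep_contacts:
                    contacts.append(ContactRecord(t, (i, j), dmin, cutoff,
                                                  bool(hit)))
        per_frame[t] = n_contacts / n_n
    return ValencyResult(mean=float(per_frame.mean()), per_frame=per_frame,
                         n_frames=frames.shape[0], n_particles=n_n,
                         std=float(per_frame.std()), cutoff=cutoff,
                         contacts=contacts)


# ---------------------------------------------------------------------------
# body frame and SDF
# ---------------------------------------------------------------------------

@dataclass
class BodyFrame:
    origin: np.ndarray
    axes: np.ndarray          # rows x, y, z; orthonormal, right-handed

    def __post_init__(self):
        gram = self.axes @ self.axes.T
        if np.max(np.abs(gram - np.eye(3))) > 1e-10:
            raise ValueError("body-frame axes are not orthonormal")

    def to_body(self, points):
        return (np.asarray(points, dtype=float) - self.origin) @ self.axes.T

    @classmethod
    def from_positions(cls, core_positions, masses=None, x_reference=None,
                       z_reference=None, degeneracy_tol=1e-6):
        """Principal-axes frame of a bead cloud (see module docstring for
        the sign conventions).  ``x_reference`` is a body-attached point
        (lab coordinates) whose in-plane direction defines +x; it is
        required.  ``z_reference`` overrides the third-moment z-sign rule
        for shapes symmetric along the cylinder axis."""
        pos = np.asarray(core_positions, dtype=float)
        m = np.ones(len(pos)) if masses is None else np.asarray(masses,
                                                                dtype=float)
        com = np.average(pos, axis=0, weights=m)
        d = pos - com
        inertia = np.einsum("i,ij,ik->jk", m, d, d)
        inertia = np.trace(inertia) * np.eye(3) - inertia
        evals, evecs = np.linalg.eigh(inertia)
        if (evals[2] - evals[1]) / max(evals[2], 1e-300) < degeneracy_tol:
            raise ValueError(
                "degenerate inertia tensor (near-spherical shape); supply "
                "an explicit frame override")
        z = evecs[:, 2]
        if z_reference is not None:
            if np.dot(z, np.asarray(z_reference, dtype=float) - com) < 0:
                z = -z
        else:
            third = float(np.sum(m * (d @ z) ** 3))
            if abs(third) < 1e-9 * float(np.sum(m * (d @ z) ** 2)) ** 1.5:
                raise ValueError(
                    "mass distribution symmetric along the principal axis; "
                    "supply z_reference to fix the z sign")
            if third < 0:
                z = -z
        if x_reference is None:
            raise ValueError("x_reference point is required")
        v = np.asarray(x_reference, dtype=float) - com
        v = v - np.dot(v, z) * z
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ValueError("x_reference lies on the z axis")
        x = v / norm
        y = np.cross(z, x)
        return cls(origin=com, axes=np.stack([x, y, z]))


@dataclass
class SDFGrid:
    edges: tuple              # (ex, ey, ez) bin edges in body coordinates
    density: np.ndarray
    mode: str = "probability"
    n_frames: int = 0

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("negative SDF density")
        if self.mode == "probability" and self.n_frames > 0:
            total = float(self.density.sum())
            if abs(total - 1.0) > 1e-9 and total > 0:
                raise ValueError(f"probability SDF sums to {total}")

    @property
    def centers(self):
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)


def sdf(frames, center_indices, target_indices, edges,
        x_reference_indices, masses=None, z_reference_indices=None,
        box=None, mode="probability") -> SDFGrid:
    """Spatial distribution function of target beads in the body frame of
    a center particle.

    ``center_indices`` select the beads defining the frame (the histone
    core); ``x_reference_indices`` a bead set whose midpoint fixes +x
    (for an NCP, the DNA-end beads).  ``mode``: "probability" (voxels sum
    to 1) or "bulk" (density relative to the mean target density in the
    grid volume)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    edges = tuple(np.asarray(e, dtype=float) for e in edges)
    center_indices = np.asarray(center_indices, dtype=int)
    target_indices = np.asarray(target_indices, dtype=int)
    hist = np.zeros([e.size - 1 for e in edges])
    m = None if masses is None else np.asarray(masses,
                                               dtype=float)[center_indices]
    for frame in frames:
        xref = frame[np.asarray(x_reference_indices, dtype=int)].mean(axis=0)
        zref = None
        if z_reference_indices is not None:
            zref = frame[np.asarray(z_reference_indices,
                                    dtype=int)].mean(axis=0)
        bf = BodyFrame.from_positions(frame[center_indices], masses=m,
                                      x_reference=xref, z_reference=zref)
        targets = frame[target_indices]
        if box is not None:
            targets = bf.origin + minimum_image(
                targets - bf.origin, np.asarray(box, dtype=float))
        body = bf.to_body(targets)
        hist += np.histogramdd(body, bins=edges)[0]
    if mode == "probability":
        total = hist.sum()
        density = hist / total if total > 0 else hist
    elif mode == "bulk":
        voxel = np.prod([np.diff(e)[0] for e in edges])
        volume = np.prod([e[-1] - e[0] for e in edges])
        bulk = frames.shape[0] * target_indices.size * voxel / volume
        density = hist / max(bulk, 1e-300)
    else:
        raise ValueError(f"unknown SDF mode {mode!r}")
    return SDFGrid(edges=edges, density=density, mode=mode,
                   n_frames=frames.shape[0])


def write_sdf_dx(grid: SDFGrid, path):
    """Write an SDF as OpenDX-style volumetric text."""
    nx, ny, nz = grid.density.shape
    ox = [float(e[0] + (e[1] - e[0]) / 2) for e in grid.edges]
    dx = [float(e[1] - e[0]) for e in grid.edges]
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox[0]:g} {ox[1]:g} {ox[2]:g}",
        f"delta {dx[0]:g} 0 0",
        f"delta 0 {dx[1]:g} 0",
        f"delta 0 0 {dx[2]:g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} "
        "data follows",
    ]
    flat = grid.density.ravel()
    for start in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.8g}" for v in flat[start:start + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "sdf" class field')
    from pathlib import Path as _P
    _P(path).write_text("\n".join(lines) + "\n")
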