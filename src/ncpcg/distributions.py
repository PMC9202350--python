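"""Reference structural distributions from CG trajectories.

Bottom-up coarse-graining targets the pair structure of a finer-grained
reference simulation: radial distribution functions (RDFs) between
nonbonded CG sites and probability densities of bond lengths and angles.
This module computes those targets from mapped trajectories, with the
block-RMSF convergence diagnostic used to decide which part of a
trajectory is equilibrated: for a block RDF g and the final-window RDF
g_fin on the same N-bin grid,

    RMSF = sqrt( sum_bins (g - g_fin)^2 / N ).

Conventions: orthorhombic periodic boxes with the minimum-image
convention; 1-2 and 1-3 bonded pairs are omitted from RDFs; RDFs from
multiple trajectories are averaged with equal weights per trajectory
(pooled-count averaging is available but not the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RDF", "RMSFSeries", "BondedHistogram",
    "compute_rdf", "average_rdfs", "rdf_rmsf", "compute_bonded_histograms",
    "write_distribution", "read_distribution",
]


@dataclass
class RDF:
    pair: tuple              # (label_a, label_b)
    edges: np.ndarray        # bin edges, nm
    g: np.ndarray            # dimensionless
    n_frames: int
    density: float           # number density of the partner selection, nm^-3
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.g.size != self.edges.size - 1:
            raise ValueError("g must have one value per bin")
        if np.any(self.g < -1e-12):
            raise ValueError("negative g(r)")
        widths = np.diff(self.edges)
        if not np.allclose(widths, widths[0], rtol=1e-8):
            raise ValueError("bin widths must be uniform")

    @property
    def centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def same_grid(self, other: "RDF") -> bool:
        return (self.edges.size == other.edges.size
                and np.allclose(self.edges, other.edges))


@dataclass
class RMSFSeries:
    block_length: int             # frames per block
    values: np.ndarray            # RMSF per block
    n_entries: int                # N of the RDF grid
    reference_window: str = "final"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSF must be non-negative")


@dataclass
class BondedHistogram:
    kind: str                 # "bond" | "angle"
    potential: str            # potential id
    edges: np.ndarray         # nm for bonds, degrees for angles
    density: np.ndarray       # normalized probability density
    n_samples: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.kind not in ("bond", "angle"):
            raise ValueError(f"unknown histogram kind {self.kind!r}")
        if self.n_samples > 0:
            integral = float(np.sum(self.density * np.diff(self.edges)))
            if abs(integral - 1.0) > 1e-6:
                raise ValueError(f"density integrates to {integral}, not 1")

    @property
    def centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])


# ---------------------------------------------------------------------------

def minimum_image(vectors, box):
    """Apply the orthorhombic minimum-image convention."""
    return vectors - box * np.round(vectors / box)


def _pair_distances(frame, box, sel_a, sel_b, same, exclusion_mask=None):
    ra, rb = frame[sel_a], frame[sel_b]
    d = ra[:, None, :] - rb[None, :, :]
    d = minimum_image(d, box)
    dist = np.linalg.norm(d, axis=-1)
    if same:
        iu = np.triu_indices(len(sel_a), k=1)
        dist = dist[iu]
        if exclusion_mask is not None:
            dist = dist[~exclusion_mask[iu]]
    else:
        if exclusion_mask is not None:
            dist = dist[~exclusion_mask]
        else:
            dist = dist.ravel()
    return dist


def compute_rdf(frames, box, sel_a, sel_b, edges, exclusions=(),
                pair_label=("A", "B")) -> RDF:
    """Radial distribution function between two index selections.

    Parameters
    ----------
    frames : (F, N, 3) array of wrapped or unwrapped coordinates (nm)
    box : (3,) orthorhombic box lengths (nm)
    sel_a, sel_b : integer index arrays (may be identical)
    edges : uniform bin edges; the last edge must not exceed half the
        shortest box edge
    exclusions : iterable of (i, j) bead-index pairs to omit (1-2/1-3)
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    box = np.asarray(box, dtype=float)
    edges = np.asarray(edges, dtype=float)
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("empty selection")
    if edges[-1] > box.min() / 2 + 1e-9:
        raise ValueError(
            f"bin range {edges[-1]} exceeds half the shortest box edge "
            f"{box.min() / 2}")
    same = sel_a.size == sel_b.size and np.array_equal(sel_a, sel_b)

    excl_mask = None
    excl = {tuple(sorted(p)) for p in exclusions}
    if excl:
        excl_mask = np.zeros((sel_a.size, sel_b.size), dtype=bool)
        pos_a = {int(v): n for n, v in enumerate(sel_a)}
        pos_b = {int(v): n for n, v in enumerate(sel_b)}
        for i, j in excl:
            if i in pos_a and j in pos_b:
                excl_mask[pos_a[i], pos_b[j]] = True
            if j in pos_a and i in pos_b:
                excl_mask[pos_a[j], pos_b[i]] = True

    counts = np.zeros(edges.size - 1)
    n_pairs = 0
    for f, frame in enumerate(frames):
        dist = _pair_distances(frame, box, sel_a, sel_b, same, excl_mask)
        if f == 0:
            n_pairs = dist.size + (0 if excl_mask is None else 0)
            # number of distinct pairs counted per frame (after exclusions)
            n_pairs = dist.size
        counts += np.histogram(dist, bins=edges)[0]

    volume = float(np.prod(box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * shell / volume        # expected counts per frame
    g = counts / (len(frames) * ideal)
    density = sel_b.size / volume
    return RDF(pair=tuple(pair_label), edges=edges, g=g,
               n_frames=len(frames), density=density,
               meta={"n_pairs": int(n_pairs), "counts": counts})


def average_rdfs(rdfs, mode="equal") -> RDF:
    """Combine RDFs from several trajectories.

    ``mode="equal"`` (default): average the g values with equal weight per
    trajectory.  ``mode="pooled"``: pool the raw pair counts, weighting
    trajectories by their frame counts.
    """
    first = rdfs[0]
    for r in rdfs[1:]:
        if not first.same_grid(r):
            raise ValueError("RDF grids differ; cannot average")
    if mode == "equal":
        g = np.mean([r.g for r in rdfs], axis=0)
    elif mode == "pooled":
        weights = np.array([r.n_frames for r in rdfs], dtype=float)
        g = np.average([r.g for r in rdfs], axis=0, weights=weights)
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    return replace(first, g=g, n_frames=sum(r.n_frames for r in rdfs),
                   meta={"averaged": len(rdfs), "mode": mode})


def rdf_rmsf(blocks, reference: RDF) -> RMSFSeries:
    """Root-mean-square fluctuation of block RDFs against a reference
    window: sqrt(sum_bins (g - g_fin)^2 / N) per block."""
    values = []
    n = reference.g.size
    for blk in blocks:
        if not blk.same_grid(reference):
            raise ValueError("block RDF binning differs from reference")
        values.append(float(np.sqrt(np.sum((blk.g - reference.g) ** 2) / n)))
    block_len = blocks[0].n_frames if blocks else 0
    return RMSFSeries(block_length=block_len, values=np.array(values),
                      n_entries=n)


def compute_bonded_histograms(frames, topology, bond_edges=None,
                              angle_edges=None):
    """Normalized bond-length and angle densities, one histogram per
    potential id defined in the topology.  Angles are in degrees on
    [0, 180].  Terms that collect no samples are returned with a
    ``zero_samples`` flag rather than dropped."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    out = []

    by_pot = {}
    for bd in topology.bonds:
        by_pot.setdefault(("bond", bd.potential), []).append((bd.i, bd.j))
    for an in topology.angles:
        by_pot.setdefault(("angle", an.potential), []).append(
            (an.i, an.j, an.k))

    for (kind, pot), terms in sorted(by_pot.items()):
        samples = []
        for frame in frames:
            if kind == "bond":
                for i, j in terms:
                    samples.append(np.linalg.norm(frame[j] - frame[i]))
            else:
                for i, j, k in terms:
                    v1 = frame[i] - frame[j]
                    v2 = frame[k] - frame[j]
                    c = np.dot(v1, v2) / (np.linalg.norm(v1)
                                          * np.linalg.norm(v2))
                    samples.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
        samples = np.asarray(samples)
        if kind == "bond":
            edges = (bond_edges if bond_edges is not None else
                     np.linspace(0.0, max(samples.max() * 1.2, 1e-6), 101))
        else:
            edges = (angle_edges if angle_edges is not None
                     else np.linspace(0.0, 180.0, 91))
        if samples.size == 0:
            out.append(BondedHistogram(kind, pot, edges,
                                       np.zeros(edges.size - 1), 0,
                                       meta={"zero_samples": True}))
            continue
        density, _ = np.histogram(samples, bins=edges, density=True)
        out.append(BondedHistogram(kind, pot, edges, density,
                                   n_samples=samples.size))
    return out


# ---------------------------------------------------------------------------
# two-column text files (same files the inversion module reads)
# ---------------------------------------------------------------------------

def write_distribution(path, x, y, meta=None):
    lines = []
    for key, val in (meta or {}).items():
        lines.append(f"# {key}: {val}")
    for xi, yi in zip(np.asarray(x), np.asarray(y)):
        lines.append(f"{xi:.10g} {yi:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_distribution(path):
    meta = {}
    xs, ys = [], []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if ":" in s:
                key, _, val = s[1:].partition(":")
                meta[key.strip()] = val.strip()
            continue
        a, b = s.split()[:2]
        xs.append(float(a))
        ys.append(float(b))
    return np.array(xs), np.array(ys), meta
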