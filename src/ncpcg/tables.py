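"""Tabulated interaction potentials on uniform grids.

All short-range nonbonded, bond and angle potentials of the CG model are
carried as tables (energy values on a uniform abscissa grid) rather than as
closed-form expressions; energies between nodes are obtained by exact linear
interpolation, so the force is piecewise constant.  Pair potentials vanish
identically beyond the last grid node (the cutoff); inside the first node
the potential continues linearly with the inner-wall slope, which gives a
well-defined repulsive wall for bins the reference sampling never visited.
Bond and angle tables are instead extrapolated linearly at both ends.

The on-disk dialect is the widely used molecular-dynamics "pair table"
format (keyword header, ``N <n>`` line, rows of ``index r energy force``),
so exported tables can be consumed directly by engines that read it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["TabulatedPotential", "read_table", "write_table"]


@dataclass
class TabulatedPotential:
    """A potential sampled on a strictly increasing uniform grid.

    Parameters
    ----------
    r : array
        Grid abscissa: distance in nm for ``kind`` "pair"/"bond", angle in
        degrees on [0, 180] for ``kind`` "angle".
    u : array
        Energy at the nodes, in k_B*T.
    kind : {"pair", "bond", "angle"}
        Controls out-of-range behaviour (see module docstring).
    name : str
        Identifier used in files and manifests.
    """

    r: np.ndarray
    u: np.ndarray
    kind: str = "pair"
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.r.ndim != 1 or self.r.size < 2:
            raise ValueError("grid must be 1-D with at least two nodes")
        if self.r.shape != self.u.shape:
            raise ValueError("grid and energy arrays differ in length")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("non-finite grid values")
        if not np.all(np.isfinite(self.u)):
            raise ValueError(f"non-finite energy in table {self.name!r}")
        dr = np.diff(self.r)
        if np.any(dr <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(dr, dr[0], rtol=1e-8, atol=1e-12):
            raise ValueError("grid must be uniform")
        if self.kind not in ("pair", "bond", "angle"):
            raise ValueError(f"unknown table kind {self.kind!r}")

    # -- basic grid properties -------------------------------------------
    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def cutoff(self) -> float:
        return float(self.r[-1])

    @property
    def inner_slope(self) -> float:
        """Slope of the first grid segment; used to continue the repulsive
        wall below the first node."""
        return float((self.u[1] - self.u[0]) / self.dr)

    @property
    def outer_slope(self) -> float:
        return float((self.u[-1] - self.u[-2]) / self.dr)

    def same_grid(self, other: "TabulatedPotential") -> bool:
        return self.r.shape == other.r.shape and np.allclose(self.r, other.r)

    # -- evaluation ------------------------------------------------------
    def evaluate(self, x):
        """Energy and force (= -dU/dx) at ``x``; both arrays match the
        shape of ``x``."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        u = np.empty_like(x)
        f = np.empty_like(x)

        lo, hi = self.r[0], self.r[-1]
        below = x < lo
        above = x > hi
        inside = ~(below | above)

        # interior: exact linear interpolation, piecewise-constant force
        seg = np.clip(((x[inside] - lo) / self.dr).astype(int),
                      0, self.r.size - 2)
        slope = (self.u[seg + 1] - self.u[seg]) / self.dr
        u[inside] = self.u[seg] + slope * (x[inside] - self.r[seg])
        f[inside] = -slope

        u[below] = self.u[0] + self.inner_slope * (x[below] - lo)
        f[below] = -self.inner_slope

        if self.kind == "pair":
            u[above] = 0.0
            f[above] = 0.0
        else:
            u[above] = self.u[-1] + self.outer_slope * (x[above] - hi)
            f[above] = -self.outer_slope

        if scalar:
            return float(u[0]), float(f[0])
        return u, f

    def __call__(self, x):
        return self.evaluate(x)

    def energy(self, x):
        return self.evaluate(x)[0]

    # -- transformations -------------------------------------------------
    def shifted_to_zero(self) -> "TabulatedPotential":
        """Return a copy with the cutoff value subtracted, so U(cutoff)=0."""
        return replace(self, u=self.u - self.u[-1],
                       meta={**self.meta, "shifted": True})

    def resampled(self, r_new: np.ndarray) -> "TabulatedPotential":
        u_new, _ = self.evaluate(np.asarray(r_new, dtype=float))
        return replace(self, r=np.asarray(r_new, dtype=float), u=u_new)

    @classmethod
    def from_function(cls, fn, r_min, r_max, n, kind="pair", name="",
                      shift_to_zero=False):
        r = np.linspace(r_min, r_max, n)
        u = np.asarray([fn(x) for x in r], dtype=float)
        pot = cls(r, u, kind=kind, name=name)
        return pot.shifted_to_zero() if shift_to_zero else pot

    @classmethod
    def zeros_like(cls, other: "TabulatedPotential", name=""):
        return cls(other.r.copy(), np.zeros_like(other.u),
                   kind=other.kind, name=name or other.name)


# ---------------------------------------------------------------------------
# table file dialect
# ---------------------------------------------------------------------------

def write_table(pot: TabulatedPotential, path, keyword: str | None = None,
                comment: str = "") -> None:
    """Write a potential in the engine table dialect.

    Format: optional ``#`` comments, a keyword line, ``N <n>`` line, a blank
    line, then ``index r energy force`` rows.  Forces are recomputed from
    the energies (midpoint of the adjacent segment slopes at interior
    nodes) so the file is always internally consistent.
    """
    keyword = keyword or (pot.name or "POTENTIAL")
    r, u = pot.r, pot.u
    # node force: average of adjacent segment slopes (one-sided at the ends)
    slopes = np.diff(u) / pot.dr
    f = np.empty_like(u)
    f[0] = -slopes[0]
    f[-1] = -slopes[-1]
    f[1:-1] = -(slopes[:-1] + slopes[1:]) / 2.0

    buf = io.StringIO()
    buf.write(f"# ncpcg tabulated potential; kind={pot.kind}; units kT, nm/deg\n")
    if comment:
        buf.write(f"# {comment}\n")
    buf.write(f"{keyword}\n")
    buf.write(f"N {r.size}\n\n")
    for i in range(r.size):
        buf.write(f"{i + 1} {r[i]:.17g} {u[i]:.17g} {f[i]:.17g}\n")
    Path(path).write_text(buf.getvalue())


def read_table(path, kind: str | None = None) -> TabulatedPotential:
    """Read a potential from the engine table dialect written by
    :func:`write_table` (forces in the file are ignored; they are always
    recomputed from the energies)."""
    lines = Path(path).read_text().splitlines()
    keyword = None
    n = None
    meta_kind = "pair"
    rows = []
    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "kind=" in s:
                meta_kind = s.split("kind=")[1].split(";")[0].strip()
            continue
        if n is None:
            if s.upper().startswith("N ") or s.upper().startswith("N\t"):
                n = int(s.split()[1])
            elif keyword is None:
                keyword = s.split()[0]
            continue
        parts = s.split()
        if len(parts) >= 3:
            rows.append((float(parts[1]), float(parts[2])))
    if n is None or not rows:
        raise ValueError(f"{path}: not a table file")
    if len(rows) != n:
        raise ValueError(f"{path}: header claims N={n}, found {len(rows)} rows")
    r = np.array([row[0] for row in rows])
    u = np.array([row[1] for row in rows])
    return TabulatedPotential(r, u, kind=kind or meta_kind, name=keyword or "")
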