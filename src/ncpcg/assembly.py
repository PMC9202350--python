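"""Composition of the final NCP model from per-subsystem potential sets.

Effective potentials are state-point dependent: the same CG-site pair
derived from different reference subsystems (DNA with multivalent ions,
DNA with peptides, peptides with multivalent ions) gives similar but not
identical tables.  When several sources provide a pair, the bundle picks
the one derived from the subsystem closest to the target system.  The
default precedence encodes that principle:

* DNA-DNA and DNA-amino-acid pairs from the DNA-Peptide subsystem (in an
  NCP the DNA is surrounded primarily by histone protein);
* pairs involving a multivalent cation from the subsystem containing
  that cation;
* monovalent-ion pairs from any source (their potentials are nearly
  transferable, so the sources are flagged equivalent).

Interactions between two histone-core beads are never assigned a table:
the core's short-range nonbonded interaction is excluded volume only,
with its internal structure maintained by the elastic network.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .potentials import CoulombTerm, ExcludedVolumeTerm, InteractionSet
from .tables import TabulatedPotential, read_table, write_table
from .topology import CGTopology, read_topology, write_topology

__all__ = ["PotentialLibrary", "PrecedenceRules", "ModelBundle",
           "assemble", "compare_sources", "export_bundle", "import_bundle",
           "lint_bundle"]

AA_TYPES = {"POL", "NPL", "POS", "NEG", "GLY"}
DNA_TYPES = {"P", "D"}
MULTIVALENT = {"MgW6": "Mg", "CoHex": "Co"}


def _norm_pair(pair):
    return tuple(sorted(pair))


def pair_class(pair) -> str:
    """One of DNA-DNA, DNA-AA, AA-AA, AA-ion, DNA-ion, ion-ion."""
    def kind(t):
        if t in DNA_TYPES:
            return "DNA"
        if t in AA_TYPES:
            return "AA"
        return "ion"
    a, b = sorted(kind(t) for t in pair)
    order = {"AA": 0, "DNA": 1, "ion": 2}
    a, b = sorted((a, b), key=order.get)
    if a == b:
        return f"{a}-{b}"
    if {a, b} == {"DNA", "AA"}:
        return "DNA-AA"
    return f"{a}-{b}"


@dataclass
class PotentialLibrary:
    """Tabulated pair potentials keyed by (type pair, source subsystem)."""
    entries: dict = field(default_factory=dict)

    def add(self, pair, source: str, table: TabulatedPotential,
            provenance: dict | None = None):
        key = (_norm_pair(pair), source)
        if key in self.entries:
            raise ValueError(f"duplicate library entry {key}")
        table.meta.setdefault("source", source)
        if provenance:
            table.meta.update(provenance)
        self.entries[key] = table

    def sources_for(self, pair):
        pair = _norm_pair(pair)
        return sorted(src for (p, src) in self.entries if p == pair)

    def get(self, pair, source):
        return self.entries[(_norm_pair(pair), source)]

    def pairs(self):
        return sorted({p for (p, _) in self.entries})


@dataclass
class PrecedenceRules:
    """Ordered source preference per pair class, with per-pair
    overrides.  ``multivalent_tokens`` routes pairs involving a
    multivalent cation to the subsystem containing it."""
    class_rules: dict = field(default_factory=lambda: {
        "DNA-DNA": ["DNA-Peptide", "DNA-Mg", "DNA-Co"],
        "DNA-AA": ["DNA-Peptide"],
        "AA-AA": ["DNA-Peptide", "Peptide-Mg", "Peptide-Co"],
        "AA-ion": ["DNA-Peptide", "Peptide-Mg", "Peptide-Co"],
        "DNA-ion": ["DNA-Peptide", "DNA-Mg", "DNA-Co"],
        "ion-ion": ["*"],
    })
    per_pair: dict = field(default_factory=dict)
    multivalent_tokens: dict = field(
        default_factory=lambda: dict(MULTIVALENT))

    def preference(self, pair, available):
        """Ordered candidate sources for a pair, given those available."""
        pair = _norm_pair(pair)
        if pair in self.per_pair:
            order = self.per_pair[pair]
        else:
            mv = [t for t in pair if t in self.multivalent_tokens]
            if mv:
                token = self.multivalent_tokens[mv[0]]
                order = ([s for s in available if token in s]
                         + [s for s in available if token not in s])
            else:
                order = self.class_rules.get(pair_class(pair), ["*"])
        out = []
        for src in order:
            if src == "*":
                out += [s for s in sorted(available) if s not in out]
            elif src in available and src not in out:
                out.append(src)
        return out

    def to_dict(self):
        return {"class_rules": self.class_rules,
                "per_pair": {" ".join(k): v
                             for k, v in self.per_pair.items()},
                "multivalent_tokens": self.multivalent_tokens}

    @classmethod
    def from_dict(cls, d):
        return cls(class_rules=dict(d.get("class_rules", {})),
                   per_pair={tuple(k.split()): v
                             for k, v in d.get("per_pair", {}).items()},
                   multivalent_tokens=dict(d.get("multivalent_tokens",
                                                 MULTIVALENT)))


@dataclass
class ModelBundle:
    """A complete, engine-consumable parameter set for one topology."""
    topology: CGTopology
    pair_tables: dict                  # (ta, tb) -> TabulatedPotential
    pair_sources: dict                 # (ta, tb) -> source id
    bond_tables: dict = field(default_factory=dict)
    angle_tables: dict = field(default_factory=dict)
    coulomb: CoulombTerm | None = None
    excluded_volume: ExcludedVolumeTerm | None = None
    manifest: dict = field(default_factory=dict)

    def interaction_set(self) -> InteractionSet:
        return InteractionSet(pair_tables=dict(self.pair_tables),
                              bond_tables=dict(self.bond_tables),
                              angle_tables=dict(self.angle_tables),
                              coulomb=self.coulomb,
                              excluded_volume=self.excluded_volume)

    def short_range_for(self, type_a, group_a, type_b, group_b):
        """Resolved short-range interaction for a bead pair: ("table",
        table) or ("excluded_volume", sigma_ij).  Core-core pairs are
        always excluded volume."""
        if group_a == group_b == "histone_core":
            s = self.excluded_volume.sigma_ij(type_a, type_b)
            return ("excluded_volume", s)
        tab = self.pair_tables.get(_norm_pair((type_a, type_b)))
        if tab is not None:
            return ("table", tab)
        if self.excluded_volume is not None and \
                self.excluded_volume.applies(group_a, group_b):
            return ("excluded_volume",
                    self.excluded_volume.sigma_ij(type_a, type_b))
        raise KeyError(f"no interaction for pair {type_a}-{type_b}")


def assemble(library: PotentialLibrary, rules: PrecedenceRules,
             topology: CGTopology, coulomb=None, excluded_volume=None,
             bond_tables=None, angle_tables=None) -> ModelBundle:
    """Pick one potential per type pair of the topology according to the
    precedence rules and record the provenance of every choice."""
    types = sorted(set(topology.types))
    needed = [tuple(sorted((a, b))) for n, a in enumerate(types)
              for b in types[n:]]
    groups_by_type = {}
    for b in topology.beads:
        groups_by_type.setdefault(b.type, set()).add(b.group)

    chosen = {}
    sources = {}
    manifest = {"pairs": {}, "rules": rules.to_dict()}
    for pair in needed:
        core_only = all(groups_by_type.get(t) == {"histone_core"}
                        for t in pair)
        avail = library.sources_for(pair)
        if core_only or not avail:
            ev_ok = (excluded_volume is not None
                     and all(t in excluded_volume.sigma for t in pair))
            if not ev_ok:
                raise KeyError(
                    f"pair {pair} not covered: no library source among "
                    f"{avail or 'none'} and no excluded-volume radii")
            manifest["pairs"]["-".join(pair)] = {
                "source": "excluded_volume",
                "reason": "core-core" if core_only else "no table"}
            continue
        pref = rules.preference(pair, avail)
        if not pref:
            raise KeyError(f"pair {pair}: sources {avail} present but "
                           f"none admitted by the precedence rules")
        src = pref[0]
        chosen[pair] = library.get(pair, src)
        sources[pair] = src
        manifest["pairs"]["-".join(pair)] = {
            "source": src, "candidates": avail,
            "equivalent": pair_class(pair) == "ion-ion"}
    return ModelBundle(topology=topology, pair_tables=chosen,
                       pair_sources=sources,
                       bond_tables=dict(bond_tables or {}),
                       angle_tables=dict(angle_tables or {}),
                       coulomb=coulomb, excluded_volume=excluded_volume,
                       manifest=manifest)


def compare_sources(library: PotentialLibrary, pair):
    """Deviation report between all sources of a pair, after resampling
    to the common grid and shift-alignment at the common cutoff; sorted
    by descending RMS deviation."""
    srcs = library.sources_for(pair)
    if len(srcs) < 2:
        raise ValueError(f"pair {pair} has {len(srcs)} source(s); "
                         "need at least two to compare")
    tabs = {s: library.get(pair, s) for s in srcs}
    lo = max(t.r[0] for t in tabs.values())
    hi = min(t.r[-1] for t in tabs.values())
    grid = np.linspace(lo, hi, 200)
    vals = {}
    misaligned = any(not tabs[srcs[0]].same_grid(t) for t in tabs.values())
    for s, t in tabs.items():
        u = t.evaluate(grid)[0]
        vals[s] = u - u[-1]           # shift-align at the common cutoff
    report = []
    for n, a in enumerate(srcs):
        for b in srcs[n + 1:]:
            d = vals[a] - vals[b]
            report.append({"sources": (a, b),
                           "max_dev": float(np.max(np.abs(d))),
                           "rms_dev": float(np.sqrt(np.mean(d ** 2)))})
    report.sort(key=lambda r: -r["rms_dev"])
    return {"pair": _norm_pair(pair), "grid": grid,
            "resampled": misaligned, "comparisons": report}


# ---------------------------------------------------------------------------
# bundle export / import
# ---------------------------------------------------------------------------

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def lint_bundle(bundle: ModelBundle):
    """Verify completeness against the bundle's topology; returns a list
    of problems (empty = clean)."""
    problems = []
    top = bundle.topology
    groups_of = dict(zip(top.types, top.groups))
    types = sorted(set(top.types))
    for n, a in enumerate(types):
        for b in types[n:]:
            try:
                bundle.short_range_for(a, groups_of[a], b, groups_of[b])
            except KeyError as exc:
                problems.append(str(exc))
    for bd in top.bonds:
        if bd.style == "table" and bd.potential not in bundle.bond_tables:
            problems.append(f"missing bond table {bd.potential!r}")
    for an in top.angles:
        if an.potential not in bundle.angle_tables:
            problems.append(f"missing angle table {an.potential!r}")
    return sorted(set(problems))


def export_bundle(bundle: ModelBundle, directory):
    """Write tables, topology and a manifest (with checksums and
    provenance) into a directory; refuses incomplete bundles."""
    problems = lint_bundle(bundle)
    if problems:
        raise ValueError("bundle incomplete: " + "; ".join(problems))
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {}
    for pair, tab in sorted(bundle.pair_tables.items()):
        name = f"pair_{pair[0]}-{pair[1]}.table"
        write_table(tab, d / name, keyword=f"{pair[0]}-{pair[1]}",
                    comment=f"source={bundle.pair_sources.get(pair, '?')}")
        files[name] = {"kind": "pair", "pair": list(pair),
                       "source": bundle.pair_sources.get(pair)}
    for pid, tab in sorted(bundle.bond_tables.items()):
        name = f"bond_{pid}.table"
        write_table(tab, d / name, keyword=pid)
        files[name] = {"kind": "bond", "id": pid}
    for pid, tab in sorted(bundle.angle_tables.items()):
        name = f"angle_{pid}.table"
        write_table(tab, d / name, keyword=pid)
        files[name] = {"kind": "angle", "id": pid}
    write_topology(bundle.topology, d / "topology.txt")
    files["topology.txt"] = {"kind": "topology"}
    for name in files:
        files[name]["sha256"] = _checksum(d / name)
    manifest = {
        "units": {"length": "nm", "energy": "kT", "charge": "e"},
        "files": files,
        "pairs": bundle.manifest.get("pairs", {}),
        "rules": bundle.manifest.get("rules", {}),
        "coulomb": None if bundle.coulomb is None else {
            "epsilon_r": bundle.coulomb.epsilon_r,
            "temperature": bundle.coulomb.temperature,
            "method": bundle.coulomb.method,
            "cutoff": bundle.coulomb.cutoff},
        "excluded_volume": None if bundle.excluded_volume is None else {
            "sigma": bundle.excluded_volume.sigma,
            "epsilon": bundle.excluded_volume.epsilon,
            "groups": bundle.excluded_volume.groups},
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                default=str))
    return d / "manifest.json"


def import_bundle(directory) -> ModelBundle:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    pair_tables, pair_sources = {}, {}
    bond_tables, angle_tables = {}, {}
    for name, info in manifest["files"].items():
        path = d / name
        if _checksum(path) != info["sha256"]:
            raise ValueError(f"checksum mismatch for {name}")
        if info["kind"] == "pair":
            pair = tuple(info["pair"])
            pair_tables[pair] = read_table(path, kind="pair")
            pair_sources[pair] = info.get("source")
        elif info["kind"] == "bond":
            bond_tables[info["id"]] = read_table(path, kind="bond")
        elif info["kind"] == "angle":
            angle_tables[info["id"]] = read_table(path, kind="angle")
    topology = read_topology(d / "topology.txt")
    cb = manifest.get("coulomb")
    coulomb = None if cb is None else CoulombTerm(
        epsilon_r=cb["epsilon_r"], temperature=cb["temperature"],
        method=cb["method"], cutoff=cb["cutoff"])
    ev = manifest.get("excluded_volume")
    excluded = None if ev is None else ExcludedVolumeTerm(
        sigma={k: float(v) for k, v in ev["sigma"].items()},
        epsilon=float(ev["epsilon"]),
        groups=None if ev["groups"] in (None, "None") else tuple(
            tuple(g) for g in ev["groups"]))
    return ModelBundle(topology=topology, pair_tables=pair_tables,
                       pair_sources=pair_sources, bond_tables=bond_tables,
                       angle_tables=angle_tables, coulomb=coulomb,
                       excluded_volume=excluded,
                       manifest={"pairs": manifest.get("pairs", {}),
                                 "rules": manifest.get("rules", {})})
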