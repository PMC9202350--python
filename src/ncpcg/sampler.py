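"""Canonical-ensemble sampling of compiled CG models.

Two backends share one compiled-model representation:

* Metropolis Monte Carlo with single-bead displacement moves — the
  workhorse inside the iterative inversion loop, where only
  configurational averages matter;
* Langevin dynamics (BAOAB splitting) — for trajectories.  The published
  protocol thermostats Hamiltonian dynamics with velocity rescaling; a
  Langevin thermostat samples the same configurational ensemble with a
  simpler correctness contract and is used here throughout (friction
  default 1/ps).  At zero friction the integrator reduces to velocity
  Verlet.

Simulated annealing follows a piecewise-linear temperature profile: ramp
from the base to an elevated temperature, hold, ramp back, then sample a
production window at the base temperature; only those production windows
are marked for analysis.  Spans quoted in ns in production protocols are
scaled down (default x0.01) for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .distributions import RDF
from .engine import CompiledModel
from .units import KB_KJMOL, T_DEFAULT, kT_kjmol

__all__ = ["SamplerConfig", "AnnealingSchedule", "SampleResult",
           "run_mc", "run_ld", "run_annealed", "rdf_from_traj"]


@dataclass
class SamplerConfig:
    mode: str = "MC"                  # "MC" | "LD"
    temperature: float = T_DEFAULT    # K
    reference_temperature: float = T_DEFAULT  # K of the potential tables
    timestep_fs: float = 5.0
    friction: float = 1.0             # 1/ps
    mc_max_disp: float = 0.1          # nm
    n_steps: int = 10000
    sample_every: int = 100
    seed: int = 0
    max_force_kjmol: float = 1e7      # abort threshold, kJ/mol/nm

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def beta(self) -> float:
        """Inverse temperature in units of the table energy (kT at the
        reference temperature)."""
        return self.reference_temperature / self.temperature

    @property
    def dt_ps(self) -> float:
        return self.timestep_fs * 1e-3


@dataclass
class AnnealingSchedule:
    base_temperature: float           # K
    hot_temperature: float            # K
    ramp_up: int                      # steps
    hold: int
    ramp_down: int
    production: int
    cycles: int = 1

    def __post_init__(self):
        for name in ("ramp_up", "hold", "ramp_down", "production"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} span must be positive")
        if self.hot_temperature <= self.base_temperature:
            raise ValueError("elevated temperature must exceed the base")
        if self.cycles < 1:
            raise ValueError("cycle count must be >= 1")

    @property
    def steps_per_cycle(self):
        return self.ramp_up + self.hold + self.ramp_down + self.production

    def temperature_profile(self):
        """Per-step temperature trace (K) and a production-window mask."""
        t = []
        prod = []
        for _ in range(self.cycles):
            t.append(np.linspace(self.base_temperature,
                                 self.hot_temperature, self.ramp_up,
                                 endpoint=False))
            prod.append(np.zeros(self.ramp_up, dtype=bool))
            t.append(np.full(self.hold, self.hot_temperature))
            prod.append(np.zeros(self.hold, dtype=bool))
            t.append(np.linspace(self.hot_temperature,
                                 self.base_temperature, self.ramp_down,
                                 endpoint=False))
            prod.append(np.zeros(self.ramp_down, dtype=bool))
            t.append(np.full(self.production, self.base_temperature))
            prod.append(np.ones(self.production, dtype=bool))
        return np.concatenate(t), np.concatenate(prod)


@dataclass
class SampleResult:
    frames: np.ndarray                  # (S, N, 3)
    config: SamplerConfig
    acceptance: float | None = None     # MC only
    kinetic_temperature: np.ndarray | None = None   # LD only, per sample
    production_mask: np.ndarray | None = None       # annealing only
    temperature_trace: np.ndarray | None = None
    final_positions: np.ndarray | None = None

    @property
    def production_frames(self):
        if self.production_mask is None:
            return self.frames
        return self.frames[self.production_mask]


def run_mc(model: CompiledModel, positions, config: SamplerConfig
           ) -> SampleResult:
    """Metropolis MC; detailed balance with symmetric single-bead cube
    displacements; bitwise reproducible for a given seed."""
    pos = np.array(positions, dtype=float)
    e0 = model.energy(pos)
    if not np.isfinite(e0):
        raise ValueError("non-finite starting energy")
    traj, n_acc = _kernels.mc_run(
        pos, model.box, model.itype, model.mobile_idx,
        model.u_pair, model.g_lo, model.g_dr, model.cutoff,
        model.excl_keys,
        model.hb_i, model.hb_j, model.hb_r0, model.hb_k,
        model.pb_off, model.pb_idx,
        model.tb_i, model.tb_j, model.tb_t, model.u_bond, model.b_lo,
        model.b_dr, model.ptb_off, model.ptb_idx,
        model.ang_i, model.ang_j, model.ang_k, model.ang_t, model.u_ang,
        model.a_lo, model.a_dr, model.pa_off, model.pa_idx,
        model.teth_k, model.teth_pos,
        config.beta, config.mc_max_disp, config.n_steps,
        config.sample_every, config.seed % 2 ** 31)
    return SampleResult(frames=traj, config=config,
                        acceptance=n_acc / config.n_steps,
                        final_positions=pos)


def _maxwell_velocities(model, temperature, rng):
    kt = kT_kjmol(temperature)
    v = rng.standard_normal((model.n_beads, 3))
    v *= np.sqrt(kt / model.masses)[:, None]
    v[~model.mobile] = 0.0
    return v


def run_ld(model: CompiledModel, positions, config: SamplerConfig,
           velocities=None, kt_schedule_kelvin=None) -> SampleResult:
    """Langevin dynamics (BAOAB).  ``kt_schedule_kelvin`` overrides the
    constant-temperature thermostat with a per-step profile."""
    if np.any(model.masses[model.mobile] <= 0):
        raise ValueError("masses must be positive")
    pos = np.array(positions, dtype=float)
    rng = np.random.default_rng(config.seed)
    if velocities is None:
        velocities = _maxwell_velocities(model, config.temperature, rng)
    vel = np.array(velocities, dtype=float)
    if kt_schedule_kelvin is None:
        kt_sched = np.full(config.n_steps, kT_kjmol(config.temperature))
    else:
        kt_sched = KB_KJMOL * np.asarray(kt_schedule_kelvin, dtype=float)
        if kt_sched.size != config.n_steps:
            raise ValueError("temperature schedule length != n_steps")
    e_scale = kT_kjmol(config.reference_temperature)
    traj, kin = _kernels.ld_run(
        pos, vel, model.masses, model.mobile, model.box, model.itype,
        model.f_pair, model.g_lo, model.g_dr, model.cutoff,
        model.excl_keys,
        model.hb_i, model.hb_j, model.hb_r0, model.hb_k,
        model.tb_i, model.tb_j, model.tb_t, model.u_bond, model.b_lo,
        model.b_dr,
        model.ang_i, model.ang_j, model.ang_k, model.ang_t, model.u_ang,
        model.a_lo, model.a_dr,
        model.teth_k, model.teth_pos,
        kt_sched, e_scale, config.dt_ps, config.friction,
        config.n_steps, config.sample_every, config.seed % 2 ** 31,
        config.max_force_kjmol)
    n_free = int(model.mobile.sum())
    t_kin = 2.0 * kin / (3.0 * n_free * KB_KJMOL)
    return SampleResult(frames=traj, config=config,
                        kinetic_temperature=t_kin, final_positions=pos)


def run_annealed(model: CompiledModel, positions,
                 schedule: AnnealingSchedule, config: SamplerConfig
                 ) -> SampleResult:
    """Langevin dynamics under a simulated-annealing temperature profile;
    the returned production mask selects samples taken in the
    base-temperature windows after each annealing cycle."""
    temps, prod = schedule.temperature_profile()
    cfg = SamplerConfig(**{**config.__dict__,
                           "mode": "LD",
                           "n_steps": temps.size,
                           "temperature": schedule.base_temperature})
    res = run_ld(model, positions, cfg, kt_schedule_kelvin=temps)
    # a sample taken at step (s+1)*sample_every - 1
    sample_steps = (np.arange(res.frames.shape[0]) + 1) \
        * cfg.sample_every - 1
    res.production_mask = prod[sample_steps]
    res.temperature_trace = temps
    return res


def rdf_from_traj(model: CompiledModel, frames, pairs, edges,
                  return_observables=False):
    """RDFs (and optionally the per-frame pair-count observables) for a
    list of type-label pairs from sampled frames."""
    frames = np.ascontiguousarray(frames, dtype=float)
    edges = np.asarray(edges, dtype=float)
    widths = np.diff(edges)
    if not np.allclose(widths, widths[0]):
        raise ValueError("uniform bins required")
    h_lo, h_dr, nb = float(edges[0]), float(widths[0]), edges.size - 1
    blocks = model.pair_block_map(pairs)
    s_frames = _kernels.pair_hist_frames(
        frames, model.box, model.itype, blocks, len(pairs),
        model.excl_keys, h_lo, h_dr, nb)

    # distinct pair count per block (exclusions removed)
    n = model.n_beads
    excl = set(model.excl_keys.tolist())
    n_pairs = np.zeros(len(pairs), dtype=float)
    it = model.itype
    for i in range(n):
        for j in range(i + 1, n):
            blk = blocks[it[i], it[j]]
            if blk >= 0 and (i * n + j) not in excl:
                n_pairs[blk] += 1

    volume = float(np.prod(model.box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rdfs = []
    for blk, (ta, tb) in enumerate(pairs):
        counts = s_frames[:, blk * nb:(blk + 1) * nb].mean(axis=0)
        ideal = n_pairs[blk] * shell / volume
        g = np.where(ideal > 0, counts / ideal, 0.0)
        tb_itypes = [k for k, (lbl, _) in enumerate(model.type_labels)
                     if lbl == tb]
        n_partner = int(np.isin(model.itype, tb_itypes).sum())
        rdfs.append(RDF(pair=(ta, tb), edges=edges, g=g,
                        n_frames=frames.shape[0],
                        density=n_partner / volume,
                        meta={"n_pairs": float(n_pairs[blk])}))
    if return_observables:
        return rdfs, s_frames
    return rdfs
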