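"""NVE/NVT integration and temperature replica exchange.

Internal unit system: Angstrom, amu, kcal/mol; the derived time unit is
sqrt(amu A^2 / (kcal/mol)) = 48.89 fs (the "natural" unit of coarse-grained
bead MD in these units), and all user-facing times are femtoseconds.

Integrators: velocity Verlet (NVE); BAOAB-splitting Langevin dynamics, whose
friction is a dimensionless multiple of a base friction chosen so that
``friction_scale = 0.05`` gives a velocity decorrelation time of about 2 ps
on the toy chain (a stand-in for scaled-down water friction); and velocity
Verlet with Berendsen weak-coupling velocity rescaling.

Restraint modes: ``none`` (bare toy field), ``instantaneous`` (penalties on
momentary distances/angles), ``time_averaged`` (penalties on the
exponential-memory averages, block-committed every ``n_ave`` steps, with the
force-scaling ramp).  Replica exchange compares extended energies whose
time-averaged penalty component is never scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cgmodel import (KB, TIME_UNIT_FS, ChainTopology, Conformation,
                      ToyForceField, toy_energy_forces)
from .restraints import RestraintSet, instantaneous_restraint_forces
from . import timeavg as ta

__all__ = ["ThermostatSpec", "MDConfig", "TrajectoryRecord", "ReplicaState",
           "velocity_verlet_step", "langevin_step", "berendsen_rescale",
           "kinetic_temperature", "run_trajectory", "attempt_exchange",
           "run_remd", "maxwell_boltzmann_velocities"]

#: Base Langevin friction, in inverse natural time units.  friction_scale
#: multiplies this (the values 0.02 and 0.05 mimic scaled water friction).
GAMMA_BASE = 0.5


class SimulationBlowupError(RuntimeError):
    """Coordinates or energies left the numerically sane region."""


@dataclass
class ThermostatSpec:
    kind: str = "none"                 # none | langevin | berendsen
    T_bath: float = 300.0
    friction_scale: float = 0.05
    tau_berendsen_fs: float = 489.0

    def __post_init__(self):
        if self.kind not in ("none", "langevin", "berendsen"):
            raise ValueError(f"unknown thermostat kind {self.kind!r}")
        if self.T_bath <= 0 or self.friction_scale < 0 \
                or self.tau_berendsen_fs <= 0:
            raise ValueError("invalid thermostat parameters")


@dataclass
class MDConfig:
    n_steps: int
    dt_fs: float = 4.89
    save_interval: int = 1000
    restraint_mode: str = "none"       # none | instantaneous | time_averaged
    seed: int = 0
    tau_fs: float = 48900.0
    n_ave: int = 500
    n_tau: int | None = None
    energy_scaling_diagnostic: bool = False
    force_scaling: bool = True
    T_init: float = 300.0
    blowup_limit: float = 1e4

    def __post_init__(self):
        if self.dt_fs <= 0 or self.n_steps < 1 or self.save_interval < 1:
            raise ValueError("need dt > 0, n_steps >= 1, save_interval >= 1")
        if self.restraint_mode not in ("none", "instantaneous",
                                       "time_averaged"):
            raise ValueError(f"unknown restraint mode {self.restraint_mode!r}")


@dataclass
class TrajectoryRecord:
    """Saved conformations plus per-interval instrumentation."""

    conformations: list = field(default_factory=list)
    step: list = field(default_factory=list)
    time_ps: list = field(default_factory=list)
    e_pot: list = field(default_factory=list)
    e_restraint: list = field(default_factory=list)   # unscaled
    e_kin: list = field(default_factory=list)
    e_total: list = field(default_factory=list)
    t_kin: list = field(default_factory=list)
    f_scale: list = field(default_factory=list)
    seed: int = 0
    config: MDConfig | None = None
    final_velocities: np.ndarray | None = None
    timeavg_state: object = None
    final_rng_state: dict | None = None
    final_coords: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "step": self.step, "time_ps": self.time_ps, "E_pot": self.e_pot,
            "E_restraint_unscaled": self.e_restraint, "E_kin": self.e_kin,
            "E_total": self.e_total, "T_kin": self.t_kin,
            "f_i": self.f_scale})


def maxwell_boltzmann_velocities(n, masses, T, rng):
    """Velocities (A per natural time unit) at temperature T."""
    sd = np.sqrt(KB * T / masses)[:, None]
    return rng.normal(size=(n, 3)) * sd


def kinetic_temperature(velocities, masses, n_dof=None) -> float:
    """T = 2 E_kin / (kB N_dof); N_dof defaults to 3 n_beads.

    No center-of-mass correction by default: Langevin dynamics does not
    conserve momentum.  Pass ``n_dof=3*n-3`` for NVE diagnostics.
    """
    v = np.asarray(velocities, dtype=float)
    m = np.asarray(masses, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1:
        raise ValueError("need at least one bead")
    ekin = 0.5 * float(np.sum(m[:, None] * v * v))
    n_dof = 3 * v.shape[0] if n_dof is None else int(n_dof)
    return 2.0 * ekin / (KB * n_dof)


def velocity_verlet_step(coords, velocities, forces, dt_tu, masses,
                         force_fn):
    """One velocity-Verlet step; returns (coords', velocities', forces',
    force_fn auxiliary output)."""
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.isfinite(forces))[0][0])
        raise SimulationBlowupError(f"non-finite force on bead {bad + 1}")
    inv_m = 1.0 / masses[:, None]
    v_half = velocities + 0.5 * dt_tu * forces * inv_m
    x_new = coords + dt_tu * v_half
    f_new, aux = force_fn(x_new)
    v_new = v_half + 0.5 * dt_tu * f_new * inv_m
    return x_new, v_new, f_new, aux


def langevin_step(coords, velocities, forces, dt_tu, masses, force_fn,
                  thermostat: ThermostatSpec, rng):
    """One BAOAB Langevin step (kick, half-drift, OU, half-drift, kick).

    The Ornstein-Uhlenbeck substep uses friction
    gamma = friction_scale * GAMMA_BASE and noise satisfying the
    fluctuation-dissipation relation at T_bath.  With friction_scale = 0 it
    reduces exactly to velocity Verlet.
    """
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.isfinite(forces))[0][0])
        raise SimulationBlowupError(f"non-finite force on bead {bad + 1}")
    gamma = thermostat.friction_scale * GAMMA_BASE
    inv_m = 1.0 / masses[:, None]
    v = velocities + 0.5 * dt_tu * forces * inv_m
    x = coords + 0.5 * dt_tu * v
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt_tu)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * thermostat.T_bath / masses)[:, None]
        v = c1 * v + c2 * rng.normal(size=v.shape)
    x = x + 0.5 * dt_tu * v
    f_new, aux = force_fn(x)
    v = v + 0.5 * dt_tu * f_new * inv_m
    return x, v, f_new, aux


def berendsen_rescale(velocities, t_kin, spec: ThermostatSpec, dt_tu):
    """Berendsen weak-coupling rescale toward T_bath."""
    if t_kin <= 0:
        raise ValueError("kinetic temperature must be positive")
    tau_b = spec.tau_berendsen_fs / TIME_UNIT_FS
    lam = np.sqrt(1.0 + (dt_tu / tau_b) * (spec.T_bath / t_kin - 1.0))
    return velocities * lam


def _make_force_fn(ff, rset, cfg, state):
    """Force provider closure for the configured restraint mode."""

    def force_fn(x):
        conf = Conformation.__new__(Conformation)
        conf.coords = x
        e_pot, forces = toy_energy_forces(conf, ff)
        e_r = 0.0
        e_r_scaled = None
        if cfg.restraint_mode == "instantaneous" and rset is not None:
            e_r, f_r = instantaneous_restraint_forces(conf, rset)
            forces = forces + f_r
        elif cfg.restraint_mode == "time_averaged":
            f_r, e_r, e_r_scaled = ta.timeavg_forces(
                state, conf, rset, scale_energy=cfg.energy_scaling_diagnostic)
            forces = forces + f_r
        return forces, (e_pot, e_r, e_r_scaled)

    return force_fn


def run_trajectory(conf0: Conformation, ff: ToyForceField,
                   rset: RestraintSet | None, cfg: MDConfig,
                   thermostat: ThermostatSpec | None = None,
                   topology: ChainTopology | None = None,
                   velocities0: np.ndarray | None = None,
                   state: ta.MemoryWindowState | None = None,
                   start_step: int = 0,
                   record: TrajectoryRecord | None = None,
                   rng_state: dict | None = None):
    """Run an instrumented trajectory; returns a TrajectoryRecord.

    The trajectory is deterministic for a given (config, thermostat, seed).
    ``velocities0``/``state``/``start_step``/``record`` allow bit-exact
    resumption from a checkpoint (see :mod:`tavmd.cli`).
    """
    thermostat = thermostat or ThermostatSpec(kind="none")
    topo = topology or ChainTopology(n_beads=conf0.n_beads)
    masses = topo.masses
    dt_tu = cfg.dt_fs / TIME_UNIT_FS
    rng = np.random.default_rng(cfg.seed)
    if cfg.restraint_mode in ("instantaneous", "time_averaged") \
            and rset is None:
        raise ValueError("restraint mode needs a restraint set")
    if cfg.restraint_mode == "time_averaged" and state is None:
        state = ta.MemoryWindowState(
            cfg.tau_fs, cfg.dt_fs, cfg.n_ave, rset.n_distance, rset.n_angle,
            rset.n_dihedral, n_tau=cfg.n_tau)
    if state is not None and not cfg.force_scaling:
        state.f_max = 1.0
        state.n_tau = 0
    if rset is not None:
        rset.validate_for_chain(conf0.n_beads)

    x = conf0.coords.copy()
    if velocities0 is not None:
        v = np.asarray(velocities0, dtype=float).copy()
    else:
        v = maxwell_boltzmann_velocities(conf0.n_beads, masses, cfg.T_init,
                                         rng)
    if rng_state is not None:
        rng.bit_generator.state = rng_state
    force_fn = _make_force_fn(ff, rset, cfg, state)
    f, aux = force_fn(x)
    rec = record or TrajectoryRecord(seed=cfg.seed, config=cfg)

    def instrument(i, aux):
        e_pot, e_r, e_r_scaled = aux
        ekin = 0.5 * float(np.sum(masses[:, None] * v * v))
        e_r_for_total = e_r_scaled if e_r_scaled is not None else e_r
        rec.conformations.append(Conformation(x.copy()))
        rec.step.append(i)
        rec.time_ps.append(i * cfg.dt_fs * 1e-3)
        rec.e_pot.append(e_pot)
        rec.e_restraint.append(e_r)
        rec.e_kin.append(ekin)
        rec.e_total.append(e_pot + e_r_for_total + ekin)
        rec.t_kin.append(kinetic_temperature(v, masses))
        rec.f_scale.append(ta.scaling_factor(state) if state is not None
                           else 1.0)

    if start_step == 0:
        instrument(0, aux)
    for i in range(start_step + 1, cfg.n_steps + 1):
        if thermostat.kind == "langevin":
            x, v, f, aux = langevin_step(x, v, f, dt_tu, masses, force_fn,
                                         thermostat, rng)
        else:
            x, v, f, aux = velocity_verlet_step(x, v, f, dt_tu, masses,
                                                force_fn)
            if thermostat.kind == "berendsen":
                v = berendsen_rescale(
                    v, kinetic_temperature(v, masses), thermostat, dt_tu)
        if cfg.restraint_mode == "time_averaged":
            conf_now = Conformation.__new__(Conformation)
            conf_now.coords = x
            from .restraints import measure
            y_now = measure(conf_now, rset)
            ta.accumulate_step(state, y_now)
            if state.acc_count == state.n_ave:
                ta.commit_block(state)
                # next block starts on the updated energy landscape
                f, aux = force_fn(x)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > cfg.blowup_limit:
            raise SimulationBlowupError(f"trajectory blow-up at step {i}")
        if i % cfg.save_interval == 0 or i == cfg.n_steps:
            instrument(i, aux)
    rec.final_velocities = v.copy()
    rec.timeavg_state = state
    rec.final_rng_state = rng.bit_generator.state
    rec.final_coords = x.copy()
    return rec


# ---------------------------------------------------------------------------
# replica exchange

@dataclass
class ReplicaState:
    """One replica of a temperature-REMD simulation."""

    conf: Conformation
    velocities: np.ndarray
    T_bath: float
    e_extended: float          # toy energy + UNSCALED restraint penalty
    restraint_tag: str = ""    # identity check across replicas


def attempt_exchange(rep_a: ReplicaState, rep_b: ReplicaState, rng):
    """Metropolis temperature swap on the unscaled extended energies.

    p = min{1, exp[(beta_a - beta_b)(E_a - E_b)]}.  On acceptance the bath
    temperatures swap and the velocities are rescaled by sqrt(T_new/T_old).
    Returns (accepted, p).
    """
    if rep_a.restraint_tag != rep_b.restraint_tag:
        raise ValueError("replicas carry different restraint sets")
    beta_a = 1.0 / (KB * rep_a.T_bath)
    beta_b = 1.0 / (KB * rep_b.T_bath)
    arg = (beta_a - beta_b) * (rep_a.e_extended - rep_b.e_extended)
    p = 1.0 if arg >= 0 else float(np.exp(arg))
    accepted = bool(rng.random() < p) if p < 1.0 else True
    if accepted:
        ta_, tb_ = rep_a.T_bath, rep_b.T_bath
        rep_a.velocities = rep_a.velocities * np.sqrt(tb_ / ta_)
        rep_b.velocities = rep_b.velocities * np.sqrt(ta_ / tb_)
        rep_a.T_bath, rep_b.T_bath = tb_, ta_
    return accepted, min(1.0, p)


def run_remd(conf0s, ff: ToyForceField, rset: RestraintSet | None,
             cfg: MDConfig, temperatures, exchange_interval: int,
             n_exchanges: int, friction_scale: float = 0.05):
    """Sequential temperature REMD on one process.

    Each replica owns an independent seeded random stream; exchanges swap
    bath temperatures between adjacent pairs (alternating even/odd pairing)
    using unscaled extended energies.  Returns (replicas, exchange log rows,
    per-replica TrajectoryRecords).
    """
    temps = list(temperatures)
    n_rep = len(temps)
    if isinstance(conf0s, Conformation):
        conf0s = [conf0s.copy() for _ in range(n_rep)]
    if len(conf0s) != n_rep:
        raise ValueError("need one start conformation per replica")
    topo = ChainTopology(n_beads=conf0s[0].n_beads)
    masses = topo.masses
    rngs = [np.random.default_rng(cfg.seed + 7919 * k)
            for k in range(n_rep)]
    ex_rng = np.random.default_rng(cfg.seed + 104729)
    tag = f"{0 if rset is None else (rset.n_distance, rset.n_angle, rset.n_dihedral)}"

    states = []
    for k in range(n_rep):
        st = None
        if cfg.restraint_mode == "time_averaged":
            st = ta.MemoryWindowState(
                cfg.tau_fs, cfg.dt_fs, cfg.n_ave, rset.n_distance,
                rset.n_angle, rset.n_dihedral, n_tau=cfg.n_tau)
        v = maxwell_boltzmann_velocities(conf0s[k].n_beads, masses,
                                         temps[k], rngs[k])
        states.append({"x": conf0s[k].coords.copy(), "v": v, "st": st,
                       "T": temps[k], "step": 0})
    log = []
    records = [TrajectoryRecord(seed=cfg.seed + 7919 * k, config=cfg)
               for k in range(n_rep)]

    def segment(k):
        s = states[k]
        seg_cfg = replace(cfg, n_steps=exchange_interval,
                          seed=cfg.seed + 7919 * k)
        thermo = ThermostatSpec(kind="langevin", T_bath=s["T"],
                                friction_scale=friction_scale)
        rec = _run_segment(s, seg_cfg, thermo, ff, rset, masses, rngs[k],
                           records[k])
        return rec

    def _run_segment(s, seg_cfg, thermo, ff, rset, masses, rng, rec):
        dt_tu = seg_cfg.dt_fs / TIME_UNIT_FS
        force_fn = _make_force_fn(ff, rset, seg_cfg, s["st"])
        x, v = s["x"], s["v"]
        f, aux = force_fn(x)
        for i in range(exchange_interval):
            x, v, f, aux = langevin_step(x, v, f, dt_tu, masses, force_fn,
                                         thermo, rng)
            if seg_cfg.restraint_mode == "time_averaged":
                conf_now = Conformation.__new__(Conformation)
                conf_now.coords = x
                from .restraints import measure
                ta.accumulate_step(s["st"], measure(conf_now, rset))
                if s["st"].acc_count == s["st"].n_ave:
                    ta.commit_block(s["st"])
                    f, aux = force_fn(x)
        s["x"], s["v"] = x, v
        s["step"] += exchange_interval
        e_pot, e_r, _ = aux
        rec.conformations.append(Conformation(x.copy()))
        rec.step.append(s["step"])
        rec.time_ps.append(s["step"] * seg_cfg.dt_fs * 1e-3)
        rec.e_pot.append(e_pot)
        rec.e_restraint.append(e_r)
        ekin = 0.5 * float(np.sum(masses[:, None] * v * v))
        rec.e_kin.append(ekin)
        rec.e_total.append(e_pot + e_r + ekin)
        rec.t_kin.append(kinetic_temperature(v, masses))
        rec.f_scale.append(ta.scaling_factor(s["st"])
                           if s["st"] is not None else 1.0)
        return e_pot + e_r

    for attempt in range(n_exchanges):
        energies = [segment(k) for k in range(n_rep)]
        # order replicas by current bath temperature, pair neighbors
        order = sorted(range(n_rep), key=lambda k: states[k]["T"])
        start = attempt % 2
        for a_pos in range(start, n_rep - 1, 2):
            ka, kb = order[a_pos], order[a_pos + 1]
            rep_a = ReplicaState(Conformation(states[ka]["x"].copy()),
                                 states[ka]["v"], states[ka]["T"],
                                 energies[ka], tag)
            rep_b = ReplicaState(Conformation(states[kb]["x"].copy()),
                                 states[kb]["v"], states[kb]["T"],
                                 energies[kb], tag)
            accepted, p = attempt_exchange(rep_a, rep_b, ex_rng)
            log.append({"attempt": attempt, "replica_a": ka, "replica_b": kb,
                        "delta_e": energies[ka] - energies[kb], "p": p,
                        "accepted": accepted})
            if accepted:
                states[ka]["T"], states[kb]["T"] = rep_a.T_bath, rep_b.T_bath
                states[ka]["v"], states[kb]["v"] = (rep_a.velocities,
                                                    rep_b.velocities)
    return states, log, records
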