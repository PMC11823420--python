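"""Canned study set-ups on the toy chain.

These functions wire chain generation, restraint synthesis, dynamics and
analysis into the standard numerical experiments the package is validated
with: microcanonical stability of restrained MD, canonical temperature
control, the restraint-force-scaling ramp, and ensemble recovery from
two-structure averaged restraints.  They back both the command-line presets
and the acceptance script.

Problem sizes are desk-scale by design: 15-25 beads and 1e5-5e5 steps per
trajectory, sized so a full experiment runs in minutes on one core.
"""

from __future__ import annotations

import numpy as np

from .cgmodel import ToyForceField, generate_random_chain
from .restraints import synthesize_restraints
from .dynamics import MDConfig, ThermostatSpec, run_trajectory
from .timeavg import MemoryWindowState
from .analysis import kabsch_rmsd

__all__ = ["memory_fill_steps", "nve_stability", "berendsen_temperature",
           "two_reference_recovery", "pick_reference_pair"]


def memory_fill_steps(tau_fs: float = 4890.0, dt_fs: float = 0.489) -> int:
    """Steps needed to fill the memory window: the ramp length tau/dt."""
    st = MemoryWindowState(tau_fs, dt_fs, n_ave=1,
                           n_dist=0, n_theta=0, n_gamma=0)
    return st.n_tau


def nve_stability(seed: int = 1, n_beads: int = 25, n_steps: int = 100_000,
                  dt_fs: float = 0.489, pad: float = 0.5, cutoff: float = 8.0,
                  A: float = 5.0, restraint_mode: str = "instantaneous",
                  tau_fs: float = 4890.0, n_ave: int = 1,
                  save_interval: int = 50, discard_steps: int = 1000):
    """Microcanonical restrained run; peak-to-peak total-energy variation.

    A random chain is restrained to itself (so the run starts inside every
    flat bottom) and integrated at a small diagnostic time step; returns
    (peak-to-peak E_total in kcal/mol after the discard period, record).
    """
    ff = ToyForceField()
    conf0 = generate_random_chain(n_beads, seed, ff)
    rset = synthesize_restraints(conf0, cutoff=cutoff, pad=pad, A=A)
    cfg = MDConfig(n_steps=n_steps, dt_fs=dt_fs, save_interval=save_interval,
                   restraint_mode=restraint_mode, seed=seed, tau_fs=tau_fs,
                   n_ave=n_ave,
                   energy_scaling_diagnostic=(restraint_mode
                                              == "time_averaged"))
    rec = run_trajectory(conf0, ff, rset, cfg,
                         ThermostatSpec(kind="none"))
    e = np.asarray(rec.e_total)
    steps = np.asarray(rec.step)
    e = e[steps >= discard_steps]
    return float(e.max() - e.min()), rec


def berendsen_temperature(seed: int = 1, n_beads: int = 25,
                          n_steps: int = 500_000, dt_fs: float = 4.89,
                          n_traj: int = 4, T_bath: float = 300.0,
                          pad: float = 0.5, cutoff: float = 8.0,
                          A: float = 5.0, save_interval: int = 250):
    """Canonical Berendsen runs without time averaging.

    Returns (mean over trajectories of the second-half average kinetic
    temperature, per-trajectory averages).
    """
    ff = ToyForceField()
    means = []
    for k in range(n_traj):
        s = seed + 1000 * k
        conf0 = generate_random_chain(n_beads, s, ff)
        rset = synthesize_restraints(conf0, cutoff=cutoff, pad=pad, A=A)
        cfg = MDConfig(n_steps=n_steps, dt_fs=dt_fs,
                       save_interval=save_interval,
                       restraint_mode="instantaneous", seed=s, T_init=T_bath)
        rec = run_trajectory(conf0, ff, rset, cfg,
                             ThermostatSpec(kind="berendsen", T_bath=T_bath))
        t = np.asarray(rec.t_kin)
        steps = np.asarray(rec.step)
        means.append(float(t[steps > n_steps // 2].mean()))
    return float(np.mean(means)), means


def pick_reference_pair(n_beads: int = 15, min_rmsd: float = 6.0,
                        seed0: int = 1000, max_tries: int = 200):
    """First pair of seeded random chains at least ``min_rmsd`` apart."""
    ff = ToyForceField()
    ref_a = generate_random_chain(n_beads, seed0, ff)
    for s in range(seed0 + 1, seed0 + 1 + max_tries):
        ref_b = generate_random_chain(n_beads, s, ff)
        if kabsch_rmsd(ref_a, ref_b) >= min_rmsd:
            return ref_a, ref_b
    raise RuntimeError("no sufficiently distinct reference pair found")


def two_reference_recovery(seed: int = 1, n_beads: int = 15,
                           n_steps: int = 150_000, dt_fs: float = 4.89,
                           n_traj: int = 4, tau_fs: float = 48900.0,
                           n_ave: int = 500, cutoff: float = 10.0,
                           pad: float = 0.5, A: float = 5.0,
                           T_bath: float = 300.0,
                           tau_berendsen_fs: float = 48.9,
                           save_interval: int = 250):
    """Ensemble recovery from two-structure r^-6-averaged restraints.

    Restraints are synthesized as the equal-weight r^-6 averages over two
    reference chains >= 6 A RMSD apart; canonical Berendsen-thermostatted
    trajectories are run with instantaneous and with time-averaged
    restraints (the memory window and block length are the production
    values tau = 48.9 ps, n_ave = 500; Berendsen coupling is tight because
    scaled time-averaged forces pump energy into the small toy chain far
    more strongly than weak stochastic friction can remove).  Returns a
    dict mode -> list over trajectories of (min RMSD to ref A, min RMSD to
    ref B) over the saved frames, plus the references and restraint set.
    """
    ff = ToyForceField()
    ref_a, ref_b = pick_reference_pair(n_beads)
    rset = synthesize_restraints([ref_a, ref_b], weights=(0.5, 0.5),
                                 cutoff=cutoff, pad=pad, A=A)
    out = {}
    for mode in ("instantaneous", "time_averaged"):
        per_traj = []
        for k in range(n_traj):
            s = seed + k
            conf0 = generate_random_chain(n_beads, 500 + s, ff)
            cfg = MDConfig(n_steps=n_steps, dt_fs=dt_fs,
                           save_interval=save_interval, restraint_mode=mode,
                           seed=s, tau_fs=tau_fs, n_ave=n_ave, T_init=T_bath)
            rec = run_trajectory(
                conf0, ff, rset, cfg,
                ThermostatSpec(kind="berendsen", T_bath=T_bath,
                               tau_berendsen_fs=tau_berendsen_fs))
            ra = min(kabsch_rmsd(c, ref_a) for c in rec.conformations)
            rb = min(kabsch_rmsd(c, ref_b) for c in rec.conformations)
            per_traj.append((ra, rb))
        out[mode] = per_traj
    return out, (ref_a, ref_b), rset
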