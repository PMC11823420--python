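"""Exponential-memory time averaging of restrained quantities.

The restrained quantity y_j (a distance, a virtual-bond angle, or a
dihedral) is replaced in the penalty by its average over a trailing memory
window of length tau with exponential weighting exp(-(t-t')/tau).  Distances
average through y^-3 (NOE convention, m = 3); angles average directly
(m = -1); dihedrals average their sines and cosines, with the mean angle
recovered by atan2.

Block (n_ave) update.  The memory integral is committed only every n_ave
steps: during a block, the committed history is frozen and the penalty sees
the mixture of that history with the *momentary* value of y carrying a
weight of one block span Delta = n_ave*dt.  The extended energy therefore
depends only on the current coordinates within a block, which makes
microcanonical runs conserve total energy between commits.  At a commit, the
block's mean of y^-m is appended with the analytic weight of its time span,
integral of exp(-s/tau) over the span, every older block decays by
exp(-Delta/tau), and blocks older than tau are evicted, so that the
committed normalization is exactly tau*(1 - e^-1) once the window is full
(tau is treated as an integer number of blocks).

Force scaling.  For t >> tau the momentary weight makes the time-averaged
restraint gradient smaller than the instantaneous one by the factor
Delta/[tau(1-e^-1) + Delta]; the restraint *forces* (never the energy, which
replica exchange must compare unscaled) are multiplied by a factor f_i that
ramps linearly from 1 at step 0 to f_max = (1-e^-1)*tau/Delta over N_tau
steps (default: the integer part of tau/dt) and stays there, restoring
restraint forces of full instantaneous magnitude.
"""

from __future__ import annotations

import json

import numpy as np

from .cgmodel import Conformation
from .restraints import (RestraintSet, MeasuredValues, distance_penalty_vec,
                         theta_penalty_vec, gamma_penalty_vec,
                         apply_restraint_gradients, measure_cached)

__all__ = ["MemoryWindowState", "accumulate_step", "commit_block",
           "effective_average", "scaling_factor", "timeavg_forces",
           "oracle_direct_average", "save_checkpoint", "load_checkpoint"]

_E1 = 1.0 - np.exp(-1.0)


class MemoryWindowState:
    """Per-restraint exponential-memory accumulators with block commits.

    Parameters
    ----------
    tau_fs, dt_fs : float
        Memory-window length and MD step, femtoseconds.
    n_ave : int
        Steps per committed block.
    n_dist, n_theta, n_gamma : int
        Restraint counts per kind.
    n_tau : int, optional
        Ramp length of the force-scaling factor in steps; defaults to the
        integer part of tau/dt.
    """

    def __init__(self, tau_fs: float, dt_fs: float, n_ave: int,
                 n_dist: int, n_theta: int, n_gamma: int, n_tau=None):
        if tau_fs <= 0 or dt_fs <= 0 or n_ave < 1:
            raise ValueError("need tau > 0, dt > 0, n_ave >= 1")
        self.tau = float(tau_fs)
        self.dt = float(dt_fs)
        self.n_ave = int(n_ave)
        self.delta = self.n_ave * self.dt          # block span
        if self.delta > self.tau * (1 + 1e-9):
            raise ValueError("block span n_ave*dt exceeds the memory window")
        self.n_blocks = max(1, int(round(self.tau / self.delta)))
        self.decay = np.exp(-self.delta / self.tau)
        # analytic weight of the newest committed block (age 0)
        self.w0 = self.tau * (1.0 - self.decay)
        self.n_dist, self.n_theta, self.n_gamma = n_dist, n_theta, n_gamma
        self.n_tau = int(np.floor(self.tau / self.dt + 1e-9)) \
            if n_tau is None else int(n_tau)
        self.f_max = max(1.0, _E1 * self.tau / self.delta)
        self.step = 0          # i: accumulated steps
        self.block = 0         # I: committed blocks
        self._init_buffers()

    def _init_buffers(self):
        K = self.n_blocks
        # ring buffers of committed block means (newest at ring head)
        self.hist_dist = np.zeros((K, self.n_dist))
        self.hist_theta = np.zeros((K, self.n_theta))
        self.hist_sin = np.zeros((K, self.n_gamma))
        self.hist_cos = np.zeros((K, self.n_gamma))
        self.hist_valid_theta = np.zeros((K, self.n_theta))
        self.hist_valid_gamma = np.zeros((K, self.n_gamma))
        self.head = 0
        self.filled = 0
        # running committed sums (weights folded in)
        self.S_dist = np.zeros(self.n_dist)
        self.N_dist = 0.0
        self.S_theta = np.zeros(self.n_theta)
        self.N_theta = np.zeros(self.n_theta)
        self.S_sin = np.zeros(self.n_gamma)
        self.S_cos = np.zeros(self.n_gamma)
        self.N_gamma = np.zeros(self.n_gamma)
        # current-block accumulators
        self.acc_dist = np.zeros(self.n_dist)
        self.acc_theta = np.zeros(self.n_theta)
        self.acc_sin = np.zeros(self.n_gamma)
        self.acc_cos = np.zeros(self.n_gamma)
        self.cnt_theta = np.zeros(self.n_theta)
        self.cnt_gamma = np.zeros(self.n_gamma)
        self.acc_count = 0

    # -- serialization ------------------------------------------------------

    _SCALARS = ("tau", "dt", "n_ave", "delta", "n_blocks", "decay", "w0",
                "n_dist", "n_theta", "n_gamma", "n_tau", "f_max",
                "step", "block", "head", "filled", "N_dist", "acc_count")
    _ARRAYS = ("hist_dist", "hist_theta", "hist_sin", "hist_cos",
               "hist_valid_theta", "hist_valid_gamma",
               "S_dist", "S_theta", "N_theta", "S_sin", "S_cos", "N_gamma",
               "acc_dist", "acc_theta", "acc_sin", "acc_cos",
               "cnt_theta", "cnt_gamma")

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self._SCALARS}
        for k in self._ARRAYS:
            a = getattr(self, k)
            out[k] = {"shape": list(a.shape), "data": a.ravel().tolist()}
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "MemoryWindowState":
        st = cls.__new__(cls)
        for k in cls._SCALARS:
            v = d[k]
            setattr(st, k, int(v) if k in (
                "n_ave", "n_blocks", "n_dist", "n_theta", "n_gamma",
                "n_tau", "step", "block", "head", "filled", "acc_count")
                else float(v))
        for k in cls._ARRAYS:
            setattr(st, k, np.asarray(d[k]["data"], dtype=float).reshape(
                d[k]["shape"]))
        return st


def save_checkpoint(path, state: MemoryWindowState) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(state.to_dict(), fh)


def load_checkpoint(path) -> MemoryWindowState:
    with open(path, "r", encoding="utf-8") as fh:
        return MemoryWindowState.from_dict(json.load(fh))


def accumulate_step(state: MemoryWindowState, y_now: MeasuredValues) -> None:
    """Add one step's momentary values to the current-block accumulator.

    Degenerate dihedrals (NaN) skip accumulation for that restraint; their
    block weight is renormalized by the per-restraint valid count.  Raises
    for non-positive distances (y^-m undefined).
    """
    d = np.asarray(y_now.dist, dtype=float)
    th = np.asarray(y_now.theta, dtype=float)
    ga = np.asarray(y_now.gamma, dtype=float)
    if d.shape != (state.n_dist,) or th.shape != (state.n_theta,) \
            or ga.shape != (state.n_gamma,):
        raise ValueError("value/restraint count mismatch")
    if np.any(d <= 0):
        raise ValueError("non-positive distance cannot be power-averaged")
    state.acc_dist += d**-3.0
    ok_t = np.isfinite(th)
    if not np.all(ok_t):
        raise ValueError("non-finite virtual-bond angle")
    state.acc_theta += th
    state.cnt_theta += 1.0
    ok_g = np.isfinite(ga)
    gr = np.radians(np.where(ok_g, ga, 0.0))
    state.acc_sin += np.where(ok_g, np.sin(gr), 0.0)
    state.acc_cos += np.where(ok_g, np.cos(gr), 0.0)
    state.cnt_gamma += ok_g
    state.acc_count += 1
    state.step += 1


def commit_block(state: MemoryWindowState) -> None:
    """Commit the full current block to the ring buffer.

    Every stored block weight decays by exp(-Delta/tau); the oldest block
    beyond the window is evicted; the running committed sums are updated
    recursively and periodically recomputed from the buffer to cancel
    floating-point drift.
    """
    if state.acc_count != state.n_ave:
        raise ValueError(
            f"block holds {state.acc_count} of {state.n_ave} steps")
    K = state.n_blocks
    mean_dist = state.acc_dist / state.n_ave
    mean_theta = np.where(state.cnt_theta > 0,
                          state.acc_theta / np.maximum(state.cnt_theta, 1), 0.0)
    mean_sin = np.where(state.cnt_gamma > 0,
                        state.acc_sin / np.maximum(state.cnt_gamma, 1), 0.0)
    mean_cos = np.where(state.cnt_gamma > 0,
                        state.acc_cos / np.maximum(state.cnt_gamma, 1), 0.0)
    valid_theta = (state.cnt_theta > 0).astype(float)
    valid_gamma = (state.cnt_gamma > 0).astype(float)

    # weight of the block being evicted (age K-1), if the ring is full
    if state.filled == K:
        w_old = state.w0 * state.decay ** (K - 1)
        old = state.head  # oldest slot is the one about to be overwritten
        state.S_dist = (state.S_dist - w_old * state.hist_dist[old]) \
            * state.decay
        state.N_dist = (state.N_dist - w_old) * state.decay
        state.S_theta = (state.S_theta - w_old * state.hist_theta[old]
                         * state.hist_valid_theta[old]) * state.decay
        state.N_theta = (state.N_theta - w_old
                         * state.hist_valid_theta[old]) * state.decay
        state.S_sin = (state.S_sin - w_old * state.hist_sin[old]
                       * state.hist_valid_gamma[old]) * state.decay
        state.S_cos = (state.S_cos - w_old * state.hist_cos[old]
                       * state.hist_valid_gamma[old]) * state.decay
        state.N_gamma = (state.N_gamma - w_old
                         * state.hist_valid_gamma[old]) * state.decay
    else:
        state.S_dist = state.S_dist * state.decay
        state.N_dist = state.N_dist * state.decay
        state.S_theta = state.S_theta * state.decay
        state.N_theta = state.N_theta * state.decay
        state.S_sin = state.S_sin * state.decay
        state.S_cos = state.S_cos * state.decay
        state.N_gamma = state.N_gamma * state.decay

    slot = state.head
    state.hist_dist[slot] = mean_dist
    state.hist_theta[slot] = mean_theta
    state.hist_sin[slot] = mean_sin
    state.hist_cos[slot] = mean_cos
    state.hist_valid_theta[slot] = valid_theta
    state.hist_valid_gamma[slot] = valid_gamma
    state.head = (state.head + 1) % K
    state.filled = min(state.filled + 1, K)

    state.S_dist = state.S_dist + state.w0 * mean_dist
    state.N_dist = state.N_dist + state.w0
    state.S_theta = state.S_theta + state.w0 * mean_theta * valid_theta
    state.N_theta = state.N_theta + state.w0 * valid_theta
    state.S_sin = state.S_sin + state.w0 * mean_sin * valid_gamma
    state.S_cos = state.S_cos + state.w0 * mean_cos * valid_gamma
    state.N_gamma = state.N_gamma + state.w0 * valid_gamma

    state.block += 1
    if state.block % K == 0:
        _recompute_sums(state)

    state.acc_dist[:] = 0.0
    state.acc_theta[:] = 0.0
    state.acc_sin[:] = 0.0
    state.acc_cos[:] = 0.0
    state.cnt_theta[:] = 0.0
    state.cnt_gamma[:] = 0.0
    state.acc_count = 0


def _recompute_sums(state: MemoryWindowState) -> None:
    """Rebuild the running sums exactly from the ring buffer."""
    K = state.n_blocks
    ages = np.arange(state.filled)
    # slot index of the block of a given age (age 0 = newest)
    slots = (state.head - 1 - ages) % K
    w = state.w0 * state.decay ** ages
    state.S_dist = w @ state.hist_dist[slots]
    state.N_dist = float(w.sum())
    vt = state.hist_valid_theta[slots]
    state.S_theta = w @ (state.hist_theta[slots] * vt)
    state.N_theta = w @ vt
    vg = state.hist_valid_gamma[slots]
    state.S_sin = w @ (state.hist_sin[slots] * vg)
    state.S_cos = w @ (state.hist_cos[slots] * vg)
    state.N_gamma = w @ vg


def effective_average(state: MemoryWindowState, y_now: MeasuredValues):
    """Time-averaged quantities seen by the penalties at the current step.

    Returns (MeasuredValues ybar, aux dict with the momentary-term weights
    needed for the gradient chain rule).  Before any commit, ybar equals the
    momentary values exactly.
    """
    d = np.asarray(y_now.dist, dtype=float)
    th = np.asarray(y_now.theta, dtype=float)
    ga = np.asarray(y_now.gamma, dtype=float)
    if d.shape != (state.n_dist,) or th.shape != (state.n_theta,) \
            or ga.shape != (state.n_gamma,):
        raise ValueError("momentary values missing or inconsistent with "
                         "the memory state")
    w_now = state.delta
    den_d = state.N_dist + w_now
    Y = (state.S_dist + w_now * d**-3.0) / den_d
    dbar = Y ** (-1.0 / 3.0)
    lam_d = np.full(state.n_dist, w_now / den_d)

    den_t = state.N_theta + w_now
    tbar = (state.S_theta + w_now * th) / den_t
    lam_t = w_now / den_t

    ok = np.isfinite(ga)
    gr = np.radians(np.where(ok, ga, 0.0))
    den_g = state.N_gamma + np.where(ok, w_now, 0.0)
    safe = den_g > 0
    sbar = np.where(safe, (state.S_sin + np.where(ok, w_now * np.sin(gr), 0.0))
                    / np.where(safe, den_g, 1.0), 0.0)
    cbar = np.where(safe, (state.S_cos + np.where(ok, w_now * np.cos(gr), 0.0))
                    / np.where(safe, den_g, 1.0), 1.0)
    gbar = np.where(safe, np.degrees(np.arctan2(sbar, cbar)), np.nan)
    ybar = MeasuredValues(dist=dbar, theta=tbar, gamma=gbar)
    aux = {"Y_dist": Y, "lam_dist": lam_d, "lam_theta": lam_t,
           "den_gamma": den_g, "sbar": sbar, "cbar": cbar, "ok_gamma": ok}
    return ybar, aux


def scaling_factor(state: MemoryWindowState, i=None) -> float:
    """Restraint-force scaling factor f_i: 1 -> f_max over N_tau steps.

    The ramp is linear in the step index but frozen within each n_ave block
    (it advances only at commits), so that the extended energy landscape --
    and with it the total energy of a microcanonical run -- is strictly
    constant between block updates, ramp included.
    """
    if i is None:
        i = state.block * state.n_ave      # last commit's step count
    elif i < 0:
        raise ValueError("step index must be non-negative")
    i = int(i)
    if state.n_tau <= 0 or i >= state.n_tau:
        return state.f_max
    return 1.0 + (state.f_max - 1.0) * i / state.n_tau


def timeavg_forces(state: MemoryWindowState, conf: Conformation,
                   rset: RestraintSet, scale_energy: bool = False):
    """Forces and energy of the time-averaged restraint penalty.

    The penalty is evaluated at the effective averages; its gradient is
    chained through the momentary-term weight and the measurement geometry,
    and the *force* is multiplied by the current scaling factor f_i.  The
    returned energy is the unscaled V(ybar) (the quantity replica exchange
    compares); with ``scale_energy`` the f_i-scaled energy is also returned
    for total-energy-conservation diagnostics.

    Returns (forces, V_unscaled, V_scaled_or_None).
    """
    if (rset.n_distance != state.n_dist or rset.n_angle != state.n_theta
            or rset.n_dihedral != state.n_gamma):
        raise ValueError("restraint set inconsistent with memory state")
    values, cache = measure_cached(conf, rset)
    ybar, aux = effective_average(state, values)
    comp = rset.compiled()
    f_i = scaling_factor(state)
    energy = 0.0
    g_dist = np.zeros(rset.n_distance)
    g_theta = np.zeros(rset.n_angle)
    g_gamma = np.zeros(rset.n_dihedral)
    if rset.n_distance:
        V, dV = distance_penalty_vec(ybar.dist, comp)
        energy += V.sum()
        # dbar/dd = (dbar/d)^4 * lambda
        g_dist = dV * (ybar.dist / values.dist) ** 4 * aux["lam_dist"]
    if rset.n_angle:
        V, dV = theta_penalty_vec(ybar.theta, comp)
        energy += V.sum()
        g_theta = dV * aux["lam_theta"]
    if rset.n_dihedral:
        V, dV = gamma_penalty_vec(ybar.gamma, comp)
        energy += V.sum()
        ok = aux["ok_gamma"] & (aux["den_gamma"] > 0)
        gr = np.radians(np.where(ok, values.gamma, 0.0))
        r2 = aux["sbar"]**2 + aux["cbar"]**2
        # dgammabar/dgamma (degree/degree), through averaged sin and cos
        dgb = np.where(ok, state.delta
                       * (aux["cbar"] * np.cos(gr) + aux["sbar"] * np.sin(gr))
                       / np.where(ok, aux["den_gamma"], 1.0)
                       / np.where(r2 > 0, r2, 1.0), 0.0)
        g_gamma = dV * dgb
    forces = f_i * apply_restraint_gradients(conf, rset, g_dist, g_theta,
                                             g_gamma, cache=cache)
    v_scaled = f_i * float(energy) if scale_energy else None
    return forces, float(energy), v_scaled


def oracle_direct_average(history, tau_fs, dt_fs, m, n_ave: int = 1):
    """Brute-force effective average from a complete per-step value list.

    Recomputes, by direct summation over the raw history (no recursion, no
    ring buffer), the truncated-exponential-window average that the block
    scheme maintains incrementally: block means of y^-m over the most recent
    floor(tau/(n_ave*dt)) complete blocks weighted by the analytic integral
    of exp(-age/tau) over their spans, plus the momentary (last) value with
    one block span's weight.  With ``n_ave=1`` this is plain direct
    quadrature of the memory integral.  For m = -1 the history is averaged
    directly; dihedral histories should be passed through sin/cos by the
    caller.
    """
    y = np.asarray(history, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("history must be a non-empty 1-D value list")
    tau, dt = float(tau_fs), float(dt_fs)
    delta = n_ave * dt
    K = max(1, int(round(tau / delta)))
    i = y.size
    n_complete = i // n_ave
    use = min(n_complete, K)
    num = 0.0
    den = 0.0
    for age in range(use):
        blk = n_complete - 1 - age
        seg = y[blk * n_ave:(blk + 1) * n_ave]
        w = tau * (np.exp(-age * delta / tau) - np.exp(-(age + 1) * delta / tau))
        num += w * np.mean(seg**(-float(m)) if m != -1 else seg)
        den += w
    ynow = y[-1]
    num += delta * (ynow**(-float(m)) if m != -1 else ynow)
    den += delta
    val = num / den
    return float(val ** (-1.0 / m)) if m != -1 else float(val)
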