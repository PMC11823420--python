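"""Integrators, thermostats, trajectory driver, and replica exchange."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from tavmd.cgmodel import (KB, TIME_UNIT_FS, Conformation, ToyForceField,
                           generate_random_chain)
from tavmd.dynamics import (MDConfig, ReplicaState, SimulationBlowupError,
                            ThermostatSpec, attempt_exchange,
                            berendsen_rescale, kinetic_temperature,
                            langevin_step, maxwell_boltzmann_velocities,
                            run_remd, run_trajectory, velocity_verlet_step)
from tavmd.restraints import RestraintSet, synthesize_restraints


def harmonic_pair_force(k, r0):
    def force_fn(x):
        d = x[1] - x[0]
        r = np.linalg.norm(d)
        f = -k * (r - r0) * d / r
        e = 0.5 * k * (r - r0) ** 2
        forces = np.array([-f, f])
        return forces, (e, 0.0, None)
    return force_fn


class TestVelocityVerlet:
    def test_zero_force_free_flight(self):
        x = np.zeros((2, 3))
        v = np.array([[1.0, 0, 0], [0, -2.0, 0]])
        masses = np.full(2, 110.0)

        def free(xx):
            return np.zeros_like(xx), (0.0, 0.0, None)

        xn, vn, _, _ = velocity_verlet_step(x, v, np.zeros_like(x), 0.1,
                                            masses, free)
        assert np.allclose(xn, x + 0.1 * v)
        assert np.array_equal(vn, v)

    def test_harmonic_dimer_period(self):
        k, r0, m = 10.0, 3.8, 110.0
        mu = m / 2
        period = 2 * np.pi * np.sqrt(mu / k)  # natural time units
        dt = period / 1000
        x = np.array([[0, 0, 0], [r0 + 0.1, 0, 0.0]])
        v = np.zeros((2, 3))
        f = harmonic_pair_force(k, r0)(x)[0]
        masses = np.full(2, m)
        seps = []
        for _ in range(3000):
            x, v, f, _ = velocity_verlet_step(x, v, f, dt, masses,
                                              harmonic_pair_force(k, r0))
            seps.append(x[1, 0] - x[0, 0])
        seps = np.asarray(seps)
        # measured period from zero crossings of (separation - r0)
        s = np.sign(seps - r0)
        crossings = np.flatnonzero(np.diff(s) != 0)
        measured = 2 * np.mean(np.diff(crossings)) * dt
        assert measured == pytest.approx(period, rel=1e-3)

    def test_two_bead_energy_drift_small(self):
        k, r0, m = 10.0, 3.8, 110.0
        dt = 2 * np.pi * np.sqrt(m / 2 / k) / 5000
        x = np.array([[0, 0, 0], [r0 + 0.2, 0, 0.0]])
        v = np.zeros((2, 3))
        ffn = harmonic_pair_force(k, r0)
        f, aux = ffn(x)
        masses = np.full(2, m)
        e0 = aux[0]
        emin = emax = e0
        for i in range(100_000):
            x, v, f, aux = velocity_verlet_step(x, v, f, dt, masses, ffn)
            e = aux[0] + 0.5 * np.sum(masses[:, None] * v * v)
            emin, emax = min(emin, e), max(emax, e)
        assert (emax - emin) / abs(0.5 * k * 0.2**2) < 1e-6

    def test_nonfinite_force_aborts_with_bead_index(self):
        x = np.zeros((3, 3))
        f = np.zeros((3, 3))
        f[1, 2] = np.nan
        with pytest.raises(SimulationBlowupError, match="bead 2"):
            velocity_verlet_step(x, np.zeros_like(x), f, 0.1,
                                 np.full(3, 110.0),
                                 lambda xx: (np.zeros_like(xx),
                                             (0.0, 0.0, None)))


class TestLangevin:
    def test_zero_friction_equals_velocity_verlet(self):
        rng = np.random.default_rng(0)
        x = np.array([[0, 0, 0], [4.0, 0, 0.0]])
        v = rng.normal(size=(2, 3)) * 0.01
        masses = np.full(2, 110.0)
        ffn = harmonic_pair_force(10.0, 3.8)
        f = ffn(x)[0]
        spec = ThermostatSpec(kind="langevin", T_bath=300, friction_scale=0.0)
        x1, v1, _, _ = langevin_step(x.copy(), v.copy(), f.copy(), 0.05,
                                     masses, ffn, spec, rng)
        x2, v2, _, _ = velocity_verlet_step(x.copy(), v.copy(), f.copy(),
                                            0.05, masses, ffn)
        assert np.allclose(x1, x2, atol=1e-14)
        assert np.allclose(v1, v2, atol=1e-14)

    def test_free_bead_reaches_bath_temperature(self):
        rng = np.random.default_rng(1)
        masses = np.full(1, 110.0)
        spec = ThermostatSpec(kind="langevin", T_bath=300.0,
                              friction_scale=1.0)
        x = np.zeros((1, 3))
        v = np.zeros((1, 3))
        f = np.zeros((1, 3))

        def free(xx):
            return np.zeros_like(xx), (0.0, 0.0, None)

        temps = []
        for i in range(40_000):
            x, v, f, _ = langevin_step(x, v, f, 0.1, masses, free, spec, rng)
            if i > 2000:
                temps.append(kinetic_temperature(v, masses))
        mean = np.mean(temps)
        # ~ 3 standard errors of the mean of correlated samples
        tau_c = 1.0 / (1.0 * 0.5 * 0.1)  # steps of velocity decorrelation
        se = 300.0 * np.sqrt(2.0 / 3.0) / np.sqrt(len(temps) / tau_c)
        assert abs(mean - 300.0) < 3 * se

    def test_fixed_seed_reproducible_bitwise(self, ff):
        conf = generate_random_chain(10, seed=3, ff=ff)
        cfg = MDConfig(n_steps=200, dt_fs=4.89, save_interval=50, seed=17)
        spec = ThermostatSpec(kind="langevin", T_bath=300.0,
                              friction_scale=0.05)
        a = run_trajectory(conf, ff, None, cfg, spec)
        b = run_trajectory(conf, ff, None, cfg, spec)
        assert np.array_equal(a.final_coords, b.final_coords)
        assert np.array_equal(a.final_velocities, b.final_velocities)


class TestBerendsen:
    def test_no_rescale_at_bath_temperature(self):
        spec = ThermostatSpec(kind="berendsen", T_bath=300.0)
        v = np.ones((4, 3))
        out = berendsen_rescale(v, 300.0, spec, 0.1)
        assert np.allclose(out, v)

    def test_lambda_matches_closed_form(self):
        rng = np.random.default_rng(2)
        spec = ThermostatSpec(kind="berendsen", T_bath=300.0,
                              tau_berendsen_fs=489.0)
        for _ in range(30):
            t_kin = rng.uniform(50, 900)
            dt = rng.uniform(0.001, 0.2)
            v = rng.normal(size=(3, 3))
            lam = np.sqrt(1 + (dt / (489.0 / TIME_UNIT_FS))
                          * (300.0 / t_kin - 1))
            assert np.allclose(berendsen_rescale(v, t_kin, spec, dt),
                               lam * v, atol=1e-12)

    def test_drives_temperature_toward_bath(self):
        rng = np.random.default_rng(3)
        masses = np.full(20, 110.0)
        v = maxwell_boltzmann_velocities(20, masses, 600.0, rng)
        spec = ThermostatSpec(kind="berendsen", T_bath=300.0,
                              tau_berendsen_fs=489.0)
        temps = [kinetic_temperature(v, masses)]
        for _ in range(2000):
            v = berendsen_rescale(v, kinetic_temperature(v, masses), spec,
                                  0.1)
            temps.append(kinetic_temperature(v, masses))
        assert np.all(np.diff(temps) <= 1e-9)  # monotone cooling toward bath
        assert temps[-1] == pytest.approx(300.0, abs=1.0)


class TestKineticTemperature:
    def test_zero_velocities(self):
        assert kinetic_temperature(np.zeros((5, 3)), np.full(5, 110.0)) == 0.0

    def test_constructed_single_bead(self):
        m = np.array([110.0])
        speed = np.sqrt(3 * KB * 250.0 / 110.0)
        v = np.array([[speed, 0.0, 0.0]])
        assert kinetic_temperature(v, m) == pytest.approx(250.0, rel=1e-12)

    def test_maxwell_boltzmann_sampling(self):
        rng = np.random.default_rng(4)
        masses = np.full(10_000, 110.0)
        v = maxwell_boltzmann_velocities(10_000, masses, 300.0, rng)
        t = kinetic_temperature(v, masses)
        se = 300.0 * np.sqrt(2.0 / (3 * 10_000))
        assert abs(t - 300.0) < 3 * se


class TestRunTrajectory:
    def test_empty_instantaneous_set_equals_unrestrained_bitwise(self, ff):
        conf = generate_random_chain(10, seed=3, ff=ff)
        cfg_a = MDConfig(n_steps=300, dt_fs=4.89, save_interval=100, seed=5,
                         restraint_mode="none")
        cfg_b = MDConfig(n_steps=300, dt_fs=4.89, save_interval=100, seed=5,
                         restraint_mode="instantaneous")
        spec = ThermostatSpec(kind="langevin", T_bath=300.0,
                              friction_scale=0.05)
        a = run_trajectory(conf, ff, None, cfg_a, spec)
        b = run_trajectory(conf, ff, RestraintSet(), cfg_b, spec)
        assert np.array_equal(a.final_coords, b.final_coords)

    def test_canonical_second_half_temperature_within_one_percent(self, ff):
        conf = generate_random_chain(15, seed=6, ff=ff)
        cfg = MDConfig(n_steps=60_000, dt_fs=4.89, save_interval=50, seed=6)
        spec = ThermostatSpec(kind="langevin", T_bath=300.0,
                              friction_scale=0.5)
        rec = run_trajectory(conf, ff, None, cfg, spec)
        t = np.asarray(rec.t_kin)
        steps = np.asarray(rec.step)
        mean = t[steps > 30_000].mean()
        assert mean == pytest.approx(300.0, rel=0.01)

    def test_blowup_detection_aborts_with_step_index(self, ff):
        conf = generate_random_chain(6, seed=7, ff=ff)
        # absurd initial temperature sends beads far outside the sane box
        cfg = MDConfig(n_steps=1000, dt_fs=4.89, save_interval=100, seed=7,
                       T_init=1e7, blowup_limit=200.0)
        with pytest.raises(SimulationBlowupError, match="step"):
            run_trajectory(conf, ff, None, cfg, ThermostatSpec(kind="none"))

    def test_checkpoint_resume_bitwise_identical(self, ff):
        conf = generate_random_chain(10, seed=8, ff=ff)
        rset = synthesize_restraints(conf, cutoff=9.0)
        spec = ThermostatSpec(kind="langevin", T_bath=300.0,
                              friction_scale=0.05)
        full_cfg = MDConfig(n_steps=400, dt_fs=4.89, save_interval=100,
                            seed=9, restraint_mode="time_averaged",
                            tau_fs=489.0, n_ave=10)
        full = run_trajectory(conf, ff, rset, full_cfg, spec)
        half_cfg = MDConfig(n_steps=200, dt_fs=4.89, save_interval=100,
                            seed=9, restraint_mode="time_averaged",
                            tau_fs=489.0, n_ave=10)
        half = run_trajectory(conf, ff, rset, half_cfg, spec)
        resumed = run_trajectory(
            Conformation(half.final_coords), ff, rset, full_cfg, spec,
            velocities0=half.final_velocities, state=half.timeavg_state,
            start_step=200, rng_state=half.final_rng_state)
        assert np.array_equal(full.final_coords, resumed.final_coords)
        assert np.array_equal(full.final_velocities,
                              resumed.final_velocities)


def test_temperature_deviation_shrinks_with_longer_memory_window(ff):
    """Canonical time-averaged runs heat above the bath; the deviation is
    far smaller at the long-window production settings (tau = 489 ps,
    n_ave = 1000) than at the shortest window (tau = 4.89 ps, n_ave = 1)."""
    conf0 = generate_random_chain(25, 1, ff)
    rset = synthesize_restraints(conf0, cutoff=8.0, pad=0.5, A=5.0)
    dev = {}
    for tau_fs, n_ave in ((4890.0, 1), (489000.0, 1000)):
        cfg = MDConfig(n_steps=30_000, dt_fs=4.89, save_interval=100,
                       restraint_mode="time_averaged", seed=1, tau_fs=tau_fs,
                       n_ave=n_ave)
        rec = run_trajectory(conf0, ff, rset, cfg,
                             ThermostatSpec(kind="langevin", T_bath=300.0,
                                            friction_scale=0.05))
        t = np.asarray(rec.t_kin)
        s = np.asarray(rec.step)
        dev[(tau_fs, n_ave)] = abs(t[s > 15_000].mean() - 300.0)
    assert dev[(489000.0, 1000)] < dev[(4890.0, 1)]


class TestReplicaExchange:
    def make(self, T, E):
        return ReplicaState(Conformation(np.zeros((4, 3)) + np.arange(4)[:, None] * [4.0, 0, 0]),
                            np.ones((4, 3)), T, E, "tag")

    def test_equal_energies_always_accepted(self):
        rng = np.random.default_rng(0)
        a, b = self.make(300.0, -50.0), self.make(320.0, -50.0)
        acc, p = attempt_exchange(a, b, rng)
        assert acc and p == 1.0

    def test_downhill_swap_always_accepted(self):
        rng = np.random.default_rng(0)
        # hot replica has the lower energy: swapping it down is downhill
        a, b = self.make(300.0, -10.0), self.make(400.0, -60.0)
        acc, p = attempt_exchange(a, b, rng)
        assert acc and p == 1.0
        assert a.T_bath == 400.0 and b.T_bath == 300.0

    def test_velocities_rescaled_on_swap(self):
        rng = np.random.default_rng(0)
        a, b = self.make(300.0, -10.0), self.make(400.0, -60.0)
        attempt_exchange(a, b, rng)
        assert np.allclose(a.velocities, np.sqrt(400 / 300))
        assert np.allclose(b.velocities, np.sqrt(300 / 400))

    def test_mismatched_restraints_rejected(self):
        rng = np.random.default_rng(0)
        a, b = self.make(300.0, -10.0), self.make(400.0, -60.0)
        b.restraint_tag = "other"
        with pytest.raises(ValueError):
            attempt_exchange(a, b, rng)

    def test_acceptance_rate_matches_analytic_overlap(self):
        # two harmonic-system replicas: energies are Gamma-distributed;
        # compare the empirical acceptance over 1e4 attempts with the
        # numeric double integral of min(1, exp(dbeta*dE))
        ndof = 12
        Ta, Tb = 300.0, 360.0
        rng = np.random.default_rng(11)
        ba, bb = 1 / (KB * Ta), 1 / (KB * Tb)
        n = 10_000
        Ea = gamma_dist.rvs(ndof / 2, scale=1 / ba, size=n, random_state=rng)
        Eb = gamma_dist.rvs(ndof / 2, scale=1 / bb, size=n, random_state=rng)
        acc = []
        for ea, eb in zip(Ea, Eb):
            a, b = self.make(Ta, ea), self.make(Tb, eb)
            accepted, _ = attempt_exchange(a, b, rng)
            acc.append(accepted)
        emp = np.mean(acc)

        def inner(ea):
            f = lambda eb: np.exp(min(0.0, (ba - bb) * (ea - eb))) \
                * gamma_dist.pdf(eb, ndof / 2, scale=1 / bb)
            return quad(f, 0, np.inf, limit=200)[0] \
                * gamma_dist.pdf(ea, ndof / 2, scale=1 / ba)
        expect = quad(inner, 0, np.inf, limit=200)[0]
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(emp - expect) < 3 * se + 1e-3

    def test_identical_replicas_same_temperature_always_exchange(self, ff):
        conf = generate_random_chain(8, seed=12, ff=ff)
        cfg = MDConfig(n_steps=100, dt_fs=4.89, save_interval=50, seed=13)
        states, log, recs = run_remd(conf, ff, None, cfg, [300.0, 300.0],
                                     exchange_interval=50, n_exchanges=6)
        rows = [r for r in log]
        assert len(rows) == 3  # alternating pairing: odd attempts pair none
        assert all(r["p"] == 1.0 or r["accepted"] for r in rows)
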