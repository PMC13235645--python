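"""Langevin integrator physics, motors and the preparation protocol."""

import numpy as np
import pytest
from scipy import integrate, stats

import supercoil as sc
from supercoil.fixtures import planar_circle
from supercoil.model import ModelParams

FREE = ModelParams(epsilon=0.0, K_fene=0.0, K_bend=0.0, K_tilt=0.0, K_torsion=0.0)


def _free_state(n=4, spacing=0.5):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    quat = np.tile([1.0, 0, 0, 0], (n, 1))
    return sc.SystemState(rings=[sc.RingConformation(pos, quat)], box_length=0.0)


class TestLangevinLimits:
    def test_velocity_decay_at_zero_temperature(self):
        """Free particle at T = 0: v(t) = v0 exp(-gamma t)."""
        state = _free_state()
        state._vel = np.zeros((1, 4, 3))
        state._vel[0, :, 0] = 1.0
        state._omg = np.zeros((1, 4, 3))
        cfg = sc.IntegratorConfig(dt=0.001, gamma=1.0, temperature=0.0, seed=1)
        sc.simulate(state, 2000, FREE, cfg)
        assert state._vel[0, 0, 0] == pytest.approx(np.exp(-2.0), rel=1e-3)

    def test_einstein_relation_free_diffusion(self):
        """Long-time MSD/6t of a free bead equals D = k_B T / (m gamma)."""
        msds = []
        t_run = 40.0
        for rep in range(6):
            state = _free_state()
            start = state.positions_array().copy()
            cfg = sc.IntegratorConfig(dt=0.001, gamma=1.0, temperature=1.0, seed=100 + rep)
            sc.simulate(state, int(t_run * 1000), FREE, cfg)
            disp = state.positions_array() - start
            msds.append(np.mean(np.sum(disp**2, axis=2)))
        D = np.mean(msds) / (6 * t_run)
        assert D == pytest.approx(1.0, rel=0.25)

    def test_equipartition_in_ring(self):
        """Mean kinetic energy per translational DOF is k_B T / 2."""
        ring = planar_circle(16)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        cfg = sc.IntegratorConfig(seed=7)
        sc.simulate(state, 2000, None, cfg)  # thermalize
        samples = []
        for k in range(60):
            cfg.seed = 1000 + k
            sc.simulate(state, 200, None, cfg)
            samples.append(np.mean(state._vel**2))
        ke = 0.5 * np.mean(samples)  # m = 1
        se = 0.5 * np.std(samples) / np.sqrt(len(samples))
        assert abs(ke - 0.5) < max(3 * se, 0.02)

    def test_blowup_reports_broken_bond(self):
        ring = planar_circle(12)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        cfg = sc.IntegratorConfig(dt=0.05, seed=3)  # unstable timestep
        with pytest.raises(sc.BrokenBondError):
            sc.simulate(state, 20000, None, cfg)


def _sample_ring(params, n_snap=30, N=64, seed0=5000, warmup=5000):
    ring = planar_circle(N)
    state = sc.SystemState(rings=[ring], box_length=0.0)
    cfg = sc.IntegratorConfig(seed=seed0 - 1)
    sc.simulate(state, warmup, params, cfg)  # decorrelate from the circle
    snaps = []
    for k in range(n_snap):
        cfg.seed = seed0 + k
        sc.simulate(state, 500, params, cfg)
        snaps.append(state.rings[0])
        state.rings[0] = sc.RingConformation(
            state.rings[0].positions.copy(), state.rings[0].quat.copy()
        )
    return snaps


class TestBoltzmannSampling:
    """Detailed-balance surrogate: with motors off, equilibrium marginals
    match 1D Boltzmann quadratures of the individual potential terms.

    The bond-angle check runs with tilt/torsion off: frame coupling adds a
    (physical) extra bending stiffness, so only then is the bare
    Kratky-Porod weight the exact marginal."""

    def test_bond_length_distribution(self):
        snaps = _sample_ring(ModelParams(), seed0=5000)
        bonds = np.concatenate([np.linalg.norm(r.bonds(), axis=1) for r in snaps])
        p = ModelParams()

        def weight(r):
            return r**2 * np.exp(
                -(sc.bond_energy_fene(r, p) + sc.pair_energy_wca(r, p))
            )

        rs = np.linspace(0.7, 1.25, 2000)
        ws = np.array([weight(r) for r in rs])
        cdf = integrate.cumulative_trapezoid(ws, rs, initial=0)
        cdf /= cdf[-1]
        sub = bonds[:: max(1, len(bonds) // 800)]
        ks = stats.ks_1samp(sub, lambda x: np.interp(x, rs, cdf))
        assert ks.pvalue > 0.01

    def test_bond_angle_distribution(self):
        """Angle marginal vs the Kratky-Porod weight
        exp(-beta K (1 - cos t)) sin t (frame terms off)."""
        snaps = _sample_ring(ModelParams(K_tilt=0.0, K_torsion=0.0), seed0=6000)
        angles = []
        for r in snaps:
            t = r.bonds()
            tn = t / np.linalg.norm(t, axis=1)[:, None]
            angles.extend(
                np.arccos(np.clip(np.einsum("ij,ij->i", tn, np.roll(tn, -1, 0)), -1, 1))
            )
        angles = np.asarray(angles)
        ts = np.linspace(1e-4, np.pi / 2, 2000)
        ws = np.exp(-20.0 * (1 - np.cos(ts))) * np.sin(ts)
        cdf = integrate.cumulative_trapezoid(ws, ts, initial=0)
        cdf /= cdf[-1]
        sub = angles[:: max(1, len(angles) // 400)]
        ks = stats.ks_1samp(sub, lambda x: np.interp(x, ts, cdf))
        assert ks.pvalue > 0.01

    def test_dihedral_angle_distribution(self):
        """Relative frame rotation about the bond vs the double-dihedral
        weight exp(-2 beta K (1 - cos phi)), a von Mises law with kappa = 2K."""
        snaps = _sample_ring(ModelParams(), seed0=7000)
        phis = []
        for r in snaps:
            f = r.f
            t = r.bonds()
            tn = t / np.linalg.norm(t, axis=1)[:, None]
            f1p = f - np.einsum("ij,ij->i", f, tn)[:, None] * tn
            f2 = np.roll(f, -1, axis=0)
            f2p = f2 - np.einsum("ij,ij->i", f2, tn)[:, None] * tn
            s = np.einsum("ij,ij->i", np.cross(f1p, f2p), tn)
            c = np.einsum("ij,ij->i", f1p, f2p)
            phis.extend(np.arctan2(s, c))
        phis = np.asarray(phis)
        sub = phis[:: max(1, len(phis) // 400)]
        ks = stats.kstest(sub, lambda x: stats.vonmises.cdf(x, 100.0))
        assert ks.pvalue > 0.01

    def test_mean_cos_close_to_kp_theory(self):
        """<cos theta> of the full model sits near coth(bK) - 1/(bK); the
        small stiffening excess comes from the frame coupling."""
        snaps = _sample_ring(ModelParams(), seed0=8000)
        coss = []
        for r in snaps:
            t = r.bonds()
            tn = t / np.linalg.norm(t, axis=1)[:, None]
            coss.extend(np.einsum("ij,ij->i", tn, np.roll(tn, -1, 0)))
        assert np.mean(coss) == pytest.approx(sc.kp_mean_cos_theta(20.0), abs=0.01)


class TestMotor:
    def test_zero_torque_sigma_fluctuates_about_zero(self):
        """beta TQ = 0 is the nicked-ring limit: no net supercoiling."""
        ring = planar_circle(32)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        state.motors = [sc.MotorSite(ring_id=0, bond_index=5, torque=0.0)]
        traj = sc.run_protocol(state, [sc.Phase("active", 20.0, 0.0, 2.0)], seed=9)
        sig = traj.sigma()[:, 0]
        assert np.abs(sig).max() < 0.02

    def test_motor_torque_increments(self):
        ring = planar_circle(16)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        motor = sc.MotorSite(ring_id=0, bond_index=3, torque=2.5)
        inc = sc.apply_motor(state, motor)
        t = ring.positions[4] - ring.positions[3]
        that = t / np.linalg.norm(t)
        # equal and opposite torques of magnitude TQ about the bond axis
        assert inc[0, 3] == pytest.approx(2.5 * that, abs=1e-12)
        assert inc[0, 4] == pytest.approx(-2.5 * that, abs=1e-12)
        assert np.abs(inc[0, [0, 1, 2, 5, 6]]).max() == 0.0

    def test_sigma_formula(self):
        motor = sc.MotorSite(ring_id=0, bond_index=0, torque=1.0,
                             accumulated_angle=2 * np.pi * 24)
        assert motor.sigma(400) == pytest.approx(0.06)

    def test_motor_force_calibration_pn(self):
        assert sc.motor_force_pn(1.0, 0.80) == pytest.approx(2.07, abs=0.005)

    def test_sigma_antisymmetric_in_torque(self):
        """Steady-state |sigma| statistics match under TQ -> -TQ."""
        finals = []
        for tq in (6.0, -6.0):
            ring = planar_circle(32)
            state = sc.SystemState(rings=[ring], box_length=0.0)
            state.motors = [sc.MotorSite(ring_id=0, bond_index=2, torque=tq)]
            traj = sc.run_protocol(state, [sc.Phase("active", 30.0, tq, 3.0)], seed=17)
            finals.append(traj.sigma()[-3:, 0].mean())
        assert finals[0] == pytest.approx(-finals[1], abs=0.01)
        assert abs(finals[0]) > 0.003  # torque does build supercoiling


class TestPreparation:
    def test_rescale_arithmetic(self):
        # one compression cycle: L0 = 100 -> 99 for s = 1
        assert 100.0 * (100.0 - 1.0) / 100.0 == pytest.approx(99.0)

    def test_prepare_reaches_density_unlinked(self, dense_state):
        state, info = dense_state
        assert state.density == pytest.approx(0.08, rel=1e-6)
        assert info["max_pairwise_Lk"] < 1e-6
        assert np.all(np.diff(info["box_history"]) <= 1e-12)  # monotone compression

    def test_single_ring_dilute(self):
        state, info = sc.prepare_initial_state(
            1, 24, sc.PreparationProtocol(target_density=0.001, thermalize_steps=100,
                                          final_equilibration_tau=1.0), seed=3
        )
        assert state.M == 1
        assert state.density == pytest.approx(0.001, rel=1e-6)

    def test_persistence_length_from_short_run(self):
        """<cos theta> from a short dilute-ring run gives l_p ~ 20 s,
        matching the Kratky-Porod prediction coth(bK) - 1/(bK)."""
        ring = planar_circle(64)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        cfg = sc.IntegratorConfig(seed=31)
        sc.simulate(state, 4000, None, cfg)
        coss = []
        for k in range(25):
            cfg.seed = 31000 + k
            sc.simulate(state, 400, None, cfg)
            t = state.rings[0].bonds()
            tn = t / np.linalg.norm(t, axis=1)[:, None]
            coss.extend(np.einsum("ij,ij->i", tn, np.roll(tn, -1, 0)))
        mc = float(np.mean(coss))
        lp = sc.persistence_length(mc, bond_length=1.0)
        lp_theory = sc.persistence_length(sc.kp_mean_cos_theta(20.0), bond_length=1.0)
        assert lp_theory == pytest.approx(19.5, abs=0.1)
        assert lp == pytest.approx(lp_theory, rel=0.2)


class TestRunProtocol:
    def test_zero_duration_schedule(self):
        ring = planar_circle(16)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        traj = sc.run_protocol(state, [sc.Phase("equilibrium", 0.0)], seed=1)
        assert traj.n_snapshots == 1
        assert traj.times[0] == 0.0

    def test_reproducible_with_seed(self):
        outs = []
        for _ in range(2):
            ring = planar_circle(16)
            state = sc.SystemState(rings=[ring], box_length=0.0)
            traj = sc.run_protocol(state, [sc.Phase("active", 2.0, 4.0, 1.0)], seed=5)
            outs.append(traj.positions.copy())
        assert np.array_equal(outs[0], outs[1])
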