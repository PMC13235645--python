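"""Force-field terms: printed values, limits, symmetries and gradients."""

import numpy as np
import pytest

import supercoil as sc
from supercoil import _kernels
from supercoil.model import ModelParams

from conftest import random_ring


@pytest.fixture
def params():
    return ModelParams()


class TestPairPotentials:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (2.0 ** (1.0 / 6.0), 0.0),  # WCA cutoff continuity
            (1.0, 1.0),  # 4(1 - 1 + 1/4)
            (1.05, 0.24248808616372750),  # independent symbolic evaluation
        ],
    )
    def test_wca_values(self, r, expected, params):
        assert sc.pair_energy_wca(r, params) == pytest.approx(expected, abs=1e-12)

    def test_wca_zero_beyond_cutoff(self, params):
        assert sc.pair_energy_wca(1.5, params) == 0.0
        assert sc.pair_force_wca(1.5, params) == 0.0

    def test_wca_overlap_is_domain_error(self, params):
        with pytest.raises(ValueError):
            sc.pair_energy_wca(0.0, params)

    def test_wca_force_is_minus_derivative(self, params):
        h = 1e-7
        for r in (0.9, 1.0, 1.1):
            fd = -(sc.pair_energy_wca(r + h, params) - sc.pair_energy_wca(r - h, params)) / (2 * h)
            assert sc.pair_force_wca(r, params) == pytest.approx(fd, rel=1e-6)

    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.0, 0.0),
            (0.8 * 1.6, 52.308543873637446),  # -0.5*40*1.6^2*ln(0.36)
        ],
    )
    def test_fene_values(self, r, expected, params):
        assert sc.bond_energy_fene(r, params) == pytest.approx(expected, abs=1e-10)

    def test_fene_monotone_and_divergent(self, params):
        rs = np.linspace(0.1, 1.55, 30)
        es = [sc.bond_energy_fene(r, params) for r in rs]
        assert np.all(np.diff(es) > 0)
        with pytest.raises(sc.BrokenBondError):
            sc.bond_energy_fene(1.6, params)


class TestAngularPotentials:
    @pytest.mark.parametrize(
        "t2,expected",
        [
            ([1, 0, 0], 0.0),  # collinear
            ([0, 1, 0], 20.0),  # perpendicular
            ([-1, 0, 0], 40.0),  # antiparallel
        ],
    )
    def test_bend_values(self, t2, expected, params):
        assert sc.angle_energy_bend([1, 0, 0], t2, params) == pytest.approx(expected)

    def test_bend_zero_bond_error(self, params):
        with pytest.raises(ValueError):
            sc.angle_energy_bend([0, 0, 0], [1, 0, 0], params)

    @pytest.mark.parametrize(
        "u,expected",
        [
            ([1, 0, 0], 0.0),  # aligned with bond
            ([0, 1, 0], 200.0),  # perpendicular
            ([0.5, np.sqrt(3) / 2, 0], 100.0),  # 60 degrees: 1 - cos60
        ],
    )
    def test_tilt_values(self, u, expected, params):
        assert sc.tilt_energy(u, [2.0, 0, 0], params) == pytest.approx(expected)

    def test_torsion_aligned_frames_zero(self, params):
        t = np.array([1.0, 0, 0])
        f = np.array([0, 1.0, 0])
        v = np.array([0, 0, 1.0])
        assert sc.torsion_energy(t, f, f, v, v, 0.0, params) == pytest.approx(0.0)

    def test_torsion_quarter_turn(self, params):
        # frames of bead i+1 rotated by pi/2 about the bond: both dihedral
        # terms sit at cos = 0, i.e. K each
        t = np.array([1.0, 0, 0])
        f1 = np.array([0, 1.0, 0])
        v1 = np.array([0, 0, 1.0])
        f2 = np.array([0, 0, 1.0])
        v2 = np.array([0, -1.0, 0])
        assert sc.torsion_energy(t, f1, f2, v1, v2, 0.0, params) == pytest.approx(100.0)

    def test_torsion_rotation_invariance(self, params):
        rng = np.random.default_rng(3)
        t = np.array([1.0, 0.3, -0.2])
        f1 = np.array([-0.3, 1.0, 0.1])
        f1 -= f1 @ t / (t @ t) * t
        f1 /= np.linalg.norm(f1)
        v1 = np.cross(t / np.linalg.norm(t), f1)
        ang = 0.7
        axis = t / np.linalg.norm(t)
        f2 = f1 * np.cos(ang) + np.cross(axis, f1) * np.sin(ang)
        v2 = v1 * np.cos(ang) + np.cross(axis, v1) * np.sin(ang)
        e0 = sc.torsion_energy(t, f1, f2, v1, v2, 0.0, params)
        # random rigid rotation of every vector leaves the energy unchanged
        from scipy.spatial.transform import Rotation

        Q = Rotation.random(random_state=7).as_matrix()
        e1 = sc.torsion_energy(Q @ t, Q @ f1, Q @ f2, Q @ v1, Q @ v2, 0.0, params)
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_torsion_minimum_at_psi0(self, params):
        # with a preferred angle psi0, the energy is minimal when the second
        # frame is the first rotated by psi0 about the bond
        t = np.array([1.0, 0, 0])
        f1 = np.array([0, 1.0, 0])
        v1 = np.array([0, 0, 1.0])
        psi0 = 0.4
        angs = np.linspace(-1.0, 1.0, 81)
        es = []
        for a in angs:
            f2 = f1 * np.cos(a) + np.cross(t, f1) * np.sin(a)
            v2 = v1 * np.cos(a) + np.cross(t, v1) * np.sin(a)
            es.append(sc.torsion_energy(t, f1, f2, v1, v2, psi0, params))
        assert angs[int(np.argmin(es))] == pytest.approx(psi0, abs=0.03)
        assert min(es) == pytest.approx(0.0, abs=1e-9)

    def test_torsion_degenerate_bond_parallel_frame(self, params):
        t = np.array([0, 1.0, 0])
        f = np.array([0, 1.0, 0])  # parallel to bond: degenerate cross
        v = np.array([0, 0, 1.0])
        with pytest.raises(ValueError):
            sc.torsion_energy(t, f, f, v, v, 0.0, params)


def _rot_quat(q_i, ax, ang):
    dq = np.r_[np.cos(ang / 2), np.sin(ang / 2) * np.asarray(ax)]
    w, x, y, z = dq
    qw, qx, qy, qz = q_i
    return np.array(
        [
            w * qw - x * qx - y * qy - z * qz,
            w * qx + x * qw + y * qz - z * qy,
            w * qy - x * qz + y * qw + z * qx,
            w * qz + x * qy - y * qx + z * qw,
        ]
    )


class TestTotalEnergyAndGradients:
    def test_gradients_match_central_differences(self):
        """Analytic forces and frame torques vs numerical differentiation."""
        ring = random_ring(N=9, seed=5)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        p = ModelParams()
        e0, F, T = sc.total_energy_and_gradients(state, p)
        pos = state.positions_array()
        quat = state.quat_array()
        par = p.to_kernel_array()
        mb = np.array([-1], dtype=np.int64)
        h = 1e-6
        for i in range(ring.N):
            for k in range(3):
                pp = pos.copy()
                pp[0, i, k] += h
                pm = pos.copy()
                pm[0, i, k] -= h
                ep = _kernels.compute_forces(pp, quat, 0.0, par, mb)[0]
                em = _kernels.compute_forces(pm, quat, 0.0, par, mb)[0]
                fd = -(ep - em) / (2 * h)
                assert F[0, i, k] == pytest.approx(fd, rel=1e-5, abs=1e-5)
                ax = np.zeros(3)
                ax[k] = 1.0
                qp = quat.copy()
                qp[0, i] = _rot_quat(quat[0, i], ax, h)
                qm = quat.copy()
                qm[0, i] = _rot_quat(quat[0, i], ax, -h)
                ep = _kernels.compute_forces(pos, qp, 0.0, par, mb)[0]
                em = _kernels.compute_forces(pos, qm, 0.0, par, mb)[0]
                fd = -(ep - em) / (2 * h)
                assert T[0, i, k] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_energy_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        ring = random_ring(N=12, seed=8)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        e0, _, _ = sc.total_energy_and_gradients(state)
        Q = Rotation.random(random_state=11).as_matrix()
        shift = np.array([3.0, -2.0, 7.0])
        pos2 = ring.positions @ Q.T + shift
        frames2 = np.einsum("ab,nbc->nac", Q, ring.frames)
        ring2 = sc.RingConformation.from_frames(pos2, frames2)
        e1, _, _ = sc.total_energy_and_gradients(sc.SystemState(rings=[ring2], box_length=0.0))
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_flat_circle_energy_is_pure_bending(self):
        """A flat, torsion-aligned circle of uniformly spaced beads costs
        exactly N K_bend (1 - cos(2 pi / N)) plus the (constant) tilt
        residual from frames pointing along chords."""
        from supercoil.fixtures import planar_circle

        N = 32
        ring = planar_circle(N)
        p = ModelParams()
        e, F, T = sc.total_energy_and_gradients(sc.SystemState(rings=[ring], box_length=0.0), p)
        expected_bend = N * p.K_bend * (1 - np.cos(2 * np.pi / N))
        # u is the exact bond direction and f the plane normal: tilt and
        # torsion vanish; WCA/FENE contributions at spacing 0.97 are shared
        bond = np.linalg.norm(ring.bonds(), axis=1)
        e_bonds = sum(sc.bond_energy_fene(b, p) for b in bond)
        e_wca = 0.0
        for i in range(N):
            for j in range(i + 1, N):
                r = np.linalg.norm(ring.positions[i] - ring.positions[j])
                if r < 2 ** (1 / 6):
                    e_wca += sc.pair_energy_wca(r, p)
        assert e - e_bonds - e_wca == pytest.approx(expected_bend, abs=1e-8)

    def test_distant_rings_no_interaction(self):
        r1 = random_ring(N=10, seed=1)
        r2 = sc.RingConformation(r1.positions + 50.0, r1.quat.copy())
        e1, F1, _ = sc.total_energy_and_gradients(sc.SystemState(rings=[r1], box_length=0.0))
        e2, F2, _ = sc.total_energy_and_gradients(
            sc.SystemState(rings=[r1, r2], box_length=0.0)
        )
        assert e2 == pytest.approx(2 * e1, rel=1e-12)
        assert F2[0] == pytest.approx(F1[0], abs=1e-12)

    def test_broken_bond_reports_indices(self):
        ring = random_ring(N=8, seed=2)
        ring.positions[3] += 5.0  # stretch bond 2-3 and 3-4 beyond R0
        with pytest.raises(sc.BrokenBondError):
            sc.total_energy_and_gradients(sc.SystemState(rings=[ring], box_length=0.0))

    def test_motor_bond_dihedrals_excluded(self):
        ring = random_ring(N=10, seed=4)
        state = sc.SystemState(rings=[ring], box_length=0.0)
        e_all, _, _ = sc.total_energy_and_gradients(state)
        state.motors = [sc.MotorSite(ring_id=0, bond_index=4, torque=0.0)]
        e_motor, _, _ = sc.total_energy_and_gradients(state)
        # removing the two dihedrals of bond 4 can only lower the energy
        assert e_motor <= e_all + 1e-12
        t = ring.positions[5] - ring.positions[4]
        fr = ring.frames
        contrib = sc.torsion_energy(t, fr[4, :, 1], fr[5, :, 1], fr[4, :, 2], fr[5, :, 2])
        assert e_all - e_motor == pytest.approx(contrib, rel=1e-9)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(K_bend=-1.0)
        with pytest.raises(ValueError):
            ModelParams(dt=0.0)
        with pytest.raises(ValueError):
            ModelParams(R0=0.5)

    def test_yaml_roundtrip(self, tmp_path):
        p = ModelParams(K_torsion=55.0, psi0=0.1)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        q = ModelParams.from_yaml(path)
        assert q == p


class TestUnitsMapping:
    def test_motor_force_calibration(self):
        # TQ = k_B T at 300 K with 0.80 * 2.5 nm lever: 2.07 pN
        assert sc.motor_force_pn(1.0) == pytest.approx(2.07, abs=0.005)

    def test_dna_mapping(self):
        assert sc.contour_kbp(400) == pytest.approx(2.96, abs=1e-12)
        assert sc.mass_concentration_mg_per_ml(0.08) == pytest.approx(40.9, abs=0.1)
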