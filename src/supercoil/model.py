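"""Twistable-ribbon bead-spring model of circular DNA (plasmids).

Each plasmid is an unknotted ring of ``N`` beads carrying a right-handed
orthonormal orientation triad ``[u, f, v]`` per bead.  The potential energy
combines

* a purely repulsive WCA pair potential between all bead pairs,
* FENE bonds between consecutive beads,
* a Kratky-Porod bending term on consecutive bond vectors,
* a stiff tilt term aligning the body vector ``u_i`` with the bond ``t_i``,
* two dihedral (torsion) terms coupling ``f`` and ``v`` of consecutive beads
  through the bond direction, giving the ribbon its torsional stiffness.

Energies are in units of ``k_B T`` (epsilon), lengths in units of the bead
diameter ``s`` (2.5 nm, about 7.4 bp of double-stranded DNA) and times in the
Lennard-Jones time ``tau``.  All index arithmetic on a ring is modulo ``N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "RingConformation",
    "SystemState",
    "MotorSite",
    "BrokenBondError",
    "pair_energy_wca",
    "pair_force_wca",
    "bond_energy_fene",
    "angle_energy_bend",
    "tilt_energy",
    "torsion_energy",
    "total_energy_and_gradients",
    "quat_to_frames",
    "frames_to_quat",
    "KBT_300K_PN_NM",
    "BEAD_NM",
    "BP_PER_BEAD",
    "motor_force_pn",
    "contour_kbp",
    "mass_concentration_mg_per_ml",
]

# ---------------------------------------------------------------------------
# physical constants for mapping reduced units onto real DNA
# ---------------------------------------------------------------------------

#: k_B * 300 K in pN nm
KBT_300K_PN_NM = 1.380649e-23 * 300.0 * 1e21
#: bead diameter s in nm
BEAD_NM = 2.5
#: base pairs represented by one bead
BP_PER_BEAD = 7.4
#: average molar mass of one DNA base pair, g/mol
BP_G_PER_MOL = 650.0
AVOGADRO = 6.02214076e23


def motor_force_pn(torque_kbt: float = 1.0, lever_arm: float = 0.80) -> float:
    """Magnitude (pN) of each force in the motor couple realizing a torque.

    A torque of ``torque_kbt`` (in units of k_B T at 300 K) applied as a force
    couple with lever distance ``lever_arm * s`` from the bead center.
    """
    return torque_kbt * KBT_300K_PN_NM / (lever_arm * BEAD_NM)


def contour_kbp(n_beads: int) -> float:
    """Contour length of a ring of ``n_beads`` in kilo-base-pairs."""
    return n_beads * BP_PER_BEAD / 1000.0


def mass_concentration_mg_per_ml(rho_s3: float) -> float:
    """DNA mass concentration (mg/mL) at reduced monomer density ``rho s^3``."""
    beads_per_cm3 = rho_s3 / (BEAD_NM * 1e-7) ** 3
    gram_per_bead = BP_PER_BEAD * BP_G_PER_MOL / AVOGADRO
    return beads_per_cm3 * gram_per_bead * 1000.0  # g/cm^3 -> mg/mL


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Force-field and integration parameters (reduced units).

    Defaults are the standard twistable-ribbon values: FENE bonds
    (K=40 eps/s^2, R0=1.6 s), Kratky-Porod bending K=20 eps (persistence
    length ~20 s), tilt K=200 eps, torsion K=50 eps, flat ribbon psi0=0.
    """

    epsilon: float = 1.0
    s: float = 1.0
    K_fene: float = 40.0
    R0: float = 1.6
    K_bend: float = 20.0
    K_tilt: float = 200.0
    K_torsion: float = 50.0
    psi0: float = 0.0
    m: float = 1.0
    gamma: float = 1.0
    dt: float = 0.001
    rot_inertia: float = 1.0

    def __post_init__(self) -> None:
        for name in ("K_fene", "K_bend", "K_tilt", "K_torsion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.R0 <= self.s * 0 or self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.R0 <= self.s:
            raise ValueError("R0 must exceed the bead diameter s")

    def to_kernel_array(self) -> np.ndarray:
        return np.array(
            [
                self.epsilon,
                self.s,
                self.K_fene,
                self.R0,
                self.K_bend,
                self.K_tilt,
                self.K_torsion,
                self.psi0,
            ],
            dtype=np.float64,
        )

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# orientation frames <-> quaternions
# ---------------------------------------------------------------------------


def quat_to_frames(q: np.ndarray) -> np.ndarray:
    """Rotation matrices for unit quaternions ``q`` (..., 4) -> (..., 3, 3).

    Columns of each matrix are the body axes ``u = R e_x``, ``f = R e_y``,
    ``v = R e_z``.  Quaternion convention ``(w, x, y, z)``.
    """
    q = np.asarray(q, dtype=np.float64)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def frames_to_quat(frames: np.ndarray) -> np.ndarray:
    """Unit quaternions ``(w,x,y,z)`` from rotation matrices (..., 3, 3)."""
    R = np.asarray(frames, dtype=np.float64)
    out = np.empty(R.shape[:-2] + (4,))
    it = np.ndindex(R.shape[:-2])
    for idx in it:
        M = R[idx]
        tr = M[0, 0] + M[1, 1] + M[2, 2]
        if tr > 0:
            S = math.sqrt(tr + 1.0) * 2
            w = 0.25 * S
            x = (M[2, 1] - M[1, 2]) / S
            y = (M[0, 2] - M[2, 0]) / S
            z = (M[1, 0] - M[0, 1]) / S
        elif M[0, 0] > M[1, 1] and M[0, 0] > M[2, 2]:
            S = math.sqrt(1.0 + M[0, 0] - M[1, 1] - M[2, 2]) * 2
            w = (M[2, 1] - M[1, 2]) / S
            x = 0.25 * S
            y = (M[0, 1] + M[1, 0]) / S
            z = (M[0, 2] + M[2, 0]) / S
        elif M[1, 1] > M[2, 2]:
            S = math.sqrt(1.0 + M[1, 1] - M[0, 0] - M[2, 2]) * 2
            w = (M[0, 2] - M[2, 0]) / S
            x = (M[0, 1] + M[1, 0]) / S
            y = 0.25 * S
            z = (M[1, 2] + M[2, 1]) / S
        else:
            S = math.sqrt(1.0 + M[2, 2] - M[0, 0] - M[1, 1]) * 2
            w = (M[1, 0] - M[0, 1]) / S
            x = (M[0, 2] + M[2, 0]) / S
            y = (M[1, 2] + M[2, 1]) / S
            z = 0.25 * S
        q = np.array([w, x, y, z])
        out[idx] = q / np.linalg.norm(q)
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class BrokenBondError(RuntimeError):
    """A FENE bond reached or exceeded its maximal extension R0."""

    def __init__(self, ring: int, bond: int, length: float):
        self.ring, self.bond, self.length = ring, bond, length
        super().__init__(
            f"bond {bond} of ring {ring} has length {length:.4f} >= R0"
        )


@dataclass
class RingConformation:
    """One closed chain: bead positions plus per-bead orientation triads."""

    positions: np.ndarray  # (N, 3) unwrapped coordinates
    quat: np.ndarray  # (N, 4) unit quaternions (w, x, y, z)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.quat = np.ascontiguousarray(self.quat, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.quat.shape != (self.N, 4):
            raise ValueError("quat must be (N, 4)")

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    @property
    def closed(self) -> bool:
        return True

    @property
    def frames(self) -> np.ndarray:
        """(N, 3, 3) rotation matrices with columns [u, f, v]."""
        return quat_to_frames(self.quat)

    @property
    def u(self) -> np.ndarray:
        return self.frames[:, :, 0]

    @property
    def f(self) -> np.ndarray:
        return self.frames[:, :, 1]

    @property
    def v(self) -> np.ndarray:
        return self.frames[:, :, 2]

    @classmethod
    def from_frames(cls, positions: np.ndarray, frames: np.ndarray) -> "RingConformation":
        return cls(positions, frames_to_quat(frames))

    def bonds(self) -> np.ndarray:
        """Bond vectors t_i = r_{i+1} - r_i, cyclic, shape (N, 3)."""
        return np.roll(self.positions, -1, axis=0) - self.positions

    def validate(self, R0: float = 1.6, tol: float = 1e-8) -> None:
        F = self.frames
        eye = np.einsum("nij,nkj->nik", F, F)
        if not np.allclose(eye, np.eye(3), atol=10 * tol):
            raise ValueError("frames are not orthonormal")
        det = np.linalg.det(F)
        if not np.all(det > 0):
            raise ValueError("frames are not right-handed")
        blen = np.linalg.norm(self.bonds(), axis=1)
        if np.any(blen >= R0):
            raise BrokenBondError(0, int(np.argmax(blen)), float(blen.max()))

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class MotorSite:
    """A gyrase-like torque agent acting on one bond of one ring.

    The two bond dihedral potentials are removed at ``bond_index`` and equal
    and opposite torques of magnitude ``torque`` (k_B T units) about the bond
    axis are applied to the two bond monomers.  ``accumulated_angle`` tracks
    the signed relative frame rotation (psi_a) across the motor bond; the
    supercoiling density follows as sigma = psi_a / (2 pi N).
    """

    ring_id: int
    bond_index: int
    torque: float
    lever_arm: float = 0.80
    accumulated_angle: float = 0.0

    def sigma(self, N: int) -> float:
        return self.accumulated_angle / (2.0 * math.pi * N)


@dataclass
class SystemState:
    """M rings in a periodic cubic box."""

    rings: list
    box_length: float
    time: float = 0.0
    motors: list = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.rings)

    @property
    def N(self) -> int:
        return self.rings[0].N

    @property
    def density(self) -> float:
        return self.M * self.N / self.box_length**3

    def positions_array(self) -> np.ndarray:
        return np.stack([r.positions for r in self.rings])

    def quat_array(self) -> np.ndarray:
        return np.stack([r.quat for r in self.rings])

    def motor_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-ring motor bond index (-1 if absent) and torque."""
        bond = np.full(self.M, -1, dtype=np.int64)
        tq = np.zeros(self.M)
        for mot in self.motors:
            bond[mot.ring_id] = mot.bond_index
            tq[mot.ring_id] = mot.torque
        return bond, tq

    def copy(self) -> "SystemState":
        return SystemState(
            rings=[RingConformation(r.positions.copy(), r.quat.copy()) for r in self.rings],
            box_length=self.box_length,
            time=self.time,
            motors=[MotorSite(m.ring_id, m.bond_index, m.torque, m.lever_arm, m.accumulated_angle) for m in self.motors],
        )


# ---------------------------------------------------------------------------
# individual potential terms (reference implementations, numpy scalar math)
# ---------------------------------------------------------------------------

_WCA_CUT = 2.0 ** (1.0 / 6.0)


def pair_energy_wca(r, params: ModelParams | None = None):
    """Weeks-Chandler-Andersen repulsion; zero beyond 2^(1/6) s."""
    p = params or ModelParams()
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("overlapping beads: r must be positive")
    sr6 = (p.s / r) ** 6
    e = 4.0 * p.epsilon * (sr6 * sr6 - sr6 + 0.25)
    return np.where(r < _WCA_CUT * p.s, e, 0.0)[()]


def pair_force_wca(r, params: ModelParams | None = None):
    """Radial force magnitude -dU/dr of the WCA potential."""
    p = params or ModelParams()
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("overlapping beads: r must be positive")
    sr6 = (p.s / r) ** 6
    f = 24.0 * p.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return np.where(r < _WCA_CUT * p.s, f, 0.0)[()]


def bond_energy_fene(r, params: ModelParams | None = None):
    """FENE bond energy; diverges (raises) at r >= R0."""
    p = params or ModelParams()
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= p.R0):
        raise BrokenBondError(0, 0, float(np.max(r)))
    return (-0.5 * p.K_fene * p.R0**2 * np.log1p(-((r / p.R0) ** 2)))[()]


def angle_energy_bend(t1: Sequence[float], t2: Sequence[float], params: ModelParams | None = None) -> float:
    """Kratky-Porod energy K_bend (1 - cos theta) between consecutive bonds."""
    p = params or ModelParams()
    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    n1, n2 = np.linalg.norm(t1), np.linalg.norm(t2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length bond in bending term")
    return p.K_bend * (1.0 - float(t1 @ t2) / (n1 * n2))


def tilt_energy(u: Sequence[float], t: Sequence[float], params: ModelParams | None = None) -> float:
    """Tilt energy K_tilt (1 - u . t_hat) aligning u with the bond."""
    p = params or ModelParams()
    u = np.asarray(u, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    nt = np.linalg.norm(t)
    if nt == 0:
        raise ValueError("zero-length bond in tilt term")
    return p.K_tilt * (1.0 - float(u @ t) / nt)


def _dihedral_term(t, w1, w2, K):
    a = np.cross(t, w1)
    b = np.cross(t, w2)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("bond parallel to a frame vector: degenerate dihedral")
    return K * (1.0 - float(a @ b) / (na * nb))


def _rotate_about(vec, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s_ = math.cos(angle), math.sin(angle)
    return vec * c + np.cross(axis, vec) * s_ + axis * float(axis @ vec) * (1 - c)


def torsion_energy(t, f1, f2, v1, v2, psi0: float = 0.0, params: ModelParams | None = None) -> float:
    """Sum of the two bond dihedral terms on one pair of consecutive beads.

    For a preferred pitch angle ``psi0`` the second bead's ribbon vectors are
    pre-rotated by ``-psi0`` about its own long axis before evaluation, so the
    minimum sits at a relative frame rotation of ``psi0``; at ``psi0 = 0``
    this is exactly the bare dihedral pair.
    """
    p = params or ModelParams()
    t = np.asarray(t, dtype=np.float64)
    f1, f2 = np.asarray(f1, dtype=np.float64), np.asarray(f2, dtype=np.float64)
    v1, v2 = np.asarray(v1, dtype=np.float64), np.asarray(v2, dtype=np.float64)
    if psi0 != 0.0:
        u2 = np.cross(f2, v2)  # u = f x v for a right-handed [u, f, v] triad
        f2 = _rotate_about(f2, u2, -psi0)
        v2 = _rotate_about(v2, u2, -psi0)
    return _dihedral_term(t, f1, f2, p.K_torsion) + _dihedral_term(t, v1, v2, p.K_torsion)


# ---------------------------------------------------------------------------
# aggregate energy / gradients through the compiled kernel
# ---------------------------------------------------------------------------


def total_energy_and_gradients(state: SystemState, params: ModelParams | None = None):
    """Total energy, per-bead forces and frame torques for a system state.

    Forces are ``-grad_r U`` (WCA with the minimum-image convention across
    the periodic box); torques are rotational generalized forces, i.e. minus
    the derivative of the energy with respect to an infinitesimal body
    rotation of each bead's triad.  Motor bonds are excluded from the
    dihedral terms but the external motor torques themselves are *not*
    included here (they are applied by the integrator).

    Returns ``(energy, forces (M,N,3), torques (M,N,3))``.
    """
    from . import _kernels

    p = params or ModelParams()
    pos = state.positions_array()
    quat = state.quat_array()
    bond, _tq = state.motor_arrays()
    energy, forces, torques, broken = _kernels.compute_forces(
        pos, quat, float(state.box_length), p.to_kernel_array(), bond
    )
    if broken[0] >= 0:
        raise BrokenBondError(int(broken[0]), int(broken[1]), float(broken[2]))
    return energy, forces, torques
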