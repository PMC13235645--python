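"""Langevin dynamics driver, active-torque motors and system preparation.

Propagation uses a BAOAB-type splitting for both translational and
rotational degrees of freedom: positions/velocities follow the underdamped
Langevin equation m r'' = F - m gamma r' + Y with <Y Y> = 2 gamma m k_B T,
and each bead's orientation quaternion is advanced by its angular velocity
with matching rotational friction and noise (scalar inertia).  The active
supercoiling agent is a fixed torque +-TQ about one bond of each ring, with
the dihedral potentials removed on that bond; the accumulated relative
frame angle psi_a at the motor bond measures the injected supercoiling
sigma = psi_a / (2 pi N).

Preparation follows the compression protocol: flat rings on a cubic
lattice, iterated thermalize + rescale-by-(L0-s)/L0 cycles down to the
target density, then equilibration, with pairwise linking numbers verified
to remain zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import (
    BrokenBondError,
    ModelParams,
    MotorSite,
    SystemState,
)

__all__ = [
    "IntegratorConfig",
    "PreparationProtocol",
    "Phase",
    "Trajectory",
    "simulate",
    "langevin_step",
    "apply_motor",
    "attach_motors",
    "prepare_initial_state",
    "run_protocol",
    "kp_mean_cos_theta",
    "persistence_length",
]


@dataclass
class IntegratorConfig:
    dt: float = 0.001
    gamma: float = 1.0
    temperature: float = 1.0
    seed: int = 0
    rot_inertia: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class Trajectory:
    """Snapshots of a run: unwrapped positions, quaternions, motor angles."""

    times: np.ndarray  # (T,)
    box_length: float
    positions: np.ndarray  # (T, M, N, 3) unwrapped
    quats: np.ndarray  # (T, M, N, 4)
    psi_a: np.ndarray  # (T, M) accumulated motor angles
    energies: np.ndarray  # (T,)
    motor_torque: float = 0.0
    seed: int = 0

    @property
    def n_snapshots(self) -> int:
        return self.times.shape[0]

    @property
    def M(self) -> int:
        return self.positions.shape[1]

    @property
    def N(self) -> int:
        return self.positions.shape[2]

    def com(self) -> np.ndarray:
        """Ring centers of mass, (T, M, 3), from unwrapped coordinates."""
        return self.positions.mean(axis=2)

    def sigma(self) -> np.ndarray:
        """Supercoiling density series sigma = psi_a / (2 pi N), (T, M)."""
        return self.psi_a / (2 * np.pi * self.N)

    def ring(self, t: int, m: int):
        from .model import RingConformation

        return RingConformation(self.positions[t, m].copy(), self.quats[t, m].copy())

    def rings_at(self, t: int):
        return [self.ring(t, m) for m in range(self.M)]

    @staticmethod
    def concatenate(parts: list) -> "Trajectory":
        return Trajectory(
            times=np.concatenate([p.times for p in parts]),
            box_length=parts[-1].box_length,
            positions=np.concatenate([p.positions for p in parts]),
            quats=np.concatenate([p.quats for p in parts]),
            psi_a=np.concatenate([p.psi_a for p in parts]),
            energies=np.concatenate([p.energies for p in parts]),
            motor_torque=parts[-1].motor_torque,
            seed=parts[0].seed,
        )


def _ensure_velocities(state: SystemState) -> tuple[np.ndarray, np.ndarray]:
    vel = getattr(state, "_vel", None)
    omg = getattr(state, "_omg", None)
    if vel is None or vel.shape != (state.M, state.N, 3):
        vel = np.zeros((state.M, state.N, 3))
        omg = np.zeros((state.M, state.N, 3))
    return vel, omg


def simulate(
    state: SystemState,
    n_steps: int,
    params: ModelParams | None = None,
    config: IntegratorConfig | None = None,
    snapshot_every: int = 0,
) -> Trajectory:
    """Advance ``state`` in place by ``n_steps`` and collect snapshots.

    ``snapshot_every`` is in steps (0: only the final state is stored).
    Raises BrokenBondError if any FENE bond reaches R0.
    """
    p = params or ModelParams()
    c = config or IntegratorConfig(dt=p.dt, gamma=p.gamma)
    M, N = state.M, state.N
    pos = state.positions_array()
    quat = state.quat_array()
    vel, omg = _ensure_velocities(state)
    motor_bond, motor_tq = state.motor_arrays()
    psi_acc = np.zeros(M)
    for mot in state.motors:
        psi_acc[mot.ring_id] = mot.accumulated_angle

    every = snapshot_every if snapshot_every > 0 else max(n_steps, 1)
    n_snap = n_steps // every if n_steps > 0 else 0
    snap_pos = np.empty((n_snap, M, N, 3))
    snap_quat = np.empty((n_snap, M, N, 4))
    snap_psi = np.empty((n_snap, M))
    snap_energy = np.empty(n_snap)

    broken, written = _kernels.run_langevin(
        pos,
        quat,
        vel,
        omg,
        float(state.box_length),
        p.to_kernel_array(),
        motor_bond,
        motor_tq,
        n_steps,
        c.dt,
        c.gamma,
        c.temperature,
        p.m,
        c.rot_inertia,
        int(c.seed) % 2**31,
        every,
        psi_acc,
        snap_pos,
        snap_quat,
        snap_psi,
        snap_energy,
    )
    if broken[0] >= 0:
        raise BrokenBondError(int(broken[0]), int(broken[1]), float(broken[2]))

    # push evolved arrays back into the state
    for m in range(M):
        state.rings[m].positions[:] = pos[m]
        state.rings[m].quat[:] = quat[m]
    state._vel = vel
    state._omg = omg
    for mot in state.motors:
        mot.accumulated_angle = float(psi_acc[mot.ring_id])
    t0 = state.time
    state.time = t0 + n_steps * c.dt

    times = t0 + np.arange(1, written + 1) * every * c.dt
    traj = Trajectory(
        times=times,
        box_length=state.box_length,
        positions=snap_pos[:written],
        quats=snap_quat[:written],
        psi_a=snap_psi[:written],
        energies=snap_energy[:written],
        motor_torque=float(motor_tq.max()) if M else 0.0,
        seed=c.seed,
    )
    return traj


def langevin_step(state: SystemState, params: ModelParams | None = None,
                  config: IntegratorConfig | None = None, n_steps: int = 1) -> SystemState:
    """Advance the state by ``n_steps`` Langevin steps (in place)."""
    simulate(state, n_steps, params, config, snapshot_every=0)
    return state


def apply_motor(state: SystemState, motor: MotorSite) -> np.ndarray:
    """Torque increments (M, N, 3) exerted by one motor on the current state.

    Equal and opposite torques +-TQ about the motor bond axis on the two
    bond monomers; equivalently force couples of magnitude TQ / (0.80 s)
    at lever distance 0.80 s from each bead center.  The accumulated angle
    psi_a is advanced by the integrator as the system evolves.
    """
    M, N = state.M, state.N
    torques = np.zeros((M, N, 3))
    bond = np.full(M, -1, dtype=np.int64)
    tq = np.zeros(M)
    bond[motor.ring_id] = motor.bond_index
    tq[motor.ring_id] = motor.torque
    _kernels._add_motor_torques(state.positions_array(), torques, bond, tq)
    return torques


def attach_motors(state: SystemState, torque: float, seed: int = 0) -> None:
    """One motor per ring at a random bond (dihedrals removed there)."""
    rng = np.random.default_rng(seed)
    state.motors = [
        MotorSite(ring_id=m, bond_index=int(rng.integers(state.N)), torque=torque)
        for m in range(state.M)
    ]


# ---------------------------------------------------------------------------
# preparation protocol
# ---------------------------------------------------------------------------


@dataclass
class PreparationProtocol:
    """Compress a dilute lattice of flat rings to the target density by
    iterating thermalize + rescale-by-(L0 - s)/L0 cycles."""

    target_density: float = 0.08
    thermalize_steps: int = 500
    final_equilibration_tau: float = 20.0
    max_cycles: int = 10000


def prepare_initial_state(
    M: int,
    N: int,
    protocol: PreparationProtocol | None = None,
    params: ModelParams | None = None,
    seed: int = 0,
    verify_topology: bool = True,
) -> tuple[SystemState, dict]:
    """Equilibrated solution of flat (sigma = 0) rings at the target density.

    Returns (state, info); info carries the box/R_g histories and the
    pairwise linking-number check.
    """
    from .fixtures import make_initial_lattice
    from .observables import gyration_and_shape
    from .topology import linking_number

    proto = protocol or PreparationProtocol()
    p = params or ModelParams()
    state = make_initial_lattice(M, N)
    L_target = (M * N / proto.target_density) ** (1.0 / 3.0)
    if state.box_length < L_target:
        state.box_length = L_target  # lattice already denser than target
    cfg = IntegratorConfig(dt=p.dt, gamma=p.gamma, seed=seed)

    box_hist = [state.box_length]
    rg_hist = []
    cycles = 0
    while state.box_length > L_target * (1 + 1e-12):
        cfg.seed = seed + 13 * cycles + 1
        simulate(state, proto.thermalize_steps, p, cfg)
        L0 = state.box_length
        Lnew = max(L0 * (L0 - p.s) / L0, L_target)
        scale = Lnew / L0
        for r in state.rings:
            r.positions *= scale
        state.box_length = Lnew
        box_hist.append(Lnew)
        rg_hist.append(np.mean([gyration_and_shape(r)["R_g"] for r in state.rings]))
        cycles += 1
        if cycles > proto.max_cycles:
            raise RuntimeError("compression failed to reach target density")

    eq_steps = int(round(proto.final_equilibration_tau / p.dt))
    if eq_steps > 0:
        cfg.seed = seed + 999331
        simulate(state, eq_steps, p, cfg)
    rg_hist.append(np.mean([gyration_and_shape(r)["R_g"] for r in state.rings]))

    info = {
        "cycles": cycles,
        "box_history": np.asarray(box_hist),
        "rg_history": np.asarray(rg_hist),
        "density": state.density,
    }
    if verify_topology:
        max_lk = 0.0
        for i in range(M):
            ci = state.rings[i].positions
            for j in range(i + 1, M):
                cj = state.rings[j].positions
                # nearest periodic image of ring j relative to ring i
                dc = cj.mean(0) - ci.mean(0)
                shift = state.box_length * np.rint(dc / state.box_length)
                lk = abs(linking_number(ci, cj - shift))
                max_lk = max(max_lk, lk)
        info["max_pairwise_Lk"] = max_lk
        if max_lk > 0.1:
            raise RuntimeError(f"preparation produced linked rings (|Lk| = {max_lk:.2f})")
    return state, info


# ---------------------------------------------------------------------------
# run schedules
# ---------------------------------------------------------------------------


@dataclass
class Phase:
    name: str  # "equilibrium" | "active"
    duration_tau: float
    torque: float = 0.0
    snapshot_every_tau: float = 1.0


def run_protocol(
    state: SystemState,
    schedule: list,
    params: ModelParams | None = None,
    seed: int = 0,
    motor_seed: int | None = None,
    retries: int = 0,
) -> Trajectory:
    """Run a sequence of phases; active phases attach one motor per ring.

    A zero-duration schedule yields a trajectory holding only the initial
    snapshot.  Returns the concatenated trajectory (initial snapshot first).
    With ``retries > 0`` a run aborted by a broken FENE bond (a rare
    fixed-timestep hazard under strong driving) is restarted from the
    initial state with a fresh noise seed.
    """
    if retries > 0:
        initial = state.copy()
        last: BrokenBondError | None = None
        for attempt in range(retries + 1):
            work = initial.copy() if attempt else state
            try:
                traj = run_protocol(
                    work, schedule, params, seed + 77 * attempt, motor_seed, retries=0
                )
            except BrokenBondError as err:
                last = err
                continue
            if attempt:  # propagate the successful attempt into the caller's state
                state.rings = work.rings
                state.motors = work.motors
                state.time = work.time
                state._vel = getattr(work, "_vel", None)
                state._omg = getattr(work, "_omg", None)
            return traj
        raise last
    p = params or ModelParams()
    M, N = state.M, state.N
    psi0 = np.zeros(M)
    for mot in state.motors:
        psi0[mot.ring_id] = mot.accumulated_angle
    initial = Trajectory(
        times=np.array([state.time]),
        box_length=state.box_length,
        positions=state.positions_array()[None],
        quats=state.quat_array()[None],
        psi_a=psi0[None],
        energies=np.array([np.nan]),
        motor_torque=0.0,
        seed=seed,
    )
    parts = [initial]
    for k, phase in enumerate(schedule):
        steps = int(round(phase.duration_tau / p.dt))
        if steps <= 0:
            continue
        if phase.name == "active":
            if not state.motors or state.motors[0].torque != phase.torque:
                attach_motors(
                    state, phase.torque, seed if motor_seed is None else motor_seed
                )
        else:
            state.motors = []
        every = max(1, int(round(phase.snapshot_every_tau / p.dt)))
        cfg = IntegratorConfig(dt=p.dt, gamma=p.gamma, seed=seed + 7919 * (k + 1))
        parts.append(simulate(state, steps, p, cfg, snapshot_every=every))
    return Trajectory.concatenate(parts)


# ---------------------------------------------------------------------------
# persistence length
# ---------------------------------------------------------------------------


def kp_mean_cos_theta(beta_K: float) -> float:
    """<cos theta> of the Kratky-Porod bond angle at stiffness beta K:
    coth(beta K) - 1/(beta K)."""
    return 1.0 / math.tanh(beta_K) - 1.0 / beta_K


def persistence_length(mean_cos: float, bond_length: float = 1.0) -> float:
    """l_p = -b / ln <cos theta> for a discrete worm-like chain."""
    return -bond_length / math.log(mean_cos)
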