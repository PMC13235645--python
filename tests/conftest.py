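import numpy as np
import pytest
from hypothesis import settings

import supercoil as sc
from supercoil.model import frames_to_quat

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def random_ring(N: int = 10, noise: float = 0.12, seed: int = 0) -> sc.RingConformation:
    """Perturbed circle with slightly randomized frames — a generic, valid
    ring conformation for gradient and invariance checks."""
    rng = np.random.default_rng(seed)
    th = np.linspace(0, 2 * np.pi, N, endpoint=False)
    R = N * 0.97 / (2 * np.pi)
    pos = np.c_[R * np.cos(th), R * np.sin(th), np.zeros(N)]
    pos = pos + noise * rng.standard_normal((N, 3))
    t = np.roll(pos, -1, axis=0) - pos
    frames = np.zeros((N, 3, 3))
    for i in range(N):
        u = t[i] / np.linalg.norm(t[i])
        a = np.array([0.0, 0.0, 1.0])
        if abs(u @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        f = np.cross(a, u)
        f /= np.linalg.norm(f)
        frames[i] = np.c_[u, f, np.cross(u, f)]
    q = frames_to_quat(frames)
    # small random body rotations keep frames orthonormal but generic
    for i in range(N):
        ax = rng.standard_normal(3)
        ax /= np.linalg.norm(ax)
        ang = 0.15 * rng.standard_normal()
        w = np.cos(ang / 2)
        x, y, z = np.sin(ang / 2) * ax
        qw, qx, qy, qz = q[i]
        q[i] = [
            w * qw - x * qx - y * qy - z * qz,
            w * qx + x * qw + y * qz - z * qy,
            w * qy - x * qz + y * qw + z * qx,
            w * qz + x * qy - y * qx + z * qw,
        ]
    return sc.RingConformation(pos, q)


@pytest.fixture(scope="session")
def dense_state():
    """Small equilibrated solution at the study density rho s^3 = 0.08.

    Session-scoped: preparation (lattice, compression, equilibration) is
    shared by the topology-conservation, threading and activity tests.
    """
    proto = sc.PreparationProtocol(
        target_density=0.08, thermalize_steps=250, final_equilibration_tau=10.0
    )
    state, info = sc.prepare_initial_state(8, 48, proto, seed=42)
    return state, info


@pytest.fixture(scope="session")
def overlap_state():
    """Melt-like solution (rho s^3 = 0.2) of flat rings.

    Small stiff rings have a much higher overlap concentration than the
    long rings of the full-scale study, so the above-overlap regime with a
    percolating threading network is reached here by raising the monomer
    density instead of the chain length.
    """
    proto = sc.PreparationProtocol(
        target_density=0.2, thermalize_steps=250, final_equilibration_tau=40.0
    )
    state, info = sc.prepare_initial_state(8, 48, proto, seed=42)
    return state, info
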