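"""Deterministic synthetic configurations with known topological ground
truth.

These generators stand in for raw MD trajectories wherever an analysis
operation needs an input whose linking number, writhe, branch count,
piercing pattern or diffusivity is known by construction, and they provide
the initial ring lattice for the preparation protocol.  Geometry parameters
default to a bead spacing near the FENE equilibrium bond length (~0.97 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import RingConformation, SystemState, frames_to_quat

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "planar_circle",
    "twisted_circle",
    "hopf_pair",
    "helical_ribbon",
    "plectoneme",
    "threaded_pair",
    "brownian_walk",
    "mc_network",
    "make_initial_lattice",
]

BOND = 0.97  # target bead spacing, in units of s


@dataclass
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _tangent_frames(pos: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
    """Right-handed frames with u along the bond and f built from a
    reference direction (untwisted framing where the reference permits)."""
    n = pos.shape[0]
    t = np.roll(pos, -1, axis=0) - pos
    t /= np.linalg.norm(t, axis=1)[:, None]
    frames = np.empty((n, 3, 3))
    a = np.array([0.0, 0.0, 1.0]) if ref is None else np.asarray(ref, dtype=np.float64)
    for i in range(n):
        u = t[i]
        f = a - np.dot(a, u) * u
        nf = np.linalg.norm(f)
        if nf < 1e-9:
            # reference parallel to the bond: fall back to the least-aligned axis
            alt = np.zeros(3)
            alt[int(np.argmin(np.abs(u)))] = 1.0
            f = alt - np.dot(alt, u) * u
            nf = np.linalg.norm(f)
        f = f / nf
        v = np.cross(u, f)
        frames[i] = np.c_[u, f, v]
    return frames


def _transport_frames(pos: np.ndarray, extra_turns: int = 0) -> np.ndarray:
    """Closed framing by parallel transport with the closure mismatch (plus
    ``extra_turns`` full turns) distributed uniformly; by construction the
    resulting ribbon has integer linking number Wr + Tw."""
    n = pos.shape[0]
    t = np.roll(pos, -1, axis=0) - pos
    t /= np.linalg.norm(t, axis=1)[:, None]
    f = np.empty((n, 3))
    a = np.array([0.0, 0.0, 1.0])
    f0 = a - np.dot(a, t[0]) * t[0]
    if np.linalg.norm(f0) < 1e-9:
        a = np.array([1.0, 0.0, 0.0])
        f0 = a - np.dot(a, t[0]) * t[0]
    f[0] = f0 / np.linalg.norm(f0)
    for i in range(1, n):
        axis = np.cross(t[i - 1], t[i])
        na = np.linalg.norm(axis)
        fi = f[i - 1]
        if na > 1e-12:
            axis = axis / na
            ang = math.atan2(na, float(np.dot(t[i - 1], t[i])))
            fi = (
                fi * math.cos(ang)
                + np.cross(axis, fi) * math.sin(ang)
                + axis * np.dot(axis, fi) * (1 - math.cos(ang))
            )
        fi = fi - np.dot(fi, t[i]) * t[i]
        f[i] = fi / np.linalg.norm(fi)
    # closure mismatch: transport f[n-1] across the last vertex back to f[0]
    axis = np.cross(t[n - 1], t[0])
    na = np.linalg.norm(axis)
    fi = f[n - 1]
    if na > 1e-12:
        axis = axis / na
        ang = math.atan2(na, float(np.dot(t[n - 1], t[0])))
        fi = (
            fi * math.cos(ang)
            + np.cross(axis, fi) * math.sin(ang)
            + axis * np.dot(axis, fi) * (1 - math.cos(ang))
        )
    fi = fi - np.dot(fi, t[0]) * t[0]
    fi /= np.linalg.norm(fi)
    mismatch = math.atan2(float(np.dot(np.cross(fi, f[0]), t[0])), float(np.dot(fi, f[0])))
    total = mismatch + 2 * math.pi * extra_turns
    frames = np.empty((n, 3, 3))
    for i in range(n):
        ang = total * i / n
        u = t[i]
        fr = f[i] * math.cos(ang) + np.cross(u, f[i]) * math.sin(ang)
        frames[i] = np.c_[u, fr, np.cross(u, fr)]
    return frames


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def planar_circle(N: int, radius: float | None = None, center=(0, 0, 0), normal="z") -> RingConformation:
    """Flat circle with untwisted (Tw = 0) frames: Lk = Tw = Wr = 0."""
    R = radius if radius is not None else N * BOND / (2 * math.pi)
    th = np.linspace(0, 2 * math.pi, N, endpoint=False)
    if normal == "z":
        pos = np.c_[R * np.cos(th), R * np.sin(th), np.zeros(N)]
        ref = np.array([0.0, 0.0, 1.0])
    elif normal == "y":
        pos = np.c_[R * np.cos(th), np.zeros(N), R * np.sin(th)]
        ref = np.array([0.0, -1.0, 0.0])
    else:
        pos = np.c_[np.zeros(N), R * np.cos(th), R * np.sin(th)]
        ref = np.array([1.0, 0.0, 0.0])
    pos = pos + np.asarray(center, dtype=np.float64)
    # framing against the plane normal keeps f constant: a flat, untwisted
    # ribbon (Tw = 0) regardless of orientation
    return RingConformation.from_frames(pos, _tangent_frames(pos, ref=ref))


def twisted_circle(N: int, k: int, radius: float | None = None) -> RingConformation:
    """Planar circle whose frames wind k full turns: Tw = k, Wr = 0, Lk = k."""
    base = planar_circle(N, radius)
    return RingConformation.from_frames(base.positions, _transport_frames(base.positions, extra_turns=k))


def hopf_pair(N: int, radius: float = 5.0, sign: int = +1):
    """Two orthogonal circles through each other's centers: Lk = +-1."""
    c1 = planar_circle(N, radius, center=(0, 0, 0), normal="z")
    c2 = planar_circle(N, radius, center=(radius, 0, 0), normal="y")
    if sign < 0:
        c2 = RingConformation(c2.positions[::-1].copy(), c2.quat[::-1].copy())
    return c1, c2, {"Lk_abs": 1}


def helical_ribbon(N: int, coils: int = 3, twist_turns: int = 2,
                   R_major: float | None = None, r_minor: float | None = None) -> RingConformation:
    """Closed curve coiled around a torus, framed with extra twist.

    Has substantial writhe (from the coiling) and twist; the closed
    parallel-transport construction guarantees integer Lk = Tw + Wr.
    """
    A = R_major if R_major is not None else N * BOND / (2 * math.pi) * 0.7
    a = r_minor if r_minor is not None else 0.35 * A
    th = np.linspace(0, 2 * math.pi, N, endpoint=False)
    pos = np.c_[
        (A + a * np.cos(coils * th)) * np.cos(th),
        (A + a * np.cos(coils * th)) * np.sin(th),
        a * np.sin(coils * th),
    ]
    return RingConformation.from_frames(pos, _transport_frames(pos, extra_turns=twist_turns))


def plectoneme(N: int, arms: int = 2, pitch_beads: float = 12.0, arm_radius: float = 1.0):
    """Closed interwound (plectonemic) ring with ``arms`` superhelical arms.

    Each arm is a pair of strands wound around a straight axis radiating
    from a central hub, closed by a hairpin cap at the arm tip.  Ground
    truth: the branch tips are the cap apices (indices returned).
    """
    if arms < 2:
        raise ValueError("need at least two arms for a closed plectoneme")
    per_arm = N // arms
    half = per_arm // 2  # beads per strand of one arm (out or back)
    pts = []
    tip_indices = []
    rot = 2 * math.pi / arms
    for a_i in range(arms):
        phi_arm = a_i * rot
        ca, sa = math.cos(phi_arm), math.sin(phi_arm)
        # outgoing strand: superhelix about the arm axis (handedness chosen
        # so the interwound pair carries positive local writhe)
        for k in range(half):
            x = 2.0 + k * BOND * 0.9
            hph = -2 * math.pi * k / pitch_beads
            p = np.array([x, arm_radius * math.cos(hph), arm_radius * math.sin(hph)])
            pts.append([ca * p[0] - sa * p[1], sa * p[0] + ca * p[1], p[2]])
            if k == half - 1:
                tip_indices.append(len(pts))  # apex comes right after
        # hairpin cap apex
        xtip = 2.0 + half * BOND * 0.9
        pts.append([ca * xtip, sa * xtip, 0.0])
        # returning strand, anti-phase so the two strands interwind
        for k in range(half - 1, -1, -1):
            x = 2.0 + k * BOND * 0.9
            hph = -2 * math.pi * k / pitch_beads + math.pi
            p = np.array([x, arm_radius * math.cos(hph), arm_radius * math.sin(hph)])
            pts.append([ca * p[0] - sa * p[1], sa * p[0] + ca * p[1], p[2]])
    pos = np.asarray(pts, dtype=np.float64)
    ring = RingConformation.from_frames(pos, _tangent_frames(pos, ref=np.array([0.0, 0.0, 1.0])))
    return ring, {"n_br": arms, "tip_indices": tip_indices}


def threaded_pair(N_threaded: int = 60, segments=(100, 300), R: float = 10.0, inner_radius: float = 5.0):
    """A planar ring plus a threader crossing its disk with a prescribed
    segment decomposition.

    The threader's beads alternate between z = +-h in blocks given by
    ``segments`` (crossings inside the disk), so the piercing analysis must
    recover exactly ``p = len(segments)`` piercings, the segment lengths and
    L_sep = min(alternating sums).
    """
    segs = list(segments)
    if len(segs) % 2 != 0:
        raise ValueError("segment count p must be even for nonconcatenated rings")
    ring = planar_circle(N_threaded, R)
    Nt = sum(segs)
    h = 2.0
    phi = 2 * math.pi * np.arange(Nt) / Nt
    z = np.empty(Nt)
    side = +1.0
    j = 0
    for L in segs:
        z[j : j + L] = side * h
        side = -side
        j += L
    thr_pos = np.c_[inner_radius * np.cos(phi), inner_radius * np.sin(phi), z]
    threader = RingConformation.from_frames(thr_pos, _tangent_frames(thr_pos, ref=np.array([1.0, 0.0, 0.0])))
    lsep = min(sum(segs[0::2]), sum(segs[1::2]))
    return ring, threader, {"p": len(segs), "segments": segs, "L_sep": lsep}


def brownian_walk(T: int, M: int, D: float = 1.0, dt: float = 1.0, seed: int = 0):
    """Free Brownian center-of-mass trajectories: (times, com (T, M, 3))."""
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((T - 1, M, 3)) * math.sqrt(2 * D * dt)
    com = np.concatenate([np.zeros((1, M, 3)), np.cumsum(steps, axis=0)])
    times = np.arange(T) * dt
    return times, com, {"D": D}


@dataclass
class _FakeRecord:
    threader_id: int
    threaded_id: int
    segment_lengths: list
    L_sep: int
    parity_ok: bool = True


def mc_network(kind: str, M: int = 2, N: int = 400, L_sep: int = 100):
    """Threading-record sets with known relaxation behaviour for the 1D MC.

    kinds: 'empty', 'single' (one active threading), 'chain' (0 threads 1
    threads 2 ...), 'deadlock' (mutual threading pair whose passive ends
    block cyclically — never relaxes under end-blocking placement).
    """
    if kind == "empty":
        return [], {"deadlocked": False}
    if kind == "single":
        return (
            [_FakeRecord(0, 1, [L_sep, N - L_sep], min(L_sep, N - L_sep))],
            {"deadlocked": False},
        )
    if kind == "chain":
        recs = [
            _FakeRecord(i, i + 1, [L_sep, N - L_sep], min(L_sep, N - L_sep))
            for i in range(M - 1)
        ]
        return recs, {"deadlocked": False}
    if kind == "deadlock":
        # each chain pierced by the other at both of its ends: every move of
        # either chain is rejected, so all four threadings are frozen
        recs = [
            _FakeRecord(0, 1, [N // 2, N // 2], N // 2),
            _FakeRecord(0, 1, [N // 2, N // 2], N // 2),
            _FakeRecord(1, 0, [N // 2, N // 2], N // 2),
            _FakeRecord(1, 0, [N // 2, N // 2], N // 2),
        ]
        return recs, {"deadlocked": True}
    raise ValueError(f"unknown network kind {kind!r}")


# ---------------------------------------------------------------------------
# dispatcher and initial lattice
# ---------------------------------------------------------------------------


def make_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; returns (objects, ground_truth dict)."""
    k, p = spec.kind, dict(spec.params)
    if k == "planar_circle":
        ring = planar_circle(**p)
        return ring, {"Lk": 0, "Tw": 0, "Wr": 0.0}
    if k == "twisted_circle":
        kk = p.pop("k", 1)
        ring = twisted_circle(p.pop("N", 100), kk, **p)
        return ring, {"Lk": kk, "Tw": kk, "Wr": 0.0}
    if k == "hopf_pair":
        r1, r2, gt = hopf_pair(**p)
        return (r1, r2), gt
    if k == "helical_ribbon":
        ring = helical_ribbon(**p)
        return ring, {"Lk_integer": True}
    if k == "plectoneme":
        return plectoneme(**p)
    if k == "threaded_pair":
        return threaded_pair(**p)
    if k == "brownian_walk":
        times, com, gt = brownian_walk(seed=spec.seed, **p)
        return (times, com), gt
    if k == "mc_network":
        return mc_network(**p)
    raise ValueError(f"unknown fixture kind {k!r}")


def make_initial_lattice(M: int, N: int, radius: float | None = None,
                         box: float | None = None) -> SystemState:
    """Flat circles on a primitive cubic lattice: unknotted, pairwise
    unlinked (disjoint bounding spheres), untwisted frames (Tw = 0)."""
    R = radius if radius is not None else N * BOND / (2 * math.pi)
    ncell = math.ceil(M ** (1 / 3))
    spacing = 2 * R + 2.0
    L = box if box is not None else ncell * spacing
    if L < ncell * spacing - 1e-9:
        raise ValueError("box too small to place rings without overlap")
    rings = []
    idx = 0
    for ix in range(ncell):
        for iy in range(ncell):
            for iz in range(ncell):
                if idx >= M:
                    break
                center = (np.array([ix, iy, iz]) + 0.5) * spacing
                normal = ("z", "y", "x")[idx % 3]
                rings.append(planar_circle(N, R, center=center, normal=normal))
                idx += 1
    if idx < M:
        raise ValueError("could not place all rings on the lattice")
    return SystemState(rings=rings, box_length=float(L), time=0.0, motors=[])
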