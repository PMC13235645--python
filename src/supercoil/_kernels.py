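"""Compiled numerical kernels: force field evaluation and Langevin driver.

Everything here operates on packed arrays — positions ``(M, N, 3)`` and unit
quaternions ``(M, N, 4)`` for M rings of N beads.  Positions are kept
*unwrapped*; the WCA pair search wraps them into the box internally and uses
the minimum-image convention.  Frame torques are rotational generalized
forces: minus the derivative of the energy with respect to an infinitesimal
body rotation of a bead's [u, f, v] triad.
"""

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _cross(a, b, out):
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]


@njit(cache=True, inline="always")
def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True)
def _quat_frame(q, u, f, v):
    """Body axes (columns of the rotation matrix) of quaternion q=(w,x,y,z)."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    u[0] = 1 - 2 * (y * y + z * z)
    u[1] = 2 * (x * y + w * z)
    u[2] = 2 * (x * z - w * y)
    f[0] = 2 * (x * y - w * z)
    f[1] = 1 - 2 * (x * x + z * z)
    f[2] = 2 * (y * z + w * x)
    v[0] = 2 * (x * z + w * y)
    v[1] = 2 * (y * z - w * x)
    v[2] = 1 - 2 * (x * x + y * y)


@njit(cache=True)
def _rotate_about_axis(vec, axis, angle):
    """Rodrigues rotation of vec about unit axis."""
    c = np.cos(angle)
    s = np.sin(angle)
    out = np.empty(3)
    cx = np.empty(3)
    _cross(axis, vec, cx)
    d = _dot(axis, vec)
    for k in range(3):
        out[k] = vec[k] * c + cx[k] * s + axis[k] * d * (1 - c)
    return out


# ---------------------------------------------------------------------------
# force field
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pair_wca(pos, L, eps, s, forces):
    """WCA repulsion over all bead pairs, minimum image; returns energy."""
    M, N = pos.shape[0], pos.shape[1]
    P = M * N
    rc = WCA_CUT * s
    rc2 = rc * rc
    flat = pos.reshape(P, 3)
    energy = 0.0

    # cap the grid so the per-step cell reset stays O(P)
    nc_max = int(np.cbrt(4.0 * P)) + 1
    nc = int(L / rc)
    if nc > nc_max:
        nc = nc_max
    use_cells = L > 0 and nc >= 3
    if not use_cells:
        for i in range(P):
            for j in range(i + 1, P):
                dx = flat[i, 0] - flat[j, 0]
                dy = flat[i, 1] - flat[j, 1]
                dz = flat[i, 2] - flat[j, 2]
                if L > 0:
                    dx -= L * np.rint(dx / L)
                    dy -= L * np.rint(dy / L)
                    dz -= L * np.rint(dz / L)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc2 and r2 > 0.0:
                    sr2 = s * s / r2
                    sr6 = sr2 * sr2 * sr2
                    energy += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
                    fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                    fi = forces.reshape(P, 3)
                    fi[i, 0] += fmag * dx
                    fi[i, 1] += fmag * dy
                    fi[i, 2] += fmag * dz
                    fi[j, 0] -= fmag * dx
                    fi[j, 1] -= fmag * dy
                    fi[j, 2] -= fmag * dz
        return energy

    cell_sz = L / nc
    ncell3 = nc * nc * nc
    head = np.full(ncell3, -1, dtype=np.int64)
    nxt = np.full(P, -1, dtype=np.int64)
    cix = np.empty((P, 3), dtype=np.int64)
    for i in range(P):
        for k in range(3):
            w = flat[i, k] - L * np.floor(flat[i, k] / L)
            c = int(w / cell_sz)
            if c >= nc:
                c = nc - 1
            cix[i, k] = c
        cid = (cix[i, 0] * nc + cix[i, 1]) * nc + cix[i, 2]
        nxt[i] = head[cid]
        head[cid] = i

    fflat = forces.reshape(P, 3)
    for i in range(P):
        for ox in range(-1, 2):
            cx = (cix[i, 0] + ox) % nc
            for oy in range(-1, 2):
                cy = (cix[i, 1] + oy) % nc
                for oz in range(-1, 2):
                    cz = (cix[i, 2] + oz) % nc
                    cid = (cx * nc + cy) * nc + cz
                    j = head[cid]
                    while j >= 0:
                        if j > i:
                            dx = flat[i, 0] - flat[j, 0]
                            dy = flat[i, 1] - flat[j, 1]
                            dz = flat[i, 2] - flat[j, 2]
                            dx -= L * np.rint(dx / L)
                            dy -= L * np.rint(dy / L)
                            dz -= L * np.rint(dz / L)
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2 and r2 > 0.0:
                                sr2 = s * s / r2
                                sr6 = sr2 * sr2 * sr2
                                energy += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
                                fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                                fflat[i, 0] += fmag * dx
                                fflat[i, 1] += fmag * dy
                                fflat[i, 2] += fmag * dz
                                fflat[j, 0] -= fmag * dx
                                fflat[j, 1] -= fmag * dy
                                fflat[j, 2] -= fmag * dz
                        j = nxt[j]
    return energy


@njit(cache=True)
def compute_forces(pos, quat, L, par, motor_bond):
    """Total energy, forces and frame torques.

    par = [eps, s, K_fene, R0, K_bend, K_tilt, K_torsion, psi0].
    motor_bond[m] is the bond whose two dihedrals are removed (-1: none).
    Returns (energy, forces, torques, broken) where broken = [ring, bond,
    length] with ring = -1 when all bonds are intact.
    """
    eps, s, kfene, r0, kbend, ktilt, ktors, psi0 = (
        par[0], par[1], par[2], par[3], par[4], par[5], par[6], par[7],
    )
    M, N = pos.shape[0], pos.shape[1]
    forces = np.zeros((M, N, 3))
    torques = np.zeros((M, N, 3))
    broken = np.empty(3)
    broken[0] = -1.0

    energy = _pair_wca(pos, L, eps, s, forces)

    r02 = r0 * r0
    tvec = np.empty((N, 3))
    tlen = np.empty(N)
    u = np.empty((N, 3))
    f = np.empty((N, 3))
    v = np.empty((N, 3))
    a = np.empty(3)
    b = np.empty(3)
    ga = np.empty(3)
    gb = np.empty(3)
    tmp = np.empty(3)
    tmp2 = np.empty(3)

    for m in range(M):
        # bond vectors (unwrapped coordinates are continuous within a ring)
        for i in range(N):
            j = (i + 1) % N
            for k in range(3):
                tvec[i, k] = pos[m, j, k] - pos[m, i, k]
            tlen[i] = np.sqrt(_dot(tvec[i], tvec[i]))
            if not np.isfinite(tlen[i]) or (kfene > 0.0 and tlen[i] >= r0):
                broken[0] = m
                broken[1] = i
                broken[2] = tlen[i]
                return energy, forces, torques, broken

        for i in range(N):
            _quat_frame(quat[m, i], u[i], f[i], v[i])

        for i in range(N):
            j = (i + 1) % N
            r = tlen[i]
            # --- FENE bond ---
            x2 = (r * r) / r02
            energy += -0.5 * kfene * r02 * np.log(1.0 - x2)
            dudr = kfene * r / (1.0 - x2)
            for k in range(3):
                g = dudr * tvec[i, k] / r
                forces[m, i, k] += g
                forces[m, j, k] -= g

            # --- bending (bonds i, i+1 share bead j) ---
            i2 = (i + 1) % N
            n1 = tlen[i]
            n2 = tlen[i2]
            c = _dot(tvec[i], tvec[i2]) / (n1 * n2)
            energy += kbend * (1.0 - c)
            j2 = (i + 2) % N
            for k in range(3):
                g1 = -kbend * (tvec[i2, k] / (n1 * n2) - c * tvec[i, k] / (n1 * n1))
                g2 = -kbend * (tvec[i, k] / (n1 * n2) - c * tvec[i2, k] / (n2 * n2))
                forces[m, i, k] += g1
                forces[m, j, k] += -g1 + g2
                forces[m, j2, k] += -g2

            # --- tilt: align u_i with bond t_i ---
            ut = _dot(u[i], tvec[i]) / r
            energy += ktilt * (1.0 - ut)
            _cross(u[i], tvec[i], tmp)  # torque K u x t_hat
            for k in range(3):
                torques[m, i, k] += ktilt * tmp[k] / r
                dUdt = -ktilt * (u[i, k] - ut * tvec[i, k] / r) / r
                forces[m, i, k] += dUdt
                forces[m, j, k] -= dUdt

            # --- torsion: two dihedrals, removed at the motor bond ---
            if motor_bond[m] == i:
                continue
            for ch in range(2):
                if ch == 0:
                    w1 = f[i]
                    w2b = f[j]
                else:
                    w1 = v[i]
                    w2b = v[j]
                if psi0 != 0.0:
                    w2 = _rotate_about_axis(w2b, u[j], -psi0)
                else:
                    w2 = w2b
                _cross(tvec[i], w1, a)
                _cross(tvec[i], w2, b)
                na = np.sqrt(_dot(a, a))
                nb = np.sqrt(_dot(b, b))
                if na < 1e-10 or nb < 1e-10:
                    continue  # degenerate: bond parallel to a frame vector
                cab = _dot(a, b) / (na * nb)
                energy += ktors * (1.0 - cab)
                for k in range(3):
                    ga[k] = -ktors * (b[k] / (na * nb) - cab * a[k] / (na * na))
                    gb[k] = -ktors * (a[k] / (na * nb) - cab * b[k] / (nb * nb))
                # translational channel through t
                _cross(w1, ga, tmp)
                _cross(w2, gb, tmp2)
                for k in range(3):
                    dUdt = tmp[k] + tmp2[k]
                    forces[m, i, k] += dUdt
                    forces[m, j, k] -= dUdt
                # rotational channels: tau = -(w x dU/dw), dU/dw = g x t
                _cross(ga, tvec[i], tmp)   # dU/dw1
                _cross(w1, tmp, tmp2)
                for k in range(3):
                    torques[m, i, k] -= tmp2[k]
                _cross(gb, tvec[i], tmp)   # dU/dw2 (body vector of bead j)
                _cross(w2, tmp, tmp2)
                for k in range(3):
                    torques[m, j, k] -= tmp2[k]

    return energy, forces, torques, broken


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB splitting for translation and rotation)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _advance_quat(quat, omg, h):
    M, N = quat.shape[0], quat.shape[1]
    for m in range(M):
        for i in range(N):
            wx, wy, wz = omg[m, i, 0], omg[m, i, 1], omg[m, i, 2]
            wn = np.sqrt(wx * wx + wy * wy + wz * wz)
            if wn < 1e-14:
                continue
            ang = 0.5 * wn * h
            sa = np.sin(ang) / wn
            dw = np.cos(ang)
            dx = sa * wx
            dy = sa * wy
            dz = sa * wz
            qw, qx, qy, qz = quat[m, i, 0], quat[m, i, 1], quat[m, i, 2], quat[m, i, 3]
            nw = dw * qw - dx * qx - dy * qy - dz * qz
            nx = dw * qx + dx * qw + dy * qz - dz * qy
            ny = dw * qy - dx * qz + dy * qw + dz * qx
            nz = dw * qz + dx * qy - dy * qx + dz * qw
            norm = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
            quat[m, i, 0] = nw / norm
            quat[m, i, 1] = nx / norm
            quat[m, i, 2] = ny / norm
            quat[m, i, 3] = nz / norm


@njit(cache=True)
def _motor_psi_angles(pos, quat, motor_bond, out):
    """Angle of f_{i+1} relative to f_i about the motor bond axis, per ring."""
    M, N = pos.shape[0], pos.shape[1]
    u1 = np.empty(3)
    f1 = np.empty(3)
    v1 = np.empty(3)
    u2 = np.empty(3)
    f2 = np.empty(3)
    v2 = np.empty(3)
    cx = np.empty(3)
    for m in range(M):
        bi = motor_bond[m]
        if bi < 0:
            out[m] = 0.0
            continue
        j = (bi + 1) % N
        tx = pos[m, j, 0] - pos[m, bi, 0]
        ty = pos[m, j, 1] - pos[m, bi, 1]
        tz = pos[m, j, 2] - pos[m, bi, 2]
        tn = np.sqrt(tx * tx + ty * ty + tz * tz)
        if tn < 1e-12:
            out[m] = 0.0
            continue
        tx, ty, tz = tx / tn, ty / tn, tz / tn
        _quat_frame(quat[m, bi], u1, f1, v1)
        _quat_frame(quat[m, j], u2, f2, v2)
        d1 = f1[0] * tx + f1[1] * ty + f1[2] * tz
        d2 = f2[0] * tx + f2[1] * ty + f2[2] * tz
        ax = f1[0] - d1 * tx
        ay = f1[1] - d1 * ty
        az = f1[2] - d1 * tz
        bx = f2[0] - d2 * tx
        by = f2[1] - d2 * ty
        bz = f2[2] - d2 * tz
        cx[0] = ay * bz - az * by
        cx[1] = az * bx - ax * bz
        cx[2] = ax * by - ay * bx
        s = cx[0] * tx + cx[1] * ty + cx[2] * tz
        c = ax * bx + ay * by + az * bz
        # sign: psi_a counts the winding the motor stores in the chain, so a
        # torque that builds positive writhe yields positive psi_a
        out[m] = -np.arctan2(s, c)


@njit(cache=True)
def _add_motor_torques(pos, torques, motor_bond, motor_tq):
    M, N = pos.shape[0], pos.shape[1]
    for m in range(M):
        bi = motor_bond[m]
        if bi < 0 or motor_tq[m] == 0.0:
            continue
        j = (bi + 1) % N
        tx = pos[m, j, 0] - pos[m, bi, 0]
        ty = pos[m, j, 1] - pos[m, bi, 1]
        tz = pos[m, j, 2] - pos[m, bi, 2]
        tn = np.sqrt(tx * tx + ty * ty + tz * tz)
        if tn < 1e-12:
            continue  # degenerate motor bond: skip increment
        tq = motor_tq[m] / tn
        torques[m, bi, 0] += tq * tx
        torques[m, bi, 1] += tq * ty
        torques[m, bi, 2] += tq * tz
        torques[m, j, 0] -= tq * tx
        torques[m, j, 1] -= tq * ty
        torques[m, j, 2] -= tq * tz


@njit(cache=True)
def run_langevin(
    pos,
    quat,
    vel,
    omg,
    L,
    par,
    motor_bond,
    motor_tq,
    n_steps,
    dt,
    gamma,
    kT,
    mass,
    inertia,
    seed,
    snap_every,
    psi_acc,
    snap_pos,
    snap_quat,
    snap_psi,
    snap_energy,
):
    """Advance the system n_steps with the BAOAB Langevin scheme.

    Translational and rotational degrees of freedom experience the same
    friction gamma and temperature kT; the random kicks satisfy
    <Y Y> = 2 gamma m kT delta (and the rotational analogue with inertia).
    Snapshots (unwrapped positions, quaternions, accumulated motor angles,
    energy) are stored every ``snap_every`` steps.  Returns (broken,
    n_snapshots_written).
    """
    np.random.seed(seed)
    M, N = pos.shape[0], pos.shape[1]
    c1 = np.exp(-gamma * dt)
    c2v = np.sqrt(kT / mass * (1.0 - c1 * c1))
    c2w = np.sqrt(kT / inertia * (1.0 - c1 * c1))
    h2 = 0.5 * dt

    energy, forces, torques, broken = compute_forces(pos, quat, L, par, motor_bond)
    if broken[0] >= 0:
        return broken, 0
    _add_motor_torques(pos, torques, motor_bond, motor_tq)

    psi_prev = np.empty(M)
    psi_now = np.empty(M)
    _motor_psi_angles(pos, quat, motor_bond, psi_prev)

    isnap = 0
    for step in range(n_steps):
        for m in range(M):
            for i in range(N):
                for k in range(3):
                    vel[m, i, k] += h2 * forces[m, i, k] / mass
                    omg[m, i, k] += h2 * torques[m, i, k] / inertia
                    pos[m, i, k] += h2 * vel[m, i, k]
        _advance_quat(quat, omg, h2)
        if kT > 0.0:
            xi = np.random.standard_normal((M, N, 3))
            et = np.random.standard_normal((M, N, 3))
            for m in range(M):
                for i in range(N):
                    for k in range(3):
                        vel[m, i, k] = c1 * vel[m, i, k] + c2v * xi[m, i, k]
                        omg[m, i, k] = c1 * omg[m, i, k] + c2w * et[m, i, k]
        else:
            for m in range(M):
                for i in range(N):
                    for k in range(3):
                        vel[m, i, k] = c1 * vel[m, i, k]
                        omg[m, i, k] = c1 * omg[m, i, k]
        for m in range(M):
            for i in range(N):
                for k in range(3):
                    pos[m, i, k] += h2 * vel[m, i, k]
        _advance_quat(quat, omg, h2)

        energy, forces, torques, broken = compute_forces(pos, quat, L, par, motor_bond)
        if broken[0] >= 0:
            return broken, isnap
        _add_motor_torques(pos, torques, motor_bond, motor_tq)
        for m in range(M):
            for i in range(N):
                for k in range(3):
                    vel[m, i, k] += h2 * forces[m, i, k] / mass
                    omg[m, i, k] += h2 * torques[m, i, k] / inertia

        # accumulated motor angle psi_a, continuously unwrapped
        _motor_psi_angles(pos, quat, motor_bond, psi_now)
        for m in range(M):
            if motor_bond[m] >= 0:
                dphi = psi_now[m] - psi_prev[m]
                if dphi > np.pi:
                    dphi -= 2.0 * np.pi
                elif dphi < -np.pi:
                    dphi += 2.0 * np.pi
                psi_acc[m] += dphi
                psi_prev[m] = psi_now[m]

        if snap_every > 0 and (step + 1) % snap_every == 0 and isnap < snap_pos.shape[0]:
            for m in range(M):
                for i in range(N):
                    for k in range(3):
                        snap_pos[isnap, m, i, k] = pos[m, i, k]
                    for k in range(4):
                        snap_quat[isnap, m, i, k] = quat[m, i, k]
                snap_psi[isnap, m] = psi_acc[m]
            snap_energy[isnap] = energy
            isnap += 1

    return broken, isnap
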