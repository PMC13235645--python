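"""Trajectory file formats.

Two text dialects are supported:

* an extended-XYZ flavour with per-bead quaternion columns, written and
  read losslessly (17 significant digits):

      <n_atoms>
      time=<tau> box=<L> M=<m> N=<n> psi_a=<comma list> torque=<TQ>
      <ring_id> <bead_id> <xu> <yu> <zu> <qw> <qx> <qy> <qz>

  coordinates are stored unwrapped (wrapped copies are derived on demand);

* a common MD dump dialect (``ITEM: TIMESTEP`` / ``ITEM: BOX BOUNDS`` /
  ``ITEM: ATOMS id type x y z qw qx qy qz``, any column order declared in
  the ATOMS header) where ``type`` is the ring id and coordinates may be
  wrapped — rings are made whole by minimum-image walking along the bonds,
  and the unwrap is validated against the maximal FENE extension.
"""

from __future__ import annotations

import numpy as np

from .dynamics import Trajectory

__all__ = ["write_traj", "read_traj", "read_dump", "wrap_positions"]


def wrap_positions(pos: np.ndarray, box_length: float) -> np.ndarray:
    """Wrap coordinates into [0, L)."""
    return pos - box_length * np.floor(pos / box_length)


def write_traj(path, traj: Trajectory) -> None:
    """Write a trajectory in the quaternion-extended XYZ dialect."""
    with open(path, "w") as fh:
        T, M, N = traj.n_snapshots, traj.M, traj.N
        for t in range(T):
            fh.write(f"{M * N}\n")
            psi = ",".join("%.17g" % x for x in traj.psi_a[t])
            fh.write(
                "time=%.17g box=%.17g M=%d N=%d torque=%.17g psi_a=%s\n"
                % (traj.times[t], traj.box_length, M, N, traj.motor_torque, psi)
            )
            for m in range(M):
                for i in range(N):
                    x, y, z = traj.positions[t, m, i]
                    qw, qx, qy, qz = traj.quats[t, m, i]
                    fh.write(
                        "%d %d %.17g %.17g %.17g %.17g %.17g %.17g %.17g\n"
                        % (m, i, x, y, z, qw, qx, qy, qz)
                    )


def read_traj(path) -> Trajectory:
    """Read the quaternion-extended XYZ dialect written by write_traj."""
    times, psis, poss, quats = [], [], [], []
    box = None
    torque = 0.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not any(ln.strip() for ln in lines):
        raise ValueError("empty trajectory file")
    k = 0
    lineno = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            nat = int(lines[k].strip())
        except ValueError as e:
            raise ValueError(f"line {k + 1}: expected atom count") from e
        header = lines[k + 1]
        meta = {}
        for tok in header.split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = val
        try:
            t = float(meta["time"])
            box = float(meta["box"])
            M = int(meta["M"])
            N = int(meta["N"])
        except KeyError as e:
            raise ValueError(f"line {k + 2}: missing header field {e}") from e
        torque = float(meta.get("torque", 0.0))
        psi = np.array([float(x) for x in meta["psi_a"].split(",")]) if "psi_a" in meta else np.zeros(M)
        pos = np.empty((M, N, 3))
        quat = np.empty((M, N, 4))
        for row in range(nat):
            lineno = k + 2 + row
            parts = lines[lineno].split()
            if len(parts) < 9:
                raise ValueError(f"line {lineno + 1}: expected 9 columns, got {len(parts)}")
            m, i = int(parts[0]), int(parts[1])
            pos[m, i] = [float(parts[2]), float(parts[3]), float(parts[4])]
            quat[m, i] = [float(p) for p in parts[5:9]]
        times.append(t)
        psis.append(psi)
        poss.append(pos)
        quats.append(quat)
        k += 2 + nat
    order = np.argsort(times)
    return Trajectory(
        times=np.asarray(times)[order],
        box_length=box,
        positions=np.stack(poss)[order],
        quats=np.stack(quats)[order],
        psi_a=np.stack(psis)[order],
        energies=np.full(len(times), np.nan),
        motor_torque=torque,
    )


def _unwrap_ring(pos: np.ndarray, L: float, R0: float) -> np.ndarray:
    """Make a ring whole across periodic boundaries by walking its bonds."""
    out = pos.copy()
    for i in range(1, len(out)):
        d = out[i] - out[i - 1]
        out[i] -= L * np.rint(d / L)
    blen = np.linalg.norm(np.diff(out, axis=0), axis=1)
    closure = np.linalg.norm(
        out[0] - (out[-1] - L * np.rint((out[-1] - out[0]) / L))
    )
    if blen.size and (blen.max() >= R0 or closure >= R0):
        raise ValueError(
            "unwrap failed: bond longer than R0 after minimum-image walk "
            "(broken bond or corrupt dump)"
        )
    return out


def read_dump(path, R0: float = 1.6) -> Trajectory:
    """Read an MD dump dialect (id, type, x y z, quaternion columns).

    ``type`` is the ring id (bead order within a ring follows ``id``).
    Wrapped coordinates are unwrapped per ring.  Missing quaternion columns
    are an error: orientation-dependent analyses cannot run without frames.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError("empty trajectory file")
    snaps = []
    k = 0
    while k < len(lines):
        ln = lines[k].strip()
        if not ln:
            k += 1
            continue
        if not ln.startswith("ITEM: TIMESTEP"):
            raise ValueError(f"line {k + 1}: expected 'ITEM: TIMESTEP', got {ln!r}")
        step = float(lines[k + 1].strip())
        k += 2
        assert lines[k].startswith("ITEM: NUMBER OF ATOMS"), f"line {k + 1}"
        nat = int(lines[k + 1].strip())
        k += 2
        if not lines[k].startswith("ITEM: BOX BOUNDS"):
            raise ValueError(f"line {k + 1}: expected box bounds")
        lo, hi = (float(x) for x in lines[k + 1].split()[:2])
        L = hi - lo
        k += 4
        if not lines[k].startswith("ITEM: ATOMS"):
            raise ValueError(f"line {k + 1}: expected atoms header")
        cols = lines[k].split()[2:]
        need = ["id", "type", "x", "y", "z", "qw", "qx", "qy", "qz"]
        missing = [c for c in need if c not in cols]
        if any(c in missing for c in ("qw", "qx", "qy", "qz")):
            raise ValueError(
                "dump lacks quaternion columns: orientation-dependent "
                "analyses are not possible with this file"
            )
        if missing:
            raise ValueError(f"dump missing columns: {missing}")
        idx = {c: cols.index(c) for c in need}
        k += 1
        rows = []
        for r in range(nat):
            parts = lines[k + r].split()
            rows.append([float(parts[idx[c]]) for c in need])
        k += nat
        arr = np.asarray(rows)
        snaps.append((step, L, arr))

    M = int(max(s[2][:, 1].max() for s in snaps)) + 1
    N = snaps[0][2].shape[0] // M
    times, poss, quats = [], [], []
    box = snaps[0][1]
    for step, L, arr in snaps:
        pos = np.empty((M, N, 3))
        quat = np.empty((M, N, 4))
        for m in range(M):
            sel = arr[arr[:, 1] == m]
            sel = sel[np.argsort(sel[:, 0])]
            if sel.shape[0] != N:
                raise ValueError(f"ring {m}: expected {N} beads, got {sel.shape[0]}")
            pos[m] = _unwrap_ring(sel[:, 2:5], L, R0)
            quat[m] = sel[:, 5:9]
        times.append(step)
        poss.append(pos)
        quats.append(quat)
    return Trajectory(
        times=np.asarray(times, dtype=np.float64),
        box_length=box,
        positions=np.stack(poss),
        quats=np.stack(quats),
        psi_a=np.zeros((len(times), M)),
        energies=np.full(len(times), np.nan),
    )
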