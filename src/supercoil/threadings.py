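"""Threading detection via minimal surfaces spanned on ring contours.

A disk-like surface triangulated to exactly 4N triangles is spanned on every
ring (fan from the centroid, refined once by midpoint subdivision) and its
interior vertices are relaxed by area-gradient descent with backtracking.
Intersections of another ring's contour with the relaxed surface are
threadings; the piercings split the threader contour into segments
L_1..L_p and the threading depth is the separation length

    L_sep = min(sum of even-indexed L_i, sum of odd-indexed L_i),

bounded by N/2.  Per-snapshot threading records define a directed graph on
the M rings (threader -> threaded) whose weakly connected components are the
threading clusters; f_max is the fraction of rings in the largest cluster
and f_0 the fraction of dangling (unthreaded) rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

__all__ = [
    "MinimalSurface",
    "ThreadingRecord",
    "ThreadingGraph",
    "span_minimal_surface",
    "detect_piercings",
    "separation_length",
    "build_threading_graph",
    "threading_timeseries",
    "analyze_snapshot",
]


# ---------------------------------------------------------------------------
# surface spanning
# ---------------------------------------------------------------------------


@dataclass
class MinimalSurface:
    """Triangulated spanning surface of one ring (boundary vertices fixed)."""

    vertices: np.ndarray  # (3N+1, 3)
    triangles: np.ndarray  # (4N, 3) int
    boundary_vertex_ids: np.ndarray  # (N,)
    converged: bool
    area: float
    ring_id: int = -1


def _initial_mesh(positions: np.ndarray):
    """Centroid fan refined by one midpoint subdivision: 4N triangles."""
    n = positions.shape[0]
    centroid = positions.mean(axis=0)
    nxt = np.roll(np.arange(n), -1)
    spoke_mid = 0.5 * (centroid + positions)  # N
    edge_mid = 0.5 * (positions + positions[nxt])  # N

    verts = np.concatenate([positions, centroid[None, :], spoke_mid, edge_mid])
    C = n
    MC = n + 1  # spoke midpoints start
    ME = 2 * n + 1  # edge midpoints start

    tris = []
    for i in range(n):
        j = nxt[i]
        tris.append((i, ME + i, MC + i))
        tris.append((ME + i, j, MC + j))
        tris.append((ME + i, MC + j, MC + i))
        tris.append((MC + i, MC + j, C))
    return verts, np.asarray(tris, dtype=np.int64)


@njit(cache=True)
def _area_and_grad(verts, tris, grad):
    total = 0.0
    grad[:] = 0.0
    for t in range(tris.shape[0]):
        i0, i1, i2 = tris[t, 0], tris[t, 1], tris[t, 2]
        e1 = verts[i1] - verts[i0]
        e2 = verts[i2] - verts[i0]
        n = np.cross(e1, e2)
        a2 = np.sqrt(n[0] ** 2 + n[1] ** 2 + n[2] ** 2)
        if a2 < 1e-14:
            continue
        total += 0.5 * a2
        nh = n / a2
        g0 = 0.5 * np.cross(verts[i1] - verts[i2], nh)
        g1 = 0.5 * np.cross(verts[i2] - verts[i0], nh)
        g2 = 0.5 * np.cross(verts[i0] - verts[i1], nh)
        for k in range(3):
            grad[i0, k] += g0[k]
            grad[i1, k] += g1[k]
            grad[i2, k] += g2[k]
    return total


def span_minimal_surface(ring, max_iters: int = 10000, tol: float = 1e-6) -> MinimalSurface:
    """Relax the interior vertices of the spanning surface by gradient
    descent on total area (backtracking step) until the relative area change
    per iteration falls below ``tol``."""
    pos = np.ascontiguousarray(
        ring.positions if hasattr(ring, "positions") else ring, dtype=np.float64
    )
    n = pos.shape[0]
    verts, tris = _initial_mesh(pos)
    free = np.ones(len(verts), dtype=bool)
    free[:n] = False
    # chord midpoints subdividing the boundary edges lie on the ring polygon
    # itself and are part of the fixed boundary, not of the relaxable interior
    free[2 * n + 1:] = False

    grad = np.zeros_like(verts)
    area = _area_and_grad(verts, tris, grad)
    step = 0.25
    converged = False
    quiet = 0  # consecutive iterations below tolerance
    for _ in range(max_iters):
        g = np.where(free[:, None], grad, 0.0)
        gnorm2 = float((g * g).sum())
        if gnorm2 < 1e-20:
            converged = True
            break
        new_area = np.inf
        trial = verts
        while step > 1e-12:
            trial = verts - step * g
            new_area = _area_and_grad(trial, tris, grad)
            if new_area < area:
                break
            step *= 0.5
        if new_area >= area:
            converged = True  # no descent direction left at float precision
            break
        verts = trial
        rel = (area - new_area) / max(area, 1e-300)
        area = new_area
        step *= 1.3
        # grad was refreshed by the accepted _area_and_grad call
        quiet = quiet + 1 if rel < tol else 0
        if quiet >= 10:
            converged = True
            break
    return MinimalSurface(
        vertices=verts,
        triangles=tris,
        boundary_vertex_ids=np.arange(n),
        converged=converged,
        area=float(area),
    )


# ---------------------------------------------------------------------------
# piercing detection
# ---------------------------------------------------------------------------


@njit(cache=True)
def _segment_triangle_hits(verts, tris, pts, hits):
    """Moller-Trumbore over all (contour segment, triangle) pairs.

    hits rows: [segment index, fraction along segment, triangle id, sign].
    Returns the number of hits found (-1 if hits array overflowed).
    """
    nseg = pts.shape[0]
    count = 0
    for s in range(nseg):
        p0 = pts[s]
        p1 = pts[(s + 1) % nseg]
        d = p1 - p0
        for t in range(tris.shape[0]):
            v0 = verts[tris[t, 0]]
            v1 = verts[tris[t, 1]]
            v2 = verts[tris[t, 2]]
            e1 = v1 - v0
            e2 = v2 - v0
            pv = np.cross(d, e2)
            det = np.dot(e1, pv)
            if abs(det) < 1e-12:
                continue
            inv = 1.0 / det
            tv = p0 - v0
            uu = np.dot(tv, pv) * inv
            if uu < 0.0 or uu > 1.0:
                continue
            qv = np.cross(tv, e1)
            vv = np.dot(d, qv) * inv
            if vv < 0.0 or uu + vv > 1.0:
                continue
            frac = np.dot(e2, qv) * inv
            if frac < 0.0 or frac >= 1.0:
                continue
            if count >= hits.shape[0]:
                return -1
            hits[count, 0] = s
            hits[count, 1] = frac
            hits[count, 2] = t
            hits[count, 3] = 1.0 if det > 0 else -1.0
            count += 1
    return count


@dataclass
class ThreadingRecord:
    """One directed threading event: ``threader`` pierces the minimal
    surface of ``threaded`` at an even number of points."""

    threader_id: int
    threaded_id: int
    piercings: list  # (contour position s in [0,N), triangle id, sign)
    segment_lengths: list  # L_1..L_p in monomers, sum N
    L_sep: int
    parity_ok: bool = True


def separation_length(segment_lengths, N: int) -> int:
    """Eq-style separation length: min over the two alternating segment
    sums; validates that the segments partition the contour."""
    L = list(segment_lengths)
    if sum(L) != N:
        raise ValueError(f"segment lengths sum to {sum(L)}, expected N={N}")
    even = sum(L[0::2])
    odd = sum(L[1::2])
    return int(min(even, odd))


def _segments_from_positions(svals: np.ndarray, N: int) -> list:
    """Bead counts of the contour arcs between ordered piercing positions."""
    s = np.sort(np.asarray(svals, dtype=np.float64))
    segs = []
    p = len(s)
    for k in range(p):
        lo = s[k]
        hi = s[(k + 1) % p] + (N if k == p - 1 else 0)
        segs.append(int(np.floor(hi) - np.floor(lo)))
    return segs


def detect_piercings(
    surface: MinimalSurface,
    other,
    threader_id: int = -1,
    threaded_id: int = -1,
    box_length: float = 0.0,
) -> ThreadingRecord | None:
    """Intersections of ``other``'s contour with a ring's minimal surface.

    With a periodic ``box_length`` all 27 nearest images of the contour whose
    bounding spheres overlap the surface's are tested.  Returns ``None`` when
    there is no intersection; a record with ``parity_ok=False`` (odd piercing
    count, a numerical failure mode — the pair is excluded from statistics)
    otherwise carries no segment decomposition.
    """
    pts0 = np.ascontiguousarray(
        other.positions if hasattr(other, "positions") else other, dtype=np.float64
    )
    n = pts0.shape[0]
    scen = surface.vertices.mean(axis=0)
    srad = np.linalg.norm(surface.vertices - scen, axis=1).max()

    shifts = [np.zeros(3)]
    if box_length > 0:
        shifts = [
            np.array([ix, iy, iz], dtype=np.float64) * box_length
            for ix in (-1, 0, 1)
            for iy in (-1, 0, 1)
            for iz in (-1, 0, 1)
        ]

    all_hits = []
    hits = np.empty((4 * n, 4))
    for sh in shifts:
        pts = pts0 + sh
        ccen = pts.mean(axis=0)
        crad = np.linalg.norm(pts - ccen, axis=1).max()
        if np.linalg.norm(ccen - scen) > srad + crad + 1.0:
            continue
        cnt = _segment_triangle_hits(surface.vertices, surface.triangles, pts, hits)
        if cnt < 0:
            cnt = hits.shape[0]
        for k in range(cnt):
            all_hits.append((hits[k, 0] + hits[k, 1], int(hits[k, 2]), int(hits[k, 3])))
        # degenerate in-plane segments produce near-zero determinants that are
        # skipped; nudge deterministically and retry once if parity is odd
    if not all_hits:
        return None
    if len(all_hits) % 2 == 1:
        nudged = pts0 + 1e-9
        cnt = _segment_triangle_hits(surface.vertices, surface.triangles, nudged, hits)
        if cnt >= 0 and cnt % 2 == 0 and cnt > 0:
            all_hits = [
                (hits[k, 0] + hits[k, 1], int(hits[k, 2]), int(hits[k, 3]))
                for k in range(cnt)
            ]
        elif cnt == 0:
            return None
        else:
            return ThreadingRecord(
                threader_id, threaded_id, all_hits, [], 0, parity_ok=False
            )

    svals = np.array([h[0] for h in all_hits])
    segs = _segments_from_positions(svals, n)
    lsep = separation_length(segs, n)
    return ThreadingRecord(
        threader_id,
        threaded_id,
        sorted(all_hits),
        segs,
        lsep,
        parity_ok=True,
    )


# ---------------------------------------------------------------------------
# threading graph
# ---------------------------------------------------------------------------


@dataclass
class ThreadingGraph:
    """Directed threading connectivity of one snapshot."""

    adjacency: np.ndarray  # (M, M) 0/1, A[i, j] = 1 if i threads j
    threshold: int = 0
    clusters: list = field(default_factory=list)
    f_max: float = 0.0
    f_0: float = 0.0

    @property
    def M(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.M))
        ii, jj = np.nonzero(self.adjacency)
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
        return g


def build_threading_graph(records, M: int, L_sep_thr: int = 0) -> ThreadingGraph:
    """Adjacency (threader -> threaded, L_sep > threshold), weakly connected
    clusters, largest-cluster fraction f_max and dangling fraction f_0."""
    A = np.zeros((M, M), dtype=np.int64)
    for rec in records:
        if rec is None or not rec.parity_ok:
            continue
        if rec.L_sep > L_sep_thr:
            A[rec.threader_id, rec.threaded_id] = 1
    np.fill_diagonal(A, 0)
    g = nx.DiGraph()
    g.add_nodes_from(range(M))
    ii, jj = np.nonzero(A)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(c) for c in nx.weakly_connected_components(g)]
    comps.sort(key=len, reverse=True)
    f_max = max(len(c) for c in comps) / M if M else 0.0
    dangling = sum(1 for v in range(M) if g.degree(v) == 0)
    return ThreadingGraph(
        adjacency=A,
        threshold=L_sep_thr,
        clusters=comps,
        f_max=f_max,
        f_0=dangling / M if M else 0.0,
    )


def analyze_snapshot(rings, box_length: float = 0.0, L_sep_thr: int = 0,
                     max_iters: int = 10000, tol: float = 1e-6):
    """Span surfaces on all rings, detect all directed threadings, build the
    graph.  Returns (records, graph, n_unconverged)."""
    M = len(rings)
    surfaces = []
    bad = 0
    for i, r in enumerate(rings):
        s = span_minimal_surface(r, max_iters=max_iters, tol=tol)
        s.ring_id = i
        if not s.converged:
            bad += 1
        surfaces.append(s)
    records = []
    for j, surf in enumerate(surfaces):
        if not surf.converged:
            continue
        for i, r in enumerate(rings):
            if i == j:
                continue
            rec = detect_piercings(surf, r, threader_id=i, threaded_id=j,
                                   box_length=box_length)
            if rec is not None:
                records.append(rec)
    graph = build_threading_graph(records, M, L_sep_thr)
    return records, graph, bad


def threading_timeseries(snapshots, box_length: float = 0.0, L_sep_thr: int = 0):
    """Per-snapshot mean threadings per ring, f_max and f_0.

    ``snapshots`` is an iterable of ring lists.  Snapshots whose surfaces all
    failed to converge are excluded (bookkept in the returned dict).
    """
    out = {"mean_threadings": [], "f_max": [], "f_0": [], "excluded": 0,
           "labels": []}
    any_ok = False
    for rings in snapshots:
        M = len(rings)
        records, graph, bad = analyze_snapshot(rings, box_length, L_sep_thr)
        if bad == M:
            out["excluded"] += 1
            continue
        any_ok = True
        nthr = sum(1 for r in records if r.parity_ok and r.L_sep > L_sep_thr)
        out["mean_threadings"].append(nthr / M)
        out["f_max"].append(graph.f_max)
        out["f_0"].append(graph.f_0)
        threaded = np.asarray(graph.adjacency.sum(0) + graph.adjacency.sum(1) > 0)
        out["labels"].append(threaded)
    if not any_ok:
        raise RuntimeError("no snapshot produced a converged surface set")
    return out
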