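"""Effective 1D Monte Carlo model of threading-network relaxation.

Adapted from the Lo-Turner picture of a topological glass: each ring is a
linear, doubly folded chain of effective length ``N_eff`` that diffuses
curvilinearly in unit steps.  Threadings between chain pairs carry two
coordinates — an *active* coordinate ``x_a`` on the threading chain (how
deep its contour reaches through the partner's surface) and a *passive*
coordinate ``x_p`` on the threaded chain (where its contour is pierced).

Move rules per attempted unit step of a chain:

* a passive threading sitting at the chain end facing the move (``x_p = 0``
  for a left move, ``x_p = N_eff - 1`` for a right move) rejects the move —
  the pierced chain cannot slide past the blocking partner;
* an accepted move shifts *all* coordinates carried by the moving chain
  (its own ``x_p`` s and ``x_a`` s) by the step;
* an active coordinate leaving ``[0, N_eff - 1]`` means the threader has
  retracted out of the partner: the threading is relaxed and removed from
  both chains.

No new threadings are ever created, so the total threading count is
monotone non-increasing; mutually end-blocking cycles never relax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Threading1D",
    "EffectiveChain",
    "McState",
    "init_from_threading_network",
    "mc_sweep",
    "relaxation_curve",
    "mean_exit_time_enumeration",
]


@dataclass
class Threading1D:
    """One threading event shared by two chains."""

    event_id: int
    active_chain: int
    passive_chain: int
    x_a: int  # coordinate on the active (threading) chain
    x_p: int  # coordinate on the passive (threaded) chain
    alive: bool = True


@dataclass
class EffectiveChain:
    chain_id: int
    N_eff: int
    active_threadings: list = field(default_factory=list)  # Threading1D refs
    passive_threadings: list = field(default_factory=list)


@dataclass
class McState:
    chains: list
    threadings: list
    sweep: int = 0
    rng: np.random.Generator | None = None

    @property
    def M(self) -> int:
        return len(self.chains)

    def n_alive(self) -> int:
        return sum(1 for t in self.threadings if t.alive)

    def dangling_fraction(self) -> float:
        dang = 0
        for c in self.chains:
            if not any(t.alive for t in c.active_threadings) and not any(
                t.alive for t in c.passive_threadings
            ):
                dang += 1
        return dang / self.M if self.M else 0.0

    def check_consistency(self) -> None:
        for t in self.threadings:
            if not t.alive:
                continue
            ca = self.chains[t.active_chain]
            cp = self.chains[t.passive_chain]
            if t not in ca.active_threadings or t not in cp.passive_threadings:
                raise RuntimeError(f"threading {t.event_id} pairing inconsistent")
            if not (0 <= t.x_a < ca.N_eff) or not (0 <= t.x_p < cp.N_eff):
                raise RuntimeError(f"threading {t.event_id} out of bounds")


def init_from_threading_network(
    records,
    M: int,
    N_eff: int = 50,
    N: int | None = None,
    placement_rule: str = "uniform",
    end_margin: int = 0,
    seed: int = 0,
) -> McState:
    """Build the 1D state from MD threading records.

    Active coordinates map from the separation length: x_a = L_sep * N_eff /
    (N/2), rounded to the nearest site and clamped; passive coordinates are
    drawn uniformly on [0, N_eff - 1] (``uniform``) or on
    [end_margin, N_eff - 1 - end_margin] (``end-excluded``).
    """
    rng = np.random.default_rng(seed)
    chains = [EffectiveChain(i, N_eff) for i in range(M)]
    threadings = []
    lo, hi = 0, N_eff - 1
    if placement_rule == "end-excluded":
        lo, hi = end_margin, N_eff - 1 - end_margin
        if lo > hi:
            raise ValueError("end_margin leaves no admissible sites")
    elif placement_rule != "uniform":
        raise ValueError(f"unknown placement rule {placement_rule!r}")

    for k, rec in enumerate(records):
        if rec is None or not getattr(rec, "parity_ok", True):
            continue
        n_beads = N if N is not None else sum(rec.segment_lengths)
        if rec.L_sep > n_beads / 2:
            raise ValueError("L_sep exceeds N/2: invalid record")
        x_a = int(round(rec.L_sep * N_eff / (n_beads / 2)))
        x_a = min(max(x_a, 0), N_eff - 1)
        x_p = int(rng.integers(lo, hi + 1))
        t = Threading1D(k, rec.threader_id, rec.threaded_id, x_a, x_p)
        threadings.append(t)
        chains[rec.threader_id].active_threadings.append(t)
        chains[rec.threaded_id].passive_threadings.append(t)
    return McState(chains=chains, threadings=threadings, rng=rng)


def mc_sweep(state: McState, check: bool = False) -> McState:
    """One sweep: every chain, in random order, attempts one unit move."""
    rng = state.rng if state.rng is not None else np.random.default_rng()
    order = rng.permutation(state.M)
    for ci in order:
        chain = state.chains[ci]
        step = 1 if rng.random() < 0.5 else -1
        blocked_end = chain.N_eff - 1 if step == 1 else 0
        blocked = any(
            t.alive and t.x_p == blocked_end for t in chain.passive_threadings
        )
        if blocked:
            continue
        for t in chain.passive_threadings:
            t.x_p += step
        died = []
        for t in chain.active_threadings:
            t.x_a += step
            if t.x_a < 0 or t.x_a > chain.N_eff - 1:
                t.alive = False  # threader retracted: threading relaxed
                died.append(t)
        if died:
            chain.active_threadings = [t for t in chain.active_threadings if t.alive]
            for t in died:
                state.chains[t.passive_chain].passive_threadings.remove(t)
    state.sweep += 1
    if check:
        state.check_consistency()
    return state


def relaxation_curve(state: McState, n_sweeps: int, record_every: int = 1):
    """Total alive threading count and dangling fraction vs sweep.

    Returns dict with 'sweeps', 'count', 'f_dangling' arrays and the
    half-life estimate 'half_life' (first sweep at which the count dropped
    to <= half the initial; NaN if never reached).
    """
    sweeps = [0]
    count = [state.n_alive()]
    fdang = [state.dangling_fraction()]
    n0 = count[0]
    half_life = np.nan
    for k in range(1, n_sweeps + 1):
        mc_sweep(state)
        if k % record_every == 0 or k == n_sweeps:
            c = state.n_alive()
            sweeps.append(k)
            count.append(c)
            fdang.append(state.dangling_fraction())
            if np.isnan(half_life) and n0 > 0 and c <= n0 / 2:
                half_life = k
        if state.n_alive() == 0:
            break
    return {
        "sweeps": np.asarray(sweeps),
        "count": np.asarray(count),
        "f_dangling": np.asarray(fdang),
        "half_life": half_life,
    }


def mean_exit_time_enumeration(N_eff: int, x0: int) -> float:
    """Exact mean first-exit sweep count of a single unbiased unit-step walk
    started at site ``x0``, absorbing once the coordinate leaves
    [0, N_eff - 1].  Independent oracle for the single-threading relaxation
    time: solves the tridiagonal first-passage system."""
    n = N_eff
    # tau(x) = 1 + 0.5 tau(x-1) + 0.5 tau(x+1), tau(-1) = tau(n) = 0
    A = np.zeros((n, n))
    b = np.ones(n)
    for x in range(n):
        A[x, x] = 1.0
        if x - 1 >= 0:
            A[x, x - 1] = -0.5
        if x + 1 < n:
            A[x, x + 1] = -0.5
    tau = np.linalg.solve(A, b)
    return float(tau[x0])
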