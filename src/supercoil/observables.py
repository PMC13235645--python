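"""Dynamic and conformational observables of ring solutions.

Center-of-mass mean-square displacement g3(t), the normalized relaxation
function Gamma(t, t') = g3(t) t' / (t g3(t')) diagnosing sub/super-diffusion
relative to a reference time t', gyration-tensor shape descriptors and the
overlap parameter rho R_g^3 / N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MsdSeries",
    "GammaSeries",
    "msd_com",
    "relaxation_gamma",
    "gyration_and_shape",
    "overlap_parameter",
]


@dataclass
class MsdSeries:
    """g3(t) over lag times, with its averaging mode and ring population."""

    lags: np.ndarray  # lag times (tau)
    g3: np.ndarray  # mean square displacement (s^2)
    averaging_mode: str = "onset"  # "onset" | "time_averaged"
    population: str = "all"  # "all" | "threaded" | "dangling"
    n_rings: np.ndarray | None = None  # rings averaged per lag


@dataclass
class GammaSeries:
    """Gamma(t, t') relaxation function values over t."""

    t: np.ndarray
    gamma: np.ndarray
    t_prime: float


def _check_unwrapped(com: np.ndarray, box_length: float | None) -> None:
    if box_length is None or box_length <= 0 or com.shape[0] < 2:
        return
    jumps = np.abs(np.diff(com, axis=0)).max()
    if jumps > box_length / 2:
        raise ValueError(
            "trajectory looks wrapped (per-step jump > L/2); "
            "g3 requires unwrapped coordinates"
        )


def msd_com(
    times: np.ndarray,
    com: np.ndarray,
    mode: str = "onset",
    population_labels: np.ndarray | None = None,
    population: str = "all",
    box_length: float | None = None,
) -> MsdSeries:
    """Center-of-mass MSD g3(t) = <[r_C(t) - r_C(0)]^2>.

    ``com`` is (T, M, 3) unwrapped.  In ``onset`` mode a single origin (the
    first frame, e.g. the activity onset) is used, matching the convention
    for driven systems; ``time_averaged`` averages over all origins at each
    lag (equilibrium convention).  ``population_labels`` is (T, M) boolean
    (True = threaded): a ring contributes to the "threaded"/"dangling" mean
    at lag t according to its label *at that time*.
    """
    times = np.asarray(times, dtype=np.float64)
    com = np.asarray(com, dtype=np.float64)
    T, M = com.shape[0], com.shape[1]
    _check_unwrapped(com, box_length)

    if population != "all":
        if population_labels is None:
            raise ValueError("population splitting requires labels")
        labels = np.asarray(population_labels, dtype=bool)
        want = labels if population == "threaded" else ~labels
    else:
        want = np.ones((T, M), dtype=bool)

    if mode == "onset":
        disp2 = np.sum((com - com[0]) ** 2, axis=2)  # (T, M)
        g3 = np.empty(T)
        nn = np.empty(T, dtype=np.int64)
        for t in range(T):
            sel = want[t]
            nn[t] = sel.sum()
            g3[t] = disp2[t, sel].mean() if nn[t] else np.nan
        lags = times - times[0]
    elif mode == "time_averaged":
        lags = times - times[0]
        g3 = np.zeros(T)
        nn = np.zeros(T, dtype=np.int64)
        for dt_idx in range(T):
            acc = 0.0
            cnt = 0
            for t0 in range(T - dt_idx):
                d2 = np.sum((com[t0 + dt_idx] - com[t0]) ** 2, axis=1)
                sel = want[t0 + dt_idx]
                acc += d2[sel].sum()
                cnt += sel.sum()
            g3[dt_idx] = acc / cnt if cnt else np.nan
            nn[dt_idx] = cnt
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MsdSeries(lags=lags, g3=g3, averaging_mode=mode, population=population, n_rings=nn)


def relaxation_gamma(msd: MsdSeries, t_prime: float) -> GammaSeries:
    """Gamma(t, t') = g3(t) t' / (t g3(t')); constant (=1) for pure diffusion,
    below 1 for slowdown relative to the reference time t'."""
    lags = msd.lags
    idx = np.nonzero(np.isclose(lags, t_prime, rtol=1e-9, atol=1e-12))[0]
    if idx.size == 0:
        raise ValueError(f"t'={t_prime} is not among the sampled lags; refusing to interpolate")
    g3p = msd.g3[idx[0]]
    if not g3p > 0:
        raise ValueError("g3(t') must be positive")
    mask = lags > 0
    t = lags[mask]
    gamma = msd.g3[mask] * t_prime / (t * g3p)
    return GammaSeries(t=t, gamma=gamma, t_prime=t_prime)


def gyration_and_shape(ring) -> dict:
    """Radius of gyration and gyration-tensor shape descriptors.

    Returns R_g, the ordered eigenvalues l1 <= l2 <= l3, the asphericity
    b = l3 - (l1 + l2)/2, the prolateness and the relative shape anisotropy
    kappa^2 (0 for a sphere, 1 for a rod).
    """
    pos = np.asarray(ring.positions if hasattr(ring, "positions") else ring, dtype=np.float64)
    d = pos - pos.mean(axis=0)
    S = d.T @ d / pos.shape[0]
    lam = np.sort(np.linalg.eigvalsh(S))
    tr = lam.sum()
    rg = np.sqrt(tr)
    asph = lam[2] - 0.5 * (lam[0] + lam[1])
    if tr > 0:
        prol = (3 * lam[0] - tr) * (3 * lam[1] - tr) * (3 * lam[2] - tr) / tr**3
        kappa2 = 1.5 * float(lam @ lam) / tr**2 - 0.5
    else:
        prol = 0.0
        kappa2 = 0.0
    return {
        "R_g": float(rg),
        "eigenvalues": lam,
        "asphericity": float(asph),
        "prolateness": float(prol),
        "kappa2": float(kappa2),
    }


def overlap_parameter(density: float, rg_samples, N: int) -> tuple[float, float]:
    """Overlap parameter rho R_g^3 / N with propagated uncertainty.

    Equals rho / rho* with the overlap concentration rho* = N / R_g^3;
    ``rg_samples`` are equilibrium R_g estimates for rings of N beads.
    Returns (value, standard error).
    """
    rg = np.atleast_1d(np.asarray(rg_samples, dtype=np.float64))
    mean_rg = float(rg.mean())
    se_rg = float(rg.std(ddof=1) / np.sqrt(rg.size)) if rg.size > 1 else 0.0
    val = density * mean_rg**3 / N
    err = 3 * density * mean_rg**2 * se_rg / N
    return val, err
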