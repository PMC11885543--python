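"""Out-of-equilibrium cryptic SFS theory and Bayesian (W, Theta) inference.

The Kingman coalescent guarantees that, for a broad class of neutral forward
models including the Moran process, the normalized cryptic site frequency
spectrum depends on time only through the dimensionless *mitochondrial age*

    W = (chronological time) / (expected time to fixation),

and on the mutation influx only through the scaled rate Theta = N * nu (per
base; multiplied by L_mtDNA for per-genome rates).  Because every mutation
evolves independently under neutrality, the expected spectrum is linear in
Theta: Theta scales the expected number of mutations per cell while leaving
the spectrum shape untouched.

``expected_csfs`` computes the expected spectrum with either an exact
tridiagonal Markov-chain propagation of the marginal copy-number law at a
reference copy number (default, deterministic) or a forward-Moran ensemble
(the brute-force oracle).  The likelihood of a donor's observed cryptic
heteroplasmies is multinomial over spectrum bins times Poisson in the total
count; the posterior over (W, Theta) is evaluated on a dense grid with a
uniform prior on W and a log-uniform prior on Theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage, special, stats

from .moran_sim import (
    MoranParams,
    ensemble_frequencies,
    fixation_timescale_events,
)

__all__ = [
    "CoalescentParams",
    "PosteriorFit",
    "expected_csfs",
    "log_likelihood",
    "fit_donor",
    "rate_from_theta",
    "theta_from_rate",
    "predict_curves",
]

DEFAULT_REFERENCE_N = 100
DEFAULT_L = 16569


@dataclass
class CoalescentParams:
    """Point in the (W, Theta) parameter space plus binning conventions.

    W >= 0 is the mitochondrial age as a proportion of the expected time to
    fixation; theta = N * nu > 0 is the scaled per-base mutation rate; N is
    only used to convert theta back to a per-base rate.
    """

    W: float
    theta: float
    N: int = 1000
    floor: float = 0.10
    bins: int = 20
    homoplasmy_cut: float = 0.95
    L: int = DEFAULT_L
    reference_N: int = DEFAULT_REFERENCE_N

    def __post_init__(self) -> None:
        if self.W < 0:
            raise ValueError("W must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.N < 2 or self.reference_N < 2:
            raise ValueError("copy numbers must be at least 2")


@dataclass
class PosteriorFit:
    """Grid posterior over (W, Theta) with MAP point and credible intervals."""

    map_W: float
    map_theta: float
    ci_W: tuple[float, float]
    ci_theta: tuple[float, float]
    samples_W: np.ndarray
    samples_theta: np.ndarray
    log_evidence: float
    grid_W: np.ndarray = field(repr=False)
    grid_theta: np.ndarray = field(repr=False)
    log_posterior: np.ndarray = field(repr=False)
    diagnostics: dict = field(default_factory=dict)

    @property
    def map_params(self) -> tuple[float, float]:
        return self.map_W, self.map_theta


@lru_cache(maxsize=32)
def _transient_spectra(N: int, event_counts: tuple[int, ...]) -> np.ndarray:
    """Expected per-state occupancy of the marginal Moran chain, unit influx.

    Propagates S <- S P + e_1 per event, where P is the tridiagonal
    transition kernel with off-diagonals q_k = k(N-k)/N^2, state 0 is
    dropped (loss) and state N accumulates (fixation).  Returns an array of
    shape (len(event_counts), N+1): entry [i, k] is the expected number of
    mutations at copy number k after event_counts[i] events when one new
    mutation enters at copy number 1 per event; entry [i, N] is the expected
    fixed-mutation count.
    """
    ks = np.arange(0, N + 1, dtype=float)
    q = ks * (N - ks) / N**2  # q[0] = q[N] = 0
    S = np.zeros(N + 1)
    out = np.empty((len(event_counts), N + 1))
    done = 0
    for ev in range(event_counts[-1] + 1):
        while done < len(event_counts) and event_counts[done] == ev:
            out[done] = S
            done += 1
        if done == len(event_counts):
            break
        flow = S * q  # probability mass moving off each segregating state
        S[1 : N - 1] += -2.0 * flow[1 : N - 1] + flow[2:N]
        S[2:N] += flow[1 : N - 1]
        S[N - 1] -= 2.0 * flow[N - 1]
        S[N] += flow[N - 1]
        S[1] += 1.0  # unit influx of fresh single-copy mutations
    return out


def _bin_edges(floor: float, cut: float, bins: int) -> np.ndarray:
    return np.append(np.linspace(floor, cut, bins + 1), 1.0)


def _bin_state_masses(
    spectrum: np.ndarray, N: int, floor: float, cut: float, bins: int
) -> tuple[np.ndarray, float]:
    """Fold a per-state spectrum into cSFS bins.

    Each segregating state k is spread as a uniform block of width 1/N
    centred on k/N, which keeps the binning consistent across reference copy
    numbers (no aliasing between the state grid and the bin grid); the part
    of a block above ``cut`` joins the fixed mutations in the terminal
    homoplasmic bin.  Returns (per-bin expected counts, total expected count
    above the floor).
    """
    seg = spectrum[1:N]
    lo = (np.arange(1, N) - 0.5) / N  # block boundaries per state
    hi = (np.arange(1, N) + 0.5) / N
    edges = np.append(np.linspace(floor, cut, bins + 1), 1.0)
    out = np.zeros(bins + 1)
    for b in range(bins + 1):
        overlap = np.clip(
            np.minimum(hi, edges[b + 1]) - np.maximum(lo, edges[b]), 0.0, None
        )
        out[b] = (seg * overlap * N).sum()
    out[-1] += spectrum[N]
    return out, float(out.sum())


def expected_csfs(
    params: CoalescentParams,
    backend: str = "matrix",
    n_cells: int = 4000,
    seed: int = 0,
) -> dict:
    """Expected cryptic SFS at scaled age W, per cell.

    Returns a dict with ``bin_edges``, normalized ``bin_probs`` (terminal bin
    homoplasmic), ``expected_count`` of detectable (h > floor) mutations per
    cell, ``expected_homoplasmic`` per cell, and an ``empty`` flag for W = 0.
    The default backend propagates the exact marginal Moran chain at
    ``reference_N``; ``backend="moran"`` uses a seed-fixed forward ensemble.
    """
    edges = _bin_edges(params.floor, params.homoplasmy_cut, params.bins)
    if params.W == 0:
        return {
            "bin_edges": edges,
            "bin_probs": np.zeros(params.bins + 1),
            "expected_count": 0.0,
            "expected_homoplasmic": 0.0,
            "empty": True,
        }
    N = params.reference_N
    if backend == "matrix":
        n_events = int(round(params.W * fixation_timescale_events(N)))
        spectrum = _transient_spectra(N, (n_events,))[0].copy()
        spectrum *= params.L * params.theta / N  # influx per event = L*nu_ref
        masses, total = _bin_state_masses(
            spectrum, N, params.floor, params.homoplasmy_cut, params.bins
        )
        homo = masses[-1]
    elif backend == "moran":
        # forward ensemble at the reference N; theta fixes nu = theta / N
        moran = MoranParams(
            N=N, t_half=1.0, nu=params.theta / N, L_mtDNA=params.L, seed=seed
        )
        age_years = params.W * fixation_timescale_events(N) / (N / moran.t_half * math.log(2))
        freqs, _, fixed = ensemble_frequencies(moran, n_cells, age_years, seed=seed)
        spectrum = np.zeros(N + 1)
        states = np.rint(freqs * N).astype(int)
        np.add.at(spectrum, states, 1.0)
        spectrum[N] += fixed.sum()
        spectrum /= n_cells
        masses, total = _bin_state_masses(
            spectrum, N, params.floor, params.homoplasmy_cut, params.bins
        )
        homo = float(masses[-1])
    else:
        raise ValueError(f"unknown backend {backend!r}")
    probs = masses / total if total > 0 else np.zeros_like(masses)
    return {
        "bin_edges": edges,
        "bin_probs": probs,
        "expected_count": total,
        "expected_homoplasmic": homo,
        "empty": total == 0,
    }


def _bin_observations(
    obs: np.ndarray, floor: float, bins: int, homoplasmy_cut: float
) -> np.ndarray:
    counts = np.zeros(bins + 1, dtype=int)
    homo = obs >= homoplasmy_cut
    counts[-1] = int(homo.sum())
    seg_edges = np.linspace(floor, homoplasmy_cut, bins + 1)
    counts[:-1], _ = np.histogram(obs[~homo], bins=seg_edges)
    return counts


def log_likelihood(
    observed,
    n_cells: int,
    params: CoalescentParams,
    backend: str = "matrix",
) -> float:
    """Multinomial-bin x Poisson-count log-likelihood of a donor's cSFS.

    The observed heteroplasmies (all strictly above the detection floor) are
    binned and scored against the expected spectrum shape; the total count is
    Poisson with mean n_cells times the expected per-cell count, which scales
    linearly in Theta.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size and obs.min() <= params.floor:
        raise ValueError(
            "observations at or below the detection floor; filter upstream"
        )
    exp = expected_csfs(params, backend=backend)
    mean_total = n_cells * exp["expected_count"]
    total = obs.size
    if total == 0:
        return float(stats.poisson.logpmf(0, mean_total))
    if exp["empty"]:
        return -np.inf
    probs = np.clip(exp["bin_probs"], 1e-300, None)
    probs /= probs.sum()
    counts = _bin_observations(obs, params.floor, params.bins, params.homoplasmy_cut)
    ll_shape = float(
        special.gammaln(total + 1)
        - special.gammaln(counts + 1).sum()
        + (counts * np.log(probs)).sum()
    )
    ll_count = float(stats.poisson.logpmf(total, mean_total))
    return ll_shape + ll_count


def _default_priors() -> dict:
    return {
        "W_max": 3.0,
        "theta_bounds": (1e-7, 1e-2),
        "n_W": 121,
        "n_theta": 121,
    }


def fit_donor(
    observed,
    n_cells: int,
    priors: dict | None = None,
    seed: int = 0,
    floor: float = 0.10,
    bins: int = 20,
    homoplasmy_cut: float = 0.95,
    reference_N: int = DEFAULT_REFERENCE_N,
    L: int = DEFAULT_L,
    n_samples: int = 4000,
) -> PosteriorFit:
    """Posterior over (W, Theta) for one donor's cryptic heteroplasmies.

    Dense-grid evaluation under a uniform prior on W over [0, W_max] and a
    log-uniform prior on Theta; MAP with ties broken toward smaller W;
    central 95% credible intervals from posterior samples.  Deterministic
    given ``seed``.
    """
    pr = _default_priors()
    if priors:
        pr.update(priors)
    obs = np.asarray(observed, dtype=float)
    grid_W = np.linspace(0.0, pr["W_max"], pr["n_W"])
    lo, hi = pr["theta_bounds"]
    grid_theta = np.geomspace(lo, hi, pr["n_theta"])

    # precompute spectrum shape and unit-theta counts along the W grid
    theta_ref = grid_theta[0]
    N = reference_N
    events = tuple(
        int(round(w * fixation_timescale_events(N))) for w in grid_W
    )
    spectra = _transient_spectra(N, tuple(sorted(set(events))))
    ev_index = {e: i for i, e in enumerate(sorted(set(events)))}

    total = obs.size
    if total and obs.min() <= floor:
        raise ValueError("observations at or below the detection floor")
    counts = (
        _bin_observations(obs, floor, bins, homoplasmy_cut) if total else None
    )
    log_post = np.full((grid_W.size, grid_theta.size), -np.inf)
    ratio = grid_theta / theta_ref
    for i, w in enumerate(grid_W):
        spectrum = spectra[ev_index[events[i]]].copy()
        spectrum *= L * theta_ref / N
        masses, c_ref = _bin_state_masses(spectrum, N, floor, homoplasmy_cut, bins)
        if c_ref == 0:
            if total == 0:
                log_post[i, :] = stats.poisson.logpmf(0, 0.0)
            continue
        if total:
            probs = np.clip(masses / c_ref, 1e-300, None)
            probs /= probs.sum()
            ll_shape = float(
                special.gammaln(total + 1)
                - special.gammaln(counts + 1).sum()
                + (counts * np.log(probs)).sum()
            )
        else:
            ll_shape = 0.0
        mean_totals = n_cells * c_ref * ratio
        ll_count = stats.poisson.logpmf(total, mean_totals)
        log_post[i, :] = ll_shape + ll_count

    # flat priors on the grid (uniform in W, uniform in log theta)
    log_norm = special.logsumexp(log_post)
    post = np.exp(log_post - log_norm)
    post /= post.sum()

    # MAP with ties toward smaller W, then smaller theta
    best = np.argwhere(log_post == log_post.max())
    bi, bj = min(map(tuple, best))
    map_W, map_theta = float(grid_W[bi]), float(grid_theta[bj])

    rng = np.random.default_rng(seed)
    flat = post.ravel()
    draw = rng.choice(flat.size, size=n_samples, p=flat)
    wi, tj = np.unravel_index(draw, post.shape)
    dW = grid_W[1] - grid_W[0]
    dlt = math.log(grid_theta[1] / grid_theta[0])
    samples_W = grid_W[wi] + rng.uniform(-0.5, 0.5, n_samples) * dW
    samples_W = np.clip(samples_W, 0.0, pr["W_max"])
    samples_theta = grid_theta[tj] * np.exp(
        rng.uniform(-0.5, 0.5, n_samples) * dlt
    )
    ci_W = tuple(np.quantile(samples_W, [0.025, 0.975]))
    ci_theta = tuple(np.quantile(samples_theta, [0.025, 0.975]))
    return PosteriorFit(
        map_W=map_W,
        map_theta=map_theta,
        ci_W=(float(ci_W[0]), float(ci_W[1])),
        ci_theta=(float(ci_theta[0]), float(ci_theta[1])),
        samples_W=samples_W,
        samples_theta=samples_theta,
        log_evidence=float(
            log_norm - math.log(grid_W.size * grid_theta.size)
        ),
        grid_W=grid_W,
        grid_theta=grid_theta,
        log_posterior=log_post,
        diagnostics={
            "n_observations": int(total),
            "n_cells": int(n_cells),
            "grid_shape": log_post.shape,
            "reference_N": N,
        },
    )


def rate_from_theta(theta: float, N: int) -> float:
    """Per-base per-replication mutation rate nu = Theta / N."""
    if N <= 0:
        raise ValueError("N must be positive")
    return theta / N


def theta_from_rate(nu: float, N: int) -> float:
    """Scaled mutation rate Theta = N * nu."""
    if N <= 0:
        raise ValueError("N must be positive")
    return nu * N


def predict_curves(
    map_params: tuple[float, float],
    N: int,
    t_half: float,
    ages,
    thresholds,
    floor: float = 0.10,
    homoplasmy_cut: float = 0.95,
    L: int = DEFAULT_L,
    reference_N: int = DEFAULT_REFERENCE_N,
    smooth_sigma: float = 2.0,
) -> dict:
    """Fig.-2-style prediction curves from a fitted (W, Theta).

    ``ages`` are chronological years, converted to scaled time with the
    fixation timescale (N-1) t_half / ln 2.  Returns the expected
    near-homoplasmic mutation count per cell versus age, its smoothed first
    and second derivatives (speed and acceleration of mitochondrial ageing),
    and the fraction of cells expected to carry at least one mutation at or
    above each threshold (1 - exp(-expected count), by Poisson statistics).
    """
    W_map, theta = map_params
    ages = np.asarray(ages, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    t_fix_years = (N - 1) * t_half / math.log(2)
    Ws = ages / t_fix_years
    Nr = reference_N
    events = tuple(int(round(w * fixation_timescale_events(Nr))) for w in Ws)
    uniq = tuple(sorted(set(events)))
    spectra = _transient_spectra(Nr, uniq)
    ev_index = {e: i for i, e in enumerate(uniq)}
    influx = L * theta / Nr
    homo_count = np.zeros(ages.size)
    frac_above = np.zeros((ages.size, thresholds.size))
    h_states = np.arange(1, Nr) / Nr
    for i in range(ages.size):
        spectrum = spectra[ev_index[events[i]]] * influx
        seg = spectrum[1:Nr]
        homo_count[i] = seg[h_states >= homoplasmy_cut].sum() + spectrum[Nr]
        for j, thr in enumerate(thresholds):
            if thr >= 1.0:
                expect = spectrum[Nr]
            else:
                expect = seg[h_states >= max(thr, floor)].sum() + spectrum[Nr]
            frac_above[i, j] = 1.0 - math.exp(-expect)
    def _smooth(y):
        if smooth_sigma > 0:
            return ndimage.gaussian_filter1d(y, smooth_sigma, mode="nearest")
        return y

    speed = np.gradient(_smooth(homo_count), ages)
    accel = np.gradient(_smooth(speed), ages)
    return {
        "ages": ages,
        "W": Ws,
        "homoplasmic_per_cell": homo_count,
        "speed": speed,
        "acceleration": accel,
        "thresholds": thresholds,
        "fraction_above": frac_above,
    }
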