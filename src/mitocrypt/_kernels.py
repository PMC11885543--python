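"""Numba kernels for the neutral Moran birth-death process.

The population of one cell is N mtDNA molecules.  Per birth-death event a
mutation segregating at copy number k moves to k+1 or k-1 each with
probability k(N-k)/N^2 and otherwise stays put, so each mutation's copy
number is a lazy symmetric random walk on {0..N} absorbing at 0 (loss) and
N (fixation).  The kernels below simulate that marginal chain directly,
skipping the no-change events with geometric waiting times.  Mutations are
statistically exchangeable and neutral, so the marginal chain reproduces
the site frequency spectrum of the full per-molecule process exactly; only
cross-mutation linkage is dropped (the per-molecule reference simulator in
``moran_sim`` keeps it, for small-N cross-checks).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "evolve_count",
    "fixation_trials",
    "ensemble_freqs",
    "trajectory_snapshots",
]


@njit(cache=True)
def _geometric(p: float) -> int:
    # number of Bernoulli(p) trials up to and including the first success
    u = np.random.random()
    return 1 + int(np.floor(np.log1p(-u) / np.log1p(-p)))


@njit(cache=True)
def evolve_count(k: int, N: int, n_events: int) -> int:
    """Advance one mutation's copy number through ``n_events`` Moran events."""
    remaining = n_events
    while 0 < k < N and remaining > 0:
        p_change = 2.0 * k * (N - k) / (N * N)
        gap = _geometric(p_change)
        if gap > remaining:
            return k
        remaining -= gap
        if np.random.random() < 0.5:
            k += 1
        else:
            k -= 1
    return k


@njit(cache=True)
def fixation_trials(N: int, n_trials: int, seed: int) -> int:
    """Track ``n_trials`` fresh single-copy mutations to absorption.

    Returns the number that fixed (reached copy number N).  The neutral
    expectation is ``n_trials / N``.
    """
    np.random.seed(seed)
    fixed = 0
    for _ in range(n_trials):
        k = 1
        while 0 < k < N:
            if np.random.random() < 0.5:
                k += 1
            else:
                k -= 1
        if k == N:
            fixed += 1
    return fixed


@njit(cache=True)
def _evolve_unbounded_events(k: int, N: int, lam: float) -> int:
    """Evolve through a Poisson(lam) number of events without materializing it.

    Draws the event count first; kept separate so callers can reuse it.
    """
    n_ev = np.random.poisson(lam)
    return evolve_count(k, N, n_ev)


@njit(cache=True)
def ensemble_freqs(
    n_cells: int,
    N: int,
    mean_events: float,
    influx_per_event: float,
    seed: int,
):
    """Simulate ``n_cells`` independent cells for ``mean_events`` expected events.

    Each cell starts mutation-free.  New mutations enter at
    ``influx_per_event`` expected mutations per event (the per-genome
    replication error rate L*nu) and each evolves through the events
    remaining after its birth.

    Returns ``(freqs, cell_index, fixed_counts)``: segregating frequencies
    pooled over cells with their cell of origin, plus the per-cell count of
    fixed (homoplasmic) mutations.
    """
    np.random.seed(seed)
    cap = 64
    freqs = np.empty(cap, dtype=np.float64)
    cells = np.empty(cap, dtype=np.int64)
    fixed = np.zeros(n_cells, dtype=np.int64)
    m = 0
    for c in range(n_cells):
        n_ev = np.random.poisson(mean_events)
        n_mut = np.random.poisson(n_ev * influx_per_event)
        for _ in range(n_mut):
            birth = np.random.randint(1, n_ev + 1)
            k = evolve_count(1, N, n_ev - birth)
            if k == N:
                fixed[c] += 1
            elif k > 0:
                if m == cap:
                    cap *= 2
                    nf = np.empty(cap, dtype=np.float64)
                    nc = np.empty(cap, dtype=np.int64)
                    nf[:m] = freqs[:m]
                    nc[:m] = cells[:m]
                    freqs = nf
                    cells = nc
                freqs[m] = k / N
                cells[m] = c
                m += 1
    return freqs[:m].copy(), cells[:m].copy(), fixed


@njit(cache=True)
def trajectory_snapshots(
    N: int,
    events_per_year: float,
    influx_per_event: float,
    obs_times: np.ndarray,
    seed: int,
):
    """One cell observed at ``obs_times`` (years, sorted ascending).

    Returns ``(counts, obs_index, fixed_at_obs)``: segregating copy numbers
    with the snapshot they belong to, and the running fixed-mutation count.
    """
    np.random.seed(seed)
    n_obs = obs_times.shape[0]
    fixed_at_obs = np.zeros(n_obs, dtype=np.int64)

    cap_active = 64
    active = np.empty(cap_active, dtype=np.int64)
    n_active = 0
    n_fixed = 0

    cap_out = 64
    out_counts = np.empty(cap_out, dtype=np.int64)
    out_obs = np.empty(cap_out, dtype=np.int64)
    n_out = 0

    t_prev = 0.0
    for i in range(n_obs):
        dt = obs_times[i] - t_prev
        if dt > 0.0:
            # existing mutations advance through the window
            keep = 0
            for j in range(n_active):
                k = _evolve_unbounded_events(active[j], N, events_per_year * dt)
                if k == N:
                    n_fixed += 1
                elif k > 0:
                    active[keep] = k
                    keep += 1
            n_active = keep
            # new mutations born uniformly in the window
            n_births = np.random.poisson(events_per_year * influx_per_event * dt)
            for _ in range(n_births):
                t_b = t_prev + dt * np.random.random()
                k = _evolve_unbounded_events(
                    1, N, events_per_year * (obs_times[i] - t_b)
                )
                if k == N:
                    n_fixed += 1
                elif k > 0:
                    if n_active == cap_active:
                        cap_active *= 2
                        na = np.empty(cap_active, dtype=np.int64)
                        na[:n_active] = active[:n_active]
                        active = na
                    active[n_active] = k
                    n_active += 1
        fixed_at_obs[i] = n_fixed
        for j in range(n_active):
            if n_out == cap_out:
                cap_out *= 2
                nc = np.empty(cap_out, dtype=np.int64)
                no = np.empty(cap_out, dtype=np.int64)
                nc[:n_out] = out_counts[:n_out]
                no[:n_out] = out_obs[:n_out]
                out_counts = nc
                out_obs = no
            out_counts[n_out] = active[j]
            out_obs[n_out] = i
            n_out += 1
        t_prev = obs_times[i]
    return out_counts[:n_out].copy(), out_obs[:n_out].copy(), fixed_at_obs
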