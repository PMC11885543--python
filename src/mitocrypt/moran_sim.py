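"""Forward-in-time Moran model of the mtDNA population of a post-mitotic cell.

A cell holds a constant population of N mtDNA molecules.  Birth-death events
arrive with exponential waiting times of rate N*ln(2)/t_half (each molecule
replicates on average once per half-life); at each event one molecule is
chosen uniformly to replicate and one uniformly to die (the replicator may
itself die).  Each replication adds m ~ Binomial(L_mtDNA, nu) brand-new
mutations to the daughter molecule — the infinite-sites assumption, with no
back mutation.  The population starts mutation-free, so the site frequency
spectrum is out of equilibrium for times short compared with the fixation
timescale.

Two implementations are provided: the production simulator evolves each
mutation's copy number through its exact marginal Moran chain (fast,
arbitrary N); :func:`simulate_cell_molecular` keeps literal per-molecule
genomes and is used as the small-N oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import (
    ensemble_freqs,
    fixation_trials,
    trajectory_snapshots,
)
from .sfs_stats import CrypticSFS, csfs_from_values

__all__ = [
    "MoranParams",
    "MutationTrajectory",
    "events_per_year",
    "fixation_timescale_events",
    "fixation_timescale_years",
    "simulate_cell",
    "simulate_cell_molecular",
    "fixation_probability",
    "ensemble_csfs",
    "ensemble_frequencies",
    "summarize_ages",
    "pair_coalescence_oracle",
]

LN2 = math.log(2.0)


@dataclass
class MoranParams:
    """Configuration of the sub-cellular Moran process.

    N: mtDNA copy number per cell.  t_half: mtDNA half-life in years (sets
    the turnover clock).  nu: mutation probability per base per replication.
    L_mtDNA: genome length in bases.  seed: master seed for all randomness.
    """

    N: int = 1000
    t_half: float = 1.0
    nu: float = 4.6e-8
    L_mtDNA: int = 16569
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.t_half <= 0:
            raise ValueError("t_half must be positive")
        if not 0 <= self.nu <= 1e-4:
            raise ValueError("nu must lie in [0, 1e-4]")
        if self.L_mtDNA <= 0:
            raise ValueError("L_mtDNA must be positive")

    @property
    def influx_per_event(self) -> float:
        """Expected new mutations per replication, L_mtDNA * nu."""
        return self.L_mtDNA * self.nu


@dataclass
class MutationTrajectory:
    """Observation times with the segregating frequencies and fixed counts."""

    obs_times: np.ndarray
    frequencies: list  # list of arrays, one per observation time
    fixed_counts: np.ndarray
    params: MoranParams = field(repr=False, default=None)


def events_per_year(params: MoranParams) -> float:
    return params.N * LN2 / params.t_half


def fixation_timescale_events(N: int) -> float:
    """Expected events until the population finds a single common ancestor.

    Kingman scaling: pairwise lineages coalesce after N^2/2 events on
    average, and the full genealogy of N lineages takes 2(1 - 1/N) pair
    timescales, i.e. N(N-1) events.  This is the normalizing constant behind
    the dimensionless mitochondrial age W.
    """
    return float(N * (N - 1))


def fixation_timescale_years(params: MoranParams) -> float:
    """The fixation timescale in years: (N-1) * t_half / ln 2."""
    return fixation_timescale_events(params.N) / events_per_year(params)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % np.uint32(2**31 - 1)


def simulate_cell(
    params: MoranParams,
    duration_years: float,
    obs_times=None,
) -> MutationTrajectory:
    """Simulate one cell from a mutation-free state for ``duration_years``.

    ``obs_times`` (within [0, duration]) defaults to the single endpoint.
    Deterministic given ``params.seed``.
    """
    if duration_years < 0:
        raise ValueError("duration must be non-negative")
    if obs_times is None:
        obs_times = [duration_years]
    obs = np.asarray(sorted(obs_times), dtype=float)
    if obs.size and (obs[0] < 0 or obs[-1] > duration_years + 1e-12):
        raise ValueError("obs_times must lie within [0, duration]")
    seed = int(_child_seeds(params.seed, 1)[0])
    if params.nu == 0.0 or duration_years == 0.0:
        return MutationTrajectory(
            obs_times=obs,
            frequencies=[np.empty(0) for _ in obs],
            fixed_counts=np.zeros(obs.size, dtype=int),
            params=params,
        )
    counts, obs_idx, fixed = trajectory_snapshots(
        params.N,
        events_per_year(params),
        params.influx_per_event,
        obs,
        seed,
    )
    freqs = [counts[obs_idx == i] / params.N for i in range(obs.size)]
    return MutationTrajectory(
        obs_times=obs, frequencies=freqs, fixed_counts=fixed, params=params
    )


def simulate_cell_molecular(
    params: MoranParams,
    duration_years: float,
    obs_times=None,
    rng: np.random.Generator | None = None,
) -> MutationTrajectory:
    """Literal per-molecule reference implementation (small N only).

    Each molecule is a frozenset of mutation identifiers.  At each event the
    parent is drawn uniformly, the daughter receives the parent's mutations
    plus m ~ Binomial(L, nu) fresh ones, and the victim is drawn uniformly
    from the N pre-event molecules (so the parent itself can die).  Keeps
    full cross-mutation linkage; used to validate the marginal-chain
    simulator.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if obs_times is None:
        obs_times = [duration_years]
    obs = np.asarray(sorted(obs_times), dtype=float)
    rate = events_per_year(params)
    population: list[frozenset] = [frozenset() for _ in range(params.N)]
    next_id = 0
    t = 0.0
    results: list[np.ndarray] = []
    fixed_counts = []
    fixed_total = 0

    def snapshot():
        nonlocal fixed_total, population
        tallies: dict[int, int] = {}
        for genome in population:
            for mut in genome:
                tallies[mut] = tallies.get(mut, 0) + 1
        fixed_now = [m for m, c in tallies.items() if c == params.N]
        if fixed_now:
            # fold fixed mutations into the running count and strip them so
            # identifiers are never re-counted (infinite sites bookkeeping)
            fixed_total += len(fixed_now)
            strip = frozenset(fixed_now)
            population = [g - strip for g in population]
            for m in fixed_now:
                del tallies[m]
        results.append(
            np.array([c for c in tallies.values()], dtype=float) / params.N
        )
        fixed_counts.append(fixed_total)

    obs_i = 0
    while obs_i < obs.size:
        gap = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        while obs_i < obs.size and t + gap > obs[obs_i]:
            snapshot()
            obs_i += 1
        if obs_i >= obs.size:
            break
        t += gap
        parent = rng.integers(params.N)
        victim = rng.integers(params.N)
        m = rng.binomial(params.L_mtDNA, params.nu)
        daughter = population[parent]
        if m:
            daughter = daughter | frozenset(range(next_id, next_id + m))
            next_id += m
        population[victim] = daughter
    return MutationTrajectory(
        obs_times=obs,
        frequencies=results,
        fixed_counts=np.asarray(fixed_counts, dtype=int),
        params=params,
    )


def fixation_probability(N: int, n_trials: int, seed: int = 0) -> float:
    """Monte-Carlo fixation fraction of a fresh single-copy neutral mutation.

    The neutral expectation is 1/N.
    """
    seed = int(_child_seeds(seed, 1)[0])
    return fixation_trials(N, n_trials, seed) / n_trials


def ensemble_frequencies(
    params: MoranParams,
    n_cells: int,
    age_years: float,
    seed: int | None = None,
):
    """Pooled (frequencies, cell_index, fixed_counts) over an ensemble of cells."""
    if seed is None:
        seed = params.seed
    seed = int(_child_seeds(seed, 1)[0])
    mean_events = events_per_year(params) * age_years
    return ensemble_freqs(
        n_cells, params.N, mean_events, params.influx_per_event, seed
    )


def ensemble_csfs(
    params: MoranParams,
    n_cells: int,
    age_years: float,
    floor: float = 0.10,
    bins: int = 20,
    homoplasmy_cut: float = 0.95,
    seed: int | None = None,
) -> CrypticSFS:
    """Pool segregating and fixed mutation frequencies of an ensemble of cells
    into a cryptic site frequency spectrum (fixed mutations enter at h = 1)."""
    freqs, _, fixed = ensemble_frequencies(params, n_cells, age_years, seed)
    pooled = np.concatenate([freqs, np.ones(int(fixed.sum()))])
    pooled = pooled[pooled > floor]
    return csfs_from_values(
        pooled,
        donor=f"moran_age{age_years:g}",
        floor=floor,
        bins=bins,
        homoplasmy_cut=homoplasmy_cut,
        n_cells=n_cells,
    )


def summarize_ages(
    params: MoranParams,
    ages,
    thresholds,
    n_cells: int = 500,
) -> dict:
    """Ensemble age curves: threshold-crossing fractions and fixed counts.

    For each age, the fraction of cells carrying at least one mutation at
    heteroplasmy >= threshold (fixed mutations count as h = 1) with binomial
    Monte-Carlo standard errors, and the mean fixed-mutation count per cell
    with its standard error.
    """
    ages = np.asarray(sorted(ages), dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    seeds = _child_seeds(params.seed, ages.size)
    frac = np.zeros((ages.size, thresholds.size))
    frac_se = np.zeros_like(frac)
    fixed_mean = np.zeros(ages.size)
    fixed_se = np.zeros(ages.size)
    for i, age in enumerate(ages):
        freqs, cells, fixed = ensemble_frequencies(
            params, n_cells, age, seed=int(seeds[i])
        )
        per_cell_max = np.zeros(n_cells)
        np.maximum.at(per_cell_max, cells, freqs)
        per_cell_max[fixed > 0] = 1.0
        for j, thr in enumerate(thresholds):
            hit = per_cell_max >= thr if thr > 0 else per_cell_max > 0
            p = hit.mean()
            frac[i, j] = p
            frac_se[i, j] = math.sqrt(p * (1 - p) / n_cells)
        fixed_mean[i] = fixed.mean()
        fixed_se[i] = fixed.std(ddof=1) / math.sqrt(n_cells) if n_cells > 1 else 0.0
    return {
        "ages": ages,
        "thresholds": thresholds,
        "fraction_above": frac,
        "fraction_above_se": frac_se,
        "mean_fixed": fixed_mean,
        "mean_fixed_se": fixed_se,
    }


def pair_coalescence_oracle(
    params: MoranParams,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Empirical mean time for two mtDNA lineages to find a common ancestor.

    Backward in time, a pair of lineages merges at a given event iff one is
    the fresh daughter and the other its parent: probability 2/N^2 per event.
    The waiting time is therefore a Geometric(2/N^2) number of events, each
    an Exp(N ln2 / t_half) gap; the mean is N * t_half / (2 ln2) years,
    proportional to both copy number and half-life.
    """
    if n_reps < 2:
        raise ValueError("n_reps too small")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    p = 2.0 / params.N**2
    n_events = rng.geometric(p, size=n_reps)
    times = rng.gamma(shape=n_events, scale=1.0 / events_per_year(params))
    return {
        "mean_years": float(times.mean()),
        "se_years": float(times.std(ddof=1) / math.sqrt(n_reps)),
        "mean_events": float(n_events.mean()),
    }
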