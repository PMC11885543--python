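"""Synthetic multi-donor single-cell cohorts with known mutational ground truth.

Each donor is a set of post-mitotic cells whose mtDNA populations evolved
independently under the Moran model for the donor's age, so the true cryptic
mutations carry genuine coalescent structure.  On top of the cryptic layer
the generator plants donor-level *shared* variants (copied into every cell
with binomial down-sampling of the donor frequency, a stand-in for
developmental variants) and *common* variants present across donors (a
stand-in for inherited/RNA variants).  Truth is rendered into noisy base
counts with negative-binomial depth, site-specific coverage multipliers, and
uniform per-read miscalls, mimicking the coverage unevenness of single-cell
protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .moran_sim import MoranParams, ensemble_frequencies
from .variant_calling import BASES

__all__ = [
    "CohortConfig",
    "TrueCohort",
    "generate_cohort",
    "render_base_counts",
    "make_annotation_table",
]


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_donors: int
    ages_years: tuple
    cells_per_donor: int
    moran: MoranParams = field(default_factory=MoranParams)
    shared_variant_rate: float = 2.0  # expected planted shared variants/donor
    common_variant_sites: tuple = ()
    mean_depth: float = 2000.0
    depth_dispersion: float = 5.0  # negative-binomial size parameter
    site_depth_sigma: float = 0.5  # lognormal spread of per-site coverage
    error_rate: float = 1e-3
    genome_length: int = 16569
    species: str = "human"
    seed: int = 0

    def __post_init__(self) -> None:
        self.ages_years = tuple(float(a) for a in self.ages_years)
        if len(self.ages_years) != self.n_donors:
            raise ValueError("ages_years length must equal n_donors")
        if any(a < 0 for a in self.ages_years):
            raise ValueError("ages must be non-negative")
        if not 0 <= self.error_rate <= 0.01:
            raise ValueError("error_rate must lie in [0, 0.01]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        sites = tuple(int(s) for s in self.common_variant_sites)
        if len(set(sites)) != len(sites):
            raise ValueError("duplicate common_variant_sites")
        if any(not 1 <= s <= self.genome_length for s in sites):
            raise ValueError("common_variant_sites outside the genome")
        self.common_variant_sites = sites


@dataclass
class TrueCohort:
    """Ground-truth cohort: cell metadata, mutations, and the reference."""

    cells: pd.DataFrame  # cell, donor, age_years, species
    mutations: pd.DataFrame  # cell, donor, site, ref, alt, true_freq, origin
    reference: pd.Series  # 1-based position -> reference base
    config: CohortConfig


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[rng.integers(3)]


def generate_cohort(config: CohortConfig) -> TrueCohort:
    """Evolve every cell under the Moran model and plant shared/common variants.

    Cryptic mutations receive cohort-wide unique sites (infinite sites), so a
    cryptic mutation appears in exactly one cell of its donor by
    construction; planted sites are excluded from the cryptic site pool, so
    collisions cannot occur.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ref_seq = pd.Series(
        rng.choice(BASES, size=config.genome_length),
        index=np.arange(1, config.genome_length + 1),
    )
    planted = set(config.common_variant_sites)
    cell_rows = []
    mut_rows = []
    free_sites = np.setdiff1d(
        np.arange(1, config.genome_length + 1),
        np.fromiter(planted, dtype=int, count=len(planted)),
    )
    rng.shuffle(free_sites)
    next_free = 0

    def take_sites(n: int) -> np.ndarray:
        nonlocal next_free
        if next_free + n > free_sites.size:
            raise RuntimeError("genome exhausted; too many mutations for L")
        out = free_sites[next_free : next_free + n]
        next_free += n
        return out

    donor_seeds = np.random.SeedSequence(config.seed).spawn(config.n_donors)
    common_alt = {
        s: _alt_base(rng, ref_seq.loc[s]) for s in config.common_variant_sites
    }
    for d in range(config.n_donors):
        donor = f"donor{d}"
        age = config.ages_years[d]
        drng = np.random.default_rng(donor_seeds[d])
        cells = [f"{donor}_cell{c}" for c in range(config.cells_per_donor)]
        for c, cell in enumerate(cells):
            cell_rows.append(
                {
                    "cell": cell,
                    "donor": donor,
                    "age_years": age,
                    "species": config.species,
                }
            )
        # cryptic layer: independent Moran realizations of length `age`
        moran = MoranParams(
            N=config.moran.N,
            t_half=config.moran.t_half,
            nu=config.moran.nu,
            L_mtDNA=config.moran.L_mtDNA,
            seed=int(drng.integers(2**31 - 1)),
        )
        freqs, cell_idx, fixed = ensemble_frequencies(
            moran, config.cells_per_donor, age
        )
        all_freqs = np.concatenate(
            [freqs, np.ones(int(fixed.sum()))]
        )
        all_cells = np.concatenate(
            [cell_idx, np.repeat(np.arange(config.cells_per_donor), fixed)]
        )
        sites = take_sites(all_freqs.size)
        for f, ci, s in zip(all_freqs, all_cells, sites):
            ref = ref_seq.loc[s]
            mut_rows.append(
                {
                    "cell": cells[int(ci)],
                    "donor": donor,
                    "site": int(s),
                    "ref": ref,
                    "alt": _alt_base(drng, ref),
                    "true_freq": float(f),
                    "origin": "cryptic",
                }
            )
        # shared layer: donor-level variants copied into every cell
        n_shared = drng.poisson(config.shared_variant_rate)
        shared_sites = take_sites(n_shared)
        for s in shared_sites:
            ref = ref_seq.loc[s]
            alt = _alt_base(drng, ref)
            f_donor = drng.uniform(0.15, 0.6)
            per_cell = drng.binomial(config.moran.N, f_donor, size=len(cells))
            for cell, k in zip(cells, per_cell):
                if k > 0:
                    mut_rows.append(
                        {
                            "cell": cell,
                            "donor": donor,
                            "site": int(s),
                            "ref": ref,
                            "alt": alt,
                            "true_freq": k / config.moran.N,
                            "origin": "shared",
                        }
                    )
        # common layer: the same (site, alt) planted in every donor
        for s in config.common_variant_sites:
            ref = ref_seq.loc[s]
            f_donor = drng.uniform(0.15, 0.6)
            per_cell = drng.binomial(config.moran.N, f_donor, size=len(cells))
            for cell, k in zip(cells, per_cell):
                if k > 0:
                    mut_rows.append(
                        {
                            "cell": cell,
                            "donor": donor,
                            "site": int(s),
                            "ref": ref,
                            "alt": common_alt[s],
                            "true_freq": k / config.moran.N,
                            "origin": "common",
                        }
                    )
    cells_df = pd.DataFrame(cell_rows)
    muts_df = pd.DataFrame(
        mut_rows,
        columns=["cell", "donor", "site", "ref", "alt", "true_freq", "origin"],
    )
    return TrueCohort(
        cells=cells_df, mutations=muts_df, reference=ref_seq, config=config
    )


def render_base_counts(
    truth: TrueCohort,
    mean_depth: float | None = None,
    depth_dispersion: float | None = None,
    error_rate: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Render ground truth into a noisy long-form base-count matrix.

    Depth at (cell, site) is negative-binomial around ``mean_depth`` times a
    lognormal per-site coverage multiplier shared across cells; alt reads are
    binomial in the true frequency; each read then miscalls with probability
    ``error_rate``, uniformly onto the other three bases.  Parameters default
    to the cohort config.
    """
    cfg = truth.config
    mean_depth = cfg.mean_depth if mean_depth is None else mean_depth
    disp = cfg.depth_dispersion if depth_dispersion is None else depth_dispersion
    err = cfg.error_rate if error_rate is None else error_rate
    if seed is None:
        seed = cfg.seed + 1
    rng = np.random.default_rng(seed)
    L = cfg.genome_length
    positions = np.arange(1, L + 1)
    site_mult = rng.lognormal(
        mean=-0.5 * cfg.site_depth_sigma**2, sigma=cfg.site_depth_sigma, size=L
    )
    site_means = mean_depth * site_mult
    ref_idx = pd.Series(
        pd.Categorical(truth.reference.to_numpy(), categories=BASES).codes,
        index=positions,
    ).to_numpy()
    base_index = {b: i for i, b in enumerate(BASES)}
    muts_by_cell = {
        cell: grp for cell, grp in truth.mutations.groupby("cell")
    }
    frames = []
    for _, cell_row in truth.cells.iterrows():
        cell = cell_row["cell"]
        counts = np.zeros((L, 4), dtype=np.int64)
        p_nb = disp / (disp + site_means)
        depth = rng.negative_binomial(disp, p_nb, size=L)
        counts[positions - 1, ref_idx] = depth
        grp = muts_by_cell.get(cell)
        if grp is not None:
            for _, m in grp.iterrows():
                i = int(m["site"]) - 1
                d = depth[i]
                alt_reads = rng.binomial(d, m["true_freq"])
                counts[i, base_index[m["alt"]]] += alt_reads
                counts[i, base_index[m["ref"]]] -= alt_reads
        if err > 0:
            for b in range(4):
                col = counts[:, b]
                miscalled = rng.binomial(col.clip(min=0), err)
                if miscalled.sum() == 0:
                    continue
                counts[:, b] -= miscalled
                others = [o for o in range(4) if o != b]
                split = rng.multinomial(
                    miscalled, [1 / 3, 1 / 3, 1 / 3]
                )
                for j, o in enumerate(others):
                    counts[:, o] += split[:, j]
        frame = pd.DataFrame(counts, columns=BASES)
        frame.insert(0, "pos", positions)
        frame.insert(0, "donor", cell_row["donor"])
        frame.insert(0, "cell", cell)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def make_annotation_table(
    substitutions: pd.DataFrame,
    proportions=(0.25, 0.35, 0.2, 0.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each (pos, ref, alt) substitution a pathology class.

    ``proportions`` are the probabilities of (synonymous, low, high,
    noncoding) respectively.  Deterministic given ``seed``; duplicate
    (pos, alt) entries are rejected.
    """
    subs = substitutions[["pos", "ref", "alt"]].copy()
    if subs.duplicated(subset=["pos", "alt"]).any():
        raise ValueError("duplicate (pos, alt) substitution entries")
    p = np.asarray(proportions, dtype=float)
    if p.min() < 0 or not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    classes = np.array(["synonymous", "low", "high", "noncoding"])
    subs["class"] = rng.choice(classes, size=len(subs), p=p)
    return subs.reset_index(drop=True)
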