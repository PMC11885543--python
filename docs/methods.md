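# Methods

## The model

Each post-mitotic cell carries a constant population of `N` mtDNA molecules
that turns over by linked birth–death events (the Moran model): waiting
times between events are exponential with rate `N ln2 / t_half`, so each
molecule replicates on average once per half-life `t_half`; at each event a
uniformly chosen molecule is copied and a uniformly chosen molecule dies
(possibly the replicator itself). Each replication introduces
`m ~ Binomial(L_mtDNA, nu)` brand-new mutations on the daughter molecule
(infinite sites, no back mutation), where `nu` is the per-base,
per-replication error rate of the mtDNA polymerase. Cells start
mutation-free, so the distribution of mutant frequencies — the cryptic site
frequency spectrum (cSFS), extended with a terminal homoplasmic class — is
out of equilibrium and evolves over the lifetime: segregating heteroplasmies
approach the stationary neutral shape (expected counts ∝ 1/k at copy number
k), while homoplasmic mutations, which drift cannot remove, accumulate
without bound at the neutral-clock flux `nu · L · ln2 / t_half` per year.

Backward in time the genealogy of the N molecules is a Kingman coalescent:
two lineages merge with probability `2/N²` per event, the whole population
finds its common ancestor after `N(N−1)` events on average, i.e.
`(N−1) t_half / ln2` years. That quantity is the *fixation timescale*; the
dimensionless **mitochondrial age** is

    W = chronological time / fixation timescale,

and the mutation influx enters only through the scaled rate **Θ = N·nu**
(per base; `L·Θ` per genome). In scaled time the normalized cSFS depends on
`(W, Θ)` alone, not on `N` — verified operationally by a total-variation
test between reference copy numbers 30 and 100.

## Simulators

Two implementations of the forward model:

- **Marginal-chain simulator** (production, `moran_sim.simulate_cell`,
  numba kernels). Under neutrality each mutation's copy number is a lazy
  symmetric random walk on {0..N} (±1 each with probability `k(N−k)/N²`
  per event); the kernels skip no-change events with geometric waiting
  times, and each mutation carries an independent Poisson event clock.
  This reproduces the marginal frequency law — hence the expected SFS,
  fixation probability (1/N) and fixation flux — exactly, but drops the
  correlation between mutations riding the same genome. Every first-moment
  quantity used downstream is unaffected; cell-to-cell variance of summary
  statistics is mildly underestimated relative to the fully linked process.
- **Per-molecule simulator** (`simulate_cell_molecular`): literal genomes
  as mutation-id sets, binomial mutation draws per replication. Kept as
  the exact small-N oracle; an ensemble test checks the two agree in mean
  segregating and fixed counts.

`pair_coalescence_oracle` samples the backward pairwise-merge process
directly (geometric number of events, gamma waiting time) and is the
empirical calibration for the fixation timescale; closed forms at N = 2 and
the linear scaling in both N and `t_half` are test oracles.

## Expected spectrum and likelihood

`coalescent_fit.expected_csfs` computes the expected cSFS at scaled age W:

- **matrix backend (default)**: the marginal copy-number law is propagated
  exactly through its tridiagonal transition kernel at a reference copy
  number (default 100) with unit mutation influx per event, for
  `round(W · N(N−1))` events; state N accumulates fixed mutations. This is
  deterministic, smooth in W, and linear in Θ.
- **moran backend**: a seed-fixed forward ensemble, used as the
  ground-truth oracle (backend equivalence: TV < 0.03, measured ≈ 0.01).

Binning: equal-width bins on `(floor, homoplasmy_cut)` plus one terminal
bin for h ≥ `homoplasmy_cut` (default 0.95) and fixed mutations. Each
copy-number state is smeared as a block of width 1/N across bin edges;
point-assignment would alias the state grid against the bin grid and break
the N-independence of the normalized spectrum. The half-block at the
detection floor biases Θ down by ~2%, well inside posterior spread at
desk-scale sample sizes.

The likelihood of a donor's observed cryptic heteroplasmies (all strictly
above the detection floor, mirroring the calling pipeline) is

    multinomial(bin counts | spectrum shape) × Poisson(total | n_cells · E[count per cell]),

where Θ enters only the Poisson mean (neutrality makes the shape Θ-free).
The posterior over (W, Θ) is evaluated on a dense 121×121 grid — uniform
prior on W over [0, 3] fixation times, log-uniform on Θ over [1e-7, 1e-2];
both configurable — with MAP ties broken toward smaller W and central 95%
credible intervals taken from jittered grid samples. Homoplasmic
observations are included in the same likelihood (joint treatment); with no
observations and no cells the posterior reproduces the prior exactly.

`rate_from_theta` converts Θ to a per-base rate via `nu = Θ/N` for an
assumed copy number. `predict_curves` turns a fitted (W, Θ) into
age curves: expected near-homoplasmic mutations per cell, its smoothed
first/second derivatives (speed and acceleration of mitochondrial ageing;
Gaussian smoothing, σ = 2 grid steps, edges unreliable within ~2σ of the
boundary), and threshold-crossing fractions `1 − exp(−E[count ≥ t])`
(Poisson statistics over independent mutations).

## Variant calling conventions

- A position in a cell qualifies when depth strictly exceeds `min_depth`
  (200); a cell is retained with ≥ `min_positions` (200) qualifying
  positions and a log10 qualifying-count within `sigma_mult` (3) SD of the
  cohort mean (computed over cells passing the absolute filter; zero
  variance retains all). All-excluded cohorts raise rather than pass.
- Heteroplasmy is the raw read fraction `h_i = N_i / ΣN_j`; several alt
  bases at one site yield several rows; no read deduplication.
- Classification order: site QC (≥ `min_cells_per_site` well-covered cells
  per donor) → common rule → cryptic test → report floor. *Presence* for
  the donor-sharing and single-cell rules means `h > cryptic_floor` (5%):
  with per-base error ~1e-3 every site shows trace alt reads in every
  donor, so counting raw nonzero reads would classify everything as
  common. Variants in more than `common_donor_count` (3) donors are
  common; a variant above the floor in exactly one cell of its donor is
  cryptic; the rest are shared. Only `h > report_floor` (10% default, 5%
  for low-coverage data) is reported. All floors are strict inequalities.
- Pathology classes come from an annotation table (pos, ref, alt →
  synonymous/low/high/noncoding); unannotated substitutions are "unknown";
  species without pathogenicity scores (mouse, rat, pig) collapse low/high
  to "non-synonymous".
- Base quality ≥ 30 and unique-alignment (NUMT) filtering are applied in
  the alignment ingestion path (`base_counts_from_alignment`); tabular
  base-count input is assumed pre-filtered. Coordinates are 1-based;
  circularity is ignored.

## Synthetic cohorts — what they emulate and what they do not

`synthetic_data.generate_cohort` evolves every cell's cryptic complement
under the Moran model for the donor's age (so true cryptic mutations have
coalescent structure), then plants donor-level *shared* variants (fixed
donor frequency, binomial down-sampling per cell) and cross-donor *common*
variants. Rendering draws per-(cell, site) depth from a negative binomial
around `mean_depth` with lognormal per-site multipliers (transcript-coverage
unevenness), binomial alt reads, and uniform per-read miscalls onto the
other three bases.

Default study conditions (used by tests and the acceptance script): five
donors at 10–80 years, 40 cells per donor, N = 150, `t_half` = 0.25 y,
`nu` = 4e-7, depth ≈ 1500×, error 1e-3. These give a fixation timescale of
~54 years so the age range spans the pre- to post-fixation regimes, with a
handful of detectable cryptic mutations per cell — qualitatively the
situation of a deep full-length scRNA-seq pancreas cohort, at desk scale.

Not emulated: real read alignment artifacts, NUMT contamination, UMI
chemistry, strand bias, batch effects, cell-type structure, any selection
on mutations, mtDNA copy-number variation, or cell turnover. The planted
shared/common scheme is plumbing, not a model of developmental or inherited
variant dynamics. Passing tests therefore demonstrate correctness of the
pipeline and the neutral theory on data generated by that theory plus a
simple noise model — not robustness to every artifact of real single-cell
data. Cohort size also matters for one familiar statistic: with 40 cells a
cryptic mutation at h = 0.2 has pseudobulk heteroplasmy 0.005, right at the
bulk-invisibility cut, so the "fraction invisible in bulk" is far smaller
than in thousand-cell cohorts.

## Numerical choices

- All randomness flows from one master seed per object
  (`numpy.random.SeedSequence` spawning; numba kernels take derived 31-bit
  seeds). Identical configs give byte-identical pipeline outputs.
- Mann–Whitney p-values use scipy's exact method for small tie-free
  samples and the tie-corrected normal approximation otherwise; all-tied
  inputs return p = 1, r = 0 by convention.
- RBC-difference is computed by sorted binary search (O((n₁+n₂) log n₂));
  ties count toward neither side.
- Fisher's dN/dS test cross-classifies observed mutations by class ×
  above/below the floor; the ratio is normalized by the annotation
  universe's substitution counts; zero synonymous observations above the
  floor flag the ratio as undefined rather than raising.
- `h` exactly equal to a floor is excluded everywhere (strict
  inequalities); the homoplasmy cut is inclusive (h ≥ 0.95).
- Degenerate inputs: W = 0 yields a flagged empty spectrum, not a
  histogram; empty donors yield flagged empty cSFS objects; a QC pass that
  removes every cell raises `EmptyCohortError`.

## Known limitations

- The likelihood ignores read-sampling noise on observed heteroplasmies
  (depth > 200 makes it second-order at the 10% floor).
- The marginal-chain approximation slightly understates across-mutation
  correlations within a cell (linkage); exact small-N checks bound this.
- The grid posterior resolves Θ to ~10% (grid step); W to ~0.025.
- Selection, copy-number dynamics and cell division are out of scope; the
  cryptic regime is treated as strictly neutral.
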