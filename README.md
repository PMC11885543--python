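# mitocrypt

Cryptic mitochondrial DNA mutations — somatic mtDNA variants unique to a
single cell in a tissue sample — are invisible in bulk sequencing but make
up the bulk of mtDNA mutations in aged post-mitotic tissue. `mitocrypt` is
a pipeline and library for studying them from single-cell sequencing data:

- **call** per-cell heteroplasmies from base counts
  (`h_i = N_i / Σ_{j∈{A,C,G,T}} N_j`), with depth and log-normal cell QC;
- **classify** variants as *cryptic* (one cell of a donor, above floor),
  *shared*, or *common* (more than three donors; likely inherited/RNA
  variants), and attach pathology classes
  (synonymous / low / high pathogenicity);
- **summarize** each donor's cryptic site frequency spectrum (cSFS,
  extended with a homoplasmic class), per-cell mutation load
  `μ^t% = Σ_j h_j · H(h_j − t)`, pseudobulk spectra, homoplasmy rates,
  rank-biserial effect sizes `r = f − u` with Mann–Whitney U tests, and
  dN/dS Fisher tests;
- **simulate** the sub-cellular mtDNA population of a post-mitotic cell
  under a fixed-size Moran birth–death model with infinite-sites mutation
  (`m ~ Binomial(L, ν)` per replication, event rate `N ln2 / t_half`),
  and render whole multi-donor cohorts into noisy base counts with known
  ground truth;
- **infer**, per donor, the *mitochondrial age* `W` (chronological time as
  a fraction of the expected fixation time `(N−1) t_half / ln2`) and the
  scaled mutation rate `Θ = Nν` by a Bayesian fit of the out-of-equilibrium
  coalescent cSFS, plus prediction curves for homoplasmy accumulation and
  threshold-crossing fractions.

Intended users: groups doing single-cell RNA/ATAC-seq who want to extract
mtDNA ageing signal from data they already have, and modellers who need a
tested neutral-theory reference for sub-cellular population genetics.

## Worked example

```python
import mitocrypt as mc

moran = mc.MoranParams(N=150, t_half=0.25, nu=4e-7, seed=0)
cfg = mc.CohortConfig(n_donors=3, ages_years=(10, 45, 80), cells_per_donor=30,
                      moran=moran, genome_length=3000, seed=1)
truth = mc.generate_cohort(cfg)
counts = mc.render_base_counts(truth)
mask = mc.qc_filter(counts)
vt = mc.classify_variants(mc.call_variants(counts, mask, truth.reference), mask)
print("variants:", vt["classification"].value_counts().to_dict())

old = mc.build_csfs(vt, "donor2", floor=0.10)
young = mc.build_csfs(vt, "donor0", floor=0.10)
res = mc.compare_sfs(old.heteroplasmies, young.heteroplasmies)
print(f"RBC-difference old vs young: r={res['r']:.3f}, p={res['p']:.2e}")

fit = mc.fit_donor(old.heteroplasmies, old.n_cells, seed=1)
nu = mc.rate_from_theta(fit.map_theta, moran.N)
print(f"donor2 (80 y): W = {fit.map_W:.2f} "
      f"(95% CI {fit.ci_W[0]:.2f}-{fit.ci_W[1]:.2f}), nu = {nu:.2e}")
```

prints

```
variants: {'shared': 330, 'cryptic': 148}
RBC-difference old vs young: r=0.627, p=4.74e-04
donor2 (80 y): W = 1.12 (95% CI 0.89-1.51), nu = 5.00e-07
```

Reading this: the 80-year-old donor's cryptic spectrum sits clearly above
the 10-year-old's (`r = 0.63`: a random old-donor mutation out-ranks a
random young-donor one 63 points more often than the reverse), and the fit
places the old donor at `W ≈ 1.1` fixation times with a credible interval
covering the generative truth (`W = 1.49`, `ν = 4e-7` at `N = 150` —
the inferred rate, `5.0e-7`, is one ~10% grid step above it).

The same analysis is available from the shell:

```bash
mitocrypt simulate --config sim.yaml --out cohort/
mitocrypt run --config pipeline.yaml          # qc -> call -> classify -> cSFS -> stats -> fit
mitocrypt fit --sfs cohort_out/csfs_donor2_raw.tsv --n-cells 30 --out fit/
mitocrypt predict --w 1.1 --theta 6e-5 --n 1000 --t-half 0.04 --out curves.tsv
```

## Layout

| module | contents |
| --- | --- |
| `mitocrypt.synthetic_data` | cohort generator and base-count renderer |
| `mitocrypt.variant_calling` | QC, heteroplasmy calling, classification, annotation, SAM ingestion |
| `mitocrypt.sfs_stats` | cSFS, mutation load, RBC/Mann–Whitney, dN/dS, pseudobulk, homoplasmy rate |
| `mitocrypt.moran_sim` | forward Moran simulators and coalescence oracles |
| `mitocrypt.coalescent_fit` | expected cSFS, likelihood, grid posterior, prediction curves |
| `mitocrypt.io` / `.pipeline` / `.cli` | TSV/VCF/FASTA formats, the one-command run, click CLI |

See `docs/methods.md` for the model, its assumptions, and numerical
conventions.
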