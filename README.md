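# telosig

Statistical machinery for telomere-length genetic epidemiology, built as a
tested, simulation-verifiable pipeline:

- **io_core** — summary-statistics / LD-matrix I/O, variant keying,
  regional dataset extraction with allele harmonisation.
- **instruments** — p-value-ordered LD clumping, exposure/outcome
  harmonisation (allele flips, palindromes, LD proxies), polygenic risk
  scoring, asymptotic MR power.
- **mr_core** — two-sample MR estimator battery: IVW with multiplicative
  random effects, MR-Egger, weighted median, contamination mixture,
  leave-one-out diagnostics and multivariable MR (IVW / Egger / LASSO).
- **coloc** — approximate-Bayes-factor colocalisation (PP0–PP4, priors
  p1=1e-3, p2=1e-4, p12=1e-5), conditioning/masking for secondary signals
  with PP4 averaging, and a simplified divisive multi-trait clustering.
- **ldsc** — cross-trait LD-score regression: observed-scale h², genetic
  correlation, delete-a-block jackknife uncertainty.
- **signature** — RNA-seq count normalisation (low-count filter,
  upper-quartile depth scaling, binned-median GC/length correction),
  expression PCA with outlier refitting, PRS–component association,
  orthogonal-Procrustes embedding alignment, bootstrap-tuned LASSO gene
  signatures and tumour-feature association models.
- **simulate** — seeded ground-truth generators for every stage
  (MR instruments with pleiotropy, AR(1) regional summary statistics,
  polygenic z-scores with sample overlap, negative-binomial tumour cohorts
  with a genotype-driven latent factor).

## Command-line interface

The `telosig` entry point exposes one subcommand per stage; every
stochastic step takes an explicit `--seed`.

```bash
# synthetic data in the same dialects the analysis commands read
telosig simulate mr     --seed 1 --out scratch/mr
telosig simulate region --seed 1 --out scratch/region
telosig simulate ldsc   --seed 1 --out scratch/ldsc
telosig simulate cohort --seed 1 --out scratch/cohort

# two-sample MR battery on exposure/outcome summary statistics
telosig mr --exposure exp.tsv --outcome out.tsv --ld ld.tsv \
           --methods ivw,egger,median,conmix --seed 1 --out mr.tsv

# colocalisation in a 150 kb window with conditioning/masking averaging
telosig coloc --traits a.tsv,b.tsv --ld ld.tsv --center rs123 \
              --window-kb 150 --p1 1e-3 --p2 1e-4 --p12 1e-5 --out coloc.json

# cross-trait LD-score regression
telosig ldsc-rg --sumstats1 a.tsv --sumstats2 b.tsv --ldscores l.tsv \
                --blocks 200 --out rg.json

# polygenic score and the expression signature
telosig prs --weights w.tsv --dosages dos.tsv --out prs.tsv
telosig signature fit   --counts counts.tsv --gene-meta meta.tsv \
                        --pcs 5 --component 2 --fdr 0.05 --boot 1000 \
                        --seed 1 --out sig.tsv
telosig signature apply --model sig.tsv --counts counts2.tsv --out scores.tsv
telosig extract-region  --traits a.tsv --ld ld.tsv --center rs123 \
                        --window-kb 150 --out region.json
```

Summary statistics are delimited text with a header (configurable column
map in the API; the CLI reads the canonical dialect written by
`io_core.write_sumstats`). LD matrices are delimited square tables with
variant ids on both margins; signed r is stored, r² derived.

## Conventions

- Coordinates are 1-based inclusive; genome build is a pass-through label.
- Variant identity is by id string; no positional fallback.
- Case-control effect sizes are log odds ratios; ORs are reported by
  exponentiation.
- A "150 kb window" means ±75 kb around the lead variant.
- p-values below 1e-300 are clamped and flagged.
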