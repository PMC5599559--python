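# nhsa

Two-stage detection of high-order (k-way) SNP combinations associated
with case/control disease status:

1. **Screening** — a niche harmony search over k-way SNP combinations,
   guided by three complementary scores computed from a single
   contingency pass per combination: a Bayesian K2 score (stored as a
   negative log marginal likelihood), Gini phenotype impurity, and the
   phenotype-blind joint entropy of the genotype distribution (a
   heuristic for models with little or no single-locus marginal effect).
   Three harmony memories (one per score) improvise candidates jointly;
   stagnation triggers niche identification, the converged region is
   exploited (linear sweep of its missing locus) and then recorded in a
   taboo table, and the memories restart elsewhere. Per-score elite sets
   accumulate the best combinations into a candidate set.
2. **Verification** — a modified G-test on each candidate: genotype
   columns whose smallest per-phenotype observed count falls below a
   sparsity threshold (default 5) are excluded from both the statistic
   and the degrees of freedom, and significance is judged against a
   Bonferroni-corrected (or fixed) cutoff.

The package also ships a penetrance-table simulator (2-locus
multiplicative/threshold models calibrated to a target heritability, and
3–5-locus models with near-zero marginal effects found by constrained
stochastic search), plus batch evaluation metrics (Power, TPR, SPC, ACC,
FDR, mean evaluations).

## CLI

Simulate replicate datasets with ground truth:

```bash
nhsa simulate --model threshold --maf 0.2 --h2 0.02 \
    --cases 1000 --controls 1000 --snps 100 --reps 5 --seed 1 --out sim/
```

Run the two-stage detector on a genotype table (TSV/CSV with a header of
SNP names and a `Class` phenotype column coded 0/1, or a PLINK
`.raw`-style file via `--dialect plink_raw`):

```bash
nhsa run --input sim/replicate_000.tsv --k 2 --seed 7 --out run_000/
```

Each run directory contains `config.yaml`, `candidates.tsv` (stage-one
scores), `results.tsv` (G, df, p-value, exclusions, significance),
`trace.tsv` and `log.txt`. Identical input + seed reproduces the result
tables byte-for-byte.

Summarize replicate runs against truth files:

```bash
nhsa evaluate --results runs/ --truth sim/ --out summary.tsv
```

## Notes

- All three stage-one scores are minimized; lower is stronger.
- The G-test's expected counts default to the classical independence
  construction E = n_i n_j / n, which is calibrated against the
  chi-square reference with (I−1)(J−1) df. The Hardy-Weinberg product
  construction is available via `expected_mode="hwe"`; note it folds a
  genotype goodness-of-fit component into G and is anti-conservative at
  the same df.
- Genotypes are coded 0/1/2 by minor-allele dosage; missing-genotype
  rows are dropped on read (count reported on the dataset).
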