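# knnmdr

Window-based KNN-MDR interaction scan for case-control SNP data, with a
zero-marginal-effect epistasis simulator and a power / false-positive
evaluation harness.

The classic multifactor cell-vote classifier labels each multi-locus
genotype cell high/low risk by a training-set majority vote; it breaks
down as soon as cells get sparse. The KNN variant implemented here
replaces the cell vote with a majority vote among the K nearest training
individuals under a squared genotype distance computed over *windows* of
contiguous markers. Per-window distance matrices are precomputed once
and combined additively, so an exhaustive scan over all window sets of
order 1–3 and its phenotype-permutation significance test stay cheap.

## Features

- **genotype_io** — PLINK-text `.ped`/`.map` and TSV genotype dialects,
  minor-allele 0/1/2 coding, phenotype files, MAF computation, validation.
- **windowing** — marker windows (fixed size or explicit boundaries),
  normalized-Euclidean / Mahalanobis / binary squared-distance matrices,
  additive combination across windows.
- **engine** — KNN vote and classic cell vote, deterministic tie rules,
  stratified 10-fold cross-validated balanced accuracy, fast vectorized
  batch scoring of many permuted phenotype vectors at once.
- **search** — exhaustive window-set enumeration, ranking, permutation
  p-values (per-model or max-statistic family-wise null), adaptive
  permutation schedules with early abandonment, Bonferroni thresholds,
  and a three-stage hierarchical scan for large panels (stride
  subsampling, region recovery, final marker-pair stage).
- **simulate** — synthetic LD founder panel, block-mosaic resampling,
  penetrance tables with *exactly* zero marginal effect at every causal
  locus (null-space construction), phenotype assignment, marker thinning.
- **evaluate** — replicate-level power / corrected-power / FPR
  experiments with resumable on-disk artifacts.

## CLI

```sh
# simulate a dataset with 2 interacting causal SNPs and no marginal effects
knn-mdr simulate --G 2 --cases 500 --controls 500 --effect 0.4 --seed 7 --out sim

# exhaustive scan of all window sets of order <= 2
knn-mdr scan --genotypes sim --phenotypes sim.pheno.tsv \
    --windows 10 --order 2 --perm 100 --k 10 --out results.tsv

# hierarchical scan for large panels
knn-mdr hierarchical --genotypes big --phenotypes big.pheno.tsv \
    --stride 15 --round1-window 100 --round2-window 100 --out hits.tsv

# classic cell-vote baseline over marker pairs
knn-mdr mdr-baseline --genotypes sim --phenotypes sim.pheno.tsv --out mdr.tsv

# replicated power experiment from a YAML config
knn-mdr experiment --config experiment.yaml --out-dir out/
```

Experiment configs look like:

```yaml
n_replicates: 100
seed_base: 0
simulation:
  n_causal: 2
  n_cases: 500
  n_controls: 500
  n_markers: 2000
  effect_size: 0.4
  thin: true
analysis:
  window_size: 10
  n_perm: 99
  alpha: 0.05
```

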