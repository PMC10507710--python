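# hapblock

Haplotype-block construction and haplotype-based genomic prediction for crop
breeding panels (doubled-haploid / inbred lines and in-silico hybrids).

The toolkit partitions SNP maps into haplotype blocks by six methods, encodes
block haplotypes as multi-allelic markers, builds additive / epistatic /
Gaussian relationship kernels, fits four prediction models, and evaluates
prediction accuracy by random and family-wise cross-validation. A forward
simulator generates realistic test populations (LD decay, NAM half-sib
families, hybrids, additive + local-epistatic phenotypes) so everything runs
without external data.

## Components

| Module | Purpose |
| --- | --- |
| `genotype_io` | VCF / matrix readers and writers, MAF + missingness filtering, seeded naive imputation, in-silico hybrid crossing |
| `ld_stats` | gamete counts, r², D′, bootstrap D′ confidence intervals, four-gamete recombination evidence |
| `block_builders` | LD-threshold (with tolerance), fixed marker windows, fixed bp windows, D′-CI ("Gabriel"), four-gamete rule, solid spine of LD, partition import/export, parameter grids |
| `haplotype_coding` | haplotype enumeration per block, frequency summaries, centered multi-allelic design matrix |
| `kinship` | VanRaden G, Hadamard-square epistatic kernel, Gaussian kernels (bandwidths 0.1 / 0.5 / 2.5), relationship-structure correlation |
| `predictors` | GBLUP / EGBLUP by REML, Bayesian LASSO and RKHS kernel averaging by Gibbs sampling, BLUP prediction for new samples |
| `evaluation` | Pearson accuracy, repeated random 80/20 CV, leave-one-family-out CV, method × model sweeps |
| `synthetic` | forward-in-time founder-recombination simulator and phenotype generator |
| `cli` | `hapblock` command-line entry point |

## CLI

```bash
# simulate a panel (VCF + matrix + phenotypes + truth record)
hapblock simulate --seed 1 --out pop

# filter + impute
hapblock filter --matrix pop --maf 0.05 --max-missing 0.10 --out filt

# haplotype blocks (methods: ld, fixm, fixbp, gabriel, fourgamete, spine, snp)
hapblock blocks --matrix filt --method ld --param 0.5 --out blocks.bed
hapblock haplotypes --matrix filt --method fixm --param 4 --out catalog.tsv

# kernels, model fits, cross-validation
hapblock grm --matrix filt --method fixm --param 4 --out G.tsv
hapblock fit --matrix filt --pheno pop.pheno.csv --model egblup --out fitres
hapblock cv --matrix filt --pheno pop.pheno.csv --model gblup \
    --scheme random --runs 100 --test-frac 0.2 --seed 1 --out cv.json

# method x model grids
hapblock sweep --matrix filt --pheno pop.pheno.csv \
    --methods "snp,fixm:2,fixm:4,ld:0.5" --models "gblup,rkhs" \
    --runs 100 --out sweep.csv

# full YAML-configured pipeline
hapblock run --config run.yaml --out results/run1
```

A pipeline config names either input files or a `simulate` section:

```yaml
seed: 1
simulate: {n_samples: 200, n_chromosomes: 3, markers_per_chromosome: 60}
blocks:
  - {method: snp}
  - {method: fixed_markers, param: 4}
models: [gblup, bayesian_lasso]
cv: {scheme: random, n_runs: 100, test_frac: 0.2}
```

Every results file embeds the toolkit version, the resolved-config hash and
the master seed; all randomness flows from that seed through named
substreams.

## Conventions

- Dosages count the minor allele (orientation fixed when a file is read) and
  live in {0, 1, 2}; homozygous material never carries dosage 1.
- Physical positions are 1-based bp; block index ranges are half-open over
  the sorted marker order; exported intervals follow the BED convention.
- A homozygous line contributes one gamete to haplotype frequencies; a phased
  diploid contributes two.
- Blocks with two haplotypes are coded like biallelic markers (one column);
  blocks with k > 2 haplotypes contribute one column per haplotype.
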