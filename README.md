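# mksel

Hierarchical Bayesian McDonald–Kreitman (MK) selection inference for
two-species variant data, with the cross-species comparative statistics used
to ask whether independently evolved social insect lineages share adaptively
evolving genes.

## The problem

Given resequencing data from a focal species (e.g. the paper wasp *Polistes
dominula*) and a close outgroup (*P. gallicus*), every coding site that
survives quality filtering is either a **polymorphism** (segregating within a
species) or a **fixed difference** (monomorphic within each species, different
between them), and either **synonymous** or **non-synonymous**. The per-gene
counts (PN, PS, DN, DS) form the MK table: an excess of non-synonymous fixed
differences relative to the synonymous baseline is the signature of adaptive
protein evolution.

`mksel` turns two VCFs, a genome and gene models into those tables, then fits
a hierarchical Poisson log-linear model to estimate, per gene, the scaled
selection coefficient γ = 2Nₑs on non-synonymous mutations. Genes with γ > 1
are classified as positively selected. Downstream modules resolve
reciprocal-best-hit (RBH) orthologs between species, test gene-set overlap
enrichment (one-tailed Fisher; three-way χ² independence test), and contrast
selection on queen-biased vs worker-biased vs non-differentially-expressed
genes (ANOVA + Tukey–Kramer; two-proportion χ²).

## The model

Counts for gene *i* in cell (R, F) — R = 1 for non-synonymous, F = 1 for
fixed differences — are modelled as

```
Y_iRF ~ Poisson(μ_iRF)
log μ_iRF = β₀ + b_i + (β_R + r_i)·R + β_F·F + (β_RF + s_i)·R·F
b_i ~ N(0, σ_b²),  r_i ~ N(0, σ_r²),  s_i ~ N(0, σ_s²)
```

The gene's selection effect S_i = β_RF + s_i is mapped to γ through the
Poisson random field (PRF) link

```
exp(S) = H(γ) / Qratio(γ, n),   H(γ) = γ / (1 − e^(−γ))
```

where H is the relative fixation rate and Qratio the expected relative
polymorphism level in a sample of n haploid sequences (n = 20 by default: ten
diploid focal samples). Borrowing strength across the genome, the model needs
no prior estimate of species divergence and shrinks noisy per-gene estimates
toward the genome-wide pattern.

Two estimators are provided: a seeded adaptive Metropolis-within-Gibbs MCMC
(default; 4 chains × 2000 iterations with split-R̂ convergence diagnostics)
and a fast empirical-Bayes Laplace approximation. They agree to rank
correlation > 0.98 on simulations.

## Worked example

Everything below runs from synthetic data with known ground truth — no
downloads. The numbered scripts under `analysis/` form the full narrative:

```
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_variant_pipeline.py
python analysis/03_fit_selection.py --seed 1
python analysis/04_orthology_overlap.py --seed 1
python analysis/05_caste_bias.py
```

`02_variant_pipeline.py` audits the variant pipeline against the generator's
manifest:

```
MK tables recovered exactly: 7/7
gene exclusions match manifest: True
removal reasons match planted: True
stage counts reconcile: True
```

`03_fit_selection.py` fits 500 genes simulated under the PRF model
(~10% truly positive) and reports parameter recovery:

```
mcmc: Spearman(gamma_hat, gamma_true) = 0.923; 11.8% classified gamma > 1 (true 10.2%)
empirical_bayes: Spearman(gamma_hat, gamma_true) = 0.924; 11.6% classified gamma > 1
sparse genes (<10 sites, n=9): RMSE hierarchical 1.23 vs per-gene MLE 6.10
```

The last line shows the point of partial pooling: on genes with fewer than
ten classified sites the no-pooling maximum-likelihood γ is essentially
noise, while the hierarchical estimate stays usable.

The same stages are available as a CLI
(`mksel simulate|filter|annotate|tables|estimate|orthology|compare|run-all`),
e.g. `mksel run-all --seed 1 --out-dir runs/demo`.

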