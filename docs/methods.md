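# Methods

## Scope and data flow

The package starts from called variants (VCF), not reads: alignment,
duplicate marking and variant calling are upstream of its interface. The
stages are

1. **Site filtering** (`variant_filtering`) — GATK-style hard filters,
   per-site mean-depth limits, missing-genotype fraction, homology-mask
   intervals; a gene-level rule removes genes with low coverage over more
   than 10% of the coding sequence.
2. **Effect annotation** (`effect_annotation`) — synonymous/non-synonymous
   classification of coding SNVs under the standard nuclear genetic code,
   plus the disqualifying effects (stop gained/lost, start lost,
   non-synonymous start) and gene-model warnings (incomplete transcript,
   multiple stop codons, no start codon) that exclude a gene entirely.
3. **Site classification and MK tables** (`mk_tables`) — each surviving
   biallelic site becomes a polymorphism, a fixed difference, or is removed
   (triallelic across the species pair; both species fixed for the same
   non-reference allele), and the per-gene cross-tabulation with the
   synonymous/non-synonymous label yields (PN, PS, DN, DS).
4. **Selection inference** (`selection_inference`) — the hierarchical
   Poisson GLMM described below, the classic per-gene Fisher MK test,
   neutrality index NI = (PN/PS)/(DN/DS) and α = 1 − NI.
5. **Comparative statistics** (`orthology`, `comparative_stats`) —
   reciprocal-best-hit orthology and the overlap/caste-bias battery.

## The hierarchical model

Counts Y per gene × cell follow `log μ = β₀ + b_i + (β_R + r_i)R + β_F F +
(β_RF + s_i)RF` with independent mean-zero Gaussian random effects. The
interaction effect S_i = β_RF + s_i measures how far gene *i*'s
non-synonymous divergence departs from what its own polymorphism and the
genome-wide baseline predict. Priors: Normal(0, 5²) on fixed effects,
half-Normal(1) on random-effect standard deviations. Genes whose table is
all zeros cannot inform S and are reported with no γ rather than dropped
silently — on real data a substantial minority of genes fall in this class.

### PRF link

S is converted to γ = 2Nₑs by solving `exp(S) = H(γ)/Qratio(γ, n)`, where
H(γ) = γ/(1 − e^(−γ)) is the fixation-rate ratio and

    Q(γ, n) = ∫₀¹ [(1 − e^(−γ(1−x)))/(1 − e^(−γ))] ·
                   [(1 − xⁿ − (1−x)ⁿ)/(x(1−x))] dx

is the expected relative number of segregating sites detectable in n haploid
sequences (Qratio normalises by the neutral value; the γ = 0 limit replaces
the first bracket with 1 − x). The integral is evaluated by adaptive
quadrature to 1e−12 and cached; the link is strictly increasing in γ, so the
inversion is a bracketed root-find on γ ∈ [−100, 100], exact to machine
tolerance. Note that Q itself *increases* with γ (positive selection shifts
the frequency spectrum toward higher frequencies faster than it removes
polymorphism under this parameterisation); it is the ratio H/Qratio whose
monotone growth carries the signal, and that monotonicity is what the test
suite asserts.

`n` defaults to 20 (ten diploid focal samples). Polymorphism is pooled
across both species under this single effective n; a focal-only mode is a
matter of dropping outgroup-private polymorphisms upstream.

### Estimators

**MCMC (default).** Adaptive Metropolis-within-Gibbs, vectorised across
genes: a joint 3-d random walk per gene (proposal scaled by the current
prior standard deviations), componentwise and joint fixed-effect updates
(the joint proposal covariance is learned during warmup and frozen after),
and for each variance component a centered log-scale MH step interleaved
with a non-centered move that rescales the random effects jointly with
their scale. Two exact extra Gibbs steps recenter each fixed effect against
the mean of its paired random effects (the likelihood is invariant along
that direction, so the shift has a closed-form Gaussian conditional). The
interweaving is what keeps the sampler usable when a variance component
sits near zero. Defaults: 4 chains × 2000 iterations, 1000 warmup; all
randomness derives from a single seed, so runs are bit-for-bit
reproducible. Convergence is reported as split-chain R̂ < 1.05 over the
fixed effects and the scales, monitored on the σ scale (below the data's
resolution, log σ random-walks freely while σ is pinned near zero, which
would flag a healthy fit). When a generating process puts a variance
component exactly on the boundary, R̂ on that component can hover near the
threshold; the `converged` flag reports this honestly rather than masking
it.

**Empirical Bayes.** Type-II MAP: the gene random effects are integrated
out by a per-gene Laplace approximation (the inner mode is found by damped
Newton, concave objective, vectorised over genes) and the seven
hyperparameters are optimised by Nelder–Mead. Per-gene posteriors for S are
then Gaussian from the same Laplace curvature, conditional on the
hyperparameters — intervals therefore ignore hyperparameter uncertainty,
which is small at genome scale. Roughly twice as fast as MCMC at 500 genes
and agreeing with it to rank correlation > 0.98; intervals are the main
reason to prefer MCMC.

Point estimate: posterior-mean S mapped through the link; credible bounds:
the 2.5%/97.5% S quantiles mapped through the (monotone) link.
Classification γ > 1 uses the point estimate, strictly.

### No-pooling oracle

`per_gene_prf_mle` maximises the product-Poisson likelihood of one gene
under the generative rates (θ profiled out analytically; coarse grid then
bounded refinement on γ). It exists as an independent check: the
hierarchical fit must beat it in RMSE on sparse genes, and approach it on
well-populated ones.

## The synthetic-data generators

The generators' defaults are the study conditions; they are not tuning
knobs.

**PRF counts.** PS ~ Poisson(θ), PN ~ Poisson(θ·z·Qratio(γ, n)),
DS ~ Poisson(θ·d), DN ~ Poisson(θ·d·z·H(γ)) — the same parameterisation the
model inverts, so recovery is well-posed. Defaults: n = 20 focal / 4
outgroup haploid (10 + 2 diploid samples), z = 2.5 (non-synonymous/
synonymous mutational-opportunity ratio; a typical codon-level value),
d = 1 (divergence intensity comparable to polymorphism), and per-gene θ
drawn lognormal (median 15, sdlog 1.2). The wide θ spread mirrors the
order-of-magnitude variation in mutational target size across real genes —
the reason the model carries a gene-level intercept at all — and ensures
the simulation contains the sparse genes (< 10 sites) on which shrinkage
matters; a constant-θ simulation would place σ_b exactly on its boundary,
which is neither realistic nor a healthy regime for convergence
diagnostics. The γ mixture is Normal(−2, 1.5) (deleterious/neutral) with an
Exponential(mean 3) positive component at weight 0.12, giving an analytic
P(γ > 1) ≈ 0.106 — the ~10% positive-gene regime of genome-scale MK scans
of social insects.

**Two-species VCF fixture.** A toy genome of small genes built from codons
chosen so no single-base change creates an unintended stop (CTT body
codons), on both strands, some split across two exons. Each clean gene gets
planted Poisson(3) counts of each MK category; one site is planted for
every filter rule (each hard-filter metric, low/high depth, missingness,
mask, an indel) plus a cross-species triallelic site and a same-allele-fixed
site; one gene exceeds the 10% low-coverage rule; one gene each carries a
stop-gain, stop-loss, start-loss and non-synonymous-start variant; one gene
model exists per warning type. The manifest records every plant, and the
tests assert the pipeline removes each one by exactly the targeted rule and
recovers every MK table exactly. What the fixture does **not** emulate:
linkage, realistic base composition, coalescent genealogies, overlapping
genes, multiple transcripts — passing it demonstrates the bookkeeping is
exact, not that the filters are well-tuned for any particular dataset.

**Expression and hit tables.** Caste-biased genes receive FDR < 0.05 and
FPKM > 1 in the biased direction (defaults 114 queen- and 287 worker-biased,
the focal study's class sizes); decoy non-DEGs include significant-FDR but
sub-threshold-FPKM rows. Hit tables plant mutual best hits below the 1e−10
E-value threshold plus decoys: one-directional bests, above-threshold pairs,
and tied bitscores that survive the best-hit stage and fail reciprocity.

## Statistical conventions

* Two-proportion contrasts default to Pearson χ² without continuity
  correction; Yates-corrected and Fisher-exact variants are always
  computed alongside, because printed χ² values in the comparative
  literature follow inconsistent conventions (the focal study's wasp value
  matches the Yates convention; its bumblebee value matches neither).
* Overlap enrichment is the one-tailed (upper) hypergeometric test over an
  explicit universe — here, the genes with γ estimates in both species
  among the pairwise orthologs.
* The three-way overlap test cross-classifies the universe into 8
  membership cells and tests mutual independence with df = 4 (8 − 1 − 3
  estimated marginals); its type-I error is verified by simulation.
* Tukey–Kramer HSD uses the studentized-range distribution with pooled
  within-group variance; it reduces to classic Tukey at equal sizes
  (checked to 1e−10) and matches `statsmodels.pairwise_tukeyhsd` to 1e−8.
* Reported percentages round half-up to one decimal.

## Numerical choices and edge cases

* E-value threshold comparison is inclusive (≤ 1e−10).
* An allele counts as observed only with ≥ 1 called genotype copy; declared
  but uncalled ALTs never make a site triallelic.
* A site present in only one species' VCF is treated as fixed reference in
  the other (joint-calling convention); a site failing filters in either
  species is removed from both.
* Multiple SNVs in one codon are each evaluated against the reference
  codon (the per-variant convention of standard annotators).
* For minus-strand genes both alleles are complemented before codon
  substitution; effects are strand-symmetric by construction and by test.
* The triallelic, site-classification and best-hit operations are
  order-independent; filters partition their input and are idempotent.
* Zero-called-copy sites at classification raise — they must have been
  removed by the missingness filter, so reaching them is a pipeline bug.

## Problem sizes

Simulation-backed checks run at 500 genes (recovery, specificity,
shrinkage), 10,000 genes for generator-marginal checks, and 1000 replicates
for type-I calibration; the exhaustive Fisher cross-check covers all 135,751
tables with total ≤ 40. These sizes give Monte-Carlo error comfortably below
the asserted tolerances while keeping the full suite and the acceptance
script fast on a single CPU.

## Known limitations

* Unpolarized MK only: no ancestral-state inference, no
  divergence-correction (Jukes–Cantor), single outgroup.
* No distribution-of-fitness-effects estimation or demographic correction;
  γ is a per-gene average and is biased by segregating deleterious
  variation in the same way as any unpolarized MK-family estimator.
* One transcript per gene; splice/UTR/indel effects out of scope.
* Empirical-Bayes intervals are conditional on hyperparameters.
* The depth input for the gene-coverage rule is a per-CDS-base mean-depth
  table supplied alongside the VCFs (depth at non-variant sites is not
  recoverable from a VCF).
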