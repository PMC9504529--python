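# Methods

## Scope and design

The package re-creates the analysis chain of a longevity case/control PRS
study as a library (`src/longprs/`) with thin narrative drivers
(`analysis/`). Because the genotypes such studies rest on are
access-restricted, the pipeline is exercised on a synthetic cohort
generator whose causal structure is known, so every stage can be tested
against ground truth. What passing tests demonstrate is therefore internal
correctness and qualitative behaviour (calibration, sign recovery, the
APOE masking phenomenon), not real-data effect sizes.

## The cohort simulator (`synthcohort`)

**Genotypes.** A panel of LD blocks, each on its own chromosome stretch;
within a block, haplotypes come from an AR(1) Gaussian copula with latent
correlation ρ^|i−j| thresholded at Φ⁻¹(MAF), and a genotype is the sum of
two independent haplotypes. This gives directly tunable, geometrically
decaying within-block r² (empirically, latent ρ = 0.8 yields adjacent
genotype r² ≈ 0.25, ρ = 0.985 yields ≈ 0.76) and exact between-block
independence. MAFs are uniform on the requested range; default panels use
(0.05, 0.5).

**Phenotypes.** Each disease d draws `n_causal` effects β_d ~ N(0,
effect_sd²), giving the liability `L_d = Xβ_d + ε`, dichotomized at the
empirical quantile of its target prevalence. The longevity liability is

    L_long = Σ_d c_d · z(Xβ_d) + a · z(Xβ_own) + ε,   ε ~ N(0, 1)

with z(·) the within-cohort standardization. The own-component weight `a`
is set from `longevity_own_h2` via `a² = h²(Σc² + 1)/(1 − h²)`, so the
knob is the own component's variance share against the couplings and unit
noise. The `n_lli` samples in the upper tail of `L_long` are the LLI
group, making the tail rate and both group sizes exact. Sexes are
assigned per group at exact women:men counts (defaults 2.7:1 in LLI,
0.7:1 in controls). Substructure shifts the allele frequency of a random
20% of variants by ±δ in one of two equal subpopulations. Missing
genotypes are injected at 1% per variant by default.

**APOE analogue.** One designated block is relocated to
chr19:45,351,000–45,500,000 and three of its variants receive own-effects
of −2.0 on the liability scale — more than 10× the median polygenic own
effect (σ = 0.1) — reproducing a strong-effect locus that masks the rest
of the signal. Age is not modelled; group membership is the phenotype.

**Synthetic GWAS.** Published summary statistics are emulated by
`β̂_j = β_j + N(0, se_j²)` with `se_j = 1/√(n_gwas · 2 maf_j (1 − maf_j))`
and two-sided Wald p-values. `n_gwas` is an *effective* sample size: the
masking study deliberately uses a small value (500) because longevity
meta-GWAS are underpowered relative to the APOE region — that imbalance is
precisely what makes the stringent C+T cutoffs (APOE-dominated) win the
discovery scan while looser cutoffs drown real background signal in
estimation noise.

What the generator does **not** emulate: realistic recombination maps or
demography, genotyping batch artefacts, imputation (only a per-variant R²
column consumed by QC), age structure, or ascertainment beyond the sex
ratios.

## Quality control (`qc`)

Thresholds follow array-era convention and are all configurable:
per-sample missingness < 8%, heterozygosity within mean ± 4 SD (band
computed on the post-missingness set), pairwise PI_HAT ≤ 0.1875; per-marker
missingness ≤ 5%, HWE in controls p ≥ 1e-5 (1e-9 post-imputation), MAF ≥
1%, imputation R² ≥ 0.75 when present; marker filters run in the fixed
order missingness → HWE → MAF → R² with per-filter tallies.

The HWE test is the exact conditional test on the heterozygote count,
computed by the standard probability recurrence; tests verify it against
a direct log-factorial enumeration for every genotype table of size ≤ 30.

PI_HAT is the method-of-moments IBS ratio estimator (P(IBD=1)/2 +
P(IBD=2)), fully vectorized over pairs; the finite-sample allele-frequency
bias corrections of the original are omitted. At synthetic panel sizes its
noise matters: the SD is ≈ 0.03 at ~3500 LD-thinned markers, so the
analysis driver simulates 6000 markers to keep false relatedness flags
near zero. Related pairs keep the member with lower missingness, ties
resolved to the lexicographically smaller ID.

PCA standardizes dosages by `(x − 2p)/√(2p(1−p))` (missing → 0 after
centering) on an LD-thinned subset (greedy r² < 0.2 in 50-SNV windows) and
returns orthonormal sample loadings, each sign-fixed to correlate
positively with the sample index. Substructure outliers are flagged by
local outlier factor (k = 20, cutoff 2.1) on the first five PCs.

## Association (`assoc`)

Per-variant additive ML logistic regression with sex and five PCs; Wald
p-values. Non-convergence (100-iteration cap) and separation (singular
fits or |β| > 15 on the dosage scale) are flagged, never dropped, so
result counts stay auditable. Conditional analysis appends the
conditioning SNVs' (mean-imputed) dosages to the covariates; an empty
condition set reduces exactly to the unconditional scan. BH-FDR comes
from statsmodels and is cross-checked against a literal step-up
computation in the tests.

## Scoring and evaluation (`scoring`, `evaluate`)

Scores are raw weighted dosage sums; missing dosages are mean-imputed by
2·(allele frequency of the non-missing samples) by default, or omitted
under the `omit` policy (for sensitivity analysis). Standardization is a
separate explicit step, by default against the control samples — the
natural reference population — with a switch for whole-cohort scaling.

AUC is the midrank Mann–Whitney statistic; its CI uses DeLong's
placement-value variance, collapsing to the point estimate when the
variance degenerates (perfect separation or all-tied scores). Reported
odds ratios are exp(β) rounded half-up to 2 decimals; coverage
percentages round half-up to 2 decimals in tables and 1 decimal in prose.
When a logistic fit hits a singular Hessian (separation), the Newton
solver falls back to BFGS so the report row can still be produced.

## C+T GPS (`gps`)

Clumping is the greedy index-variant rule: repeatedly take the smallest-p
unassigned variant, absorb unassigned variants on the same chromosome
within ±250 kb with r² > 0.1, r² computed from the pooled discovery-set
dosages (no external reference). Ties on p break by input row order. The
scan grid is the fixed 11-cutoff sequence; a cutoff admitting no SNV is
recorded with AUC 0.5 and n = 0; equal discovery AUCs break to the most
stringent cutoff (fewest SNVs). The selected score's weights and its
training standardization are frozen before test data are touched.

The ε haplotype is called from the two coding sites: per haplotype
(rs429358, rs7412) T&T → ε2, T&C → ε3, C&C → ε4, C&T → ε1 (rare,
flagged). The unphased double heterozygote is ambiguous between ε2/ε4 and
ε1/ε3 and resolves to ε2/ε4 (ε1 haplotypes are vanishingly rare), with
the ambiguity flag set.

The stepwise augmentation takes the region-excluded GPS score, the
region's SNV dosages greedily thinned to pairwise r² ≤ 0.1 with MAF >
0.01 (candidate count capped at 30 by default — the candidate universe is
configuration, since "region SNVs re-admitted" can reasonably mean the
thinned region set or a wider non-LD set), and the ε2/ε4 allele counts;
backward elimination minimizes AIC (a significance-threshold criterion
was considered and rejected as the less standard default). Collinear or
constant candidates are pre-dropped. The discovery/test split is 70/30,
stratified by case status, seeded.

## Meta-PRS (`metaprs`)

Elastic net via saga-solver logistic regression; mixing grid
{0, 0.25, 0.5, 0.75, 1} × 11 strengths logspaced on C ∈ [1e-3, 1e2],
selected by 10-fold CV deviance (ties to stronger penalty, then more
lasso). CV rows are put in a canonical lexicographic order first, so fold
membership and the reported deviance are invariant to how the caller
sorted the samples. The smoothed bootstrap resamples the minority class
to parity and jitters each resampled row by N(0, h²) per column, h from
Silverman's rule on the minority class; balancing happens inside each
training fold only, and the final model is refit on balanced data by
default (switchable, since either convention is defensible).

## Problem sizes and numerical choices

The study designs in `experiments.py` use cohorts of 3000–4000 samples
over 500–1250 variants (6000 for the QC driver), sizes at which every
qualitative phenomenon under study is stable across seeds while a full
test-suite run stays in the tens of seconds. Masking-study conditions:
seven diseases with couplings −0.3, own-liability share 0.3, APOE-analogue
effect −2.0, effective GWAS n = 500. Null calibration uses three diseases
with all effects and couplings zero. Logistic fits cap at 100–200
iterations; seeds derive from a single user seed via `SeedSequence.spawn`
and stay below 2³¹.

## Known limitations

- PI_HAT omits small-sample bias corrections and is noisy below ~2000
  independent markers; interpret relatedness flags on small panels
  accordingly.
- The copula LD model has no long-range LD, so clumping windows never
  interact across blocks.
- DeLong CIs are asymptotic; at very small n or extreme AUCs a bootstrap
  CI would be preferable (not implemented).
- The simulator's effect-size distributions are calibration placeholders,
  not estimates of the real architecture of human longevity; absolute
  AUCs on synthetic cohorts are not comparable to real-data values.
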