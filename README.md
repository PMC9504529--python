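# longprs

Polygenic-score analysis of human longevity: do long-lived individuals
(LLI) carry a lower genetic burden of age-related disease (ARD) risk
alleles, and how much of the longevity signal hides behind the
*TOMM40*/*APOE*/*APOC1* region?

The package implements, as a tested and reusable pipeline, the full chain
of such a case/control study — array-style quality control, single-variant
association with conditional analysis, published-weight PRS scoring, an
elastic-net meta-PRS, and clumping-and-thresholding (C+T) genome-wide
polygenic scores with and without the APOE region — together with a
liability-threshold cohort simulator that provides ground truth for every
stage. Real longevity genotypes are access-restricted, so the simulator is
a first-class component: every analysis here runs end to end on synthetic
cohorts whose causal structure is known exactly.

## The models

**Scores.** A polygenic risk score is the weighted dosage sum
`PRS_i = Σ_j d_ij β_j`, where `d_ij ∈ [0, 2]` counts effect alleles and
`β_j` is the log odds ratio from GWAS summary statistics, harmonized to
the genotype panel by position and allele orientation (direct, swapped,
strand-complemented, swapped+complemented; palindromic A/T and C/G
variants dropped). Discrimination between LLI and controls is summarized
by a logistic model `logit P(case) = α + β·z(PRS) (+ sex + 5 PCs)` and the
AUC with a DeLong 95% CI, plus McFadden's pseudo-R².

**Meta-PRS.** The standardized per-disease scores enter an elastic-net
logistic regression (mixing α ∈ {0, 0.25, 0.5, 0.75, 1}, strength chosen
by 10-fold cross-validated deviance), with smoothed-bootstrap resampling
of the minority class (Silverman-bandwidth jitter) inside each training
fold to control class imbalance.

**C+T longevity GPS.** Greedy LD clumping (r² > 0.1 within ±250 kb absorbs
a weaker neighbour into its index SNV; LD from the sample genotypes, no
external reference), then one score per p-value cutoff of the fixed
11-point grid {5e-8, …, 0.5, 1}; the cutoff with the best discovery-set
AUC is frozen before any test-set contact. Variants of the APOE-analogue
region (chr19:45,351,000–45,500,000) can be excluded and later re-admitted
— as LD-thinned SNV dosages plus the APOE ε haplotype called from
rs429358/rs7412 — through AIC-based backward stepwise regression.

**Simulator.** Haplotypes come from a block-autoregressive Gaussian copula
(within-block latent correlation ρ^distance, thresholded at the allele
frequency), two haplotypes per sample. Each disease d has liability
`L_d = X β_d + ε`; the longevity liability is
`L_long = Σ_d c_d·z(Xβ_d) + a·z(Xβ_own) + ε` with couplings `c_d < 0`
encoding "LLI carry less disease risk", and one block holding three
large-effect variants as the APOE analogue. The top tail of `L_long` at
the case rate becomes the LLI group; sex ratios (2.7:1 vs 0.7:1 women:men)
and mild two-population substructure are built in.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (750 LLI vs 2250 controls, 6000 variants) and write their tables
under `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_single_variant_association.py
python analysis/04_ard_prs_and_meta.py
python analysis/05_longevity_gps.py
```

`04_ard_prs_and_meta.py` prints the ARD-PRS profile (7 diseases, all
couplings negative by design) and the meta-PRS:

```
disease   beta  meta_coefficient
     AD -0.565            -0.685
    ISS -0.534            -0.600
     AF -0.302            -0.386
    CAD -0.348            -0.363
    CRC -0.124            -0.247
     PD -0.130            -0.184
    T2D -0.213            -0.196

all score betas negative: True
all meta coefficients <= 0: True
meta-PRS test AUC: 0.757 (n = 4000)
```

Every fitted score beta is negative — long-lived cases sit lower on every
disease score — and combining the seven scores lifts the test AUC well
above any single one.

`05_longevity_gps.py` prints the masking progression:

```
     model  n_snvs  cutoff  test_auc
   GPSlong       2     0.0     0.702
 GPSlongII     291     0.5     0.545
GPSlongII+       4     NaN     0.713
fraction of GPSlong SNVs inside the region: 1.00
```

With the APOE-analogue block present, C+T selects a tiny score made
entirely of region SNVs; excluding the region leaves a 291-SNV score with
much weaker (but real) discrimination; re-admitting the region variants
and ε haplotype by backward stepwise restores and slightly exceeds the
original AUC. On a cohort simulated with *no* genetic effects, the same
pipeline stays at AUC ≈ 0.5 at every stage and its association p-values
are uniform.

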