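"""Liability-threshold simulation of a longevity case/control cohort.

The generator produces LD-structured genotypes and coupled disease/longevity
phenotypes with known ground truth, emulating the design of a longevity
case/control study: long-lived individuals (LLI) are the upper tail of a
latent longevity liability that is a weighted sum of the genetic components
of several age-related diseases (negative weights encode "LLI carry less
disease risk") plus an independent polygenic component of its own. One
designated block plays the role of the TOMM40/APOE/APOC1 region: it carries
a few very-large-effect variants on the longevity liability, reproducing the
masking phenomenon seen around APOE.

Haplotypes come from a block-autoregressive Gaussian copula: within a block
the latent Gaussian has correlation ``rho**distance`` and is thresholded at
the allele-frequency quantile, so the within-block r^2 decays geometrically
with distance and blocks are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genoio import GenotypeMatrix

#: chromosome and 1-based bounds of the APOE-analogue block (mirrors the
#: TOMM40/APOE/APOC1 interval used for region exclusion).
APOE_REGION = ("19", 45_351_000, 45_500_000)


class ParameterError(ValueError):
    """Invalid simulation parameter."""


@dataclass
class HaplotypePanel:
    """Variant panel: block structure, allele frequencies and coordinates."""

    n_blocks: int
    snps_per_block: int
    maf: np.ndarray
    within_block_corr: float
    chrom: np.ndarray
    positions: np.ndarray
    block: np.ndarray

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        if not ((self.maf > 0) & (self.maf <= 0.5)).all():
            raise ParameterError("all MAFs must lie in (0, 0.5]")
        if not 0 <= self.within_block_corr < 1:
            raise ParameterError("within_block_corr must lie in [0, 1)")
        for c in np.unique(self.chrom):
            p = self.positions[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ParameterError(f"positions not strictly increasing on {c}")

    @property
    def n_variants(self) -> int:
        return self.maf.size

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata in the genotype-panel schema (counted allele = ALT)."""
        rng = np.random.default_rng(12345)  # fixed cosmetic allele labels
        pairs = np.array([["A", "G"], ["A", "C"], ["T", "G"], ["T", "C"]])
        pick = pairs[rng.integers(0, 4, self.n_variants)]
        return pd.DataFrame({
            "chrom": self.chrom,
            "pos": self.positions,
            "id": [f"rs{c}_{p}" for c, p in zip(self.chrom, self.positions)],
            "counted_allele": pick[:, 1],
            "other_allele": pick[:, 0],
        })


@dataclass
class DiseaseSpec:
    """Genetic architecture of one age-related disease.

    ``longevity_coupling`` weighs this disease's standardized genetic
    component into the longevity liability; negative values make high
    genetic disease risk anti-correlated with being long-lived.
    """

    name: str
    n_causal: int
    effect_sd: float = 0.15
    prevalence_target: float = 0.1
    longevity_coupling: float = -0.5

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_target < 1:
            raise ParameterError("prevalence_target must lie in (0, 1)")
        if not -1 <= self.longevity_coupling <= 1:
            raise ParameterError("longevity_coupling must lie in [-1, 1]")
        if self.n_causal < 1:
            raise ParameterError("n_causal must be >= 1")


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort (reproducible given seed)."""

    disease_beta: dict[str, np.ndarray]
    longevity_beta: np.ndarray
    own_beta: np.ndarray
    couplings: dict[str, float]
    liability_longevity: np.ndarray
    liability_disease: dict[str, np.ndarray]
    genetic_disease: dict[str, np.ndarray]
    disease_status: dict[str, np.ndarray]
    subpop: np.ndarray
    maf: np.ndarray
    seed: int
    apoe_snvs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def default_disease_specs(panel_size: int) -> list[DiseaseSpec]:
    """Seven ARD architectures mirroring the diseases scored in the study.

    All couplings are negative: long-lived individuals are enriched for low
    genetic disease risk. Prevalences are late-life ballparks.
    """
    n = max(5, panel_size // 40)
    return [
        DiseaseSpec("AD", n_causal=n, effect_sd=0.20, prevalence_target=0.10,
                    longevity_coupling=-0.45),
        DiseaseSpec("ISS", n_causal=n, effect_sd=0.18, prevalence_target=0.12,
                    longevity_coupling=-0.40),
        DiseaseSpec("AF", n_causal=n, effect_sd=0.16, prevalence_target=0.15,
                    longevity_coupling=-0.30),
        DiseaseSpec("CAD", n_causal=n, effect_sd=0.16, prevalence_target=0.20,
                    longevity_coupling=-0.30),
        DiseaseSpec("CRC", n_causal=n, effect_sd=0.12, prevalence_target=0.05,
                    longevity_coupling=-0.15),
        DiseaseSpec("PD", n_causal=n, effect_sd=0.12, prevalence_target=0.03,
                    longevity_coupling=-0.15),
        DiseaseSpec("T2D", n_causal=n, effect_sd=0.14, prevalence_target=0.20,
                    longevity_coupling=-0.15),
    ]


def simulate_panel(n_blocks: int, snps_per_block: int,
                   maf_range: tuple[float, float] = (0.05, 0.5),
                   within_block_corr: float = 0.8,
                   seed: int = 0,
                   spacing_bp: int = 5_000,
                   apoe_block: int | None = None) -> HaplotypePanel:
    """Draw a block-structured variant panel.

    Blocks are laid out on chromosomes 1..22 cycling, 1 Mb apart, so blocks
    sharing a chromosome are well outside any clumping window. When
    ``apoe_block`` is given, that block is relocated to the APOE-analogue
    interval on chromosome 19.
    """
    if n_blocks < 1 or snps_per_block < 1:
        raise ParameterError("n_blocks and snps_per_block must be >= 1")
    lo, hi = maf_range
    if not (0.005 <= lo <= hi <= 0.5):
        raise ParameterError("maf_range must lie within (0.005, 0.5)")
    if not 0 <= within_block_corr < 1:
        raise ParameterError("within_block_corr must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = n_blocks * snps_per_block
    maf = rng.uniform(lo, hi, n)
    chrom = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=int)
    block = np.repeat(np.arange(n_blocks), snps_per_block)
    per_chrom_count: dict[str, int] = {}
    for b in range(n_blocks):
        sl = slice(b * snps_per_block, (b + 1) * snps_per_block)
        if apoe_block is not None and b == apoe_block:
            c, start = APOE_REGION[0], APOE_REGION[1] + 9_000
            # spacing shrunk if needed so the block stays inside the region
            span = APOE_REGION[2] - start
            sp = min(spacing_bp, max(1, span // max(1, snps_per_block)))
        else:
            pool = [str(i) for i in range(1, 23)
                    if apoe_block is None or str(i) != APOE_REGION[0]]
            c = pool[b % len(pool)]
            k = per_chrom_count.get(c, 0)
            per_chrom_count[c] = k + 1
            start = 1_000_000 + k * 10_000_000
            sp = spacing_bp
        chrom[sl] = c
        positions[sl] = start + np.arange(snps_per_block) * sp
    return HaplotypePanel(
        n_blocks=n_blocks, snps_per_block=snps_per_block, maf=maf,
        within_block_corr=within_block_corr, chrom=chrom, positions=positions,
        block=block,
    )


def _draw_genotypes(panel: HaplotypePanel, n_samples: int, maf: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Genotypes via the block-AR(1) Gaussian copula, two haplotypes/sample."""
    rho = panel.within_block_corr
    m = panel.n_variants
    thresh = stats.norm.ppf(maf)  # allele present when z < threshold
    hap_sum = np.zeros((n_samples, m))
    for _ in range(2):
        z = rng.standard_normal((n_samples, m))
        if rho > 0:
            for b in range(panel.n_blocks):
                sl = slice(b * panel.snps_per_block, (b + 1) * panel.snps_per_block)
                zb = z[:, sl]
                w = np.sqrt(1 - rho ** 2)
                for j in range(1, zb.shape[1]):
                    zb[:, j] = rho * zb[:, j - 1] + w * zb[:, j]
                z[:, sl] = zb
        hap_sum += (z < thresh[None, :]).astype(float)
    return hap_sum


def simulate_genotypes(panel: HaplotypePanel, n_samples: int,
                       seed: int = 0) -> np.ndarray:
    """Unstructured genotype draw (single population, panel MAFs)."""
    rng = np.random.default_rng(seed)
    return _draw_genotypes(panel, n_samples, panel.maf, rng)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_cohort(panel: HaplotypePanel,
                    n_lli: int,
                    n_controls: int,
                    disease_specs: list[DiseaseSpec] | None = None,
                    longevity_own_h2: float = 0.15,
                    sex_ratio_lli: float = 2.7,
                    sex_ratio_controls: float = 0.7,
                    substructure_delta: float = 0.0,
                    missing_rate: float = 0.01,
                    apoe_block: int | None = None,
                    apoe_effect: float = 1.0,
                    seed: int = 0,
                    ) -> tuple[GenotypeMatrix, pd.DataFrame, CohortTruth]:
    """Simulate an LLI/control cohort under the liability-threshold model.

    For each disease d, liability ``L_d = G_d + e_d`` with ``G_d = X @ beta_d``.
    The longevity liability is
    ``L_long = sum_d coupling_d * std(G_d) + a * std(G_own) + e`` with the own
    polygenic weight ``a`` set so its variance share of the genetic part is
    ``longevity_own_h2``-scaled against unit environmental noise. The ``n_lli``
    samples with the largest longevity liability are the cases, matching the
    tail rate ``n_lli / (n_lli + n_controls)`` exactly.

    Sex is drawn per group at the given women:men ratios (exact counts,
    shuffled); ``substructure_delta`` shifts the allele frequency of a random
    fifth of variants in one of two equal subpopulations. When ``apoe_block``
    is given, three variants of that block get own-effects ``apoe_effect``
    (>= 10x the median own effect for the defaults), mimicking the
    large-effect APOE-region variants.

    Returns the genotype matrix (missing calls injected at ``missing_rate``
    per variant), a phenotype table (sample_id, group, case, sex, subpop) and
    the ground truth.
    """
    n_total = n_lli + n_controls
    if n_lli < 1 or n_controls < 1:
        raise ParameterError("need at least one LLI and one control")
    if n_lli > n_total:
        raise ParameterError("infeasible tail: n_lli exceeds cohort size")
    if not 0 <= longevity_own_h2 < 1:
        raise ParameterError("longevity_own_h2 must lie in [0, 1)")
    if disease_specs is None:
        disease_specs = default_disease_specs(panel.n_variants)
    for spec in disease_specs:
        if spec.n_causal > panel.n_variants:
            raise ParameterError(f"{spec.name}: n_causal exceeds panel size")

    rng = np.random.default_rng(seed)
    m = panel.n_variants

    # population substructure: two subpops, shifted MAFs on 20% of variants
    subpop = rng.integers(0, 2, n_total)
    maf0 = panel.maf.copy()
    maf1 = panel.maf.copy()
    if substructure_delta > 0:
        shifted = rng.random(m) < 0.2
        sign = rng.choice([-1.0, 1.0], m)
        maf1[shifted] = np.clip(
            maf1[shifted] + sign[shifted] * substructure_delta, 0.005, 0.995
        )
    X = np.empty((n_total, m))
    idx0, idx1 = np.where(subpop == 0)[0], np.where(subpop == 1)[0]
    X[idx0] = _draw_genotypes(panel, idx0.size, maf0, rng)
    X[idx1] = _draw_genotypes(panel, idx1.size, maf1, rng)

    # per-disease genetic components and liabilities
    disease_beta, genetic, liab_d, status = {}, {}, {}, {}
    couplings = {}
    for spec in disease_specs:
        beta = np.zeros(m)
        causal = rng.choice(m, spec.n_causal, replace=False)
        beta[causal] = rng.normal(0.0, spec.effect_sd, spec.n_causal)
        g = X @ beta
        eps = rng.standard_normal(n_total)
        ld = g + eps
        thresh = np.quantile(ld, 1 - spec.prevalence_target)
        disease_beta[spec.name] = beta
        genetic[spec.name] = g
        liab_d[spec.name] = ld
        status[spec.name] = (ld > thresh).astype(int)
        couplings[spec.name] = spec.longevity_coupling

    # longevity's own polygenic component (plus the APOE-analogue block)
    own_beta = np.zeros(m)
    n_own = max(5, m // 50)
    own_causal = rng.choice(m, n_own, replace=False)
    own_beta[own_causal] = rng.normal(0.0, 0.1, n_own)
    apoe_snvs = np.array([], dtype=int)
    if apoe_block is not None:
        sl = np.arange(apoe_block * panel.snps_per_block,
                       (apoe_block + 1) * panel.snps_per_block)
        apoe_snvs = rng.choice(sl, min(3, sl.size), replace=False)
        own_beta[apoe_snvs] = -apoe_effect  # risk alleles reduce longevity

    g_own = X @ own_beta
    csum = sum(c ** 2 for c in couplings.values())
    if longevity_own_h2 > 0 and g_own.std() > 0:
        a = np.sqrt(longevity_own_h2 * (csum + 1.0) / (1.0 - longevity_own_h2))
    else:
        a = 0.0
    z_own = _standardize(g_own) if g_own.std() > 0 else g_own
    l_long = sum(couplings[s.name] * _standardize(genetic[s.name])
                 if genetic[s.name].std() > 0 else 0.0 * genetic[s.name]
                 for s in disease_specs)
    l_long = l_long + a * z_own + rng.standard_normal(n_total)

    order = np.argsort(-l_long, kind="stable")
    case = np.zeros(n_total, dtype=int)
    case[order[:n_lli]] = 1

    # per-variant marginal true effect on the longevity liability
    longevity_beta = np.zeros(m)
    for s in disease_specs:
        gsd = genetic[s.name].std()
        if gsd > 0:
            longevity_beta += couplings[s.name] * disease_beta[s.name] / gsd
    if a > 0:
        longevity_beta += a * own_beta / g_own.std()

    # sexes at exact per-group counts (1 = female)
    sex = np.zeros(n_total, dtype=int)
    for grp, ratio in ((1, sex_ratio_lli), (0, sex_ratio_controls)):
        members = np.where(case == grp)[0]
        n_f = int(round(members.size * ratio / (1.0 + ratio)))
        fem = rng.choice(members, n_f, replace=False)
        sex[fem] = 1

    dosage = X.astype(float)
    if missing_rate > 0:
        miss = rng.random((n_total, m)) < missing_rate
        dosage = dosage.copy()
        dosage[miss] = np.nan

    samples = [f"S{i:05d}" for i in range(n_total)]
    gm = GenotypeMatrix(samples=samples, variants=panel.variant_frame(),
                        dosage=dosage)
    pheno = pd.DataFrame({
        "sample_id": samples,
        "group": np.where(case == 1, "LLI", "control"),
        "case": case,
        "sex": sex,
        "subpop": subpop,
    })
    truth = CohortTruth(
        disease_beta=disease_beta, longevity_beta=longevity_beta,
        own_beta=own_beta, couplings=couplings,
        liability_longevity=l_long, liability_disease=liab_d,
        genetic_disease=genetic, disease_status=status,
        subpop=subpop, maf=panel.maf, seed=seed, apoe_snvs=apoe_snvs,
    )
    return gm, pheno, truth


def simulate_gwas_weights(truth: CohortTruth, disease: str,
                          n_gwas: int, seed: int = 0) -> pd.DataFrame:
    """Emulate GWAS summary statistics for one disease (or "longevity").

    Estimated betas are the true betas plus Gaussian noise with standard
    error ``1 / sqrt(n_gwas * 2 * maf * (1 - maf))``; p-values come from the
    implied two-sided Wald statistic. Returns a weight table without
    panel metadata columns filled in (caller merges with the panel's variant
    frame via :func:`attach_panel_alleles`).
    """
    if n_gwas <= 0:
        raise ParameterError("n_gwas must be positive")
    if disease == "longevity":
        beta = truth.longevity_beta
    elif disease in truth.disease_beta:
        beta = truth.disease_beta[disease]
    else:
        raise KeyError(f"unknown disease {disease!r}")
    rng = np.random.default_rng(seed)
    se = 1.0 / np.sqrt(n_gwas * 2.0 * truth.maf * (1.0 - truth.maf))
    beta_hat = beta + rng.normal(0.0, se)
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"beta": beta_hat, "se": se, "p": p})


def attach_panel_alleles(weights: pd.DataFrame,
                         gm: GenotypeMatrix) -> pd.DataFrame:
    """Merge positional summary stats with the panel's variant metadata.

    ``weights`` rows must align 1:1 with ``gm.variants`` (the simulator's
    convention); the result is a full weight table in the genoio schema.
    """
    if len(weights) != gm.n_variants:
        raise ParameterError("weights do not align with the panel")
    v = gm.variants
    out = pd.DataFrame({
        "chrom": v["chrom"], "pos": v["pos"], "id": v["id"],
        "effect_allele": v["counted_allele"], "other_allele": v["other_allele"],
        "beta": weights["beta"].values, "p": weights["p"].values,
    })
    return out
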