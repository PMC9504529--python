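"""Per-individual and per-marker quality control and substructure handling.

The chain mirrors standard array-QC practice: sample filters (call rate,
heterozygosity band, relatedness via method-of-moments PI_HAT on an
LD-thinned marker subset), marker filters in a fixed order (missingness ->
Hardy-Weinberg in controls -> MAF -> imputation quality), principal
components on frequency-standardized LD-thinned genotypes, and local
outlier factor flagging of substructure outliers in PC space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genoio import GenotypeMatrix


class ParameterError(ValueError):
    pass


@dataclass
class QCThresholds:
    """Default thresholds of the QC chain (array-era conventions)."""

    ind_missing_max: float = 0.08
    marker_missing_max: float = 0.05
    het_sd: float = 4.0
    ibd_max: float = 0.1875
    hwe_p_min: float = 1e-5
    hwe_p_min_postimp: float = 1e-9
    maf_min: float = 0.01
    impq_min: float = 0.75
    n_pcs: int = 5
    lof_max: float = 2.1
    lof_k_neighbors: int = 20


@dataclass
class QCResult:
    kept_samples: list[str]
    kept_variants: np.ndarray  # integer indices into the input panel
    sample_reasons: dict[str, str] = field(default_factory=dict)
    variant_reasons: dict[str, int] = field(default_factory=dict)
    pcs: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact test of Hardy-Weinberg equilibrium on genotype counts.

    Conditional on the allele counts, the heterozygote count under HWE
    follows a known distribution; the p-value sums the probabilities of all
    heterozygote counts no more probable than the observed one (computed by
    the standard recurrence, so no factorials overflow).
    Monomorphic input returns 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ParameterError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ParameterError("all genotype counts are zero")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # probabilities over all heterozygote counts with the observed parity
    het_obs = n_Aa
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (hom_r+1)(hom_c+1))
    h = mid
    while h >= 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h + 2 <= n_rare:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        if hom_r < 1 or hom_c < 1:
            break  # upward states impossible from here on
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs[het_obs] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts (hom-other, het, hom-counted) ignoring NaN."""
    d = dosage_col[~np.isnan(dosage_col)]
    g = np.rint(d).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


# ---------------------------------------------------------------------------
# relatedness

def ld_thin(gm: GenotypeMatrix, r2_max: float = 0.2, window: int = 50,
            ) -> np.ndarray:
    """Greedy LD thinning: keep a variant unless its r^2 with an already-kept
    variant within the trailing ``window``-SNV span exceeds ``r2_max``.
    Returns kept variant indices."""
    X = gm.filled()
    sd = X.std(axis=0)
    kept: list[int] = []
    for j in range(gm.n_variants):
        if sd[j] == 0:
            continue
        ok = True
        for k in reversed(kept):
            if j - k > window:
                break
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.array(kept, dtype=int)


def pi_hat_matrix(gm: GenotypeMatrix,
                  variant_subset: np.ndarray | None = None) -> np.ndarray:
    """Method-of-moments PI_HAT (P(IBD=1)/2 + P(IBD=2)) for all sample pairs.

    Uses the classic ratio estimator from identity-by-state counts and
    panel allele frequencies (bias corrections for finite reference samples
    omitted). Dosages are hard-called; missing genotypes drop the marker
    for that pair; pairs sharing fewer than 10 markers get NaN.
    """
    cols = (variant_subset if variant_subset is not None
            else np.arange(gm.n_variants))
    D = gm.dosage[:, cols]
    G = np.rint(D)
    p = np.nanmean(D, axis=0) / 2.0
    informative = (p > 0.01) & (p < 0.99)
    G = G[:, informative]
    p = p[informative]
    q = 1.0 - p
    # expected IBS-class proportions per marker under each IBD state
    e0_ibs0 = 2 * p ** 2 * q ** 2
    e0_ibs1 = 4 * p ** 3 * q + 4 * p * q ** 3
    e1_ibs1 = 2 * p ** 2 * q + 2 * p * q ** 2
    e1_ibs2 = p ** 3 + q ** 3 + p ** 2 * q + p * q ** 2

    V = (~np.isnan(G)).astype(float)
    A = [((G == k) & (V > 0)).astype(float) for k in (0.0, 1.0, 2.0)]
    IBS0 = A[0] @ A[2].T + A[2] @ A[0].T
    IBS2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    NV = V @ V.T
    IBS1 = NV - IBS0 - IBS2
    E0_0 = (V * e0_ibs0) @ V.T
    E0_1 = (V * e0_ibs1) @ V.T
    E1_1 = (V * e1_ibs1) @ V.T
    E1_2 = (V * e1_ibs2) @ V.T
    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = np.where(E0_0 > 0, IBS0 / E0_0, 0.0)
        P1 = np.where(E1_1 > 0, (IBS1 - P0 * E0_1) / E1_1, 0.0)
        P2 = (IBS2 - P0 * (NV - E0_0 - E0_1) - P1 * E1_2) / np.maximum(NV, 1)
    P0, P1, P2 = (np.clip(x, 0.0, 1.0) for x in (P0, P1, P2))
    tot = np.maximum(P0 + P1 + P2, 1e-12)
    PH = (P1 / tot) / 2.0 + P2 / tot
    PH[NV < 10] = np.nan
    return PH


def pi_hat(gm: GenotypeMatrix, pairs: list[tuple[int, int]] | None = None,
           variant_subset: np.ndarray | None = None) -> pd.DataFrame:
    """PI_HAT per sample pair as a table (see :func:`pi_hat_matrix`)."""
    PH = pi_hat_matrix(gm, variant_subset)
    n = gm.n_samples
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rows = [(gm.samples[i], gm.samples[j], PH[i, j]) for i, j in pairs]
    return pd.DataFrame(rows, columns=["sample1", "sample2", "pi_hat"])


# ---------------------------------------------------------------------------
# sample and marker filters

def sample_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None,
              seed: int = 0) -> QCResult:
    """Per-individual QC: call rate, heterozygosity band, relatedness.

    The heterozygosity band (mean +/- ``het_sd`` SD of the per-sample
    heterozygous fraction) is computed on the post-missingness-filter set.
    For each related pair (PI_HAT above threshold) the member with higher
    missingness is removed; ties break to keeping the lexicographically
    smaller ID.
    """
    if gm.n_samples < 2:
        raise ParameterError("sample QC needs at least 2 samples")
    th = thresholds or QCThresholds()
    reasons: dict[str, str] = {}
    miss = gm.missing.mean(axis=1)
    alive = np.ones(gm.n_samples, dtype=bool)
    for i in np.where(miss > th.ind_missing_max)[0]:
        alive[i] = False
        reasons[gm.samples[i]] = "missingness"

    G = np.rint(gm.dosage)
    het = np.nanmean(G == 1, axis=1)
    band = het[alive]
    mu, sd = band.mean(), band.std()
    if sd > 0:
        for i in np.where(alive & (np.abs(het - mu) > th.het_sd * sd))[0]:
            alive[i] = False
            reasons[gm.samples[i]] = "heterozygosity"

    thin = ld_thin(gm, r2_max=0.2, window=50)
    idx_alive = np.where(alive)[0]
    sub = gm.subset_samples(idx_alive)
    PH = pi_hat_matrix(sub, variant_subset=thin)
    iu = np.triu_indices(len(idx_alive), k=1)
    hot = (PH[iu] > th.ibd_max) & ~np.isnan(PH[iu])
    related = sorted(
        (gm.samples[idx_alive[a]], gm.samples[idx_alive[b]])
        for a, b in zip(iu[0][hot], iu[1][hot])
    )
    name_to_global = {gm.samples[i]: i for i in idx_alive}
    for s1, s2 in related:
        i, j = name_to_global[s1], name_to_global[s2]
        if not (alive[i] and alive[j]):
            continue
        mi, mj = miss[i], miss[j]
        if mi > mj:
            drop = i
        elif mj > mi:
            drop = j
        else:  # tie: keep the lexicographically smaller ID
            drop = j if gm.samples[i] < gm.samples[j] else i
        alive[drop] = False
        reasons[gm.samples[drop]] = "relatedness"

    kept = [gm.samples[i] for i in np.where(alive)[0]]
    return QCResult(kept_samples=kept, kept_variants=np.arange(gm.n_variants),
                    sample_reasons=reasons)


def marker_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None,
              control_mask: np.ndarray | None = None,
              postimputation: bool = False) -> QCResult:
    """Per-marker QC in the fixed order missingness -> HWE -> MAF -> impq.

    HWE is evaluated in controls only; the imputation-quality filter applies
    only when the panel carries an ``impq`` column.
    """
    th = thresholds or QCThresholds()
    if control_mask is None:
        raise ParameterError("control_mask is required (HWE runs in controls)")
    control_mask = np.asarray(control_mask, dtype=bool)
    if not control_mask.any():
        raise ParameterError("empty control mask with HWE requested")
    hwe_min = th.hwe_p_min_postimp if postimputation else th.hwe_p_min

    reasons = {"missingness": 0, "hwe": 0, "maf": 0, "impq": 0}
    keep = np.ones(gm.n_variants, dtype=bool)
    miss = gm.missing.mean(axis=0)
    drop = miss > th.marker_missing_max
    reasons["missingness"] = int(drop.sum())
    keep &= ~drop

    ctrl = gm.dosage[control_mask]
    for j in np.where(keep)[0]:
        n0, n1, n2 = genotype_counts(ctrl[:, j])
        if n0 + n1 + n2 == 0:
            continue
        if hwe_exact_test(n2, n1, n0) < hwe_min:
            keep[j] = False
            reasons["hwe"] += 1

    freq = gm.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    drop = keep & (maf < th.maf_min)
    reasons["maf"] = int(drop.sum())
    keep &= ~drop

    if "impq" in gm.variants.columns:
        impq = gm.variants["impq"].to_numpy(dtype=float)
        drop = keep & ~np.isnan(impq) & (impq < th.impq_min)
        reasons["impq"] = int(drop.sum())
        keep &= ~drop

    return QCResult(kept_samples=list(gm.samples),
                    kept_variants=np.where(keep)[0],
                    variant_reasons={k: v for k, v in reasons.items() if v})


# ---------------------------------------------------------------------------
# substructure

def pca_substructure(gm: GenotypeMatrix, n_pcs: int = 5,
                     ld_thin_first: bool = True) -> np.ndarray:
    """Principal components of frequency-standardized genotypes.

    Markers are centered by 2p and scaled by sqrt(2p(1-p)) (missing entries
    contribute zero after centering), optionally LD-thinned first. The sign
    of each PC is fixed so it correlates positively with the sample index.
    """
    cols = ld_thin(gm) if ld_thin_first else np.arange(gm.n_variants)
    X = gm.filled()[:, cols]
    p = X.mean(axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    X = X[:, ok]
    p = p[ok]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    rank = min(Z.shape)
    if n_pcs > rank:
        raise ParameterError(f"n_pcs={n_pcs} exceeds rank {rank}")
    U, _, _ = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :n_pcs]  # orthonormal sample loadings (eigenvector convention)
    idx = np.arange(pcs.shape[0])
    for k in range(n_pcs):
        if np.corrcoef(pcs[:, k], idx)[0, 1] < 0:
            pcs[:, k] = -pcs[:, k]
    return pcs


def lof_outliers(pcs: np.ndarray, k_neighbors: int = 20,
                 lof_max: float = 2.1) -> np.ndarray:
    """Local-outlier-factor mask on PC coordinates (True = outlier)."""
    from sklearn.neighbors import LocalOutlierFactor

    pcs = np.asarray(pcs, dtype=float)
    if k_neighbors >= pcs.shape[0]:
        raise ParameterError("k_neighbors must be < n_samples")
    lof = LocalOutlierFactor(n_neighbors=k_neighbors)
    lof.fit(pcs)
    scores = -lof.negative_outlier_factor_
    return scores > lof_max
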