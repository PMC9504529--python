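"""Longevity GPS construction: LD clumping, C+T scan, region exclusion,
APOE haplotype calling and backward-stepwise augmentation.

The clumping-and-thresholding (C+T) family builds a genome-wide polygenic
score from summary statistics in two moves: greedy LD clumping keeps, at
each step, the smallest-p unassigned variant as an index and absorbs its LD
neighbours (r^2 above threshold within a physical window); then, for each
p-value cutoff of a fixed grid, the index variants passing the cutoff are
scored and the cutoff with the best discovery-set AUC wins (ties break to
the most stringent cutoff). Variants of a strong-effect region (the
TOMM40/APOE/APOC1 analogue) can be excluded up front and later re-admitted,
together with the APOE epsilon haplotype, through AIC-based backward
stepwise regression on the discovery set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scoring
from .evaluate import EvalReport, auc_with_ci, fit_score_logistic
from .genoio import GenotypeMatrix, harmonize

log = logging.getLogger(__name__)

#: default p-value cutoff grid of the C+T scan (11 entries)
DEFAULT_GRID = (5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 3e-3, 5e-3, 1e-2, 3e-2, 5e-1, 1.0)

#: the excluded strong-effect region: chromosome, 1-based inclusive bounds
DEFAULT_REGION = ("19", 45_351_000, 45_500_000)


@dataclass
class ClumpParams:
    r2_max: float = 0.1
    window_kb: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.r2_max < 1:
            raise ValueError("r2_max must lie in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


def make_grid(cutoffs=DEFAULT_GRID) -> np.ndarray:
    grid = np.asarray(cutoffs, dtype=float)
    if not (np.diff(grid) > 0).all():
        raise ValueError("grid cutoffs must be strictly increasing")
    return grid


def clump(sumstats: pd.DataFrame, gm: GenotypeMatrix,
          params: ClumpParams | None = None) -> list[int]:
    """Greedy LD clumping; returns sumstats row indices of the index variants.

    Repeatedly takes the smallest-p unassigned variant as an index and
    assigns to it every unassigned variant on the same chromosome within
    ``window_kb`` whose dosage r^2 with the index exceeds ``r2_max``
    (r^2 from the sample genotypes, no external reference). Variants absent
    from the panel are dropped with a logged count. Ties on p break by
    sumstats row order.
    """
    params = params or ClumpParams()
    if "panel_index" not in sumstats.columns:
        sumstats, _ = harmonize(sumstats, gm)
    n_dropped = 0
    ss = sumstats.reset_index(drop=True)
    if ss["panel_index"].isna().any():
        n_dropped = int(ss["panel_index"].isna().sum())
        ss = ss.dropna(subset=["panel_index"])
    if n_dropped:
        log.info("clump: dropped %d variants absent from the panel", n_dropped)
    X = gm.filled()
    order = np.lexsort((np.arange(len(ss)), ss["p"].to_numpy(dtype=float)))
    assigned = np.zeros(len(ss), dtype=bool)
    chrom = ss["chrom"].to_numpy()
    pos = ss["pos"].to_numpy(dtype=float)
    pidx = ss["panel_index"].to_numpy(dtype=int)
    window_bp = params.window_kb * 1_000.0
    indices: list[int] = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        indices.append(int(i))
        near = np.where(
            (~assigned) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        )[0]
        if near.size == 0:
            continue
        xi = X[:, pidx[i]]
        if xi.std() == 0:
            continue
        for j in near:
            xj = X[:, pidx[j]]
            if xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if r * r > params.r2_max:
                assigned[j] = True
    return indices


def exclude_region(table: pd.DataFrame,
                   region: tuple[str, int, int] = DEFAULT_REGION) -> pd.DataFrame:
    """Drop rows with chrom == region chromosome and start <= pos <= end
    (1-based inclusive bounds)."""
    chrom, start, end = region
    if start > end:
        raise ValueError("region start exceeds end")
    mask = (table["chrom"].astype(str) == str(chrom)) & \
        (table["pos"] >= start) & (table["pos"] <= end)
    return table[~mask].reset_index(drop=True)


def region_mask(variants: pd.DataFrame,
                region: tuple[str, int, int] = DEFAULT_REGION) -> np.ndarray:
    chrom, start, end = region
    return ((variants["chrom"].astype(str) == str(chrom))
            & (variants["pos"] >= start) & (variants["pos"] <= end)).to_numpy()


# ---------------------------------------------------------------------------
# C+T scan

@dataclass
class CTModel:
    """The frozen score selected by a C+T scan."""

    weights: pd.DataFrame  # harmonized subset used by the selected score
    cutoff: float
    logistic_params: np.ndarray | None = None  # [intercept, score(, covs...)]
    covariate_names: list[str] = field(default_factory=list)
    train_mean: float = 0.0
    train_sd: float = 1.0

    def score(self, gm: GenotypeMatrix) -> np.ndarray:
        if len(self.weights) == 0:
            return np.zeros(gm.n_samples)
        sv = scoring.compute_prs(gm, self.weights)
        return (sv.score - self.train_mean) / self.train_sd


@dataclass
class CTScanResult:
    grid_table: pd.DataFrame  # cutoff, n_snvs, auc_discovery
    selected: CTModel

    @property
    def selected_cutoff(self) -> float:
        return self.selected.cutoff


def ct_scan(gm: GenotypeMatrix, labels: np.ndarray, sumstats: pd.DataFrame,
            grid=DEFAULT_GRID, params: ClumpParams | None = None,
            covariates: pd.DataFrame | None = None) -> CTScanResult:
    """Clumping-and-thresholding scan on the discovery set.

    ``sumstats`` must be harmonized to ``gm`` (carry ``panel_index``) and
    have a ``p`` column. Clumping runs once on the full sumstats; each grid
    cutoff keeps the index SNVs with p <= cutoff, scores the discovery
    samples and records the discovery AUC (score alone, or of the logistic
    linear predictor including covariates when given). The winning cutoff
    maximizes discovery AUC; exact ties go to the most stringent cutoff.
    A cutoff admitting zero SNVs scores AUC 0.5 with n = 0.
    """
    grid = make_grid(grid)
    params = params or ClumpParams()
    labels = np.asarray(labels, dtype=int)
    if "panel_index" not in sumstats.columns:
        sumstats, _ = harmonize(sumstats, gm)
    ss = sumstats.reset_index(drop=True)
    index_rows = clump(ss, gm, params)
    idx_tab = ss.iloc[index_rows].reset_index(drop=True)

    rows = []
    best = None  # (auc, -cutoff) maximized with strict >
    for cutoff in grid:
        sub = idx_tab[idx_tab["p"] <= cutoff].reset_index(drop=True)
        n_snvs = len(sub)
        if n_snvs == 0:
            rows.append({"cutoff": cutoff, "n_snvs": 0, "auc_discovery": 0.5})
            continue
        sv = scoring.compute_prs(gm, sub)
        raw = sv.score
        mu, sd = raw.mean(), raw.std()
        z = (raw - mu) / sd if sd > 0 else raw - mu
        if covariates is not None:
            rep = fit_score_logistic(z, labels, covariates)
            auc = rep.auc
        else:
            auc, _, _ = auc_with_ci(z, labels)
            auc = max(auc, 1.0 - auc)  # orientation-free discrimination
        rows.append({"cutoff": cutoff, "n_snvs": n_snvs, "auc_discovery": auc})
        if best is None or auc > best[0] + 1e-12:
            best = (auc, cutoff, sub, mu, sd)

    if best is None:
        # every cutoff empty: freeze an empty score at the loosest cutoff
        selected = CTModel(weights=idx_tab.iloc[0:0], cutoff=float(grid[-1]))
    else:
        _, cutoff, sub, mu, sd = best
        selected = CTModel(weights=sub, cutoff=float(cutoff),
                           train_mean=mu, train_sd=(sd if sd > 0 else 1.0))
    return CTScanResult(grid_table=pd.DataFrame(rows), selected=selected)


def evaluate_ct_model(model: CTModel, gm_test: GenotypeMatrix,
                      labels_test: np.ndarray,
                      covariates: pd.DataFrame | None = None,
                      name: str = "GPS") -> EvalReport:
    """Score the frozen C+T model on held-out samples and evaluate it."""
    z = model.score(gm_test)
    return fit_score_logistic(z, np.asarray(labels_test, dtype=int),
                              covariates, name=name)


# ---------------------------------------------------------------------------
# APOE epsilon haplotype

@dataclass
class ApoeDiplotype:
    """Two epsilon alleles called from rs429358 and rs7412 genotypes."""

    allele1: str
    allele2: str
    ambiguous: bool = False

    @property
    def e2_count(self) -> int:
        return (self.allele1 == "e2") + (self.allele2 == "e2")

    @property
    def e4_count(self) -> int:
        return (self.allele1 == "e4") + (self.allele2 == "e4")


_HAP_TO_EPS = {("T", "T"): "e2", ("T", "C"): "e3",
               ("C", "C"): "e4", ("C", "T"): "e1"}


def call_apoe_haplotype(geno_rs429358: tuple[str, str] | None,
                        geno_rs7412: tuple[str, str] | None,
                        ) -> ApoeDiplotype | None:
    """Call the epsilon diplotype from unphased genotypes at the two sites.

    Per haplotype (rs429358, rs7412): T&T -> e2, T&C -> e3, C&C -> e4,
    C&T -> e1 (rare). The unphased double heterozygote is ambiguous
    (e2/e4 vs e1/e3) and resolves to e2/e4 by default with the flag set.
    Missing genotypes at either site return None.
    """
    if geno_rs429358 is None or geno_rs7412 is None:
        return None
    g1 = tuple(a.upper() for a in geno_rs429358)
    g2 = tuple(a.upper() for a in geno_rs7412)
    for g in (g1, g2):
        if any(a not in ("C", "T") for a in g):
            return None
    het1 = g1[0] != g1[1]
    het2 = g2[0] != g2[1]
    if het1 and het2:
        return ApoeDiplotype("e2", "e4", ambiguous=True)
    # at most one site heterozygous: phasing is unique
    hap_a = (g1[0], g2[0])
    hap_b = (g1[1], g2[1])
    if het1:
        hap_a, hap_b = (g1[0], g2[0]), (g1[1], g2[0])
    if het2:
        hap_a, hap_b = (g1[0], g2[0]), (g1[0], g2[1])
    e = sorted([_HAP_TO_EPS[hap_a], _HAP_TO_EPS[hap_b]])
    return ApoeDiplotype(e[0], e[1])


def apoe_from_dosage(dose_rs429358: float, dose_rs7412: float,
                     ) -> ApoeDiplotype | None:
    """Epsilon diplotype from hard-called C-allele dosages at the two sites.

    ``dose`` counts the C allele (0, 1 or 2) at each site; NaN -> None.
    """
    if np.isnan(dose_rs429358) or np.isnan(dose_rs7412):
        return None
    c1 = int(round(dose_rs429358))
    c2 = int(round(dose_rs7412))
    g1 = ("C",) * c1 + ("T",) * (2 - c1)
    g2 = ("C",) * c2 + ("T",) * (2 - c2)
    return call_apoe_haplotype(g1, g2)


# ---------------------------------------------------------------------------
# backward stepwise augmentation (GPSlong II+)

@dataclass
class StepwiseModel:
    retained: list[str]
    params: pd.Series
    train_columns: list[str]

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(design), float(self.params.get("const", 0.0)))
        for c in self.retained:
            lp += float(self.params[c]) * np.asarray(design[c], dtype=float)
        return lp


def thin_candidates(gm: GenotypeMatrix, candidate_index: np.ndarray,
                    r2_cap: float = 0.1, maf_min: float = 0.01,
                    max_candidates: int | None = 30) -> np.ndarray:
    """Greedily thin candidate SNVs to pairwise r^2 <= cap and MAF > min.

    Candidates are taken in panel order; a variant enters only if its r^2
    with every previously accepted candidate stays at or below the cap.
    ``max_candidates`` truncates the accepted list (configurable; the
    candidate-universe size is a knob, not a constant).
    """
    X = gm.filled()
    freq = gm.allele_freq()
    accepted: list[int] = []
    for j in candidate_index:
        maf = min(freq[j], 1 - freq[j])
        if maf <= maf_min or np.isnan(maf):
            continue
        ok = True
        for k in accepted:
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if r * r > r2_cap:
                ok = False
                break
        if ok:
            accepted.append(int(j))
        if max_candidates is not None and len(accepted) >= max_candidates:
            break
    return np.array(accepted, dtype=int)


def backward_stepwise(design: pd.DataFrame, labels: np.ndarray,
                      protected: tuple[str, ...] = (),
                      criterion: str = "aic") -> StepwiseModel:
    """AIC-based backward elimination of a logistic model.

    Starts from the full model and removes, one at a time, the variable
    whose removal lowers the AIC the most, stopping when no removal
    improves it. Collinear columns are pre-dropped (logged). Columns in
    ``protected`` are never removed.
    """
    import statsmodels.api as sm

    if criterion != "aic":
        raise ValueError("only the AIC criterion is implemented")
    y = np.asarray(labels, dtype=int)
    design = design.copy()
    # pre-drop constant and collinear candidates
    drop = [c for c in design.columns if design[c].std() == 0]
    X = design.drop(columns=drop)
    q = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    while q < X.shape[1] + 1:
        # drop the last unprotected column until full rank
        removable = [c for c in X.columns if c not in protected]
        if not removable:
            break
        c = removable[-1]
        drop.append(c)
        X = X.drop(columns=c)
        q = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if drop:
        log.info("backward_stepwise: pre-dropped %s", drop)

    def fit_aic(cols: list[str]):
        Xc = sm.add_constant(X[cols], has_constant="add")
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        return fit, float(fit.aic)

    cols = list(X.columns)
    fit, aic = fit_aic(cols)
    improved = True
    while improved and cols:
        improved = False
        best_aic, best_cols, best_fit = aic, cols, fit
        for c in cols:
            if c in protected:
                continue
            trial = [x for x in cols if x != c]
            try:
                f, a = fit_aic(trial)
            except Exception:
                continue
            if a < best_aic - 1e-9:
                best_aic, best_cols, best_fit = a, trial, f
        if best_cols is not cols:
            cols, aic, fit = best_cols, best_aic, best_fit
            improved = True
    return StepwiseModel(retained=cols, params=fit.params,
                         train_columns=list(X.columns))


def build_gpslong_ii_plus(gps2_model: CTModel,
                          gm_disc: GenotypeMatrix, labels_disc: np.ndarray,
                          region: tuple[str, int, int] = DEFAULT_REGION,
                          apoe_ids: tuple[str, str] | None = None,
                          apoe_index: tuple[int, int] | None = None,
                          r2_cap: float = 0.1, maf_min: float = 0.01,
                          max_candidates: int | None = 30,
                          ) -> tuple[StepwiseModel, pd.DataFrame]:
    """Augment a region-excluded GPS with region SNVs and the APOE haplotype.

    Candidates: the GPSlong II score, the region's SNV dosages greedily
    thinned to pairwise r^2 <= ``r2_cap`` with MAF > ``maf_min``, and the
    epsilon-2 / epsilon-4 allele counts when the two APOE coding sites are
    identified (by variant id or panel index). Backward AIC elimination on
    the discovery set returns the final model plus a function of the design;
    use :func:`stepwise_design` to build the matching test design.
    """
    design = stepwise_design(gps2_model, gm_disc, region=region,
                             apoe_ids=apoe_ids, apoe_index=apoe_index,
                             r2_cap=r2_cap, maf_min=maf_min,
                             max_candidates=max_candidates,
                             _fit_thinning_on=gm_disc)
    model = backward_stepwise(design, labels_disc, protected=())
    return model, design


def stepwise_design(gps2_model: CTModel, gm: GenotypeMatrix,
                    region: tuple[str, int, int] = DEFAULT_REGION,
                    apoe_ids: tuple[str, str] | None = None,
                    apoe_index: tuple[int, int] | None = None,
                    r2_cap: float = 0.1, maf_min: float = 0.01,
                    max_candidates: int | None = 30,
                    candidate_index: np.ndarray | None = None,
                    _fit_thinning_on: GenotypeMatrix | None = None,
                    ) -> pd.DataFrame:
    """Design matrix for the stepwise model: gps2 score, region SNVs, APOE.

    Pass ``candidate_index`` to reuse the thinned candidate set chosen on
    the discovery data when building the test design.
    """
    cols = {"gps2": gps2_model.score(gm)}
    thin_on = _fit_thinning_on or gm
    if candidate_index is None:
        cand = np.where(region_mask(thin_on.variants, region))[0]
        candidate_index = thin_candidates(thin_on, cand, r2_cap=r2_cap,
                                          maf_min=maf_min,
                                          max_candidates=max_candidates)
    X = gm.filled()
    for j in candidate_index:
        cols[f"snv_{gm.variants['id'][j]}"] = X[:, j]
    apoe = None
    if apoe_ids is not None:
        id_to_idx = {v: j for j, v in enumerate(gm.variants["id"])}
        apoe = (id_to_idx[apoe_ids[0]], id_to_idx[apoe_ids[1]])
    elif apoe_index is not None:
        apoe = apoe_index
    if apoe is not None:
        d1 = np.rint(X[:, apoe[0]])
        d2 = np.rint(X[:, apoe[1]])
        dips = [apoe_from_dosage(a, b) for a, b in zip(d1, d2)]
        cols["apoe_e2"] = [d.e2_count if d else 0 for d in dips]
        cols["apoe_e4"] = [d.e4_count if d else 0 for d in dips]
    design = pd.DataFrame(cols)
    design.attrs["candidate_index"] = np.asarray(candidate_index, dtype=int)
    return design


def apply_published_score(gm: GenotypeMatrix, weight_table: pd.DataFrame,
                          labels: np.ndarray,
                          covariates: pd.DataFrame | None = None,
                          name: str = "published",
                          drop_ambiguous: bool = True):
    """Replication path for an external weight set: harmonize, score, evaluate.

    Returns (ScoreVector, CoverageReport, EvalReport); the report carries
    the coverage so a table row renders "covered (percent)".
    """
    harmonized, coverage = harmonize(weight_table, gm,
                                     drop_ambiguous=drop_ambiguous)
    sv = scoring.compute_prs(gm, harmonized, coverage=coverage)
    z = scoring.standardize(sv.score)
    report = fit_score_logistic(z, np.asarray(labels, dtype=int), covariates,
                                name=name, coverage=coverage)
    return sv, coverage, report
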