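"""Single-variant logistic association, conditional analysis and FDR.

Each variant is tested under an additive model (dosage 0..2) by maximum-
likelihood logistic regression with sex and ancestry PCs as covariates.
Conditional analysis appends the dosages of designated SNVs (e.g. the
strong-effect APOE-region variants) to the covariate set, so signals driven
purely by LD with those variants lose significance. Multiple testing is
controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genoio import GenotypeMatrix

MAX_ITER = 100
_BETA_SEP = 15.0  # |beta| beyond this on a dosage scale signals separation


class ConditionSNVError(KeyError):
    """A conditioning SNV is absent from the panel."""


def _fit_one(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float, bool, bool]:
    """Fit one logistic model; returns (beta, se, p, converged, separation)
    for the first column of X (after the intercept)."""
    import statsmodels.api as sm
    from scipy import stats

    design = np.column_stack([np.ones(len(y)), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=MAX_ITER)
        except Exception:
            return np.nan, np.nan, np.nan, False, True
    converged = bool(fit.mle_retvals.get("converged", False))
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    separation = (not np.isfinite(beta) or not np.isfinite(se)
                  or abs(beta) > _BETA_SEP)
    if separation:
        return beta, se, np.nan, converged, True
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan
    return beta, se, p, converged, False


def single_variant_logistic(gm: GenotypeMatrix, labels: np.ndarray,
                            covariates: pd.DataFrame | None = None,
                            variant_index: np.ndarray | None = None,
                            ) -> pd.DataFrame:
    """Per-variant additive logistic association.

    Returns one row per tested variant: chrom, pos, id, beta, se, p, n,
    converged, separation. Non-converged and separated fits are flagged,
    never dropped. Missing dosages drop the sample for that variant.
    """
    labels = np.asarray(labels, dtype=int)
    cov = (np.empty((len(labels), 0)) if covariates is None
           else np.asarray(covariates, dtype=float))
    idx = (np.arange(gm.n_variants) if variant_index is None
           else np.asarray(variant_index, dtype=int))
    rows = []
    for j in idx:
        d = gm.dosage[:, j]
        ok = ~np.isnan(d)
        if cov.shape[1]:
            ok &= ~np.isnan(cov).any(axis=1)
        y = labels[ok]
        if d[ok].std() == 0 or len(np.unique(y)) < 2:
            rows.append((j, np.nan, np.nan, np.nan, int(ok.sum()), False, True))
            continue
        X = np.column_stack([d[ok], cov[ok]])
        beta, se, p, conv, sep = _fit_one(y, X)
        rows.append((j, beta, se, p, int(ok.sum()), conv, sep))
    out = pd.DataFrame(
        rows, columns=["variant_index", "beta", "se", "p", "n",
                       "converged", "separation"])
    v = gm.variants.iloc[out["variant_index"]].reset_index(drop=True)
    for c in ("chrom", "pos", "id"):
        out[c] = v[c].values
    return out[["chrom", "pos", "id", "variant_index", "beta", "se", "p", "n",
                "converged", "separation"]]


def conditional_analysis(gm: GenotypeMatrix, labels: np.ndarray,
                         condition_ids: list[str],
                         covariates: pd.DataFrame | None = None,
                         variant_index: np.ndarray | None = None,
                         ) -> pd.DataFrame:
    """Association with conditioning-SNV dosages appended to the covariates.

    ``condition_ids`` are variant IDs present in the panel; an absent ID
    raises :class:`ConditionSNVError`. With an empty condition set this
    reduces exactly to :func:`single_variant_logistic`.
    """
    id_to_idx = {v: j for j, v in enumerate(gm.variants["id"])}
    cond_idx = []
    for cid in condition_ids:
        if cid not in id_to_idx:
            raise ConditionSNVError(f"condition SNV {cid!r} absent from panel")
        cond_idx.append(id_to_idx[cid])
    if not cond_idx:
        return single_variant_logistic(gm, labels, covariates, variant_index)
    cond = pd.DataFrame(
        gm.filled()[:, cond_idx],
        columns=[f"cond_{gm.variants['id'][j]}" for j in cond_idx],
    )
    cov = cond if covariates is None else pd.concat(
        [covariates.reset_index(drop=True), cond], axis=1)
    return single_variant_logistic(gm, labels, cov, variant_index)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
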