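"""Logistic evaluation of a score: beta, OR, p, AUC with DeLong CI, McFadden R2.

One :class:`EvalReport` corresponds to one row of a score-accuracy table:
the logistic coefficient of the (standardized) score, its Wald p-value, the
AUC of the score (or of the full linear predictor when covariates are
included) with a DeLong 95% confidence interval, and McFadden's pseudo-R2
against the intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genoio import CoverageReport, round_half_up


class EvaluationError(ValueError):
    pass


@dataclass
class EvalReport:
    name: str
    beta: float
    se: float
    p: float
    auc: float
    auc_l95: float
    auc_u95: float
    mcfadden_r2: float
    n_cases: int
    n_controls: int
    covariates: list[str]
    coverage: CoverageReport | None = None

    @property
    def odds_ratio(self) -> float:
        return beta_to_or(self.beta)


def beta_to_or(beta: float) -> float:
    """exp(beta), rounded half-up to 2 decimals for reporting."""
    if not np.isfinite(beta):
        raise EvaluationError("beta must be finite")
    return round_half_up(float(np.exp(beta)), 2)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_with_ci(scores: np.ndarray, labels: np.ndarray,
                alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC (Mann-Whitney with midranks for ties) and DeLong CI.

    The variance comes from DeLong's structural components: per-case and
    per-control placement values. Degenerate variance (perfect separation
    or all-tied scores) collapses the CI to the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes required for AUC")
    all_ranks = _midrank(scores)
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # placement values
    v10 = (all_ranks[labels == 1] - pos_ranks) / n0
    v01 = 1.0 - (all_ranks[labels == 0] - neg_ranks) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    var = s10 / n1 + s01 / n0
    if var <= 0:
        return float(auc), float(auc), float(auc)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def mcfadden_r2(model_loglik: float, null_loglik: float) -> float:
    """McFadden pseudo-R2 = 1 - ll_model / ll_null (ll_null < 0 required)."""
    if null_loglik == 0:
        raise EvaluationError("null log-likelihood is zero")
    return 1.0 - model_loglik / null_loglik


def fit_score_logistic(score: np.ndarray, labels: np.ndarray,
                       covariates: pd.DataFrame | None = None,
                       name: str = "score",
                       coverage: CoverageReport | None = None) -> EvalReport:
    """Fit ``case ~ score (+ covariates)`` by ML logistic regression.

    The AUC is computed from the score alone when there are no covariates,
    otherwise from the fitted linear predictor.
    """
    import statsmodels.api as sm

    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("labels are single-class")
    X = pd.DataFrame({"score": score})
    covnames: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
        covnames = list(covariates.columns)
    Xc = sm.add_constant(X, has_constant="add")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(labels, Xc).fit(disp=0, maxiter=200)
        except Exception:
            # (near-)separated data: Newton's Hessian is singular; BFGS
            # still yields a usable fit for reporting
            fit = sm.Logit(labels, Xc).fit(disp=0, maxiter=500,
                                           method="bfgs")
    beta = float(fit.params["score"])
    se = float(fit.bse["score"])
    p = float(fit.pvalues["score"])
    pred = score if covariates is None else np.asarray(fit.fittedvalues)
    auc, lo, hi = auc_with_ci(pred, labels)
    null = sm.Logit(labels, np.ones((len(labels), 1))).fit(disp=0)
    r2 = mcfadden_r2(float(fit.llf), float(null.llf))
    return EvalReport(
        name=name, beta=beta, se=se, p=p, auc=auc, auc_l95=lo, auc_u95=hi,
        mcfadden_r2=r2, n_cases=int((labels == 1).sum()),
        n_controls=int((labels == 0).sum()), covariates=covnames,
        coverage=coverage,
    )


def report_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Accuracy table, one row per score, rounded to printed precision.

    Columns: name, AUC (2 dp), AUC_L95, AUC_U95, Beta (3 dp), OR (2 dp),
    p, input SNVs, covered "n (pct)" with coverage percent at 2 dp.
    """
    rows = []
    for r in reports:
        cov = r.coverage
        rows.append({
            "name": r.name,
            "AUC": round_half_up(r.auc, 2),
            "AUC_L95": round_half_up(r.auc_l95, 2),
            "AUC_U95": round_half_up(r.auc_u95, 2),
            "Beta": round_half_up(r.beta, 3),
            "OR": beta_to_or(r.beta),
            "p": r.p,
            "input_snvs": cov.n_input if cov else "",
            "covered": (f"{cov.n_covered} ({cov.percent:.2f})" if cov else ""),
        })
    return pd.DataFrame(
        rows, columns=["name", "AUC", "AUC_L95", "AUC_U95", "Beta", "OR", "p",
                       "input_snvs", "covered"])


def write_report_table(reports: list[EvalReport], path) -> None:
    report_table(reports).to_csv(path, sep="\t", index=False)
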