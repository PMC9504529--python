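"""Meta-PRS: elastic-net combination of the single ARD-PRSs.

The standardized disease scores (plus sex and ancestry PCs when requested)
enter a penalized logistic regression; the penalty mixing (alpha between
ridge and lasso) and strength are chosen by 10-fold cross-validated
deviance. Class imbalance (far fewer long-lived cases than controls) is
handled by smoothed-bootstrap resampling: the minority class is resampled
with replacement to parity and each resampled row is jittered with
Gaussian noise at a per-column Silverman bandwidth, inside each training
fold only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


class ParameterError(ValueError):
    pass


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb kernel bandwidth for one column."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def smoothed_bootstrap_balance(design: np.ndarray, labels: np.ndarray,
                               seed: int = 0, bandwidth_scale: float = 1.0,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Resample the minority class to parity with smoothed-bootstrap jitter.

    Original rows are returned unchanged; the appended rows are minority
    rows drawn with replacement plus N(0, (scale * h_col)^2) noise, where
    h_col is Silverman's bandwidth on the minority class. Already-balanced
    input is returned as-is. ``bandwidth_scale=0`` gives plain oversampling.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == n0:
        return X, y
    minority = 1 if n1 < n0 else 0
    need = abs(n0 - n1)
    rows = np.where(y == minority)[0]
    if rows.size < 2:
        raise ParameterError("minority class must have at least 2 members")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows, need, replace=True)
    extra = X[pick].copy()
    h = np.array([silverman_bandwidth(X[rows, j]) for j in range(X.shape[1])])
    h = h * bandwidth_scale
    if (h > 0).any():
        extra += rng.normal(0.0, 1.0, extra.shape) * h[None, :]
    return (np.vstack([X, extra]),
            np.concatenate([y, np.full(need, minority, dtype=int)]))


@dataclass
class MetaPRSModel:
    intercept: float
    coef: pd.Series  # indexed by design column name
    alpha: float  # elastic-net mixing (0 = ridge, 1 = lasso)
    C: float  # inverse penalty strength
    columns: list[str]
    cv_deviance: float
    seed: int
    dropped: list[str] = field(default_factory=list)


def _cv_deviance(X: np.ndarray, y: np.ndarray, alpha: float, C: float,
                 folds: list[tuple[np.ndarray, np.ndarray]],
                 balance: bool, seed: int) -> float:
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss

    dev = 0.0
    for k, (tr, te) in enumerate(folds):
        Xt, yt = X[tr], y[tr]
        if balance:
            Xt, yt = smoothed_bootstrap_balance(Xt, yt, seed=seed + 7 * k + 1)
        clf = LogisticRegression(
            solver="saga", l1_ratio=alpha, C=C, max_iter=5000, tol=1e-6,
            random_state=0)
        clf.fit(Xt, yt)
        prob = clf.predict_proba(X[te])[:, 1]
        dev += 2.0 * log_loss(y[te], prob, normalize=False,
                              labels=[0, 1])
    return dev / len(y)


def fit_meta_prs(ard_scores: pd.DataFrame, labels: np.ndarray,
                 covariates: pd.DataFrame | None = None,
                 cv_folds: int = 10, seed: int = 0,
                 alphas=ALPHA_GRID, Cs=None,
                 balance: bool = True,
                 final_refit_balanced: bool = True) -> MetaPRSModel:
    """Fit the elastic-net meta-PRS on the discovery data.

    ``ard_scores`` holds the standardized per-disease scores (one column
    each); covariates (sex, PCs) are appended when given. The (alpha, C)
    pair minimizing cross-validated deviance wins; ties break to stronger
    penalty then larger alpha. By default the final model is refit on the
    balanced data (switchable), matching how the CV folds were trained.
    Constant columns are dropped with a log record.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    design = ard_scores.copy()
    if covariates is not None:
        for c in covariates.columns:
            design[c] = np.asarray(covariates[c], dtype=float)
    dropped = [c for c in design.columns if design[c].std() == 0]
    if dropped:
        log.info("fit_meta_prs: dropped constant columns %s", dropped)
        design = design.drop(columns=dropped)
    X = design.to_numpy(dtype=float)
    if Cs is None:
        Cs = np.logspace(-3, 2, 11)

    # canonical row order for CV: fold membership (hence CV deviance) is
    # then invariant to how the caller happened to sort the samples
    canon = np.lexsort(X.T)
    Xc, yc = X[canon], y[canon]
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(Xc, yc)]
    best = None
    for alpha in alphas:
        for C in Cs:
            dev = _cv_deviance(Xc, yc, alpha, C, folds, balance, seed)
            key = (dev, C, -alpha)  # tie: stronger penalty, then larger alpha
            if best is None or key < best[0]:
                best = (key, alpha, C, dev)
    _, alpha, C, dev = best

    Xf, yf = X, y
    if balance and final_refit_balanced:
        Xf, yf = smoothed_bootstrap_balance(X, y, seed=seed + 9999)
    clf = LogisticRegression(solver="saga", l1_ratio=alpha, C=C,
                             max_iter=10000, tol=1e-7, random_state=0)
    clf.fit(Xf, yf)
    coef = pd.Series(clf.coef_[0], index=design.columns)
    return MetaPRSModel(intercept=float(clf.intercept_[0]), coef=coef,
                        alpha=float(alpha), C=float(C),
                        columns=list(design.columns),
                        cv_deviance=float(dev), seed=seed, dropped=dropped)


def predict_meta(model: MetaPRSModel, ard_scores: pd.DataFrame,
                 covariates: pd.DataFrame | None = None) -> np.ndarray:
    """Linear predictor (pre-logistic) of the meta-PRS on new samples.

    Columns must match the training design; scores are assumed standardized
    with the training-time parameters upstream.
    """
    design = ard_scores.copy()
    if covariates is not None:
        for c in covariates.columns:
            design[c] = np.asarray(covariates[c], dtype=float)
    for c in model.dropped:
        if c in design.columns:
            design = design.drop(columns=c)
    missing = [c for c in model.columns if c not in design.columns]
    extra = [c for c in design.columns if c not in model.columns]
    if missing or extra:
        raise ParameterError(
            f"score-column mismatch: missing {missing}, unexpected {extra}")
    X = design[model.columns].to_numpy(dtype=float)
    return model.intercept + X @ model.coef.to_numpy()
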