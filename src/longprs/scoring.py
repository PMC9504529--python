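"""Polygenic risk score computation and standardization.

A PRS is the weighted allele-dosage sum ``score_i = sum_j d_ij * beta_j``
over a weight table already harmonized to the genotype panel. Missing
dosages are mean-imputed by twice the counted-allele frequency (the default
of standard scoring tools) or omitted, per policy. Scores are raw sums;
standardization to a reference group (controls by default) is a separate,
explicit step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genoio import CoverageReport, GenotypeMatrix


class ScoringError(ValueError):
    pass


@dataclass
class ScoreVector:
    """Per-sample polygenic score plus variant-usage accounting."""

    samples: list[str]
    score: np.ndarray
    n_variants_used: np.ndarray
    coverage: CoverageReport | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.samples,
            "score": self.score,
            "n_used": self.n_variants_used,
        })


def compute_prs(gm: GenotypeMatrix, harmonized_weights: pd.DataFrame,
                missing_policy: str = "mean_impute",
                coverage: CoverageReport | None = None) -> ScoreVector:
    """Score samples against a harmonized weight table.

    ``harmonized_weights`` must carry ``panel_index`` and ``beta`` (the output
    of :func:`longprs.genoio.harmonize`). Under ``mean_impute`` a missing
    dosage contributes ``2 * freq_j * beta_j`` with ``freq_j`` estimated from
    the non-missing samples; under ``omit`` the term is dropped.
    """
    if missing_policy not in ("mean_impute", "omit"):
        raise ScoringError(f"unknown missing_policy {missing_policy!r}")
    if len(harmonized_weights) == 0:
        raise ScoringError("zero covered variants: nothing to score")
    cols = harmonized_weights["panel_index"].to_numpy(dtype=int)
    beta = harmonized_weights["beta"].to_numpy(dtype=float)
    D = gm.dosage[:, cols]
    miss = np.isnan(D)
    if missing_policy == "mean_impute":
        with np.errstate(invalid="ignore"):
            fill = np.nanmean(D, axis=0)  # equals 2 * allele frequency
        fill = np.where(np.isnan(fill), 0.0, fill)
        Df = np.where(miss, fill[None, :], D)
        score = Df @ beta
        n_used = np.full(gm.n_samples, len(cols), dtype=int)
    else:
        Df = np.where(miss, 0.0, D)
        score = Df @ beta
        n_used = (~miss).sum(axis=1)
    return ScoreVector(samples=list(gm.samples), score=score,
                       n_variants_used=n_used, coverage=coverage)


def standardize(scores: np.ndarray, reference_mask: np.ndarray | None = None,
                ) -> np.ndarray:
    """Z-transform scores against a reference subset (default: all samples).

    After the transform the reference subset has mean 0 and SD 1 (population
    SD, ddof=0).
    """
    scores = np.asarray(scores, dtype=float)
    ref = (scores if reference_mask is None
           else scores[np.asarray(reference_mask, dtype=bool)])
    if ref.size == 0:
        raise ScoringError("empty reference subset")
    sd = ref.std()
    if sd == 0:
        raise ScoringError("zero variance in reference subset")
    return (scores - ref.mean()) / sd
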