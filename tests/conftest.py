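import numpy as np
import pandas as pd
import pytest

from longprs.genoio import GenotypeMatrix
from longprs import synthcohort


def make_gm(dosage, chroms=None, positions=None, counted=None, other=None,
            ids=None):
    """Small genotype matrix from a dense dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame({
        "chrom": chroms if chroms is not None else ["1"] * m,
        "pos": positions if positions is not None else np.arange(1, m + 1) * 100,
        "id": ids if ids is not None else [f"v{j}" for j in range(m)],
        "counted_allele": counted if counted is not None else ["G"] * m,
        "other_allele": other if other is not None else ["A"] * m,
    })
    return GenotypeMatrix(samples=[f"S{i}" for i in range(n)],
                          variants=variants, dosage=dosage)


@pytest.fixture(scope="session")
def coupled_cohort():
    """Cohort whose longevity is anticorrelated with two disease liabilities."""
    panel = synthcohort.simulate_panel(30, 10, (0.1, 0.5), 0.3, seed=11)
    specs = [
        synthcohort.DiseaseSpec("D1", n_causal=15, effect_sd=0.25,
                                prevalence_target=0.1, longevity_coupling=-0.5),
        synthcohort.DiseaseSpec("D2", n_causal=15, effect_sd=0.25,
                                prevalence_target=0.15, longevity_coupling=-0.5),
    ]
    gm, pheno, truth = synthcohort.simulate_cohort(
        panel, 400, 1200, specs, longevity_own_h2=0.1, missing_rate=0.01,
        seed=12)
    return gm, pheno, truth
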