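"""C+T scoring: clumping, grid scan, region exclusion, APOE calls, stepwise."""

import numpy as np
import pandas as pd
import pytest

from longprs import synthcohort
from longprs.gps import (DEFAULT_GRID, ApoeDiplotype, ClumpParams, CTModel,
                         apoe_from_dosage, apply_published_score,
                         backward_stepwise, call_apoe_haplotype, clump,
                         ct_scan, exclude_region, make_grid, thin_candidates)

from conftest import make_gm


def sumstats_for(gm, p, beta=None):
    v = gm.variants
    return pd.DataFrame({
        "chrom": v["chrom"].astype(str), "pos": v["pos"], "id": v["id"],
        "effect_allele": v["counted_allele"], "other_allele": v["other_allele"],
        "beta": beta if beta is not None else np.ones(len(v)),
        "p": p, "panel_index": np.arange(len(v)),
    })


def clump_oracle(ss, X, r2_max, window_bp):
    """Independent, literal restatement of the greedy clumping rule."""
    remaining = set(range(len(ss)))
    indices = []
    while remaining:
        i = min(remaining, key=lambda k: (ss["p"].iloc[k], k))
        remaining.discard(i)
        indices.append(i)
        for j in list(remaining):
            if ss["chrom"].iloc[j] != ss["chrom"].iloc[i]:
                continue
            if abs(ss["pos"].iloc[j] - ss["pos"].iloc[i]) > window_bp:
                continue
            xi, xj = X[:, ss["panel_index"].iloc[i]], X[:, ss["panel_index"].iloc[j]]
            if xi.std() == 0 or xj.std() == 0:
                continue
            if np.corrcoef(xi, xj)[0, 1] ** 2 > r2_max:
                remaining.discard(j)
    return indices


class TestClump:
    def test_single_variant_is_its_own_index(self):
        gm = make_gm(np.random.default_rng(0).binomial(2, 0.4, (30, 1))
                     .astype(float))
        ss = sumstats_for(gm, p=[0.01])
        assert clump(ss, gm) == [0]

    def test_weaker_neighbour_absorbed(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(1, 0.5, 200).astype(float)
        noise = rng.binomial(1, 0.5, 200).astype(float)
        x2 = np.where(rng.random(200) < 0.85, x, noise)  # r2 ~ 0.5
        gm = make_gm(np.column_stack([x, x2]), positions=[1000, 11000])
        r2 = np.corrcoef(x, x2)[0, 1] ** 2
        assert r2 > 0.1
        ss = sumstats_for(gm, p=[1e-6, 1e-3])
        assert clump(ss, gm) == [0]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        params = ClumpParams()
        for _ in range(100):
            m = int(rng.integers(2, 21))
            n = 80
            base = rng.binomial(2, rng.uniform(0.1, 0.5, m), (n, m)).astype(float)
            # induce LD by copying columns with noise
            for j in range(1, m):
                if rng.random() < 0.4:
                    src = int(rng.integers(0, j))
                    mask = rng.random(n) < 0.8
                    base[mask, j] = base[mask, src]
            pos = np.sort(rng.choice(np.arange(1, 2000) * 1000, m,
                                     replace=False))
            gm = make_gm(base, positions=pos)
            ss = sumstats_for(gm, p=rng.random(m))
            got = clump(ss, gm, params)
            want = clump_oracle(ss, gm.filled(), params.r2_max,
                                params.window_kb * 1000)
            assert got == want


class TestGrid:
    def test_default_grid_has_eleven_cutoffs(self):
        assert len(make_grid()) == 11
        assert make_grid()[0] == 5e-8 and make_grid()[-1] == 1.0

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            make_grid([0.1, 0.1, 0.2])


class TestCtScan:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        rng = np.random.default_rng(3)
        n, m = 600, 40
        X = rng.binomial(2, 0.3, (n, m)).astype(float)
        eta = 1.2 * (X[:, 0] - X[:, 0].mean())
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        gm = make_gm(X, positions=np.arange(1, m + 1) * 10 ** 6)
        return gm, y

    def test_snv_count_nondecreasing_in_cutoff(self, cohort):
        gm, y = cohort
        rng = np.random.default_rng(4)
        p = rng.random(gm.n_variants)
        p[0] = 1e-10
        scan = ct_scan(gm, y, sumstats_for(gm, p))
        counts = scan.grid_table["n_snvs"].to_numpy()
        assert (np.diff(counts) >= 0).all()
        assert counts[-1] == gm.n_variants  # cutoff 1 keeps every index SNV

    def test_tie_break_prefers_most_stringent_cutoff(self, cohort):
        gm, y = cohort
        # one huge-effect SNV below every cutoff, all others null
        p = np.ones(gm.n_variants)
        p[0] = 1e-12
        scan = ct_scan(gm, y, sumstats_for(gm, p))
        by_cut = scan.grid_table.set_index("cutoff")
        # the lone strong SNV enters at every cutoff below 1
        assert by_cut.loc[5e-8, "n_snvs"] == 1
        assert scan.selected.cutoff == 5e-8
        assert len(scan.selected.weights) == 1

    def test_empty_cutoff_recorded_with_half_auc(self, cohort):
        gm, y = cohort
        p = np.full(gm.n_variants, 0.2)
        scan = ct_scan(gm, y, sumstats_for(gm, p))
        first = scan.grid_table.iloc[0]
        assert first["n_snvs"] == 0 and first["auc_discovery"] == 0.5


class TestExcludeRegion:
    tab = pd.DataFrame({
        "chrom": ["19", "19", "19", "18"],
        "pos": [45_400_000, 45_350_999, 45_500_000, 45_400_000],
        "id": list("abcd"),
    })

    def test_inclusive_bounds(self):
        out = exclude_region(self.tab)
        assert list(out["id"]) == ["b", "d"]

    def test_other_chromosome_untouched(self):
        out = exclude_region(self.tab)
        assert "d" in set(out["id"])


class TestApoeCalls:
    @pytest.mark.parametrize("g1,g2,e1,e2,amb", [
        (("T", "T"), ("C", "C"), "e3", "e3", False),
        (("C", "C"), ("C", "C"), "e4", "e4", False),
        (("T", "T"), ("T", "T"), "e2", "e2", False),
        (("C", "T"), ("C", "C"), "e3", "e4", False),
        (("T", "T"), ("C", "T"), "e2", "e3", False),
        (("C", "T"), ("C", "T"), "e2", "e4", True),
    ])
    def test_mapping(self, g1, g2, e1, e2, amb):
        d = call_apoe_haplotype(g1, g2)
        assert sorted([d.allele1, d.allele2]) == sorted([e1, e2])
        assert d.ambiguous is amb

    def test_missing_site_gives_missing_diplotype(self):
        assert call_apoe_haplotype(None, ("C", "C")) is None

    def test_dosage_interface(self):
        d = apoe_from_dosage(0.0, 2.0)  # T/T at rs429358, C/C at rs7412
        assert (d.allele1, d.allele2) == ("e3", "e3")
        assert apoe_from_dosage(np.nan, 1.0) is None

    def test_epsilon_allele_counts(self):
        d = ApoeDiplotype("e2", "e4", ambiguous=True)
        assert d.e2_count == 1 and d.e4_count == 1


class TestStepwise:
    def test_single_predictive_candidate_retained(self):
        rng = np.random.default_rng(5)
        n = 800
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        design = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
        model = backward_stepwise(design, y)
        assert "x" in model.retained

    def test_pure_noise_candidates_mostly_eliminated(self):
        rng = np.random.default_rng(6)
        n = 1500
        y = rng.integers(0, 2, n)
        design = pd.DataFrame(rng.normal(size=(n, 6)),
                              columns=[f"n{i}" for i in range(6)])
        model = backward_stepwise(design, y)
        assert len(model.retained) <= 2

    def test_collinear_candidate_predropped(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        design = pd.DataFrame({"x": x, "x_copy": x, "const": np.ones(n)})
        model = backward_stepwise(design, y)
        assert "const" not in model.train_columns
        assert len([c for c in model.train_columns
                    if c in ("x", "x_copy")]) == 1

    def test_thin_candidates_enforces_r2_and_maf(self):
        rng = np.random.default_rng(8)
        n = 400
        a = rng.binomial(2, 0.4, n).astype(float)
        b = a.copy()
        flip = rng.random(n) < 0.05
        b[flip] = rng.binomial(2, 0.4, int(flip.sum()))
        rare = rng.binomial(2, 0.005, n).astype(float)
        gm = make_gm(np.column_stack([a, b, rare]))
        kept = thin_candidates(gm, np.array([0, 1, 2]), r2_cap=0.1,
                               maf_min=0.01)
        assert list(kept) == [0]


class TestApplyPublishedScore:
    def test_full_coverage_and_null_evaluation(self):
        rng = np.random.default_rng(9)
        gm = make_gm(rng.binomial(2, 0.3, (400, 12)).astype(float),
                     positions=np.arange(1, 13) * 1000)
        v = gm.variants
        wt = pd.DataFrame({
            "chrom": v["chrom"], "pos": v["pos"], "id": v["id"],
            "effect_allele": v["counted_allele"],
            "other_allele": v["other_allele"],
            "beta": rng.normal(0, 0.1, 12),
        })
        y = rng.integers(0, 2, 400)
        sv, cov, rep = apply_published_score(gm, wt, y)
        assert cov.percent == 100.0
        assert rep.auc_l95 <= 0.5 <= rep.auc_u95

    def test_partial_coverage_arithmetic(self):
        rng = np.random.default_rng(10)
        gm = make_gm(rng.binomial(2, 0.3, (50, 10)).astype(float),
                     positions=np.arange(1, 11) * 1000)
        v = gm.variants
        wt = pd.DataFrame({
            "chrom": ["1"] * 10, "pos": list(v["pos"][:6]) + [99, 98, 97, 96],
            "id": [f"w{i}" for i in range(10)],
            "effect_allele": ["G"] * 10, "other_allele": ["A"] * 10,
            "beta": rng.normal(size=10),
        })
        y = rng.integers(0, 2, 50)
        _, cov, _ = apply_published_score(gm, wt, y)
        assert cov.n_covered == 6 and cov.percent == 60.0
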