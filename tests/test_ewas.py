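import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from siccaomics.ewas import (
    DegenerateFitError,
    ModelSpec,
    bonferroni_threshold,
    brown_forsythe,
    build_design,
    fit_linear_model,
    run_dmp_scan,
    run_vmp_scan,
    sensitivity_refit,
    stratified_scan,
)
from siccaomics.io import MolecularMatrix, SampleSheet
from siccaomics.simulate import SimulationConfig, simulate_cohort


class TestLinearEngine:
    def test_two_group_closed_form(self):
        fit = fit_linear_model([1, 2, 3, 4], [0, 0, 1, 1])
        assert fit.estimate == pytest.approx(2.0)
        assert fit.se == pytest.approx(0.70710678, abs=1e-6)
        assert fit.statistic == pytest.approx(2.8284271, abs=1e-6)
        assert fit.df == 2
        assert fit.p == pytest.approx(0.105573, abs=1e-4)

    def test_matches_statsmodels_on_random_designs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 30))
            k = int(rng.integers(0, 3))
            group = (rng.random(n) < 0.5).astype(float)
            if group.std() == 0:
                group[0] = 1 - group[0]
            cov = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            fit = fit_linear_model(y, group, cov if k else None)
            X = sm.add_constant(np.column_stack([group, cov]) if k else group)
            ref = sm.OLS(y, X).fit()
            assert fit.estimate == pytest.approx(ref.params[1], rel=1e-8, abs=1e-10)
            assert fit.se == pytest.approx(ref.bse[1], rel=1e-8)
            assert fit.p == pytest.approx(ref.pvalues[1], rel=1e-6, abs=1e-12)

    def test_group_orthogonal_to_duplicated_covariate(self):
        # y equals a covariate exactly; group orthogonal to it -> estimate 0
        cov = np.array([1.0, -1.0, 1.0, -1.0])
        group = np.array([0.0, 0.0, 1.0, 1.0])
        fit = fit_linear_model(cov, group, cov)
        assert fit.estimate == pytest.approx(0.0, abs=1e-12)

    def test_constant_group_rejected(self):
        with pytest.raises(DegenerateFitError, match="constant"):
            fit_linear_model([1, 2, 3], [1, 1, 1])

    def test_constant_response_degenerate(self):
        fit = fit_linear_model([2.0, 2, 2, 2], [0, 0, 1, 1])
        assert fit.degenerate and fit.p == 1.0 and fit.estimate == 0.0

    def test_collinear_design_names_columns(self):
        group = np.array([0.0, 0, 1, 1, 0, 1])
        cov = np.column_stack([group * 2])  # exact multiple of group
        with pytest.raises(DegenerateFitError, match="collinear"):
            fit_linear_model(np.arange(6.0), group, cov)


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [
        (776_284, 6.4e-8),
        (42_878, 1.17e-6),
        (298, 1.7e-4),
    ])
    def test_printed_cutoffs(self, m, expected):
        assert bonferroni_threshold(0.05, m) == pytest.approx(expected, rel=0.02)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestBrownForsythe:
    def test_equal_absolute_deviations_give_zero_statistic(self):
        # deviations from group medians are all exactly 1
        stat, p = brown_forsythe([0.0, 2.0], [1.0, 3.0])
        assert stat == 0.0 and p == 1.0

    def test_identical_distributions_zero_statistic(self):
        a = np.array([0.1, 0.4, -0.2, 0.3])
        stat, _ = brown_forsythe(a, a.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_exact_location_invariance(self):
        # dyadic values so the constant shift is exact in floating point
        rng = np.random.default_rng(3)
        a = rng.integers(-8, 8, size=20) / 4.0
        b = rng.integers(-8, 8, size=25) / 4.0
        s1, p1 = brown_forsythe(a, b)
        s2, p2 = brown_forsythe(a + 5.0, b)
        assert s1 == s2 and p1 == p2

    def test_detects_variance_difference(self):
        rng = np.random.default_rng(4)
        _, p = brown_forsythe(rng.normal(0, 2, 200), rng.normal(0, 1, 200))
        assert p < 1e-6


@pytest.fixture(scope="module")
def dmp_cohort():
    cfg = SimulationConfig(n_cases=200, n_controls=200, n_cpgs=1000, n_genes=10,
                           n_snps=10, n_dmp=50, delta_beta_range=(0.3, 0.3),
                           n_vmp=50, variance_inflation=4.0, seed=11)
    return cfg, simulate_cohort(cfg)


class TestScans:
    def test_dmp_recovery_at_bonferroni(self, dmp_cohort):
        cfg, cohort = dmp_cohort
        table = run_dmp_scan(cohort.methylation, cohort.sheet)
        th = bonferroni_threshold(0.05, cfg.n_cpgs)
        hits = set(table.loc[table.p < th, "feature_id"])
        planted = set(cohort.truth.dmp_effects)
        assert len(hits & planted) / len(planted) >= 0.9

    def test_estimate_and_delta_beta_agree_in_sign(self, dmp_cohort):
        _, cohort = dmp_cohort
        spec = ModelSpec(covariates=())
        table = run_dmp_scan(cohort.methylation, cohort.sheet, spec)
        strong = table[table.p < 1e-4]
        assert (np.sign(strong.estimate) == np.sign(strong.delta_beta)).all()

    def test_vmp_recovery(self, dmp_cohort):
        cfg, cohort = dmp_cohort
        table = run_vmp_scan(cohort.methylation, cohort.sheet).set_index("feature_id")
        planted = table.loc[list(cohort.truth.vmp_features)]
        assert (planted.p < 0.05).mean() >= 0.9

    def test_records_sorted_by_p_and_bonferroni_capped(self, dmp_cohort):
        _, cohort = dmp_cohort
        table = run_dmp_scan(cohort.methylation, cohort.sheet)
        assert (table.p.values == np.sort(table.p.values)).all()
        assert (table.p_bonferroni <= 1).all()
        expected = np.minimum(1.0, table.p * len(table))
        assert table.p_bonferroni.to_numpy() == pytest.approx(expected.to_numpy())


class TestSensitivity:
    def test_orthogonal_extra_covariate_keeps_estimates(self, dmp_cohort):
        _, cohort = dmp_cohort
        subset = list(cohort.truth.dmp_effects)[:20]
        _, r, retained = sensitivity_refit(
            cohort.methylation, cohort.sheet, ModelSpec(),
            extra_covariates=("pc1",), feature_subset=subset, threshold=1e-4,
        )
        assert r == pytest.approx(1.0, abs=1e-3)
        assert retained == 1.0

    def test_mediating_treatment_drops_signal(self):
        # methylation driven entirely by a case-only treatment: adding the
        # treatment covariate should annul the disease effect at those CpGs
        rng = np.random.default_rng(8)
        n = 200
        disease = np.array(["case"] * 100 + ["control"] * 100)
        treated = np.concatenate([rng.random(100) < 0.5, np.zeros(100, bool)])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "disease": disease,
            "sex": rng.choice(["F", "M"], n),
            "age": rng.normal(50, 10, n),
            "steroids": treated,
        }))
        betas = np.clip(
            0.5 + 0.2 * treated + rng.normal(0, 0.03, (10, n)), 0, 1
        )
        meth = MolecularMatrix(
            pd.DataFrame(betas, index=[f"cg{i}" for i in range(10)],
                         columns=sheet.sample_ids), "methylation")
        base = ModelSpec(covariates=("sex", "age"))
        refit, r, retained = sensitivity_refit(
            meth, sheet, base, extra_covariates=("steroids",),
            feature_subset=[f"cg{i}" for i in range(10)], threshold=1e-3,
        )
        assert retained < 0.5

    def test_empty_subset_rejected(self, dmp_cohort):
        _, cohort = dmp_cohort
        with pytest.raises(ValueError, match="empty"):
            sensitivity_refit(cohort.methylation, cohort.sheet, ModelSpec(),
                              ("pc1",), [], 0.05)


class TestStratified:
    def test_whole_cohort_stratum_equals_plain_scan(self, dmp_cohort):
        _, cohort = dmp_cohort
        plain = run_dmp_scan(cohort.methylation, cohort.sheet)
        strat = stratified_scan(cohort.methylation, cohort.sheet,
                                lambda df: np.ones(len(df), bool))
        pd.testing.assert_frame_equal(plain, strat)

    def test_ifn_block_ssa_stratified_pattern(self, chain_cohort):
        cfg, cohort = chain_cohort
        block = cohort.truth.ifn_block
        pos = stratified_scan(
            cohort.methylation, cohort.sheet,
            lambda df: (df.disease == "control") | (df.ssa == "positive"),
        ).set_index("feature_id").loc[block]
        neg = stratified_scan(
            cohort.methylation, cohort.sheet,
            lambda df: (df.disease == "control") | ((df.disease == "case") & (df.ssa == "negative")),
        ).set_index("feature_id").loc[block]
        assert (-pos.delta_beta.mean()) == pytest.approx(cfg.ifn_delta_beta, abs=0.05)
        assert (neg.p > 0.01).all()

    def test_conditional_on_ssa_annuls_block_signal(self, chain_cohort):
        _, cohort = chain_cohort
        block = cohort.truth.ifn_block
        cond = stratified_scan(cohort.methylation, cohort.sheet, None,
                               conditional_on="ssa").set_index("feature_id")
        assert (cond.loc[block, "p"] > 0.05).all()

    def test_empty_stratum_rejected(self, dmp_cohort):
        _, cohort = dmp_cohort
        with pytest.raises(ValueError):
            stratified_scan(cohort.methylation, cohort.sheet,
                            lambda df: np.zeros(len(df), bool))


class TestDesignBuilder:
    def test_cell_columns_drop_one(self, qtl_cohort):
        _, cohort = qtl_cohort
        design = build_design(cohort.sheet, ("cells",))
        assert design.shape[1] == len(cohort.sheet.cell_columns) - 1

    def test_batch_dummies_drop_first(self, qtl_cohort):
        _, cohort = qtl_cohort
        design = build_design(cohort.sheet, ("batch",))
        assert list(design.columns) == ["batch_B2"]
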