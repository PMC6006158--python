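import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from hetgwis import (
    CollinearityError,
    DesignError,
    NotPositiveDefiniteError,
    TestError,
)
from hetgwis.lmmcore import (
    ModelSpec,
    aic_of,
    build_design,
    fit_ml,
    loglik,
    lrt,
    marginal_covariance,
    wald_joint,
    wald_term,
)
from hetgwis.gwis import filtering_spec, pooled_spec
from hetgwis.synthdata import SimScenario, simulate_cohort, simulate_genotypes


def _dense_oracle(spec, table, beta, cov_params):
    """Independent brute force: per subject, build the full covariance and
    call a dense MVN log-density."""
    total = 0.0
    for sid, grp in table.df.groupby("subject_id"):
        smoking = grp["smoking"].iloc[0]
        if spec.covariance_groups == "shared":
            gname = "all"
        else:
            gname = "never" if smoking == "never" else "ever"
        vis = grp["visit"].tolist()
        V = marginal_covariance(spec, gname, vis, cov_params)
        X = np.column_stack([
            np.ones(len(grp)), grp["age0"], grp["sex"], grp["time"], grp["bmi"],
        ])
        total += multivariate_normal.logpdf(grp["fev1"], mean=X @ beta, cov=V)
    return total


TERMS = ("intercept", "age", "sex", "time", "bmi")


class TestMarginalCovariance:
    def _spec(self, structure):
        return ModelSpec(fixed_terms=TERMS, covariance=structure,
                         covariance_groups="shared", max_visits=3)

    def test_independence_identity(self):
        V = marginal_covariance(self._spec("independence"), "all", [1, 2, 3],
                                {"all": {"sigma2": 1.0}})
        np.testing.assert_array_equal(V, np.eye(3))

    def test_random_intercept_closed_form(self):
        spec = ModelSpec(fixed_terms=TERMS, covariance="random_intercept",
                         covariance_groups="shared", max_visits=2)
        V = marginal_covariance(spec, "all", [1, 2],
                                {"all": {"sigma2": 2.0, "resid_diag": np.array([1.0, 1.0])}})
        np.testing.assert_array_equal(V, [[3.0, 2.0], [2.0, 3.0]])

    def test_unstructured_subsetting(self):
        full = np.array([[1.0, 0.2, 0.1], [0.2, 2.0, 0.3], [0.1, 0.3, 3.0]])
        spec = self._spec("unstructured_marginal")
        V = marginal_covariance(spec, "all", [2], {"all": {"V": full}})
        assert V.shape == (1, 1) and V[0, 0] == 2.0
        V13 = marginal_covariance(spec, "all", [1, 3], {"all": {"V": full}})
        np.testing.assert_array_equal(V13, [[1.0, 0.1], [0.1, 3.0]])

    def test_non_pd_rejected(self):
        spec = self._spec("unstructured_marginal")
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(NotPositiveDefiniteError):
            marginal_covariance(spec, "all", [1, 2, 3], {"all": {"V": bad}})


class TestLoglik:
    def test_single_standard_normal(self):
        df = pd.DataFrame(dict(subject_id=["a"], visit=[1], time=[0.0], fev1=[0.0],
                               age0=[50.0], sex=[0], height=[160.0], bmi=[22.0],
                               smoking=["never"], pack_years=[0.0]))
        from hetgwis.io_config import PhenotypeTable
        tab = PhenotypeTable(df)
        spec = ModelSpec(fixed_terms=("intercept",), covariance="independence",
                         covariance_groups="shared", max_visits=1)
        b = build_design(tab, spec)
        ll = loglik(spec, b, np.zeros(1), {"all": {"sigma2": 1.0}})
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("structure,groups", [
        ("independence", "shared"),
        ("random_intercept", "by_status"),
        ("unstructured_marginal", "by_status"),
    ])
    def test_dense_oracle_equivalence(self, tiny_fixture, structure, groups):
        _, _, tab = tiny_fixture
        spec = ModelSpec(fixed_terms=TERMS, covariance=structure,
                         covariance_groups=groups, max_visits=3)
        bundle = build_design(tab, spec)
        beta = np.array([1.0, -0.01, 0.2, -0.02, 0.005])
        rngV = np.random.default_rng(0)
        A = rngV.normal(size=(3, 3))
        Vfull = A @ A.T + 3 * np.eye(3)
        if structure == "independence":
            cov = {"all": {"sigma2": 0.7}}
        elif structure == "random_intercept":
            cov = {"never": {"sigma2": 0.3, "resid_diag": np.array([0.5, 0.4, 0.6])},
                   "ever": {"sigma2": 0.9, "resid_diag": np.array([1.0, 0.8, 1.2])}}
        else:
            cov = {"never": {"V": Vfull}, "ever": {"V": 2.0 * Vfull}}
        ll = loglik(spec, bundle, beta, cov)
        oracle = _dense_oracle(spec, tab, beta, cov)
        assert abs(ll - oracle) < 1e-8

    def test_translation_invariance_of_residuals(self, tiny_fixture):
        _, _, tab = tiny_fixture
        spec = ModelSpec(fixed_terms=TERMS, covariance="independence",
                         covariance_groups="shared", max_visits=3)
        bundle = build_design(tab, spec)
        beta = np.array([1.0, -0.01, 0.2, -0.02, 0.005])
        cov = {"all": {"sigma2": 0.5}}
        ll1 = loglik(spec, bundle, beta, cov)
        shifted = tab.df.copy()
        shifted["fev1"] = shifted["fev1"] + 5.0
        from hetgwis.io_config import PhenotypeTable
        bundle2 = build_design(PhenotypeTable(shifted), spec)
        beta2 = beta.copy()
        beta2[0] += 5.0
        ll2 = loglik(spec, bundle2, beta2, cov)
        assert ll1 == pytest.approx(ll2, abs=1e-9)


class TestBuildDesign:
    def test_status_dummy_coding(self, small_null_data):
        _, _, tab = small_null_data
        spec = pooled_spec("heteroscedastic", n_pcs=0, max_visits=3, with_snp=False)
        bundle = build_design(tab, spec)
        j = bundle.colnames.index("status[ever]")
        X = bundle.stacked_X()
        assert set(np.unique(X[:, j])) <= {0.0, 1.0}
        # never smokers' dummy is zero everywhere
        for b in bundle.blocks:
            if b.group == "never":
                assert (b.X[:, :, j] == 0).all()
            if b.group == "ever":
                assert (b.X[:, :, j] == 1).all()

    def test_snp_packyears_zero_for_never(self, small_null_data):
        _, g, tab = small_null_data
        spec = pooled_spec("heteroscedastic", n_pcs=0, max_visits=3, with_snp=True)
        dos = g.dosage_series(g.snp_ids[0])
        bundle = build_design(tab, spec, snp=dos)
        j = bundle.colnames.index("snp:pack_years")
        for b in bundle.blocks:
            if b.group == "never":
                assert (b.X[:, :, j] == 0).all()

    def test_term_count_matches_pooled_equation(self, small_null_data):
        """Full testing-step model: intercept + 15 beta slots + 11 tau slots."""
        _, g, tab = small_null_data
        spec = pooled_spec("heteroscedastic", coding="two_level", n_pcs=10,
                           max_visits=3, with_snp=True)
        pcs = pd.DataFrame(np.random.default_rng(0).normal(size=(tab.n_subjects, 10)),
                           index=tab.subjects, columns=[f"pc{k}" for k in range(1, 11)])
        bundle = build_design(tab, spec, pcs=pcs, snp=g.dosage_series(g.snp_ids[0]))
        assert bundle.p == 1 + 15 + 11

    def test_three_level_empty_stratum_error(self):
        sc = SimScenario(n_subjects=60, n_snps=1, seed=3,
                         smoking_proportions=(0.5, 0.5, 0.0))
        g = simulate_genotypes(sc)
        tab = simulate_cohort(sc, g)
        spec = pooled_spec("heteroscedastic", coding="three_level", n_pcs=0,
                           max_visits=3, with_snp=False)
        with pytest.raises(DesignError, match="current"):
            build_design(tab, spec)

    def test_missing_term_error(self, small_null_data):
        _, _, tab = small_null_data
        spec = ModelSpec(fixed_terms=("intercept", "banana"), max_visits=3,
                         covariance_groups="shared")
        with pytest.raises(DesignError):
            build_design(tab, spec)


class TestFitML:
    def test_independence_consistency(self):
        sc = SimScenario(n_subjects=2000, n_snps=1, seed=10, max_visits=1,
                         sigma2_never=0.0 + 1e-12, sigma2_ever=1e-12,
                         Sigma_never=np.array([[1.0]]), Sigma_ever=np.array([[1.0]]))
        g = simulate_genotypes(sc)
        tab = simulate_cohort(sc, g)
        spec = ModelSpec(fixed_terms=("intercept", "age", "sex", "bmi"),
                         covariance="independence",
                         covariance_groups="shared", max_visits=1)
        fit = fit_ml(spec, build_design(tab, spec))
        assert fit.converged
        assert 0.9 < fit.cov_params["all"]["sigma2"] < 1.1

    def test_zero_column_is_fit_error(self, small_null_data):
        _, _, tab = small_null_data
        spec = filtering_spec("ever", n_pcs=0, max_visits=3, with_snp=True)
        zero = pd.Series(0.0, index=tab.subjects)
        strat = tab.stratum("ever")
        with pytest.raises(CollinearityError):
            bundle = build_design(strat, spec, snp=zero)
            fit_ml(spec, bundle)

    def test_refit_fixed_point(self, small_null_data):
        _, _, tab = small_null_data
        spec = ModelSpec(fixed_terms=TERMS, covariance="unstructured_marginal",
                         covariance_groups="by_status", max_visits=3)
        bundle = build_design(tab, spec)
        fit = fit_ml(spec, bundle)
        refit = fit_ml(spec, bundle, init=fit)
        assert abs(refit.loglik - fit.loglik) < 1e-8

    def test_ml_optimality_beats_truth(self, small_null_data):
        sc, _, tab = small_null_data
        spec = ModelSpec(fixed_terms=TERMS, covariance="unstructured_marginal",
                         covariance_groups="by_status", max_visits=3)
        bundle = build_design(tab, spec)
        fit = fit_ml(spec, bundle)
        truth_cov = {
            "never": {"V": sc.sigma2_never * np.ones((3, 3)) + sc.Sigma_never},
            "ever": {"V": sc.sigma2_ever * np.ones((3, 3)) + sc.Sigma_ever},
        }
        ll_truth = loglik(spec, bundle, fit.beta_hat, truth_cov)
        assert fit.loglik >= ll_truth - 1e-6

    def test_vcov_psd_and_aic_identity(self, small_null_data):
        _, _, tab = small_null_data
        spec = ModelSpec(fixed_terms=TERMS, covariance="random_intercept",
                         covariance_groups="shared", max_visits=3)
        fit = fit_ml(spec, build_design(tab, spec))
        eig = np.linalg.eigvalsh(fit.vcov_beta)
        assert eig.min() > -1e-10
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=0)


class TestLRT:
    def _fits(self, tab):
        full_spec = ModelSpec(fixed_terms=TERMS, covariance="independence",
                              covariance_groups="shared", max_visits=3)
        red_spec = ModelSpec(fixed_terms=TERMS[:-1], covariance="independence",
                             covariance_groups="shared", max_visits=3)
        full = fit_ml(full_spec, build_design(tab, full_spec))
        red = fit_ml(red_spec, build_design(tab, red_spec))
        return full, red

    def test_self_test_is_zero(self, small_null_data):
        _, _, tab = small_null_data
        full, _ = self._fits(tab)
        tr = lrt(full, full, 1)
        assert tr.statistic == 0.0 and tr.p == 1.0

    def test_chi2_quantiles(self, small_null_data):
        # reference 95th percentiles: chi2(3)=7.815, chi2(1)=3.841
        _, _, tab = small_null_data
        full, red = self._fits(tab)
        fake_full = full
        tr = lrt(fake_full, red, 1)
        assert 0.0 <= tr.p <= 1.0
        from hetgwis.lmmcore import TestResult
        from scipy.stats import chi2
        assert chi2.sf(7.81, 3) == pytest.approx(0.050, abs=5e-4)
        assert chi2.sf(3.84, 1) == pytest.approx(0.050, abs=5e-4)

    def test_nonnegative_statistic(self, small_null_data):
        _, _, tab = small_null_data
        full, red = self._fits(tab)
        tr = lrt(full, red, 1)
        assert tr.statistic >= 0.0


class TestLrtNullDistribution:
    def test_one_df_lrt_matches_chi2_under_null(self):
        """Cross-sectional null replicates: the 1-DF LRT for an added SNP
        column follows chi-square(1) (KS check, 300 replicates)."""
        rng = np.random.default_rng(99)
        n = 400
        from hetgwis.io_config import PhenotypeTable
        df = pd.DataFrame(dict(
            subject_id=[f"s{i:04d}" for i in range(n)], visit=1, time=0.0,
            fev1=rng.normal(size=n), age0=rng.uniform(40, 69, n),
            sex=rng.integers(0, 2, n), height=rng.normal(160, 8, n),
            bmi=rng.normal(24, 3, n), smoking="never", pack_years=0.0))
        tab = PhenotypeTable(df)
        spec = ModelSpec(fixed_terms=("intercept", "age", "sex"),
                         covariance="independence", covariance_groups="shared",
                         max_visits=1)
        base = build_design(tab, spec)
        reduced = fit_ml(spec, base)
        stats_ = []
        warm = reduced.theta
        for _ in range(300):
            # fresh y each replicate, fresh SNP
            y = rng.normal(size=n)
            df2 = df.assign(fev1=y)
            b2 = build_design(PhenotypeTable(df2), spec)
            r2 = fit_ml(spec, b2, init=warm)
            warm = r2.theta
            snp = pd.Series(rng.binomial(2, 0.3, n).astype(float), index=tab.subjects)
            bf = b2.with_snp(snp, ("snp",))
            f2 = fit_ml(bf.spec, bf, init=r2.theta)
            stats_.append(lrt(f2, r2, 1).statistic)
        from scipy.stats import chi2, kstest
        assert kstest(stats_, lambda x: chi2.cdf(x, 1)).pvalue > 0.01


class TestWald:
    def test_scalar_case_equals_squared_z(self, small_null_data):
        _, _, tab = small_null_data
        spec = ModelSpec(fixed_terms=TERMS, covariance="independence",
                         covariance_groups="shared", max_visits=3)
        fit = fit_ml(spec, build_design(tab, spec))
        tr = wald_joint(fit, ["bmi"])
        z2 = (fit.coef("bmi") / fit.coef_se("bmi")) ** 2
        assert tr.statistic_chi2 == pytest.approx(z2, rel=1e-10)

    def test_large_df_f_approaches_chi2(self, small_null_data):
        _, _, tab = small_null_data
        spec = ModelSpec(fixed_terms=TERMS, covariance="independence",
                         covariance_groups="shared", max_visits=3)
        fit = fit_ml(spec, build_design(tab, spec))
        fit.n_obs = 2_000_000  # force a huge denominator df
        tr = wald_joint(fit, ["bmi", "time"])
        assert tr.p == pytest.approx(tr.p_chi2, abs=1e-3)

    def test_empty_subset(self, small_null_data):
        _, _, tab = small_null_data
        spec = ModelSpec(fixed_terms=TERMS, covariance="independence",
                         covariance_groups="shared", max_visits=3)
        fit = fit_ml(spec, build_design(tab, spec))
        with pytest.raises(TestError):
            wald_joint(fit, [])


class TestAic:
    def test_formula(self, small_null_data):
        _, _, tab = small_null_data
        spec = ModelSpec(fixed_terms=TERMS, covariance="independence",
                         covariance_groups="shared", max_visits=3)
        fit = fit_ml(spec, build_design(tab, spec))
        fit2 = fit
        fit2.loglik, fit2.k = -100.0, 5
        assert aic_of(fit2) == 210.0

    def test_nested_aic_lrt_identity(self, small_null_data):
        """For nested ML fits on the same data, AIC_reduced - AIC_full
        equals the LRT statistic minus 2*delta-df."""
        _, _, tab = small_null_data
        full_spec = ModelSpec(fixed_terms=TERMS, covariance="independence",
                              covariance_groups="shared", max_visits=3)
        red_spec = ModelSpec(fixed_terms=TERMS[:-1], covariance="independence",
                             covariance_groups="shared", max_visits=3)
        full = fit_ml(full_spec, build_design(tab, full_spec))
        red = fit_ml(red_spec, build_design(tab, red_spec))
        stat = lrt(full, red, 1).statistic
        assert red.aic - full.aic == pytest.approx(stat - 2 * 1, abs=1e-8)

    def test_heteroscedastic_beats_homoscedastic_on_het_data(self, small_null_data):
        _, _, tab = small_null_data
        shared = ModelSpec(fixed_terms=TERMS, covariance="unstructured_marginal",
                           covariance_groups="shared", max_visits=3)
        grouped = ModelSpec(fixed_terms=TERMS, covariance="unstructured_marginal",
                            covariance_groups="by_status", max_visits=3)
        f1 = fit_ml(shared, build_design(tab, shared))
        f2 = fit_ml(grouped, build_design(tab, grouped))
        assert f2.aic < f1.aic  # generator is strongly heteroscedastic
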