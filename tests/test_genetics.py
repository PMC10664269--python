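"""HWE, genetic-model coding, ANOVA/Tukey, t-tests, LRT and power arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinegen.errors import DomainError, InputError, ParameterError, ValidationError
from kinegen.genetics import (
    attrition_adjusted_n,
    balanced_allocation,
    code_genetic_model,
    cohens_f_means,
    dominant_group_ttest,
    empirical_power_oneway,
    genotype_anova,
    hwe_chi_square,
    lrt_covariate,
    model_coding,
    model_variance_percent,
)


class TestHWE:
    def test_exact_proportions_give_zero(self):
        chi2, df, p = hwe_chi_square((25, 50, 25))
        assert chi2 == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_no_heterozygotes_arithmetic(self):
        # p = 0.5, expected (25, 50, 25) -> chi2 = 25 + 50 + 25 = 100
        chi2, _, _ = hwe_chi_square((50, 0, 50))
        assert chi2 == pytest.approx(100.0)

    def test_invariant_under_homozygote_swap(self, rng):
        for _ in range(20):
            c = rng.integers(0, 100, size=3)
            if c.sum() == 0:
                continue
            a = hwe_chi_square(tuple(c))
            b = hwe_chi_square((c[2], c[1], c[0]))
            assert a[0] == pytest.approx(b[0], abs=1e-10)

    def test_monomorphic_sample_fits_trivially(self):
        chi2, _, p = hwe_chi_square((40, 0, 0))
        assert chi2 == 0.0 and p == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            hwe_chi_square((0, 0, 0))


class TestModelCoding:
    def test_coding_triples(self):
        genos = ["II", "ID", "DD"]
        assert list(code_genetic_model(genos, model_coding("additive"))) == [0, 0.5, 1]
        assert list(code_genetic_model(genos, model_coding("I_dominant"))) == [0, 0, 1]
        assert list(code_genetic_model(genos, model_coding("D_dominant"))) == [0, 1, 1]

    def test_actn3_mirror(self):
        genos = ["RR", "RX", "XX"]
        add = code_genetic_model(genos, model_coding("additive", "actn3"))
        assert list(add) == [0, 0.5, 1]
        xdom = code_genetic_model(genos, model_coding("x_dominant", "actn3"))
        assert list(xdom) == [0, 1, 1]

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValidationError):
            code_genetic_model(["IZ"], model_coding("additive"))


class TestGenotypeAnova:
    def test_constant_data_zero_eta(self):
        res = genotype_anova(np.full(30, 5.0), np.repeat(["II", "ID", "DD"], 10))
        assert res.eta_squared == 0.0

    def test_zero_within_variance_eta_is_one(self):
        y = np.repeat([1.0, 2.0, 3.0], 5)
        res = genotype_anova(y, np.repeat(["II", "ID", "DD"], 5))
        assert res.eta_squared == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self, rng):
        y = rng.normal(size=60)
        g = np.repeat(["II", "ID", "DD"], 20)
        res = genotype_anova(y, g)
        grand = y.mean()
        ssb = sum(20 * (y[g == lab].mean() - grand) ** 2 for lab in ("II", "ID", "DD"))
        sst = ((y - grand) ** 2).sum()
        ssw = sst - ssb
        f_oracle = (ssb / 2) / (ssw / 57)
        assert res.F == pytest.approx(f_oracle, abs=1e-10)
        assert res.eta_squared == pytest.approx(ssb / sst, abs=1e-10)
        assert len(res.tukey) == 3  # all pairwise genotype contrasts

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            genotype_anova(np.arange(5.0), np.array(["II"] * 4 + ["DD"]))


class TestDominantTTest:
    def test_identical_samples(self):
        y = np.concatenate([np.arange(10.0), np.arange(10.0)])
        g = np.array(["RR"] * 10 + ["XX"] * 10)
        res = dominant_group_ttest(y, g, {"RR", "RX"})
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_power_against_noncentral_t_oracle(self, rng):
        # shift 1 sd at n=30/30: analytic power ~0.97, so >= 0.95 of 500 sims
        n, d, alpha, reps = 30, 1.0, 0.05, 500
        rej = 0
        for _ in range(reps):
            a = rng.normal(d, 1.0, n)
            b = rng.normal(0.0, 1.0, n)
            res = dominant_group_ttest(np.concatenate([a, b]),
                                       np.array(["DD"] * n + ["II"] * n),
                                       {"DD", "ID"})
            rej += res.p < alpha
        nc = d / np.sqrt(2 / n)
        crit = stats.t.isf(alpha / 2, 2 * n - 2)
        analytic = stats.nct.sf(crit, 2 * n - 2, nc) + stats.nct.cdf(-crit, 2 * n - 2, nc)
        se = np.sqrt(analytic * (1 - analytic) / reps)
        assert rej / reps >= 0.95
        assert abs(rej / reps - analytic) < 3 * se + 0.01

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            dominant_group_ttest(np.arange(5.0), np.array(["XX"] * 4 + ["RR"]),
                                 {"RR", "RX"})


class TestModelVariance:
    def test_pure_additive_explains_everything(self):
        y = np.repeat([0.0, 0.5, 1.0], 10)
        g = np.repeat(["II", "ID", "DD"], 10)
        res = model_variance_percent(y, g)
        assert res.r_squared["additive"] == pytest.approx(res.eta_squared)
        assert res.percent_of_anova["additive"] == pytest.approx(100.0)
        assert res.best_model == "additive"

    def test_percent_arithmetic(self):
        # r^2 = 0.04 against eta^2 = 0.08 is 50% of the genotype variance
        assert 100.0 * 0.04 / 0.08 == pytest.approx(50.0)

    def test_d_dominant_architecture_identified(self):
        # a D-dominant truth should be called D_dominant most of the time
        from kinegen.synthetic import CohortSimConfig, simulate_cohort
        wins = 0
        for rep in range(25):
            cfg = CohortSimConfig(n=1000, model="D_dominant", effect_size=0.5,
                                  seed=500 + rep)
            geno, out, _ = simulate_cohort(cfg)
            res = model_variance_percent(out["torque_peak"].to_numpy(),
                                         geno["ace"].to_numpy(), "ace")
            wins += res.best_model == "D_dominant"
        assert wins >= 22

    def test_zero_eta_undefined(self):
        with pytest.raises(DomainError):
            model_variance_percent(np.full(30, 1.0), np.repeat(["II", "ID", "DD"], 10))


class TestLRT:
    @staticmethod
    def _frame(rng, n=120):
        return pd.DataFrame({
            "y": rng.normal(size=n),
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        })

    def test_full_equals_null_gives_zero(self, rng):
        df = self._frame(rng)
        res = lrt_covariate(df, "y", ["x1"], [])
        assert res.lr == pytest.approx(0.0) and res.df == 0

    def test_closed_form_rss_identity(self, rng):
        import statsmodels.api as sm
        df = self._frame(rng)
        res = lrt_covariate(df, "y", ["x1", "x2"], "x2")
        rss_full = sm.OLS(df["y"], sm.add_constant(df[["x1", "x2"]])).fit().ssr
        rss_null = sm.OLS(df["y"], sm.add_constant(df[["x1"]])).fit().ssr
        assert res.lr == pytest.approx(len(df) * np.log(rss_null / rss_full), abs=1e-8)

    def test_non_nested_rejected(self, rng):
        with pytest.raises(InputError):
            lrt_covariate(self._frame(rng), "y", ["x1"], "x2")


class TestSampleSize:
    def test_planned_cohort_inflation(self):
        assert attrition_adjusted_n(269, 0.05) == 283

    def test_no_dropout_identity(self):
        assert attrition_adjusted_n(100, 0.0) == 100

    def test_five_percent_of_hundred(self):
        assert attrition_adjusted_n(100, 0.05) == 105

    def test_rate_bounds(self):
        with pytest.raises(ParameterError):
            attrition_adjusted_n(100, 1.0)

    def test_balanced_allocation_deterministic(self):
        assert balanced_allocation(269, 3) == [90, 90, 89]

    def test_cohens_f_means_realise_f(self):
        sizes = balanced_allocation(269, 3)
        means = cohens_f_means(3, 0.25, sizes)
        w = np.asarray(sizes) / sum(sizes)
        mu = w @ means
        assert np.sqrt(w @ (means - mu) ** 2) == pytest.approx(0.25)


class TestEmpiricalPower:
    def test_null_effect_power_near_alpha(self):
        reps = 2000
        p = empirical_power_oneway(3, 60, 0.0, alpha=0.05, reps=reps, seed=9)
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(p - 0.05) < 3 * se

    def test_underpowered_design_matches_noncentral_f(self):
        k, n, f, alpha, reps = 3, 30, 0.25, 0.05, 4000
        p = empirical_power_oneway(k, n, f, alpha, reps=reps, seed=10)
        lam = f**2 * n
        crit = stats.f.isf(alpha, k - 1, n - k)
        analytic = stats.ncf.sf(crit, k - 1, n - k, lam)
        se = np.sqrt(analytic * (1 - analytic) / reps)
        assert p < 0.5  # far below the 0.80 design target
        assert abs(p - analytic) < 3 * se

    def test_seed_determinism(self):
        a = empirical_power_oneway(3, 90, 0.25, reps=200, seed=5)
        b = empirical_power_oneway(3, 90, 0.25, reps=200, seed=5)
        assert a == b

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            empirical_power_oneway(1, 30, 0.25)
        with pytest.raises(ParameterError):
            empirical_power_oneway(3, 4, 0.25)
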