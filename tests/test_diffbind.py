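"""Moderated t-statistics: OLS, variance trend, EB shrinkage, calibration."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from damidcall.diffbind import (DesignInfo, TrendFit, estimate_prior_df,
                                fit_linear_models, fit_variance_trend,
                                moderated_t_test, squeeze_variances,
                                differential_binding_tests)

GROUPS_2V2 = ["Dam", "Dam", "DamPOI", "DamPOI"]
GROUPS_3V3 = ["Dam"] * 3 + ["DamPOI"] * 3


class TestLinearModels:
    def test_exact_fit(self):
        values = np.array([[1.0, 1.0, 3.0, 3.0]])
        logfc, s2, design = fit_linear_models(values, GROUPS_2V2)
        assert logfc[0] == pytest.approx(2.0)
        assert s2[0] == pytest.approx(0.0)
        assert design.residual_df == 2
        assert design.coef_variance_multiplier == pytest.approx(1.0)

    def test_pooled_variance_by_hand(self):
        values = np.array([[1.0, 3.0, 2.0, 4.0]])
        logfc, s2, _ = fit_linear_models(values, GROUPS_2V2)
        assert logfc[0] == pytest.approx(1.0)
        assert s2[0] == pytest.approx(2.0)  # (2 + 2) / 2

    def test_sample_order_irrelevant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(50, 6))
        logfc, s2, _ = fit_linear_models(values, GROUPS_3V3)
        perm = [3, 0, 4, 1, 5, 2]
        logfc2, s22, _ = fit_linear_models(values[:, perm],
                                           [GROUPS_3V3[i] for i in perm])
        assert np.allclose(logfc, logfc2)
        assert np.allclose(s2, s22)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_models(np.zeros((3, 2)), ["Dam", "Dam"])


class TestVarianceTrend:
    def test_flat_trend_recovery(self):
        rng = np.random.default_rng(1)
        n, d, sigma2 = 1000, 4, 0.5
        s2 = sigma2 * rng.chisquare(d, n) / d
        abundance = rng.uniform(0, 10, n)
        trend = fit_variance_trend(s2, abundance, d)
        # smoother noise at n=1000 leaves a few-percent wiggle
        assert np.all(np.abs(trend.s0_squared / sigma2 - 1) < 0.2)
        assert np.median(np.abs(trend.s0_squared / sigma2 - 1)) < 0.1

    def test_monotone_signal_gives_monotone_trend(self):
        rng = np.random.default_rng(2)
        n, d = 2000, 4
        abundance = np.sort(rng.uniform(0, 10, n))
        sigma2 = 0.1 + 0.3 * abundance
        s2 = sigma2 * rng.chisquare(d, n) / d
        trend = fit_variance_trend(s2, abundance, d)
        fitted = trend.s0_squared
        # fitted trend increases over the abundance range (allow local noise)
        assert fitted[-100:].mean() > 2 * fitted[:100].mean()

    def test_zero_variances_floor(self):
        trend = fit_variance_trend(np.zeros(20), np.arange(20.0), 4)
        assert trend.degenerate
        assert np.all(trend.s0_squared > 0)


class TestPriorDf:
    def test_no_extra_dispersion_gives_large_d0(self):
        rng = np.random.default_rng(3)
        n, d = 5000, 4
        s2 = rng.chisquare(d, n) / d
        trend = TrendFit(np.ones(n), 0.4)
        d0 = estimate_prior_df(s2, trend, d, robust=False)
        assert d0 >= 50

    @pytest.mark.parametrize("robust", [True, False])
    def test_scaled_f_recovery(self, robust):
        d, true_d0, n = 4, 4.0, 5000
        in_range = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sigma2 = true_d0 / rng.chisquare(true_d0, n)
            s2 = sigma2 * rng.chisquare(d, n) / d
            trend = TrendFit(np.ones(n), 0.4)
            d0 = estimate_prior_df(s2, trend, d, robust=robust)
            in_range += 2.0 <= d0 <= 8.0
        assert in_range >= 18

    def test_infinite_d0_returns_trend(self):
        s2 = np.array([1.0, 2.0, 0.5])
        trend = TrendFit(np.array([0.9, 1.1, 1.0]), 0.4)
        params, post = squeeze_variances(s2, trend, df=4)
        if np.isinf(params.prior_df):
            assert np.array_equal(post, trend.s0_squared)

    def test_shrinkage_direction(self):
        rng = np.random.default_rng(4)
        n, d = 500, 4
        s2 = rng.chisquare(d, n) / d * rng.lognormal(0, 0.5, n)
        trend = TrendFit(np.full(n, float(np.median(s2))), 0.4)
        params, post = squeeze_variances(s2, trend, d)
        s0 = trend.s0_squared
        assert np.all(np.abs(post - s0) <= np.abs(s2 - s0) + 1e-12)
        assert np.all((post >= np.minimum(s2, s0) - 1e-12)
                      & (post <= np.maximum(s2, s0) + 1e-12))


class TestModeratedT:
    def test_classical_t_oracle_with_moderation_disabled(self):
        """d0 = 0 and no trend must reproduce the two-sample t exactly."""
        rng = np.random.default_rng(5)
        n = 5000
        values = rng.normal(size=(n, 6))
        logfc, s2, design = fit_linear_models(values, GROUPS_3V3)
        table = moderated_t_test(logfc, s2, prior_df=0.0,
                                 df=design.residual_df,
                                 coef_multiplier=design.coef_variance_multiplier)
        oracle = stats.ttest_ind(values[:, 3:], values[:, :3], axis=1)
        assert np.allclose(table["p_value"], oracle.pvalue, atol=1e-10)
        assert np.allclose(table["t"], oracle.statistic, atol=1e-10)

    def test_zero_logfc_p_one(self):
        table = moderated_t_test(np.array([0.0]), np.array([1.0]), 4.0, 4,
                                 2 / 3)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_p_monotone_in_variance(self):
        grid = np.linspace(0.1, 10, 25)
        table = moderated_t_test(np.full(25, 1.0), grid, 4.0, 4, 2 / 3)
        assert np.all(np.diff(table["p_value"]) > 0)

    def test_infinite_prior_uses_normal_reference(self):
        table = moderated_t_test(np.array([2.0]), np.array([1.0]), np.inf, 4,
                                 1.0)
        assert table["p_value"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(2.0), abs=1e-12)

    def test_degenerate_zero_variance(self):
        table = moderated_t_test(np.array([1.0, 0.0]), np.zeros(2), 4.0, 4,
                                 1.0)
        assert table["p_value"].tolist() == [0.0, 1.0]
        assert table["degenerate"].all()


class TestFullStage:
    def test_null_p_values_uniform(self):
        """No group effect: p-value distribution close to uniform."""
        rng = np.random.default_rng(6)
        n = 5000
        mu = rng.lognormal(3, 1, n)
        counts = rng.poisson(mu[:, None], size=(n, 6)).astype(float)
        values = np.log2(counts + 0.5)
        abundance = values.mean(axis=1)
        table = differential_binding_tests(values, GROUPS_3V3, abundance)
        ks = stats.kstest(table["p_value"], "uniform").statistic
        assert ks < 0.05

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check the whole moderated-t stage against limma in R."""
        rng = np.random.default_rng(7)
        n = 500
        values = rng.normal(size=(n, 6))
        values[:50, 3:] += 1.5  # some true effects
        abundance = values.mean(axis=1)
        np.savetxt(tmp_path / "m.csv", values, delimiter=",")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv(file.path("%s", "m.csv"), header=FALSE))
            design <- cbind(1, c(0,0,0,1,1,1))
            fit <- lmFit(m, design)
            fit <- eBayes(fit, trend=TRUE, robust=FALSE)
            out <- data.frame(logFC=fit$coefficients[,2],
                              t=fit$t[,2], p=fit$p.value[,2])
            write.csv(out, file.path("%s", "limma.csv"), row.names=FALSE)
        """ % (tmp_path, tmp_path))
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True)
        ref = np.genfromtxt(tmp_path / "limma.csv", delimiter=",",
                            skip_header=1)
        table = differential_binding_tests(values, GROUPS_3V3, abundance,
                                          robust=False)
        # identical linear-model coefficients
        assert np.allclose(table["logFC"], ref[:, 0], atol=1e-8)
        # moderation details (trend smoother, d0 estimator) differ slightly,
        # but the statistics must agree closely
        rho = stats.spearmanr(table["p_value"], ref[:, 2]).statistic
        assert rho > 0.99
        assert np.corrcoef(table["t"], ref[:, 1])[0, 1] > 0.99
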