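import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import rnabias as rb
from rnabias.correct import (
    PCScores,
    _assemble,
    _penalized_solve,
    select_component_count,
)
from rnabias.models import BiasCovariateTable, ExpressionTable


class TestComponentCountRule:
    def test_cumulative_sum_example(self):
        assert select_component_count([0.60, 0.25, 0.08, 0.05, 0.02]) == 4

    def test_threshold_tie_uses_geq(self):
        assert select_component_count([0.95, 0.05]) == 1
        assert select_component_count([0.5, 0.45, 0.05]) == 2

    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=500)
        X = np.outer(base, rng.uniform(0.5, 2.0, 17))
        basis, _ = rb.principal_components(X)
        assert basis.K == 1
        assert basis.variance_share[0] == pytest.approx(1.0)

    def test_iid_columns_need_all_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5000, 17))
        basis, _ = rb.principal_components(X)
        # equal population shares 1/17: 16 components cover only ~0.941
        assert basis.K == 17


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(2)
    latent = rng.normal(size=(800, 4))
    mix = rng.normal(size=(4, 17))
    X = latent @ mix + 0.3 * rng.normal(size=(800, 17))
    return X, rb.principal_components(X)


class TestPCABasis:
    def test_loadings_orthonormal(self, fitted):
        _, (basis, _) = fitted
        eye = basis.loadings.T @ basis.loadings
        np.testing.assert_allclose(eye, np.eye(17), atol=1e-8)

    def test_variance_share_non_increasing_and_boundary(self, fitted):
        _, (basis, _) = fitted
        assert np.all(np.diff(basis.variance_share) <= 1e-12)
        cum = np.cumsum(basis.variance_share)
        assert cum[basis.K - 1] >= 0.95 - 1e-12
        if basis.K > 1:
            assert cum[basis.K - 2] < 0.95

    def test_reconstruction_of_standardized_data(self, fitted):
        X, (basis, _) = fitted
        Z = (X - basis.column_means) / basis.column_sds
        full_scores = Z @ basis.loadings
        np.testing.assert_allclose(full_scores @ basis.loadings.T, Z, atol=1e-6)

    def test_score_columns_uncorrelated(self, fitted):
        _, (basis, scores) = fitted
        corr = np.corrcoef(scores.P, rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.abs(off).max() < 1e-6

    def test_sign_convention_deterministic(self, fitted):
        X, (basis, _) = fitted
        basis2, _ = rb.principal_components(X[::-1])
        # same data in reverse row order: identical loadings incl. signs
        np.testing.assert_allclose(basis.loadings, basis2.loadings, atol=1e-8)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 5))
        X[:, 2] = 1.0
        with pytest.warns(UserWarning):
            basis, scores = rb.principal_components(X)
        assert len(basis.column_names) == 4
        assert basis.dropped_columns == ["x2"]


class TestFitBiasGam:
    def test_constant_response_gives_zero_residuals(self):
        rng = np.random.default_rng(4)
        n = 300
        scores = PCScores(list(range(n)), rng.normal(size=(n, 2)))
        fit = rb.fit_bias_gam(np.full(n, 3.0), rng.uniform(6, 9, n), scores)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-8)
        assert fit.grand_mean == pytest.approx(3.0)

    def test_fitted_plus_residual_identity_and_zero_mean(self):
        rng = np.random.default_rng(5)
        n = 500
        logL = rng.uniform(6, 9, n)
        scores = PCScores(list(range(n)), rng.normal(size=(n, 3)))
        y = 1 + 0.3 * logL + rng.normal(0, 0.5, n)
        fit = rb.fit_bias_gam(y, logL, scores)
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-10)
        assert abs(fit.residuals.mean()) < 1e-8

    def test_planted_linear_length_effect_removed(self):
        rng = np.random.default_rng(6)
        n = 3000
        logL = rng.uniform(5, 10, n)
        y = 2.0 - 0.5 * logL + rng.normal(0, 0.1, n)
        scores = PCScores(list(range(n)), np.empty((n, 0)))
        with pytest.warns(UserWarning):
            fit = rb.fit_bias_gam(y, logL, scores)
        corrected = fit.grand_mean + fit.residuals
        assert abs(rb.pearson_r(y, logL)) > 0.5
        assert abs(rb.pearson_r(corrected, logL)) < 0.05

    def test_planted_sine_pc_effect_is_significant(self):
        rng = np.random.default_rng(7)
        n = 800
        logL = rng.uniform(6, 9, n)
        p1 = rng.normal(size=(n, 1))
        y = np.sin(2 * p1[:, 0]) + rng.normal(0, 0.5, n)
        fit = rb.fit_bias_gam(y, logL, PCScores(list(range(n)), p1))
        stats = rb.term_significance(fit)
        assert stats.set_index("term").loc["PC1", "p"] < 1e-3

    def test_length_linear_switch_gives_single_linear_term(self):
        rng = np.random.default_rng(8)
        n = 400
        logL = rng.uniform(6, 9, n)
        y = 1 - 0.4 * logL + rng.normal(0, 0.2, n)
        scores = PCScores(list(range(n)), rng.normal(size=(n, 1)))
        fit = rb.fit_bias_gam(y, logL, scores, length_linear=True)
        term = [t for t in fit.terms if t.name == "log_length"][0]
        assert term.linear and term.edf == 1.0

    def test_single_term_model_has_one_significance_row(self):
        rng = np.random.default_rng(9)
        n = 300
        y = rng.normal(size=n)
        with pytest.warns(UserWarning):
            fit = rb.fit_bias_gam(
                y, rng.uniform(6, 9, n), PCScores(list(range(n)), np.empty((n, 0)))
            )
        assert len(rb.term_significance(fit)) == 1

    def test_agrees_with_statsmodels_glmgam_at_fixed_penalty(self):
        """At the same basis and penalty weights, the direct penalized solve
        must reproduce statsmodels' penalized IRLS fit."""
        from statsmodels.gam.api import GLMGam
        from statsmodels.gam.smooth_basis import BSplines

        rng = np.random.default_rng(10)
        n = 300
        x = rng.uniform(size=(n, 2))
        y = np.sin(6 * x[:, 0]) + x[:, 1] + rng.normal(0, 0.3, n)
        bs = BSplines(x, df=[10, 10], degree=[3, 3])
        alpha = [5.0, 20.0]
        sm_fit = GLMGam(y, exog=np.ones((n, 1)), smoother=bs, alpha=alpha).fit()
        blocks = [
            ("a", bs.smoothers[0].basis, bs.smoothers[0].cov_der2),
            ("b", bs.smoothers[1].basis, bs.smoothers[1].cov_der2),
        ]
        X, sl, pen = _assemble(blocks, n)
        beta, _, _ = _penalized_solve(X, y, sl, pen, np.array(alpha))
        assert np.abs(sm_fit.fittedvalues - X @ beta).max() < 0.05

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_agrees_with_mgcv_estimate(self, tmp_path):
        """Independent oracle: mgcv's gam() on the same data must estimate
        nearly the same conditional mean (different basis/penalty details,
        so agreement is at the estimate level, not coefficient level)."""
        rng = np.random.default_rng(11)
        n = 600
        logL = rng.uniform(6, 9, n)
        p1 = rng.normal(size=n)
        y = 2 - 0.5 * logL + np.sin(2 * p1) + rng.normal(0, 0.3, n)
        fit = rb.fit_bias_gam(y, logL, PCScores(list(range(n)), p1.reshape(-1, 1)))
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "logL": logL, "p1": p1, "mine": fit.fitted}).to_csv(
            csv, index=False
        )
        script = (
            'suppressMessages(library(mgcv)); d <- read.csv("%s"); '
            "m <- gam(y ~ s(logL, k=10) + s(p1, k=10), data=d); "
            'cat(sqrt(mean((fitted(m) - d$mine)^2)), cor(fitted(m), d$mine), "\\n")'
            % csv
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        rms, corr = map(float, out.stdout.split())
        assert rms < 0.1
        assert corr > 0.99


class TestCorrectExpression:
    def test_mean_preserved_and_identity(self, biased_run):
        truth, expr, corrected = biased_run
        fitted = corrected.corrected_log.dropna().index
        assert corrected.corrected_log[fitted].mean() == pytest.approx(
            corrected.raw_log[fitted].mean(), abs=1e-8
        )
        np.testing.assert_allclose(
            corrected.corrected_linear[fitted],
            np.exp(corrected.corrected_log[fitted]),
        )

    def test_zero_expression_units_passed_through_flagged(self, biased_run):
        truth, expr, corrected = biased_run
        frame = corrected.to_frame()
        excluded = frame[frame["excluded_flag"] == 1]
        y = expr.Y.iloc[:, 0]
        assert set(excluded.index) == set(y.index[y == 0])
        if len(excluded):
            np.testing.assert_allclose(
                excluded["corrected_linear"], y[excluded.index]
            )

    def test_too_few_positive_units_is_hard_error(self):
        idx = [f"g{i}" for i in range(50)]
        expr = ExpressionTable(
            Y=pd.DataFrame({"s": np.ones(50)}, index=idx),
            lengths=pd.Series(1000, index=idx),
        )
        rng = np.random.default_rng(12)
        tab = pd.DataFrame(
            rng.uniform(0.1, 0.9, size=(50, 18)), index=idx,
            columns=rb.COVARIATE_COLUMNS,
        )
        with pytest.raises(ValueError, match="positive"):
            rb.correct_expression(expr, BiasCovariateTable(tab, "gene"))

    def test_approximate_idempotence(self, biased_run):
        truth, expr, corrected = biased_run
        fitted = corrected.corrected_log.dropna().index
        expr2 = ExpressionTable(
            Y=pd.DataFrame({"s": corrected.corrected_linear[fitted]}),
            lengths=expr.lengths[fitted],
        )
        cov2 = BiasCovariateTable(truth.covariates.table.loc[fitted], "gene")
        again = rb.correct_expression(expr2, cov2)
        rms = float(
            np.sqrt(np.mean((again.corrected_log - corrected.corrected_log[fitted]) ** 2))
        )
        assert rms < 0.05

    def test_term_significance_ranks_strong_length_effect_first(self):
        models, truth = rb.simulate_transcriptome(
            n_genes=600, seed=21, bias_spec=rb.BiasSpec(length_exponent=-1.0)
        )
        lanes = rb.simulate_counts(truth, 1, seed=22)
        expr = rb.rpkm(rb.merge_lanes(lanes), truth.covariates.lengths())
        res = rb.correct_expression(expr, truth.covariates)
        stats = rb.term_significance(res.fit).set_index("term")
        assert stats["p"].idxmin() == "log_length"
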