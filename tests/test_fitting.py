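"""Quadratic fitting, diagnostics, ANOVA, and outlier handling.

The externally studentized residual and PRESS paths are checked against
literal leave-one-out refits written directly in these tests, so the
oracle shares no code with the implementation.
"""

import numpy as np
import pytest

import dietrsm as dr
from dietrsm.errors import InsufficientDataError, SingularDesignError
from dietrsm.models import basis_matrix


def _literal_esr(x, y):
    """External studentized residuals by refitting without each point."""
    X = basis_matrix(x)
    n, p = X.shape
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        beta, _, _, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        resid = yi - Xi @ beta
        mse_i = (resid @ resid) / (len(yi) - p)
        xi = X[i]
        pred_var = mse_i * (1.0 + xi @ np.linalg.inv(Xi.T @ Xi) @ xi)
        out[i] = (y[i] - xi @ beta) / np.sqrt(pred_var)
    return out


def _literal_press(x, y):
    """PRESS by literally refitting n times and predicting the held-out point."""
    X = basis_matrix(x)
    n = len(y)
    total = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        beta, _, _, _ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        total += (y[i] - X[i] @ beta) ** 2
    return total


class TestFitQuadratic:
    def test_constant_response_recovers_intercept_only(self, design20):
        y = np.full(20, 7.25)
        fit = dr.fit_quadratic(design20.actual_matrix(), y,
                               factors=design20.factors)
        assert fit.model.beta0 == pytest.approx(7.25, abs=1e-10)
        assert np.abs(fit.model.coefficients()[1:]).max() < 1e-10

    @pytest.mark.parametrize("response", ["Bf", "F"])
    def test_noiseless_recovery_of_generating_model(
        self, response, models, noiseless_tables
    ):
        """Noiseless data from the published surfaces interpolates exactly."""
        fit = dr.fit_response(noiseless_tables[response], response)
        np.testing.assert_allclose(
            fit.model.coefficients(), models[response].coefficients(),
            rtol=0, atol=1e-6,
        )

    def test_leverage_sums_to_p_and_df(self, toy_k2_fit):
        assert toy_k2_fit.leverage.sum() == pytest.approx(toy_k2_fit.model.p)
        assert np.all((toy_k2_fit.leverage >= 0) & (toy_k2_fit.leverage <= 1))
        assert toy_k2_fit.df_residual == toy_k2_fit.n_points - toy_k2_fit.model.p

    def test_coefficients_match_direct_least_squares(self, toy_k2_fit):
        """Cross-check the fit against a bare normal-equations solve."""
        X = basis_matrix(toy_k2_fit.levels)
        beta = np.linalg.solve(X.T @ X, X.T @ toy_k2_fit.response)
        np.testing.assert_allclose(toy_k2_fit.model.coefficients(), beta,
                                   rtol=1e-10)

    def test_insufficient_points_raise(self, factors):
        x = np.zeros((5, 3))
        with pytest.raises(InsufficientDataError):
            dr.fit_quadratic(x, np.ones(5), factors=factors)

    def test_rank_deficient_design_raises(self, factors):
        # 12 points all on a line: quadratic basis in 3 factors collapses
        t = np.linspace(0, 1, 12)
        x = np.column_stack([t, 2 * t, 3 * t])
        with pytest.raises(SingularDesignError):
            dr.fit_quadratic(x, np.ones(12), factors=factors)


class TestDiagnosticsOracles:
    def test_esr_equals_literal_leave_one_out(self):
        """ESR on an 8-point two-factor fit equals per-point exclusion refits."""
        rng = np.random.default_rng(77)
        x = np.array([[-1, -1], [1, -1], [-1, 1], [1, 1],
                      [-1.5, 0], [1.5, 0], [0, -1.5], [0, 1.5]], float)
        y = 1.0 + 0.5 * x[:, 0] - 0.25 * x[:, 1] + rng.normal(0, 0.3, 8)
        fit = dr.fit_quadratic(x, y, representation="coded")
        np.testing.assert_allclose(fit.esr, _literal_esr(x, y), rtol=1e-8)

    def test_esr_on_larger_design_matches_oracle(self, toy_k2_fit):
        np.testing.assert_allclose(
            toy_k2_fit.esr,
            _literal_esr(toy_k2_fit.levels, toy_k2_fit.response),
            rtol=1e-8,
        )

    def test_press_equals_literal_refits(self, toy_k2_fit):
        report = dr.anova(toy_k2_fit)
        assert report.press == pytest.approx(
            _literal_press(toy_k2_fit.levels, toy_k2_fit.response), rel=1e-10
        )

    def test_press_identity_on_toy_linear_data(self):
        """Hat-matrix PRESS equals drop-and-refit on a 6-point straight line."""
        x = np.array([0.0, 1, 2, 3, 4, 5])
        y = np.array([0.1, 1.2, 1.8, 3.3, 3.9, 5.2])
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        hat = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
        press_identity = float(((resid / (1 - hat)) ** 2).sum())
        literal = 0.0
        for i in range(6):
            keep = np.arange(6) != i
            b = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            literal += (y[i] - X[i] @ b) ** 2
        assert press_identity == pytest.approx(literal, rel=1e-10)


class TestAnova:
    def test_perfect_fit_reports_unity_r2(self, design20, models):
        y = models["Bf"].predict(design20.actual_matrix())
        fit = dr.fit_quadratic(design20.actual_matrix(), y,
                               factors=design20.factors)
        report = dr.anova(fit)
        assert report.r2 == 1.0
        assert report.r2_adjusted == 1.0
        assert report.overall_p == 0.0
        assert np.isinf(report.adequate_precision)
        assert report.press == 0.0

    def test_constant_predictions_zero_adequate_precision(self, design20):
        fit = dr.fit_quadratic(design20.actual_matrix(), np.full(20, 3.0),
                               factors=design20.factors)
        assert dr.anova(fit).adequate_precision == 0.0

    def test_fit_quality_statistics_ordering(self, toy_k2_fit):
        report = dr.anova(toy_k2_fit)
        assert report.r2_adjusted <= report.r2 <= 1.0
        # PRESS >= SSE always, so predicted R2 cannot exceed R2
        assert report.r2_predicted <= report.r2 + 1e-12
        assert 0.0 <= report.overall_p <= 1.0
        assert np.all((report.per_term["p"] >= 0) & (report.per_term["p"] <= 1))

    def test_adjusted_r2_formula(self, toy_k2_fit):
        report = dr.anova(toy_k2_fit)
        n, p = toy_k2_fit.n_points, toy_k2_fit.model.p
        assert report.r2_adjusted == pytest.approx(
            1 - (1 - report.r2) * (n - 1) / (n - p)
        )

    def test_emulated_study_fits_are_significant_and_adequate(self, design20, models):
        """Default-noise refits give p < 0.001 and adequate precision > 4."""
        for resp in ("Bf", "F"):
            tab = dr.simulate_measurements(
                design20, models[resp], noise_sd=dr.DEFAULT_NOISE_SD[resp],
                replicates_per_run=5, seed=2024,
            )
            report = dr.anova(dr.fit_response(tab, resp))
            assert report.overall_p < 1e-3
            assert report.adequate_precision > 4


class TestOutliers:
    def test_zero_residuals_flag_nothing(self, design20, models):
        y = models["F"].predict(design20.actual_matrix())
        fit = dr.fit_quadratic(design20.actual_matrix(), y,
                               factors=design20.factors)
        assert np.allclose(fit.esr, 0.0)
        assert dr.flag_outliers(fit, threshold=3.0) == []

    def test_injected_8_sigma_center_outlier_is_flagged(self, design20, models):
        """A +8-sigma offset on one center run trips the |ESR| > 3 screen."""
        sd = dr.DEFAULT_NOISE_SD["Bf"]
        center_run = int(
            design20.runs.query("point_class == 'center'")["run_id"].iloc[0]
        )
        tab = dr.simulate_measurements(
            design20, models["Bf"], noise_sd=sd, replicates_per_run=5,
            seed=31, outliers=[(center_run, 8 * sd)],
        )
        fit = dr.fit_response(tab, "Bf")
        assert center_run in dr.flag_outliers(fit, threshold=3.0)

    def test_refit_excluding_records_and_removes_runs(self, design20, models):
        tab = dr.simulate_measurements(design20, models["Bf"], noise_sd=4.0,
                                       replicates_per_run=5, seed=5)
        fit = dr.refit_excluding(tab, "Bf", run_ids=[2, 13])
        assert fit.excluded_run_ids == [2, 13]
        assert fit.n_points == 18
        assert 2 not in fit.run_ids and 13 not in fit.run_ids

    def test_excluding_too_many_runs_is_singular(self, design20, models):
        tab = dr.simulate_measurements(design20, models["Bf"], noise_sd=4.0,
                                       replicates_per_run=5, seed=5)
        # drop all factorial points: the interaction terms collapse
        with pytest.raises((SingularDesignError, InsufficientDataError)):
            dr.refit_excluding(tab, "Bf", run_ids=list(range(1, 12)))


class TestMeasurementTable:
    def test_run_means_counts_replicates(self, noiseless_tables):
        means = dr.run_means(noiseless_tables["Bf"], "Bf")
        assert len(means) == 20
        assert (means["n_replicates"] == 5).all()

    def test_csv_round_trip(self, noiseless_tables, factors, tmp_path):
        path = tmp_path / "meas.csv"
        noiseless_tables["F"].to_csv(path)
        back = dr.MeasurementTable.from_csv(path, factors)
        np.testing.assert_allclose(
            back.data["value"], noiseless_tables["F"].data["value"], rtol=1e-12
        )

    def test_inconsistent_run_levels_rejected(self, factors):
        import pandas as pd

        df = pd.DataFrame({
            "run_id": [1, 1], "S": [10.0, 20.0], "P": [2.0, 2.0],
            "D": [5.0, 5.0], "replicate_id": [1, 2],
            "response": ["Bf", "Bf"], "value": [1.0, 2.0],
        })
        with pytest.raises(dr.errors.DimensionError):
            dr.MeasurementTable(df, factors)
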