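"""Quadratic OLS fit, ANOVA decomposition, significance-based reduction."""

import numpy as np
import pytest

from extropt import rsm
from extropt.design import DesignTable, FactorSpec, PAPER_FACTORS, build_bbd
from extropt.rsm import (
    SingularFitError,
    anova,
    fit_quadratic,
    predict_rsm,
    quadratic_design_matrix,
    reduce_model,
    term_names,
)
from extropt.synth import published_yield_model

PUBLISHED_REDUCED_TERMS = {
    "Intercept", "X2", "X3", "X4", "X1X4", "X2X3", "X1^2", "X2^2", "X3^2", "X4^2",
}


def _design_with_response(factors, coded, y):
    import pandas as pd
    from extropt.design import RESPONSE_COLUMN, decode

    actual = decode(coded, factors)
    frame = pd.DataFrame(actual, columns=[f.name for f in factors])
    frame.insert(0, "run", np.arange(1, len(frame) + 1))
    frame[RESPONSE_COLUMN] = y
    return DesignTable(tuple(factors), frame)


class TestFitQuadratic:
    def test_study_intercept_and_temperature_coefficient(self, table1):
        model = fit_quadratic(table1)
        assert round(model.intercept, 2) == 7.34
        assert round(model.linear[1], 2) == 0.13

    def test_temperature_coefficient_against_contrast_oracle(self, table1):
        # On a BBD the X2 column is orthogonal to every other model column,
        # so beta_2 equals the +1/-1 contrast: (sum y at X2=+1 minus at -1)/12.
        coded, y = table1.coded, table1.response
        oracle = (y[coded[:, 1] == 1].sum() - y[coded[:, 1] == -1].sum()) / 12.0
        model = fit_quadratic(table1)
        assert model.linear[1] == pytest.approx(oracle, abs=1e-10)

    def test_noiseless_quadratic_recovered_exactly(self):
        factors = [FactorSpec(f"F{i}", "", -1.0, 1.0) for i in range(3)]
        bbd = build_bbd(factors, n_center=3)
        coded = bbd.coded
        y = 2.0 + coded[:, 0] - 0.5 * coded[:, 1] ** 2
        d = _design_with_response(factors, coded, y)
        model = fit_quadratic(d)
        expected = dict.fromkeys(term_names(3), 0.0)
        expected.update({"Intercept": 2.0, "X1": 1.0, "X2^2": -0.5})
        for name, value in model.coef_dict().items():
            assert value == pytest.approx(expected[name], abs=1e-10)

    def test_residuals_orthogonal_to_design_columns(self, table1):
        model = fit_quadratic(table1)
        X = quadratic_design_matrix(table1.coded)
        r = table1.response - model.predict(table1.coded)
        assert np.abs(X.T @ r).max() <= 1e-8

    def test_matches_generic_least_squares_on_random_instances(self, rng):
        import statsmodels.api as sm

        factors = [FactorSpec(f"F{i}", "", 0.0, 10.0) for i in range(4)]
        bbd = build_bbd(factors, n_center=4)
        for _ in range(20):
            y = rng.normal(size=bbd.n_runs)
            d = _design_with_response(factors, bbd.coded, y)
            ours = fit_quadratic(d).coef
            theirs = sm.OLS(y, quadratic_design_matrix(bbd.coded)).fit().params
            assert np.allclose(ours, theirs, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        factors = [FactorSpec(f"F{i}", "", -1.0, 1.0) for i in range(4)]
        coded = np.zeros((20, 4))  # all-centre: only the intercept is estimable
        d = _design_with_response(factors, coded, np.ones(20))
        with pytest.raises(SingularFitError):
            fit_quadratic(d)

    def test_missing_responses_rejected(self):
        bbd = build_bbd(PAPER_FACTORS, n_center=2)
        with pytest.raises(ValueError, match="missing responses"):
            fit_quadratic(bbd)


class TestAnova:
    def test_study_summary_statistics(self, table1):
        report = anova(fit_quadratic(table1), table1)
        assert round(report.R2, 4) == 0.8906
        assert round(report.R2_adj, 4) == 0.7885
        assert round(report["Model"].F, 2) == 8.72

    def test_pure_error_from_centre_replicates(self, table1):
        # oracle: squared deviations of the six centre yields about their mean
        centres = table1.response[np.all(table1.coded == 0, axis=1)]
        assert len(centres) == 6
        oracle = ((centres - centres.mean()) ** 2).sum()
        report = anova(fit_quadratic(table1), table1)
        assert report["Pure error"].SS == pytest.approx(oracle, abs=1e-12)
        assert round(report["Pure error"].SS, 3) == 0.078
        assert round(report["Lack of fit"].F, 2) == 0.11

    def test_sum_of_squares_additivity(self, table1):
        report = anova(fit_quadratic(table1), table1)
        total = report["Total"]
        assert report["Model"].SS + report["Residual"].SS == pytest.approx(
            total.SS, rel=1e-8
        )
        assert report["Lack of fit"].SS + report["Pure error"].SS == pytest.approx(
            report["Residual"].SS, rel=1e-8
        )
        assert report["Model"].df + report["Residual"].df == total.df
        assert (
            report["Lack of fit"].df + report["Pure error"].df
            == report["Residual"].df
        )

    def test_perfect_fit_gives_unit_r2(self):
        factors = [FactorSpec(f"F{i}", "", -1.0, 1.0) for i in range(3)]
        bbd = build_bbd(factors, n_center=1)
        y = 1.0 + bbd.coded[:, 0] + bbd.coded[:, 2] ** 2
        d = _design_with_response(factors, bbd.coded, y)
        report = anova(fit_quadratic(d), d)
        assert report.R2 == pytest.approx(1.0)
        assert report["Residual"].SS == pytest.approx(0.0, abs=1e-18)

    def test_no_replicates_leaves_lack_of_fit_unavailable(self, rng):
        factors = [FactorSpec(f"F{i}", "", -1.0, 1.0) for i in range(4)]
        bbd = build_bbd(factors, n_center=1)
        d = _design_with_response(factors, bbd.coded, rng.normal(size=bbd.n_runs))
        with pytest.warns(UserWarning, match="lack-of-fit"):
            report = anova(fit_quadratic(d), d)
        assert report["Lack of fit"].F is None
        assert np.isnan(report["Pure error"].SS)

    def test_additivity_on_random_synthetic_designs(self, rng):
        factors = [FactorSpec(f"F{i}", "", 0.0, 2.0) for i in range(4)]
        bbd = build_bbd(factors, n_center=5)
        for _ in range(5):
            y = rng.normal(7.0, 0.2, size=bbd.n_runs)
            d = _design_with_response(factors, bbd.coded, y)
            rep = anova(fit_quadratic(d), d)
            assert rep["Model"].SS + rep["Residual"].SS == pytest.approx(
                rep["Total"].SS, rel=1e-8
            )
            assert rep.R2_adj <= rep.R2 <= 1.0


class TestReduceModel:
    def test_study_reduction_recovers_published_term_set(self, table1):
        reduced = reduce_model(fit_quadratic(table1), table1, alpha=0.05)
        kept = {t for t, m in zip(reduced.terms, reduced.term_mask) if m}
        assert kept == PUBLISHED_REDUCED_TERMS

    def test_reduced_coefficients_match_published_rounding(self, table1):
        reduced = reduce_model(fit_quadratic(table1), table1, alpha=0.05)
        c = reduced.coef_dict()
        assert round(c["Intercept"], 2) == 7.34
        assert round(c["X2"], 2) == 0.13

    def test_alpha_one_keeps_everything(self, table1):
        full = fit_quadratic(table1)
        assert reduce_model(full, table1, alpha=1.0).term_mask.all()

    def test_single_true_term_survives_at_low_noise(self, rng):
        factors = [FactorSpec(f"F{i}", "", -1.0, 1.0) for i in range(4)]
        bbd = build_bbd(factors, n_center=5)
        y = 5.0 + 1.5 * bbd.coded[:, 2] + rng.normal(0, 0.01, bbd.n_runs)
        d = _design_with_response(factors, bbd.coded, y)
        reduced = reduce_model(fit_quadratic(d), d, alpha=0.05)
        kept = {t for t, m in zip(reduced.terms, reduced.term_mask) if m}
        assert "X3" in kept
        assert kept <= {"Intercept", "X3"} or len(kept) <= 3  # sporadic extras only

    def test_invalid_alpha_rejected(self, table1):
        with pytest.raises(ValueError):
            reduce_model(fit_quadratic(table1), table1, alpha=0.0)


class TestPredict:
    def test_published_polynomial_at_origin(self):
        assert predict_rsm(published_yield_model(), np.zeros(4))[0] == pytest.approx(7.34)

    def test_published_polynomial_at_unit_temperature(self):
        # 7.34 + 0.13 - 0.084
        point = np.array([0.0, 1.0, 0.0, 0.0])
        assert predict_rsm(published_yield_model(), point)[0] == pytest.approx(7.386)

    def test_zero_model_everywhere_zero(self, rng):
        zero = rsm.QuadraticModel(4, np.zeros(15), np.zeros(15, bool))
        pts = rng.uniform(-1, 1, size=(10, 4))
        assert np.all(predict_rsm(zero, pts) == 0.0)


class TestParameterRecovery:
    def test_coefficient_error_vanishes_with_noise(self, rng):
        """Mean absolute coefficient error shrinks as noise goes to zero."""
        truth = published_yield_model()
        bbd = build_bbd(PAPER_FACTORS, n_center=6)
        clean = truth.predict(bbd.coded)
        errors = []
        for sd in (0.2, 0.02, 0.0):
            errs = []
            for _ in range(30):
                y = clean + rng.normal(0, sd, bbd.n_runs)
                d = _design_with_response(PAPER_FACTORS, bbd.coded, y)
                errs.append(np.abs(fit_quadratic(d).coef - truth.coef).mean())
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] <= 1e-10

    def test_estimates_unbiased_at_moderate_noise(self, rng):
        truth = published_yield_model()
        bbd = build_bbd(PAPER_FACTORS, n_center=6)
        clean = truth.predict(bbd.coded)
        sd = 0.05
        coefs = []
        for _ in range(200):
            y = clean + rng.normal(0, sd, bbd.n_runs)
            d = _design_with_response(PAPER_FACTORS, bbd.coded, y)
            coefs.append(fit_quadratic(d).coef)
        bias = np.mean(coefs, axis=0) - truth.coef
        # MC standard error of each mean coefficient is ~ sd/sqrt(200*12)
        assert np.abs(bias).max() < 4 * sd / np.sqrt(200)
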