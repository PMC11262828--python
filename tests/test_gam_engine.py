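"""Tests for the penalized GAM engine."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from sdm_transfer import (
    BasisError,
    FittedGAM,
    MissingCovariateError,
    SmoothSpec,
    build_basis,
    fit_pirls,
    partial_effect,
    predict,
    select_smoothing,
)
from sdm_transfer.gam_engine import EDF_SHRUNK_TOLERANCE
from tests.conftest import logistic_records, records_from


class TestBasis:
    def test_quadratic_reproduced_exactly(self, rng):
        """A cubic-spline basis of dimension 6 contains all quadratics."""
        x = rng.uniform(0, 10, 400)
        b = build_basis(SmoothSpec("a", basis_dim=6), x)
        y = 3.0 + 0.5 * x - 0.2 * x**2
        X = np.column_stack([np.ones(x.size), b.design_columns])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(X @ coef - y)) < 1e-6

    def test_columns_sum_to_zero(self, rng):
        x = rng.uniform(-3, 7, 200)
        b = build_basis(SmoothSpec("a"), x)
        assert np.allclose(b.design_columns.sum(axis=0), 0.0, atol=1e-8)

    def test_penalty_symmetric_psd(self, rng):
        x = rng.uniform(0, 1, 150)
        b = build_basis(SmoothSpec("a"), x)
        for S in (b.penalty, b.null_penalty):
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_curvature_penalty_annihilates_linear_functions(self, rng):
        """The curvature penalty's quadratic form is zero on linear trends."""
        x = rng.uniform(0, 5, 300)
        b = build_basis(SmoothSpec("a", basis_dim=6), x)
        y = 2.0 - 0.7 * x
        X = np.column_stack([np.ones(x.size), b.design_columns])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(X @ coef - y)) < 1e-8  # linear is representable
        beta = coef[1:]
        assert float(beta @ b.penalty @ beta) < 1e-10
        # ...but the null-space penalty does see it
        assert float(beta @ b.null_penalty @ beta) > 1e-6

    def test_evaluate_matches_training_design_in_range(self, rng):
        x = rng.uniform(0, 1, 100)
        b = build_basis(SmoothSpec("a"), x)
        rows, mask = b.evaluate(x)
        assert not mask.any()
        assert np.allclose(rows, b.design_columns, atol=1e-12)

    def test_evaluate_flags_and_extends_linearly(self, rng):
        x = rng.uniform(0, 1, 100)
        b = build_basis(SmoothSpec("a"), x)
        beta = rng.normal(size=b.n_coef)
        grid = np.linspace(-1.0, 2.0, 301)
        rows, mask = b.evaluate(grid)
        assert mask.sum() == ((grid < x.min()) | (grid > x.max())).sum()
        vals = rows @ beta
        # second differences vanish on each extrapolated side -> linear
        left = vals[grid < x.min()]
        right = vals[grid > x.max()]
        for side in (left, right):
            assert np.max(np.abs(np.diff(side, n=2))) < 1e-9

    def test_extension_continuous_at_boundary(self, rng):
        x = rng.uniform(0, 1, 80)
        b = build_basis(SmoothSpec("a"), x)
        beta = rng.normal(size=b.n_coef)
        eps = 1e-9
        for bound in (b.x_min, b.x_max):
            inside, _ = b.evaluate(np.array([bound]))
            just_out = bound - eps if bound == b.x_min else bound + eps
            outside, m = b.evaluate(np.array([just_out]))
            assert m[0]
            assert abs(inside @ beta - outside @ beta) < 1e-6

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(BasisError):
            build_basis(SmoothSpec("a", basis_dim=5), np.array([1.0, 2.0, 3.0, 1.0]))

    def test_non_finite_rejected(self):
        with pytest.raises(BasisError):
            build_basis(SmoothSpec("a"), np.array([0.0, 1.0, np.nan, 2.0, 3.0]))

    def test_basis_dim_validation(self):
        with pytest.raises(ValueError):
            SmoothSpec("a", basis_dim=2)


def _two_term_records(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, n)
    b = rng.uniform(0, 1, n)
    eta = 1.2 * np.sin(2 * np.pi * a) + 0.8 * (b - 0.5)
    y = (rng.uniform(size=n) < expit(eta)).astype(int)
    return records_from(y, seed=seed + 1, a=a, b=b)


class TestPIRLS:
    def test_matches_generic_numerical_optimizer(self):
        """PIRLS at fixed penalties equals direct penalized-likelihood optimization."""
        rec = _two_term_records(200, 42)
        terms = [SmoothSpec("a"), SmoothSpec("b")]
        lambdas = [(1.0, 0.1), (5.0, 0.5)]
        fit = fit_pirls(rec, terms, lambdas)

        from sdm_transfer.gam_engine import _assemble_design, _embedded_penalties

        X, y, bases, slices = _assemble_design(rec, terms)
        P = np.zeros((X.shape[1],) * 2)
        for (lam, lam0), (S, S0) in zip(
            lambdas, _embedded_penalties(bases, slices, X.shape[1])
        ):
            P += lam * S + lam0 * S0

        def objective(beta):
            eta = X @ beta
            # -2 loglik + penalty, numerically stable log(1+exp)
            return 2.0 * np.sum(np.logaddexp(0, eta) - y * eta) + beta @ P @ beta

        res = minimize(objective, np.zeros(X.shape[1]), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 2000})
        assert np.max(np.abs(fit.coefficients - res.x)) < 1e-5

    def test_heavy_penalty_shrinks_to_intercept(self):
        rec = _two_term_records(300, 7)
        fit = fit_pirls(rec, [SmoothSpec("a")], [(1e12, 1e12)])
        assert fit.edf["a"] < 1e-3
        p = predict(fit, rec)
        assert np.allclose(p, rec["response"].mean(), atol=1e-3)

    def test_light_penalty_uses_full_basis(self):
        rec = _two_term_records(300, 8)
        fit = fit_pirls(rec, [SmoothSpec("a")], [(1e-8, 1e-8)])
        assert fit.edf["a"] == pytest.approx(4.0, abs=0.05)

    def test_edf_monotone_in_lambda(self):
        rec = _two_term_records(250, 9)
        edfs = [
            fit_pirls(rec, [SmoothSpec("a")], [(lam, 1e-6)]).edf["a"]
            for lam in (1e-4, 1e-2, 1.0, 1e2, 1e4)
        ]
        assert all(e1 >= e2 - 1e-9 for e1, e2 in zip(edfs, edfs[1:]))

    def test_smoothing_params_length_checked(self):
        rec = _two_term_records(100, 10)
        with pytest.raises(ValueError):
            fit_pirls(rec, [SmoothSpec("a"), SmoothSpec("b")], [(1.0, 1.0)])

    def test_missing_covariate_raises(self):
        rec = _two_term_records(100, 11)
        with pytest.raises(MissingCovariateError):
            fit_pirls(rec, [SmoothSpec("zz")], [(1.0, 1.0)])

    def test_non_binary_response_rejected(self):
        rec = _two_term_records(100, 12)
        rec.loc[rec.index[0], "response"] = 2
        with pytest.raises(Exception):
            fit_pirls(rec, [SmoothSpec("a")], [(1.0, 1.0)])

    def test_deviance_quantities_consistent(self):
        rec = _two_term_records(400, 13)
        fit = fit_pirls(rec, [SmoothSpec("a"), SmoothSpec("b")], [(1.0, 1.0), (1.0, 1.0)])
        assert 0 < fit.deviance < fit.null_deviance
        assert 0 < fit.deviance_explained < 1
        assert fit.ubre == pytest.approx(
            fit.deviance / fit.n_train + 2 * fit.edf_total / fit.n_train - 1.0
        )
        assert np.isfinite(fit.adjusted_r2)


class TestSelection:
    def test_informative_term_kept_and_signal_recovered(self):
        rec = logistic_records(500, 21, effect=lambda a: 2.5 * np.sin(2 * np.pi * a))
        fit = select_smoothing(rec, [SmoothSpec("a")])
        assert fit.edf["a"] > 1.5
        grid = np.linspace(0.05, 0.95, 41)
        curve = partial_effect(fit, "a", grid)
        truth = 2.5 * np.sin(2 * np.pi * grid)
        assert np.corrcoef(curve.estimate, truth - truth.mean())[0, 1] > 0.95

    def test_selected_ubre_beats_default_fit(self):
        rec = logistic_records(300, 22, effect=lambda a: 2.0 * (a - 0.5), noise=None)
        terms = [SmoothSpec("a"), SmoothSpec("noise")]
        sel = select_smoothing(rec, terms)
        base = fit_pirls(rec, terms, [(1.0, 1.0), (1.0, 1.0)])
        assert sel.ubre <= base.ubre + 1e-12

    def test_deterministic(self):
        rec = logistic_records(200, 23, effect=lambda a: 1.5 * (a - 0.5))
        f1 = select_smoothing(rec, [SmoothSpec("a")])
        f2 = select_smoothing(rec, [SmoothSpec("a")])
        assert np.array_equal(f1.coefficients, f2.coefficients)
        assert f1.smoothing_params == f2.smoothing_params

    def test_shrunk_terms_property(self):
        rec = _two_term_records(200, 24)
        fit = fit_pirls(rec, [SmoothSpec("a")], [(1e12, 1e12)])
        assert fit.edf["a"] < EDF_SHRUNK_TOLERANCE
        assert fit.shrunk_terms == ["a"]


class TestPredictionAndSerialization:
    def test_probabilities_in_unit_interval(self):
        rec = _two_term_records(300, 31)
        fit = select_smoothing(rec, [SmoothSpec("a"), SmoothSpec("b")])
        p = predict(fit, rec)
        assert p.shape == (len(rec),)
        assert p.min() >= 0 and p.max() <= 1

    def test_extrapolation_mask_reported(self):
        rec = _two_term_records(200, 32)
        fit = select_smoothing(rec, [SmoothSpec("a")])
        far = rec.copy()
        far["a"] = far["a"] + 10.0
        p, mask = predict(fit, far, return_extrapolation=True)
        assert mask.all()
        p2, mask2 = predict(fit, rec, return_extrapolation=True)
        assert not mask2.any()

    def test_missing_covariate_raises(self):
        rec = _two_term_records(150, 33)
        fit = select_smoothing(rec, [SmoothSpec("a")])
        with pytest.raises(MissingCovariateError):
            predict(fit, rec.drop(columns=["a"]))

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rec = _two_term_records(250, 34)
        fit = select_smoothing(rec, [SmoothSpec("a"), SmoothSpec("b")])
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = FittedGAM.from_json(path)
        grid = rec.copy()
        grid["a"] = np.linspace(-0.5, 1.5, len(rec))  # includes extrapolation
        assert np.allclose(predict(fit, grid), predict(back, grid), atol=1e-12)
        assert back.edf == pytest.approx(fit.edf)
        assert back.smoothing_params == fit.smoothing_params

    def test_partial_effect_band_and_errors(self):
        rec = _two_term_records(300, 35)
        fit = select_smoothing(rec, [SmoothSpec("a"), SmoothSpec("b")])
        grid = np.linspace(0, 1, 21)
        curve = partial_effect(fit, "a", grid)
        assert np.all(curve.lower <= curve.estimate)
        assert np.all(curve.estimate <= curve.upper)
        assert curve.edf == fit.edf["a"]
        with pytest.raises(MissingCovariateError):
            partial_effect(fit, "zz", grid)
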