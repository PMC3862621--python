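"""Polynomial basis, OLS and bisquare fitting, R², printed-equation fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermogerm.germdata import design_regimes
from thermogerm.surface import (
    PolynomialSurface,
    PolynomialSurfaceModel,
    build_basis,
    calibrate_orientation,
    fit_bisquare,
    fit_ols,
    load_printed_equations,
    n_coefficients,
    r_squared,
)
from conftest import matrix_from_surface


class TestBuildBasis:
    def test_origin_degree2(self):
        assert np.array_equal(build_basis(0.0, 0.0, 2), [1, 0, 0, 0, 0, 0])

    def test_quintic_has_21_terms(self):
        assert build_basis(12.0, 33.0, 5).shape == (21,)

    def test_all_ones_at_normalizer(self):
        assert np.allclose(build_basis(40.0, 40.0, 5, normalizer=40.0), 1.0)

    def test_unsupported_degree_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            build_basis(5.0, 10.0, 3)

    def test_canonical_term_order(self):
        # 1, T1, T2, T1^2, T1*T2, T2^2 at (T1, T2) = (2, 3)
        assert np.allclose(build_basis(2.0, 3.0, 2), [1, 2, 3, 4, 6, 9])


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.4, 0.9])
        assert r_squared(y, y) == 1.0

    def test_constant_mean_prediction(self):
        y = np.array([0.0, 0.5, 1.0])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_worked_example(self):
        # SSE = 0.02, SST = 0.5
        assert r_squared([0, 0.5, 1], [0.1, 0.5, 0.9]) == pytest.approx(0.96)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="sum of squares"):
            r_squared([0.5, 0.5], [0.4, 0.6])


class TestFitOLS:
    def test_exact_quadratic_recovered(self, bounded_quadratic_truth):
        coef, fn = bounded_quadratic_truth
        m = matrix_from_surface(fn)
        res = fit_ols(m, degree=2, normalizer=40.0)
        assert np.allclose(res.params, coef, atol=1e-8)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_quintic_recovery_within_3se(self):
        rng = np.random.default_rng(5)
        truth = rng.normal(0, 0.2, 21)
        model = PolynomialSurfaceModel(5, truth, normalizer=40.0)
        m = matrix_from_surface(
            lambda c, w: float(model.predict_unclamped(c, w)) * 0.05 + 0.5,
            noise_sd=0.01, seed=11,
        )
        res = fit_ols(m, degree=5, normalizer=40.0)
        assert np.all(np.abs(res.params - (truth * 0.05 + np.eye(21)[0] * 0.5))
                      <= 3.0 * res.bse + 1e-12)

    def test_quintic_nests_quadratic(self, matrices):
        for m in matrices.values():
            assert fit_ols(m, degree=5).rsquared >= fit_ols(m, degree=2).rsquared

    def test_rank_deficient_design_rejected(self):
        # all observations on one line in temperature space
        cool = np.full(40, 10.0)
        warm = np.linspace(10, 40, 40)
        y = np.linspace(0, 1, 40)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            PolynomialSurface(y, cool, warm, degree=2)

    def test_ols_beats_perturbed_coefficients(self, c_dactylon):
        res = fit_ols(c_dactylon, degree=2)
        rng = np.random.default_rng(0)
        cool, warm, frac = c_dactylon.arrays()
        X = build_basis(cool, warm, 2)
        for _ in range(25):
            other = res.params + rng.normal(0, 0.01, res.params.size)
            assert r_squared(frac, X @ other) <= res.rsquared + 1e-12


class TestFitBisquare:
    def test_matches_ols_on_clean_data(self, bounded_quadratic_truth):
        # on outlier-free (exactly polynomial) data the IRLS fixed point
        # coincides with OLS: all weights are ~1
        _, fn = bounded_quadratic_truth
        exact = matrix_from_surface(fn)
        assert np.allclose(fit_bisquare(exact, degree=2, normalizer=40.0).params,
                           fit_ols(exact, degree=2, normalizer=40.0).params,
                           atol=1e-6)

    def test_gross_outlier_downweighted(self, quadratic_truth):
        _, fn = quadratic_truth
        m = matrix_from_surface(fn, noise_sd=0.005, seed=2)
        # corrupt the coldest cell (model says ~0) to full germination
        r = design_regimes()[0]
        m.cells[r] = m.Cell(100.0, 0.0)
        ols = fit_ols(m, degree=2)
        robust = fit_bisquare(m, degree=2)
        idx = m.regimes.index(r)
        assert robust.weights[idx] < 0.01
        clean = matrix_from_surface(fn, noise_sd=0.005, seed=2)
        clean_params = fit_ols(clean, degree=2).params
        assert (np.abs(robust.params - clean_params).max()
                < np.abs(ols.params - clean_params).max())

    def test_huge_tuning_constant_reduces_to_ols(self, c_dactylon):
        ols = fit_ols(c_dactylon, degree=5)
        robust = fit_bisquare(c_dactylon, degree=5, tuning_c=1e6)
        assert np.allclose(robust.params, ols.params, atol=1e-8)

    def test_agrees_with_statsmodels_rlm(self, c_dactylon):
        # independent IRLS implementation with the same biweight and MAD scale
        import statsmodels.api as sm

        cool, warm, frac = c_dactylon.arrays()
        X = build_basis(cool, warm, 2)
        ref = sm.RLM(frac, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(
            scale_est="mad"
        )
        ours = fit_bisquare(c_dactylon, degree=2)
        assert np.allclose(ours.params, ref.params, atol=5e-3)

    def test_nonconvergence_flagged_not_raised(self, c_dactylon):
        res = fit_bisquare(c_dactylon, degree=5, max_iter=1)
        assert res.converged is False


class TestInvariants:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=10)
    def test_normalization_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        m = matrix_from_surface(lambda c, w: 0.5, noise_sd=0.2, seed=seed)
        res = fit_ols(m, degree=2, normalizer=40.0)
        # map normalized coefficients back to raw-temperature scale
        from thermogerm.surface import basis_exponents

        raw_coef = np.array([
            p / 40.0 ** (a + b)
            for p, (a, b) in zip(res.params, basis_exponents(2))
        ])
        raw = PolynomialSurfaceModel(2, raw_coef, normalizer=1.0)
        norm = res.surface
        pts = rng.uniform(5, 40, size=(20, 2))
        assert np.allclose(raw.predict_unclamped(pts[:, 0], pts[:, 1]),
                           norm.predict_unclamped(pts[:, 0], pts[:, 1]),
                           atol=1e-10)

    def test_orientation_symmetry(self):
        rng = np.random.default_rng(8)
        coef = rng.normal(0, 0.05, 6)
        a = PolynomialSurfaceModel(2, coef, orientation="cool_as_t1")
        # swapping orientation and each (a,b)->(b,a) coefficient pair
        swapped = coef[[0, 2, 1, 5, 4, 3]]
        b = PolynomialSurfaceModel(2, swapped, orientation="warm_as_t1")
        pts = rng.uniform(5, 40, size=(30, 2))
        assert np.allclose(a.predict_unclamped(pts[:, 0], pts[:, 1]),
                           b.predict_unclamped(pts[:, 0], pts[:, 1]))


class TestPrintedEquations:
    def test_nine_models_with_expected_sizes(self, printed_equations):
        assert len(printed_equations) == 9
        sizes = sorted(m.coefficients.size for m in printed_equations)
        assert sizes == [6, 6, 6] + [21] * 6

    def test_transcribed_coefficients(self, printed_equations):
        by_key = {(m.cultivar, m.backend): m for m in printed_equations}
        quad = by_key[("C. dactylon", "quadratic")]
        assert quad.coefficients[0] == -0.5856
        bisq = by_key[("Savannah", "quintic_bisquare")]
        assert bisq.coefficients[-1] == 7.051e-07

    def test_checksum_guard(self, tmp_path, printed_equations):
        import json
        from importlib.resources import files

        src = files("thermogerm.data") / "printed_equations.json"
        doc = json.loads(src.read_text())
        doc["models"][0]["coefficients"][0] = 0.0
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="checksum"):
            load_printed_equations(bad)

    def test_quadratic_prediction_at_maximum_regime(self, printed_equations):
        quad = next(m for m in printed_equations
                    if (m.cultivar, m.backend) == ("C. dactylon", "quadratic"))
        # calibrated orientation puts the warm temperature in the T1 slot
        assert quad.orientation == "warm_as_t1"
        val = float(quad.predict_unclamped(15.0, 35.0))
        assert val == pytest.approx(0.8628, abs=1e-3)

    def test_quadratic_negative_at_constant_5(self, printed_equations):
        quad = next(m for m in printed_equations
                    if (m.cultivar, m.backend) == ("C. dactylon", "quadratic"))
        assert float(quad.predict_unclamped(5.0, 5.0)) < 0.0
        assert float(quad.predict(5.0, 5.0)) == 0.0

    def test_all_zero_model_predicts_zero(self):
        m = PolynomialSurfaceModel(2, np.zeros(6))
        assert float(m.predict(17.0, 29.0)) == 0.0

    def test_calibration_recovers_stored_orientation(self, printed_equations,
                                                     matrices):
        for model in printed_equations:
            assert calibrate_orientation(model, matrices[model.cultivar]) \
                == model.orientation

    def test_model_json_round_trip(self, tmp_path, printed_equations):
        p = tmp_path / "m.json"
        printed_equations[0].save(p)
        back = PolynomialSurfaceModel.load(p)
        assert np.array_equal(back.coefficients, printed_equations[0].coefficients)
        assert back.orientation == printed_equations[0].orientation
        assert back.normalizer == printed_equations[0].normalizer


class TestSummary:
    def test_summary_mentions_fit_quality(self, c_dactylon):
        text = fit_ols(c_dactylon, degree=2).summary()
        assert "R²" in text and "ols" in text
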