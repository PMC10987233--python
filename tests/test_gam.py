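"""Spline bases, penalized fits, GCV behaviour and forward selection."""

import numpy as np
import pandas as pd
import pytest

from pondvarpart.gam import SmoothSpec, build_basis, fit_gam, forward_select


class TestBasis:
    def test_straight_line_has_zero_curvature_penalty(self, toy_predictors):
        tb = build_basis(toy_predictors, SmoothSpec(("x",)))
        # find the coefficient vector reproducing a centred straight line
        x = toy_predictors["x"].to_numpy()
        target = x - x.mean()
        coef, *_ = np.linalg.lstsq(tb.X, target, rcond=None)
        assert np.max(np.abs(tb.X @ coef - target)) < 1e-10  # representable
        assert coef @ tb.S @ coef < 1e-10

    def test_centring_constraint(self, toy_predictors):
        for spec in (SmoothSpec(("x",)), SmoothSpec(("cx", "cy"))):
            tb = build_basis(toy_predictors, spec)
            assert np.max(np.abs(tb.X.sum(axis=0))) < 1e-8

    def test_matches_cardinal_spline_interpolation(self):
        """Basis at the knots equals the textbook natural-spline construction:
        cardinal function i interpolates the indicator of knot i."""
        knots = np.array([0.0, 0.3, 0.5, 0.8, 1.0])
        x = np.linspace(0.0, 1.0, 41)
        from pondvarpart.gam import _natural_cubic
        from scipy.interpolate import CubicSpline

        X, _ = _natural_cubic(x, knots)
        for i in range(5):
            e = np.zeros(5)
            e[i] = 1.0
            cs = CubicSpline(knots, e, bc_type="natural")
            np.testing.assert_allclose(X[:, i], cs(x), atol=1e-10)

    def test_duplicate_values_reduce_k(self):
        pred = pd.DataFrame({"x": np.repeat([0.0, 1.0, 2.0, 3.0], 5)})
        with pytest.warns(UserWarning, match="k reduced"):
            tb = build_basis(pred, SmoothSpec(("x",), k=9))
        assert tb.X.shape[1] == 3  # 4 distinct values -> k=4 -> 3 centred cols

    def test_constant_covariate_rejected(self):
        pred = pd.DataFrame({"x": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            build_basis(pred, SmoothSpec(("x",)))


class TestFit:
    def test_exact_linear_truth(self, toy_predictors):
        y = 2.0 * toy_predictors["x"].to_numpy() - 1.0
        fit = fit_gam(y, [SmoothSpec(("x",))], toy_predictors)
        assert fit.r2_adj >= 0.999
        assert fit.edf[0] == pytest.approx(1.0, abs=0.05)

    def test_noise_r2_adj_unbiased_near_zero(self):
        vals = []
        for s in range(30):
            r = np.random.default_rng(s)
            pred = pd.DataFrame({"x": r.uniform(0, 1, 100)})
            y = r.standard_normal(100)
            vals.append(fit_gam(y, [SmoothSpec(("x",))], pred).r2_adj)
        assert abs(np.mean(vals)) < 0.05

    def test_fixed_lambda_matches_direct_solve(self):
        r = np.random.default_rng(3)
        pred = pd.DataFrame({"x": np.linspace(0, 1, 12)})
        y = np.sin(3 * pred["x"].to_numpy()) + 0.1 * r.standard_normal(12)
        fit = fit_gam(y, [SmoothSpec(("x",), k=6)], pred, lambdas=[1.0])
        tb = fit.bases[0]
        X = np.column_stack([np.ones(12), tb.X])
        S = np.zeros((X.shape[1], X.shape[1]))
        S[1:, 1:] = tb.S
        beta = np.linalg.solve(X.T @ X + 1.0 * S, X.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_infinite_lambda_is_nullspace_ols(self, toy_predictors):
        r = np.random.default_rng(5)
        y = r.standard_normal(len(toy_predictors))
        fit = fit_gam(y, [SmoothSpec(("x",))], toy_predictors, lambdas=[np.inf])
        x = toy_predictors["x"].to_numpy()
        X = np.column_stack([np.ones_like(x), x - x.mean()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.fitted, X @ beta, atol=1e-8)

    def test_fitted_reproduce_from_design_and_coefficients(self, toy_predictors):
        r = np.random.default_rng(6)
        y = np.sin(6 * toy_predictors["x"].to_numpy()) + 0.2 * r.standard_normal(60)
        fit = fit_gam(y, [SmoothSpec(("x",)), SmoothSpec(("cx", "cy"))], toy_predictors)
        np.testing.assert_allclose(fit.X @ fit.coefficients, fit.fitted, atol=1e-10)

    def test_unadjusted_r2_monotone_in_nested_terms(self, toy_predictors):
        r = np.random.default_rng(8)
        y = (
            np.sin(5 * toy_predictors["x"].to_numpy())
            + 0.5 * r.standard_normal(len(toy_predictors))
        )
        lam = 1.0
        f1 = fit_gam(y, [SmoothSpec(("x",))], toy_predictors, lambdas=[np.inf])
        f2 = fit_gam(
            y,
            [SmoothSpec(("x",)), SmoothSpec(("z",))],
            toy_predictors,
            lambdas=[np.inf, np.inf],
        )
        assert f2.r2 >= f1.r2 - 1e-12

    def test_sample_permutation_invariance(self, toy_predictors):
        r = np.random.default_rng(9)
        y = np.cos(4 * toy_predictors["x"].to_numpy()) + 0.3 * r.standard_normal(60)
        fit1 = fit_gam(y, [SmoothSpec(("x",))], toy_predictors)
        perm = r.permutation(60)
        fit2 = fit_gam(y[perm], [SmoothSpec(("x",))], toy_predictors.iloc[perm])
        assert fit1.r2_adj == pytest.approx(fit2.r2_adj, abs=1e-10)

    def test_edf_within_bounds(self, toy_predictors):
        r = np.random.default_rng(10)
        y = np.sin(8 * toy_predictors["x"].to_numpy()) + 0.1 * r.standard_normal(60)
        fit = fit_gam(y, [SmoothSpec(("x",), k=9)], toy_predictors)
        assert 0.0 <= fit.edf[0] <= 8.0 + 1e-8
        assert fit.r2_adj <= fit.r2 + 1e-12

    def test_intercept_only_model(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_gam(y, [], pd.DataFrame(index=range(4)))
        assert fit.r2_adj == 0.0
        np.testing.assert_allclose(fit.fitted, 2.5)


class TestForwardSelect:
    def _signal_data(self):
        r = np.random.default_rng(21)
        n = 80
        pred = pd.DataFrame(
            {
                "A": r.uniform(0, 1, n),
                "B": r.uniform(0, 1, n),
                "C": r.uniform(0, 1, n),
            }
        )
        y = np.sin(2 * np.pi * pred["A"].to_numpy()) + 0.15 * r.standard_normal(n)
        return y, pred

    def test_selects_only_true_predictor(self):
        y, pred = self._signal_data()
        cands = [SmoothSpec(("A",)), SmoothSpec(("B",)), SmoothSpec(("C",))]
        sel = forward_select(y, cands, pred)
        assert [s.label for s in sel.selected] == ["s(A)"]

    def test_alpha_zero_selects_nothing(self):
        y, pred = self._signal_data()
        cands = [SmoothSpec(("A",)), SmoothSpec(("B",))]
        sel = forward_select(y, cands, pred, alpha=0.0)
        assert sel.selected == []
        assert not sel.fallback_used

    def test_max_terms_cap(self):
        r = np.random.default_rng(22)
        n = 80
        pred = pd.DataFrame({"A": r.uniform(0, 1, n), "B": r.uniform(0, 1, n)})
        y = (
            np.sin(2 * np.pi * pred["A"].to_numpy())
            + np.cos(2 * np.pi * pred["B"].to_numpy())
            + 0.1 * r.standard_normal(n)
        )
        sel = forward_select(
            y, [SmoothSpec(("A",)), SmoothSpec(("B",))], pred, max_terms=1
        )
        assert len(sel.selected) == 1

    def test_selection_is_logged(self):
        y, pred = self._signal_data()
        sel = forward_select(y, [SmoothSpec(("A",)), SmoothSpec(("B",))], pred)
        events = {e["event"] for e in sel.log}
        assert "step" in events and "stop" in events
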