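"""GAM engine: bases, tensor products, penalized fitting, scores,
prediction, surfaces."""

import numpy as np
import pandas as pd
import pytest

import paleoniche as pn
from paleoniche.gam import basis as B
from paleoniche.gam import fit as F


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


class TestUnivariateBasis:
    def test_column_counts(self):
        data = {"x": np.linspace(0, 1, 100)}
        block = B.build_basis(data, B.SmoothSpec(("x",), (10,)))
        assert block.ncol_unconstrained == 10
        assert block.ncol == 9  # sum-to-zero removes one dimension

    def test_penalty_null_space_contains_linear(self):
        """A linear function's coefficient vector has zero penalty."""
        x = np.linspace(0, 1, 50)
        block = B.build_basis({"x": x}, B.SmoothSpec(("x",), (6,)))
        knots = block.margins[0].knots
        coef = 2.0 + 3.0 * B.greville(knots, block.margins[0].degree)  # f(x)=2+3x
        S_unc = B._difference_penalty(6, 2)
        assert coef @ S_unc @ coef == pytest.approx(0.0, abs=1e-20)
        # and it reproduces the function exactly
        X = block.margins[0].design(x)
        np.testing.assert_allclose(X @ coef, 2.0 + 3.0 * x, atol=1e-10)

    def test_reevaluation_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 7, 80)
        block = B.build_basis({"x": x}, B.SmoothSpec(("x",), (8,)))
        np.testing.assert_array_equal(block.design({"x": x}), block.design({"x": x.copy()}))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            B.build_basis({"x": np.ones(30)}, B.SmoothSpec(("x",), (5,)))

    def test_few_distinct_values_reduces_k(self):
        x = np.tile([0.0, 1.0, 2.0, 3.0], 10)
        with pytest.warns(UserWarning, match="reducing k"):
            block = B.build_basis({"x": x}, B.SmoothSpec(("x",), (9,)))
        assert block.ncol_unconstrained == 4

    def test_penalty_matrices_symmetric_psd(self):
        x = np.linspace(0, 1, 60)
        block = B.build_basis({"x": x}, B.SmoothSpec(("x",), (12,)))
        for S in block.penalties:
            np.testing.assert_allclose(S, S.T, atol=1e-12)
            assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_constrained_block_orthogonal_to_intercept(self):
        x = np.linspace(0, 5, 77)
        block = B.build_basis({"x": x}, B.SmoothSpec(("x",), (7,)))
        cols = block.design({"x": x})
        np.testing.assert_allclose(cols.sum(axis=0), 0.0, atol=1e-8)


class TestTensorBasis:
    def _tensor(self, k1=5, k2=4, n=200, seed=1):
        rng = np.random.default_rng(seed)
        data = {"x": rng.uniform(0, 1, n), "time": rng.uniform(8000, 46000, n)}
        return data, B.build_tensor(data, B.SmoothSpec(("x", "time"), (k1, k2)))

    def test_column_arithmetic(self):
        data, block = self._tensor(5, 4)
        # 5 x 4 = 20 raw product columns before constraints
        raw = (
            block.margins[0].design(data["x"])[:, :, None]
            * block.margins[1].design(data["time"])[:, None, :]
        ).reshape(len(data["x"]), -1)
        assert raw.shape[1] == 20
        # centering the env margin and the overall sum-to-zero leave 15
        assert block.ncol_unconstrained == 16
        assert block.ncol == 15

    def test_two_penalties_one_per_margin(self):
        _, block = self._tensor()
        assert len(block.penalties) == 2
        for S in block.penalties:
            np.testing.assert_allclose(S, S.T, atol=1e-12)
            assert np.linalg.eigvalsh(S).min() > -1e-9

    def test_constant_along_time_unpenalized_by_time_margin(self):
        """Coefficient fields constant along the time margin (environment
        main effects) cost nothing under the time penalty, so the tensor
        can shrink back to a constant-niche term for free."""
        rng = np.random.default_rng(3)
        _, block = self._tensor()
        k1c = block.Z1.shape[1]
        k2 = block.margins[1].k
        b = rng.standard_normal(k1c)
        beta_unc = np.kron(b, np.ones(k2))  # constant along time margin
        # env-main-effect functions have zero training mean, so they live
        # exactly in the constrained space
        np.testing.assert_allclose(block.Z @ (block.Z.T @ beta_unc), beta_unc, atol=1e-10)
        z = block.Z.T @ beta_unc
        assert z @ block.penalties[1] @ z == pytest.approx(0.0, abs=1e-12)

    def test_pure_time_function_not_in_span(self):
        """The tensor span contains no pure function of time (it is
        unidentifiable under time-matched background sampling)."""
        data, block = self._tensor(n=300)
        D = block.design(data)
        t = np.asarray(data["time"])
        target = t - t.mean()
        coef, res, *_ = np.linalg.lstsq(D, target, rcond=None)
        resid = target - D @ coef
        assert np.linalg.norm(resid) / np.linalg.norm(target) > 0.05

    def test_constant_margin_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            B.build_tensor(
                pd.DataFrame({"x": [0.0] * 10, "time": np.linspace(0, 1, 10)}),
                B.SmoothSpec(("x", "time"), (4, 4)),
            )

    def test_no_time_effect_truth_gives_flat_time_profile(self):
        """Tensor fit on data with no time effect: the fitted effect is
        nearly constant along time."""
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.uniform(-2, 2, n)
        t = rng.uniform(8000, 46000, n)
        p = _sigmoid(-1 + x - 0.8 * x**2)
        y = (rng.random(n) < p).astype(float)
        data = pd.DataFrame({"response": y, "x": x, "time": t})
        formula = F.ModelFormula(
            kind=F.CHANGING_NICHE, smooths=[B.SmoothSpec(("x", "time"), (8, 4))]
        )
        fit = F.fit_gam(data, formula)
        grid_t = np.linspace(9000, 45000, 7)
        grid_x = np.linspace(-1.5, 1.5, 9)
        tt, xx = np.meshgrid(grid_t, grid_x)
        eff = fit.term_effect("te(x,time)", pd.DataFrame({"x": xx.ravel(), "time": tt.ravel()}))
        eff = eff.reshape(xx.shape)
        time_span = np.ptp(eff, axis=1).max()
        x_span = np.ptp(eff.mean(axis=1))
        assert time_span < 0.35 * x_span


class TestFitGam:
    def test_linear_basis_matches_irls_glm_oracle(self):
        """Linear-basis GAM equals an independent IRLS logistic fit."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        n = 5000
        x1, x2 = rng.standard_normal(n), rng.uniform(-1, 2, n)
        p = _sigmoid(0.5 - 1.2 * x1 + 0.7 * x2)
        y = (rng.random(n) < p).astype(float)
        data = pd.DataFrame({"response": y, "x1": x1, "x2": x2})
        formula = F.ModelFormula(
            kind=F.CONSTANT_NICHE,
            smooths=[
                B.SmoothSpec(("x1",), (2,), basis="linear"),
                B.SmoothSpec(("x2",), (2,), basis="linear"),
            ],
        )
        fit = F.fit_gam(data, formula)
        glm = sm.GLM(y, np.column_stack([np.ones(n), x1, x2]), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.predict(data), glm.fittedvalues, atol=1e-6)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)
        assert fit.edf_total == pytest.approx(3.0, abs=1e-6)

    def test_null_truth_explains_nothing(self):
        rng = np.random.default_rng(11)
        n = 5000
        data = pd.DataFrame(
            {"response": (rng.random(n) < 0.3).astype(float), "x": rng.standard_normal(n)}
        )
        fit = F.fit_gam(
            data, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (10,))])
        )
        assert fit.dev_explained < 0.02

    def test_quadratic_logit_recovery(self, quadratic_logit_data):
        d = quadratic_logit_data
        fit = F.fit_gam(d, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO5",), (10,))]))
        eta_fit = np.log(fit.predict(d) / (1 - fit.predict(d)))
        assert np.corrcoef(d.eta_true, eta_fit)[0, 1] >= 0.99

    def test_lambda_infinity_approaches_glm_null_space(self):
        """Huge fixed lambda collapses the smooth onto its penalty null
        space: the fit matches plain linear-logistic regression."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(13)
        n = 3000
        x = rng.uniform(0, 4, n)
        y = (rng.random(n) < _sigmoid(-0.5 + 0.8 * x)).astype(float)
        data = pd.DataFrame({"response": y, "x": x})
        fit = F.fit_gam(
            data,
            F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (10,))]),
            lambdas=[1e10],
            gamma=1.0,
        )
        glm = sm.GLM(y, np.column_stack([np.ones(n), x]), family=sm.families.Binomial()).fit()
        eta_glm = np.column_stack([np.ones(n), x]) @ glm.params
        np.testing.assert_allclose(fit.linear_predictor(data), eta_glm, atol=1e-4)

    def test_both_classes_required(self):
        data = pd.DataFrame({"response": np.ones(50), "x": np.linspace(0, 1, 50)})
        with pytest.raises(ValueError, match="both classes"):
            F.fit_gam(data, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (5,))]))

    def test_scores_on_hand_dataset(self):
        """Six-row linear-basis fit: every score equals the closed-form /
        oracle value."""
        sm = pytest.importorskip("statsmodels.api")
        data = pd.DataFrame(
            {"response": [1, 0, 1, 0, 1, 0.0], "x": [2.0, 1.0, 3.0, 2.6, 2.5, 1.5]}
        )
        fit = F.fit_gam(
            data,
            F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (2,), basis="linear")]),
        )
        glm = sm.GLM(
            data.response, np.column_stack([np.ones(6), data.x]), family=sm.families.Binomial()
        ).fit()
        n, ll1, ll0 = 6, glm.llf, 6 * np.log(0.5)
        assert fit.loglik == pytest.approx(ll1, abs=1e-6)
        assert fit.aic == pytest.approx(-2 * ll1 + 2 * 2, abs=1e-5)
        assert fit.dev_explained == pytest.approx(1 - ll1 / ll0, abs=1e-6)
        nag = (1 - np.exp(2 / n * (ll0 - ll1))) / (1 - np.exp(2 / n * ll0))
        assert fit.nagelkerke == pytest.approx(nag, abs=1e-6)

    def test_separable_data_nagelkerke_near_one(self):
        x = np.concatenate([np.linspace(0, 1, 30), np.linspace(3, 4, 30)])
        y = np.concatenate([np.zeros(30), np.ones(30)])
        data = pd.DataFrame({"response": y, "x": x})
        with pytest.warns(UserWarning, match="separation"):
            fit = F.fit_gam(
                data,
                F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (2,), basis="linear")]),
            )
        assert fit.nagelkerke >= 0.99
        assert fit.separated

    def test_aic_identity_and_deviance_ordering(self, model_table):
        fit = F.fit_gam(
            model_table,
            F.make_formula(F.CONSTANT_NICHE, ["BIO5", "BIO6"], k={"BIO5": 6, "BIO6": 6}),
        )
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.edf_aic, rel=1e-12)
        # corrected df exceed tr(A) for penalized fits, match it unpenalized
        assert fit.edf_aic >= fit.edf_total - 1e-8
        assert fit.deviance <= fit.null_deviance
        for label, edf in fit.edf_per_term.items():
            block = next(b for b in fit.blocks if b.label == label)
            assert edf <= block.ncol + 1e-8

    def test_nested_deviance_unpenalized(self):
        """With no penalty, the tensor model nests the univariate one, so
        its residual deviance cannot be larger."""
        rng = np.random.default_rng(17)
        n = 2500
        x = rng.uniform(-2, 2, n)
        t = rng.uniform(8000, 46000, n)
        y = (rng.random(n) < _sigmoid(x - x**2)).astype(float)
        data = pd.DataFrame({"response": y, "x": x, "time": t})
        fc = F.fit_gam(
            data,
            F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (6,))]),
            lambdas=[0.0],
        )
        fg = F.fit_gam(
            data,
            F.ModelFormula(F.CHANGING_NICHE, [B.SmoothSpec(("x", "time"), (6, 4))]),
            lambdas=[0.0, 0.0],
        )
        assert fg.deviance <= fc.deviance + 1e-6

    def test_row_permutation_leaves_scores_unchanged(self):
        rng = np.random.default_rng(19)
        n = 2000
        x = rng.uniform(-2, 2, n)
        y = (rng.random(n) < _sigmoid(0.5 * x)).astype(float)
        data = pd.DataFrame({"response": y, "x": x})
        formula = F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (8,))])
        fit_a = F.fit_gam(data, formula, lambdas=[1.0])
        fit_b = F.fit_gam(data.sample(frac=1.0, random_state=3), formula, lambdas=[1.0])
        assert fit_a.aic == pytest.approx(fit_b.aic, abs=1e-8)
        assert fit_a.loglik == pytest.approx(fit_b.loglik, abs=1e-8)

    def test_alternative_criteria_run(self, quadratic_logit_data):
        d = quadratic_logit_data.iloc[:1500]
        for crit in ("aicc", "gcv"):
            fit = F.fit_gam(
                d,
                F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO5",), (8,))]),
                criterion=crit,
            )
            assert np.isfinite(fit.aic) and 0 < fit.edf_total < 8


class TestPrediction:
    def test_training_rows_return_fitted_values(self, quadratic_logit_data):
        d = quadratic_logit_data
        fit = F.fit_gam(d, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO5",), (8,))]))
        np.testing.assert_allclose(fit.predict(d), fit.mu, atol=1e-12)

    def test_uninformative_model_predicts_prevalence(self):
        rng = np.random.default_rng(23)
        n = 4000
        y = (rng.random(n) < 1 / 51).astype(float)
        data = pd.DataFrame({"response": y, "x": rng.standard_normal(n)})
        fit = F.fit_gam(
            data, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (8,))])
        )
        prev = y.mean()
        assert np.allclose(fit.predict(data), prev, atol=0.01)

    def test_monotone_truth_monotone_predictions(self):
        rng = np.random.default_rng(29)
        n = 4000
        x = rng.uniform(0, 10, n)
        y = (rng.random(n) < _sigmoid(-2 + 0.6 * x)).astype(float)
        data = pd.DataFrame({"response": y, "x": x})
        fit = F.fit_gam(data, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (8,))]))
        grid = pd.DataFrame({"x": np.linspace(0.5, 9.5, 50)})
        pred = fit.predict(grid)
        assert np.all(np.diff(pred) > -1e-6)

    def test_extrapolation_flagged(self, quadratic_logit_data):
        d = quadratic_logit_data
        fit = F.fit_gam(d, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO5",), (8,))]))
        probe = pd.DataFrame({"BIO5": [0.0, 5.0, -5.0]})  # training range ~[-2, 2]
        prob, flags = fit.predict(probe, return_flags=True)
        assert list(flags) == [False, True, True]
        assert np.all((prob > 0) & (prob < 1))

    def test_missing_variable_errors(self, quadratic_logit_data):
        d = quadratic_logit_data
        fit = F.fit_gam(d, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO5",), (8,))]))
        with pytest.raises(KeyError):
            fit.predict(pd.DataFrame({"BIO6": [0.0]}))


class TestBasisDimensionCheck:
    def test_smooth_truth_passes(self, quadratic_logit_data):
        fit = F.fit_gam(
            quadratic_logit_data,
            F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO5",), (10,))]),
        )
        report = F.check_basis_dimension(fit)
        assert not report.flagged.any()

    def test_saturated_smooth_flagged_then_cleared(self):
        rng = np.random.default_rng(31)
        n = 6000
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < _sigmoid(2.5 * np.sin(6 * np.pi * x))).astype(float)
        data = pd.DataFrame({"response": y, "BIO6": x})
        small = F.fit_gam(
            data, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO6",), (4,))]),
            lambdas=[1e-4], gamma=1.0,
        )
        report = F.check_basis_dimension(small)
        assert report.flagged.iloc[0]
        assert report.suggested_k.iloc[0] == 8
        big = F.fit_gam(
            data, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO6",), (16,))])
        )
        assert not F.check_basis_dimension(big).flagged.any()


class TestSmoothSurface:
    def test_constant_model_surface_flat_in_time(self, model_table):
        fit = F.fit_gam(
            model_table,
            F.make_formula(F.CONSTANT_NICHE, ["BIO6"], k={"BIO6": 8}),
        )
        surf = pn.smooth_surface([fit], "BIO6", times=np.array([10_000.0, 30_000.0, 45_000.0]))
        np.testing.assert_allclose(surf.effect[:, 0], surf.effect[:, 1], atol=1e-12)
        np.testing.assert_allclose(surf.effect[:, 0], surf.effect[:, 2], atol=1e-12)

    def test_single_fit_mean_is_identity(self, model_table):
        formula = F.make_formula(F.CHANGING_NICHE, ["BIO6"], k={"BIO6": 8}, k_time=4)
        fit = F.fit_gam(model_table, formula)
        s1 = pn.smooth_surface([fit], "BIO6")
        s2 = pn.smooth_surface([fit, fit], "BIO6")
        np.testing.assert_allclose(s1.effect, s2.effect, atol=1e-12)

    def test_unknown_variable_errors(self, model_table):
        fit = F.fit_gam(model_table, F.make_formula(F.CONSTANT_NICHE, ["BIO6"], k={"BIO6": 6}))
        with pytest.raises(KeyError, match="BIO12"):
            pn.smooth_surface([fit], "BIO12")


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, quadratic_logit_data):
        d = quadratic_logit_data.iloc[:2000]
        fit = F.fit_gam(d, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO5",), (8,))]))
        back = F.FittedGAM.from_dict(fit.to_dict())
        probe = pd.DataFrame({"BIO5": np.linspace(-1.8, 1.8, 40)})
        np.testing.assert_allclose(back.predict(probe), fit.predict(probe), atol=1e-12)
        assert back.aic == pytest.approx(fit.aic)
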