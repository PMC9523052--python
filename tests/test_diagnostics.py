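"""Correlation screen, concurvity, quantile-residual checks, Moran's I."""

import numpy as np
import pandas as pd
import pytest

import paleoniche as pn
from paleoniche.diagnostics import (
    correlation_screen,
    moran_weights,
    morans_i,
    residual_checks,
)
from paleoniche.gam import fit as F
from paleoniche.gam import basis as B


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


class TestCorrelationScreen:
    def test_identical_variables_fail(self):
        x = np.linspace(0, 1, 100)
        corr, ok = correlation_screen(pd.DataFrame({"a": x, "b": x}))
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert not ok

    def test_independent_variables_pass(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((10_000, 4)), columns=list("abcd"))
        corr, ok = correlation_screen(df)
        off = corr.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1
        assert ok

    def test_hand_computed_r(self):
        """Four-point table against the explicit Pearson formula."""
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 6.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        corr, _ = correlation_screen(pd.DataFrame({"x": x, "y": y}), threshold=0.99)
        assert corr.loc["x", "y"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            correlation_screen(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}))

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="3 rows"):
            correlation_screen(pd.DataFrame({"a": [1.0], "b": [2.0]}))

    def test_collinear_scenario_fails_screen(self):
        cube = pn.generate_climate_cube(pn.collinear_scenario(seed=1))
        env = pd.concat([cube.env_at(a) for a in cube.ages])
        _, ok = correlation_screen(env[list(pn.VARIABLES)])
        assert not ok

    def test_default_scenario_passes_screen(self, default_run):
        _, cube, _, _ = default_run
        env = pd.concat([cube.env_at(a) for a in cube.ages])
        _, ok = correlation_screen(env[list(pn.VARIABLES)])
        assert ok


class TestConcurvity:
    def _fit(self, data, *specs):
        return F.fit_gam(data, F.ModelFormula(F.CONSTANT_NICHE, list(specs)))

    def test_duplicated_variable_near_one(self):
        rng = np.random.default_rng(1)
        n = 1500
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < _sigmoid(np.sin(2 * np.pi * x))).astype(float)
        data = pd.DataFrame({"response": y, "x1": x, "x2": x + 1e-9 * rng.standard_normal(n)})
        fit = self._fit(data, B.SmoothSpec(("x1",), (6,)), B.SmoothSpec(("x2",), (6,)))
        conc = pn.concurvity(fit)
        assert conc.min() > 0.95

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(2)
        n = 4000
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y = (rng.random(n) < _sigmoid(np.sin(2 * np.pi * x1) + x2)).astype(float)
        data = pd.DataFrame({"response": y, "x1": x1, "x2": x2})
        fit = self._fit(data, B.SmoothSpec(("x1",), (6,)), B.SmoothSpec(("x2",), (6,)))
        assert pn.concurvity(fit).max() < 0.2

    def test_matches_projection_oracle(self, model_table):
        fit = F.fit_gam(
            model_table,
            F.make_formula(F.CONSTANT_NICHE, ["BIO5", "BIO6"], k={"BIO5": 6, "BIO6": 6}),
        )
        conc = pn.concurvity(fit)
        # oracle: QR-based least-squares projection R^2
        for block, sl in zip(fit.blocks, fit.slices):
            f = fit.X[:, sl] @ fit.beta[sl]
            others = np.concatenate(
                [np.ones((len(f), 1))]
                + [fit.X[:, s2] for b2, s2 in zip(fit.blocks, fit.slices) if b2 is not block],
                axis=1,
            )
            q, _ = np.linalg.qr(others)
            proj = q @ (q.T @ f)
            r2 = (proj @ proj) / (f @ f)
            assert conc[block.label] == pytest.approx(r2, abs=1e-8)

    def test_single_term_empty(self, quadratic_logit_data):
        fit = F.fit_gam(
            quadratic_logit_data,
            F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("BIO5",), (6,))]),
        )
        assert len(pn.concurvity(fit)) == 0

    def test_invariant_to_rescaling(self):
        rng = np.random.default_rng(3)
        n = 2000
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y = (rng.random(n) < _sigmoid(x1 - x2)).astype(float)
        d1 = pd.DataFrame({"response": y, "x1": x1, "x2": x2})
        d2 = pd.DataFrame({"response": y, "x1": 100 * x1 - 7, "x2": 0.01 * x2 + 3})
        f1 = self._fit(d1, B.SmoothSpec(("x1",), (6,)), B.SmoothSpec(("x2",), (6,)))
        f2 = self._fit(d2, B.SmoothSpec(("x1",), (6,)), B.SmoothSpec(("x2",), (6,)))
        c1, c2 = pn.concurvity(f1), pn.concurvity(f2)
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=0.02)


class TestResidualChecks:
    def _well_specified_fit(self, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-2, 2, n)
        y = (rng.random(n) < _sigmoid(-1 + x)).astype(float)
        data = pd.DataFrame({"response": y, "x": x})
        return F.fit_gam(data, F.ModelFormula(F.CONSTANT_NICHE, [B.SmoothSpec(("x",), (6,))]))

    def test_well_specified_model_passes(self):
        fit = self._well_specified_fit()
        res = residual_checks(fit, n_sim=250, seed=1)
        assert res.uniformity_p > 0.01
        assert res.dispersion_p > 0.01
        assert res.outlier_p > 0.01
        assert res.dispersion_ratio == pytest.approx(1.0, abs=0.15)

    def test_residuals_in_unit_interval(self):
        res = residual_checks(self._well_specified_fit(seed=5), n_sim=100, seed=2)
        assert np.all((res.residuals >= 0) & (res.residuals <= 1))

    def test_overconfident_model_rejected(self):
        """A model that is sure of its predictions (mu near 0/1) while the
        data are coin flips: residuals are overdispersed and outliers
        abound — both tests must reject."""
        from types import SimpleNamespace

        rng = np.random.default_rng(7)
        n = 2000
        mu = np.where(np.arange(n) % 2 == 0, 0.002, 0.998)
        y = (rng.random(n) < 0.5).astype(float)
        sham = SimpleNamespace(mu=mu, y=y)
        res = residual_checks(sham, n_sim=250, seed=3)
        assert res.dispersion_p < 0.01
        assert res.dispersion_ratio > 1.5
        assert res.outlier_p < 0.01
        assert res.uniformity_p < 0.01

    def test_zero_simulations_rejected(self):
        with pytest.raises(ValueError, match="n_sim"):
            residual_checks(self._well_specified_fit(), n_sim=0)


class TestMoransI:
    def _fixture(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return (
            rng.uniform(0, 10, n),  # lon
            rng.uniform(40, 50, n),  # lat
            rng.standard_normal(n),  # residuals
        )

    def test_matches_direct_formula(self):
        """Small fixture equals the textbook double-sum evaluation."""
        lon, lat, x = self._fixture()
        W = moran_weights(lon, lat)
        n = len(x)
        xc = x - x.mean()
        num = sum(W[i, j] * xc[i] * xc[j] for i in range(n) for j in range(n))
        oracle = n / W.sum() * num / (xc @ xc)
        res = morans_i(x, lon, lat, n_perm=19, seed=0)
        assert res.estimate == pytest.approx(oracle, abs=1e-12)

    def test_null_expectation(self):
        lon, lat, x = self._fixture(n=60, seed=3)
        res = morans_i(x, lon, lat, n_perm=2000, seed=1)
        se = res.perm_values.std() / np.sqrt(len(res.perm_values))
        assert abs(res.perm_values.mean() - (-1 / 59)) < 3 * se

    def test_spatial_gradient_detected(self):
        rng = np.random.default_rng(4)
        n = 80
        lon = rng.uniform(0, 10, n)
        lat = rng.uniform(40, 50, n)
        x = lon + 0.05 * rng.standard_normal(n)  # smooth spatial signal
        res = morans_i(x, lon, lat, n_perm=999, seed=2)
        assert res.estimate > 0
        assert res.p_value <= 0.002

    def test_cross_slice_pairs_get_zero_weight(self):
        lon = np.array([0.0, 0.1, 5.0, 5.1])
        lat = np.array([45.0, 45.0, 45.0, 45.0])
        W = moran_weights(lon, lat, slices=[1, 2, 1, 2])
        assert W[0, 1] == 0 and W[0, 2] > 0

    def test_identical_locations_rejected(self):
        with pytest.raises(ValueError, match="same location"):
            morans_i(np.random.default_rng(0).standard_normal(12),
                     np.full(12, 1.0), np.full(12, 45.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10 points"):
            morans_i([1.0] * 5, [0, 1, 2, 3, 4], [45] * 5)


class TestDiagnoseFit:
    def test_bundled_report(self, model_table):
        fit = F.fit_gam(
            model_table,
            F.make_formula(F.CONSTANT_NICHE, ["BIO5", "BIO6"], k={"BIO5": 6, "BIO6": 6}),
        )
        report = pn.diagnose_fit(
            fit, model_table[list(pn.VARIABLES)], n_sim=150, moran_sample=60, seed=0
        )
        d = report.to_dict()
        assert d["correlation_ok"]
        assert set(report.concurvity.index) == {"s(BIO5)", "s(BIO6)", "s(time)"}
        assert 0 < d["residuals"]["uniformity_p"] <= 1
        assert "estimate" in d["moran"]
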