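"""EBLUP random-effect prediction and calibrated DBH prediction."""

import numpy as np
import pytest
from scipy.optimize import minimize

import allomix as am
from allomix.calibration import random_effect_jacobian
from allomix.forms import mean_function


def _records(genotype, lh, lcd, p1, dbh):
    return am.Dataset.from_records([
        am.TreeRecord(genotype, int(p), lh=float(a), lcd=float(b), dbh=float(y))
        for a, b, p, y in zip(lh, lcd, p1, dbh)])


class TestJacobian:
    def test_unit_height_gives_zero_row(self, preset_fit):
        Z = random_effect_jacobian(preset_fit, lh=[1.0], lcd=[1.0], p1=[1])
        np.testing.assert_allclose(Z, 0.0, atol=1e-12)

    def test_low_density_gates_dummy_column(self, preset_fit):
        Z = random_effect_jacobian(preset_fit, lh=[3.0], lcd=[1.5], p1=[0])
        assert Z[0, 0] != 0.0
        assert Z[0, 1] == 0.0

    def test_published_model_analytic_row(self, preset_fit):
        # f * ln(2) * (1, 1) at lh=2, lcd=1, p1=1, u=0
        f = 0.8403 * 2 ** (1.1829 - 0.1427)
        Z = random_effect_jacobian(preset_fit, lh=[2.0], lcd=[1.0], p1=[1])
        np.testing.assert_allclose(Z[0], f * np.log(2.0) * np.ones(2), rtol=1e-12)
        assert f == pytest.approx(1.7278, abs=5e-4)

    def test_matches_central_finite_differences(self, preset_fit):
        rng = np.random.default_rng(2)
        lh = rng.uniform(1.5, 8.0, 10)
        lcd = rng.uniform(0.2, 4.0, 10)
        p1 = rng.integers(0, 2, 10).astype(float)
        u = np.array([0.05, -0.03])
        Z = random_effect_jacobian(preset_fit, lh, lcd, p1, u=u)
        t_ix = preset_fit.re_config.indices(preset_fit.form)
        eps = 1e-6
        for k in range(2):
            up, dn = u.copy(), u.copy()
            up[k] += eps
            dn[k] -= eps
            thu, thd = preset_fit.fixed_effects.copy(), preset_fit.fixed_effects.copy()
            thu[t_ix] += up
            thd[t_ix] += dn
            fd = (mean_function(preset_fit.form, thu, lh, lcd, p1)
                  - mean_function(preset_fit.form, thd, lh, lcd, p1)) / (2 * eps)
            np.testing.assert_allclose(Z[:, k], fd, rtol=1e-5, atol=1e-8)

    def test_nonpositive_height_rejected(self, preset_fit):
        with pytest.raises(am.ValidationError):
            random_effect_jacobian(preset_fit, lh=[0.0], lcd=[1.0], p1=[0])


def _penalized_objective(fit, ds, u):
    """Joint penalized least-squares criterion the EBLUP fixed point solves."""
    frame = ds.frame
    lh = frame["lh"].to_numpy()
    lcd = frame["lcd"].to_numpy()
    p1 = frame["p1"].to_numpy(dtype=float)
    y = frame["dbh"].to_numpy()
    theta = fit.fixed_effects.copy()
    theta[fit.re_config.indices(fit.form)] += u
    f = mean_function(fit.form, theta, lh, lcd, p1)
    x = lh if fit.variance.covariate == "lh" else lcd
    r = am.variance_weights(fit.variance, x)
    pen = u @ np.linalg.solve(fit.psi, u)
    return float(np.sum((y - f) ** 2 / r) + pen)


class TestEblup:
    def test_empty_calibration_set_gives_zero(self, preset_fit):
        res = am.eblup(preset_fit, {"G9": am.Dataset.from_records([])})
        np.testing.assert_array_equal(res.u_hat["G9"], 0.0)

    def test_zero_psi_shrinks_to_zero(self, preset_fit):
        flat = am.GenotypeMixedResults(
            form=preset_fit.form, params=preset_fit.params,
            re_config=preset_fit.re_config, psi=np.zeros((2, 2)),
            variance=preset_fit.variance, ranef={}, llf=0.0, nobs=10)
        ds = _records("A", [3.0, 4.0], [1.5, 2.0], [1, 0], [5.0, 6.0])
        res = am.eblup(flat, ds)
        np.testing.assert_array_equal(res.u_hat["A"], 0.0)

    def test_scalar_closed_form_single_tree(self, preset_fit):
        # q = 1 toy: u_hat = psi*Z*(R + Z^2 psi)^{-1} * e at the fixed point
        fit = am.GenotypeMixedResults(
            form=am.ModelForm("power"), params=am.ModelParams(a1=1.2, b1=1.1, c1=0.3),
            re_config=am.RandomEffectConfig(targets=("b1",)),
            psi=np.array([[0.04]]),
            variance=am.VarianceSpec(kind="constant", sigma=0.5),
            ranef={}, llf=0.0, nobs=10)
        ds = _records("A", [3.0], [1.5], [0], [6.0])
        res = am.eblup(fit, ds, tol=1e-12)
        u = res.u_hat["A"][0]
        theta = np.array([1.2, 1.1 + u, 0.3])
        f = mean_function(fit.form, theta, [3.0], [1.5], [0.0])[0]
        Z = f * np.log(3.0)
        fixed_point = 0.04 * Z / (0.25 + Z**2 * 0.04) * (6.0 - f + Z * u)
        assert u == pytest.approx(fixed_point, abs=1e-9)
        # and it is the minimizer of the joint penalized objective
        opt = minimize(lambda v: _penalized_objective(fit, ds, v), [0.0],
                       method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        assert u == pytest.approx(opt.x[0], abs=1e-4)

    def test_matches_joint_optimum_on_small_instances(self, preset_fit):
        # the iterated EBLUP equals the penalized least-squares optimum
        rng = np.random.default_rng(8)
        for n_cal in (1, 2, 3):
            lh = rng.uniform(2.0, 7.0, n_cal)
            lcd = rng.uniform(0.5, 3.0, n_cal)
            p1 = rng.integers(0, 2, n_cal)
            truth_u = np.array([0.08, -0.05])
            theta = preset_fit.fixed_effects.copy()
            theta[preset_fit.re_config.indices(preset_fit.form)] += truth_u
            y = mean_function(preset_fit.form, theta, lh, lcd, p1) \
                + rng.normal(0, 0.3, n_cal)
            ds = _records("A", lh, lcd, p1, np.maximum(y, 0.2))
            res = am.eblup(preset_fit, ds, tol=1e-10)
            opt = minimize(lambda v: _penalized_objective(preset_fit, ds, v),
                           np.zeros(2), method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000})
            np.testing.assert_allclose(res.u_hat["A"], opt.x, atol=1e-4)

    def test_shrinkage_under_inflated_residual_variance(self, preset_fit):
        ds = _records("A", [3.0, 5.0], [1.5, 2.5], [0, 1], [6.0, 11.0])
        norms = []
        for scale in (1.0, 2.0, 5.0, 20.0):
            inflated = am.GenotypeMixedResults(
                form=preset_fit.form, params=preset_fit.params,
                re_config=preset_fit.re_config, psi=preset_fit.psi,
                variance=am.VarianceSpec(kind="power", covariate="lh",
                                         sigma=preset_fit.sigma * np.sqrt(scale),
                                         gamma=preset_fit.gamma),
                ranef={}, llf=0.0, nobs=10)
            res = am.eblup(inflated, ds)
            norms.append(float(np.linalg.norm(res.u_hat["A"])))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_fixed_passes_mode(self, preset_fit):
        ds = _records("A", [3.0, 5.0], [1.5, 2.5], [0, 1], [6.0, 11.0])
        three = am.eblup(preset_fit, ds, fixed_passes=3)
        assert three.n_iter["A"] == 3
        converged = am.eblup(preset_fit, ds)
        np.testing.assert_allclose(three.u_hat["A"], converged.u_hat["A"], atol=1e-3)


class TestPredict:
    def test_no_calibration_equals_zero_u_calibration(self, preset_fit, tiny_data):
        zeros = am.CalibrationResult(
            u_hat={g: np.zeros(2) for g in tiny_data.genotype_ids})
        a = am.predict_dbh(preset_fit, tiny_data, None)
        b = am.predict_dbh(preset_fit, tiny_data, zeros)
        np.testing.assert_array_equal(a, b)

    def test_published_value_low_density(self, preset_fit):
        ds = am.Dataset.from_records([am.TreeRecord("X", 0, lh=2.0, lcd=1.0)])
        v = am.predict_dbh(preset_fit, ds, None)[0]
        assert v == pytest.approx(1.9078, abs=5e-4)

    def test_positive_height_effect_raises_predictions(self, preset_fit, tiny_data):
        bumped = am.CalibrationResult(
            u_hat={g: np.array([0.1, 0.0]) for g in tiny_data.genotype_ids})
        base = am.predict_dbh(preset_fit, tiny_data, None)
        up = am.predict_dbh(preset_fit, tiny_data, bumped)
        lh = tiny_data.column("lh")
        assert np.all(up[lh > 1.0] > base[lh > 1.0])

    def test_calibration_improves_own_genotype_predictions(self, preset_fit):
        # trees simulated from the model itself: calibrating on a genotype's
        # trees should beat the population prediction for that genotype
        wins = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            u = rng.multivariate_normal(np.zeros(2), preset_fit.psi)
            lh = rng.uniform(2.0, 8.0, 12)
            lcd = rng.uniform(0.5, 3.5, 12)
            p1 = rng.integers(0, 2, 12)
            theta = preset_fit.fixed_effects.copy()
            theta[preset_fit.re_config.indices(preset_fit.form)] += u
            mean = mean_function(preset_fit.form, theta, lh, lcd, p1)
            sd = preset_fit.sigma * lh**preset_fit.gamma
            y = np.maximum(mean + rng.normal(0, 1, 12) * sd, 0.2)
            ds = _records("A", lh, lcd, p1, y)
            cal_ix, eval_ix = np.arange(4), np.arange(4, 12)
            cal = am.eblup(preset_fit, {"A": ds.subset(cal_ix)})
            pred_pop = am.predict_dbh(preset_fit, ds.subset(eval_ix), None)
            pred_cal = am.predict_dbh(preset_fit, ds.subset(eval_ix), cal)
            obs = y[eval_ix]
            if np.mean((obs - pred_cal) ** 2) < np.mean((obs - pred_pop) ** 2):
                wins += 1
        assert wins > n_rep / 2

    def test_more_calibration_trees_do_not_hurt(self, preset_fit):
        # nested calibration subsets: expected squared error non-increasing
        mse = {2: [], 8: []}
        for rep in range(40):
            rng = np.random.default_rng(7000 + rep)
            u = rng.multivariate_normal(np.zeros(2), preset_fit.psi)
            lh = rng.uniform(2.0, 8.0, 20)
            lcd = rng.uniform(0.5, 3.5, 20)
            p1 = rng.integers(0, 2, 20)
            theta = preset_fit.fixed_effects.copy()
            theta[preset_fit.re_config.indices(preset_fit.form)] += u
            mean = mean_function(preset_fit.form, theta, lh, lcd, p1)
            sd = preset_fit.sigma * lh**preset_fit.gamma
            y = np.maximum(mean + rng.normal(0, 1, 20) * sd, 0.2)
            ds = _records("A", lh, lcd, p1, y)
            eval_ix = np.arange(8, 20)
            for k in (2, 8):
                cal = am.eblup(preset_fit, {"A": ds.subset(np.arange(k))})
                pred = am.predict_dbh(preset_fit, ds.subset(eval_ix), cal)
                mse[k].append(np.mean((y[eval_ix] - pred) ** 2))
        assert np.mean(mse[8]) <= np.mean(mse[2]) * 1.05
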