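"""Fixed-effects allometric model fitting (nonlinear least squares).

``AllometricModel`` fits one of the mean functions in :mod:`allomix.forms`
to a :class:`~allomix.data.Dataset` by trust-region least squares with
analytic Jacobians, data-driven deterministic starting values, and seeded
jittered restarts on non-convergence.  The log-likelihood is the i.i.d.
Gaussian one at the ML residual variance, so information criteria are
directly comparable with the mixed-effects fits (k counts the residual
scale as an estimated parameter).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import Dataset
from .exceptions import ConvergenceError, ValidationError
from .forms import ModelForm, ModelParams, mean_function, mean_gradient
from .metrics import (FitStatistics, InformationCriteria, fit_statistics,
                      information_criteria, percent_improvements)

_LCD_FLOOR = 0.05  # smallest crown diameter seen in the field data; guards log(0)


def _start_values(form: ModelForm, dbh, lh, lcd, p1) -> np.ndarray:
    """Deterministic, data-driven initial coefficients."""
    fam, slot = form.family, form.dummy_slot
    if fam == "power":
        # OLS on ln(dbh) = ln a + b ln(lh) + c ln(lcd)
        X = np.column_stack([np.ones_like(lh), np.log(lh),
                             np.log(np.maximum(lcd, _LCD_FLOOR))])
        coef, *_ = np.linalg.lstsq(X, np.log(np.maximum(dbh, 1e-6)), rcond=None)
        a, b, c = math.exp(coef[0]), coef[1], coef[2]
        base = {"a1": a, "b1": b, "c1": c, "a2": 0.0, "b2": 0.0, "c2": 0.0}
        return np.array([base[name] for name in form.param_names])
    if fam == "exponential":
        X = np.column_stack([np.ones_like(lh), -lh, -lcd])
        coef, *_ = np.linalg.lstsq(X, np.log(np.maximum(dbh, 1e-6)), rcond=None)
        return np.array([math.exp(coef[0]), coef[1], coef[2]])
    top = float(np.max(dbh)) * 1.05
    # rate starts scaled by the covariate means so the exponential term is
    # not saturated at the first iterate
    b0 = 0.5 / max(float(np.mean(lh)), 1e-6)
    c0 = 0.5 / max(float(np.mean(lcd)), 1e-6)
    if fam == "logistic":
        return np.array([top, 1.0, b0, c0])
    return np.array([top, b0, c0])  # richards


class AllometricResults:
    """Results of a fixed-effects allometric fit."""

    def __init__(self, model, theta, res, n_iter):
        self.model = model
        form = model.form
        self.form = form
        self.theta = np.asarray(theta, dtype=float)
        self.params = ModelParams.from_array(form, self.theta)
        self.converged = bool(res.success)
        self.n_iter = int(n_iter)

        dbh = model.dbh
        self.fittedvalues = mean_function(form, self.theta, model.lh, model.lcd, model.p1)
        self.resid = dbh - self.fittedvalues
        n = dbh.size
        rss = float(np.sum(self.resid**2))
        self.sigma2_ml = rss / n
        # zero-residual (degenerate) fits get the likelihood at a tiny
        # variance floor instead of +inf
        self.llf = -0.5 * n * (math.log(2.0 * math.pi * max(self.sigma2_ml, 1e-12)) + 1.0)
        self.k = form.n_params + 1  # mean coefficients + residual scale
        self.nobs = n
        self.ic: InformationCriteria = information_criteria(self.llf, self.k, n)
        self.aic, self.bic = self.ic.aic, self.ic.bic
        self.fitstats: FitStatistics = fit_statistics(dbh, self.fittedvalues)

    def predict(self, data: Dataset | None = None, lh=None, lcd=None, p1=0) -> np.ndarray:
        if data is not None:
            lh, lcd, p1 = data.column("lh"), data.column("lcd"), data.column("p1")
        return mean_function(self.form, self.theta, lh, lcd, p1)

    def summary(self) -> str:
        lines = [
            f"Allometric model: {self.form.label()}",
            f"  n = {self.nobs}, converged = {self.converged}, evaluations = {self.n_iter}",
            "  Coefficients:",
        ]
        for name, val in zip(self.form.param_names, self.theta):
            lines.append(f"    {name:>4s} = {val: .4f}")
        s = self.fitstats
        lines += [
            f"  RMSE = {s.rmse:.4f}  R2 = {s.r2:.4f}  TRE = {s.tre:.4f}",
            f"  logLik = {self.llf:.4f}  k = {self.k}  AIC = {self.aic:.4f}  BIC = {self.bic:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "form": {"family": self.form.family, "dummy_slot": self.form.dummy_slot},
            "params": self.params.as_dict(),
            "loglik": self.llf, "k": self.k, "n": self.nobs,
            "aic": self.aic, "bic": self.bic,
            "stats": self.fitstats.as_dict(),
            "converged": self.converged,
        }


class AllometricModel:
    """Nonlinear least-squares allometric DBH model.

    Parameters
    ----------
    data : Dataset
        Every record must carry dbh, lh and lcd.
    form : ModelForm
        Mean-function family and optional density-dummy slot.
    """

    def __init__(self, data: Dataset, form: ModelForm):
        self.data = data
        self.form = form
        frame = data.frame
        if frame["dbh"].isna().any():
            raise ValidationError("all records must have dbh for fitting")
        self.dbh = frame["dbh"].to_numpy(dtype=float)
        self.lh = frame["lh"].to_numpy(dtype=float)
        self.lcd = frame["lcd"].to_numpy(dtype=float)
        self.p1 = frame["p1"].to_numpy(dtype=float)
        if len(data) < form.n_params + 2:
            raise ValidationError(
                f"need at least {form.n_params + 2} records to fit {form.label()}"
            )
        if np.ptp(self.lh) == 0:
            raise ValidationError("rank-deficient design: lh is constant")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, form: ModelForm | None = None,
                       **form_kwargs) -> "AllometricModel":
        if form is None:
            form = ModelForm(**form_kwargs) if form_kwargs else ModelForm("power")
        return cls(Dataset(frame), form)

    def fit(self, start: ModelParams | None = None, max_restarts: int = 5,
            seed: int = 0) -> AllometricResults:
        """Fit by trust-region least squares with seeded jittered restarts."""
        theta0 = (start.to_array(self.form) if start is not None
                  else _start_values(self.form, self.dbh, self.lh, self.lcd, self.p1))

        def resid(theta):
            return mean_function(self.form, theta, self.lh, self.lcd, self.p1) - self.dbh

        def jac(theta):
            return mean_gradient(self.form, theta, self.lh, self.lcd, self.p1)

        rng = np.random.default_rng(seed)
        best = None
        nfev = 0
        t0 = theta0
        for attempt in range(max_restarts + 1):
            res = least_squares(resid, t0, jac=jac, method="trf",
                                x_scale="jac", max_nfev=2000)
            nfev += res.nfev
            if best is None or res.cost < best.cost:
                best = res
            if res.success and np.isfinite(res.cost):
                return AllometricResults(self, res.x, res, nfev)
            t0 = theta0 * (1.0 + 0.2 * rng.standard_normal(theta0.size))
        raise ConvergenceError(
            f"fit of {self.form.label()} did not converge after {max_restarts} restarts",
            best_params=ModelParams.from_array(self.form, best.x),
        )


def fit_fixed_model(data: Dataset, form: ModelForm,
                    init: ModelParams | None = None) -> AllometricResults:
    """Functional wrapper: fit a fixed-effects allometric model."""
    return AllometricModel(data, form).fit(start=init)


def compare_models(fits, baseline=None) -> pd.DataFrame:
    """Rank fitted models by AIC, with relative-change columns vs a baseline.

    All fits must be on the same data.  The baseline defaults to the first
    fit as given; RMSE/TRE reductions and the R^2 gain are in percent.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValidationError("need at least 2 fits to compare")
    n0 = fits[0].nobs
    y0 = np.sort(np.asarray(fits[0].model.dbh)) if fits[0].model is not None else None
    for f in fits[1:]:
        same = f.nobs == n0
        if same and y0 is not None and f.model is not None:
            same = np.allclose(np.sort(np.asarray(f.model.dbh)), y0)
        if not same:
            raise ValidationError("fits are not on the same dataset")
    base = baseline if baseline is not None else fits[0]
    rows = []
    for f in fits:
        s = f.fitstats
        row = {
            "model": f.form.label(), "k": f.k,
            "rmse": s.rmse, "r2": s.r2, "tre": s.tre,
            "aic": f.aic, "bic": f.bic, "loglik": f.llf,
        }
        row.update(percent_improvements(base.fitstats, s))
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    return out
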