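"""EBLUP calibration: localized prediction for a genotype from a few trees.

Given a fitted genotype mixed model and a small calibration subsample of a
genotype (trees with measured DBH), the random-effect vector is predicted by
the empirical best linear unbiased predictor

    u_hat = Psi Z' (R + Z Psi Z')^{-1} [y - f(beta, u*) + Z u*],

where Z is the Jacobian of the mean function with respect to the random
effects at the current iterate u*, and R is the fitted residual covariance
at the calibration trees' covariates.  Because u* appears on both sides the
update is iterated from u* = 0 to a fixed point (or for a fixed number of
passes).  The calibrated model predicts a genotype's trees at beta + u_hat;
genotypes without calibration data fall back to the population prediction
(u = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import Dataset
from .exceptions import ValidationError
from .forms import mean_function, mean_gradient
from .mixed import GenotypeMixedResults, variance_weights

logger = logging.getLogger(__name__)


@dataclass
class CalibrationResult:
    """Per-genotype predicted random effects from a calibration subsample."""

    u_hat: dict[str, np.ndarray]
    n_iter: dict[str, int] = field(default_factory=dict)
    converged: bool = True
    calibration_trees: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "u_hat": {g: u.tolist() for g, u in self.u_hat.items()},
            "n_iter": dict(self.n_iter),
            "converged": self.converged,
            "calibration_trees": {g: ix.tolist() for g, ix in self.calibration_trees.items()},
        }


def random_effect_jacobian(fit: GenotypeMixedResults, lh, lcd, p1,
                           u: np.ndarray | None = None) -> np.ndarray:
    """n x q matrix of partial derivatives of the mean w.r.t. each random effect.

    Random effects enter additively on their target coefficients, so column
    k is the mean-function gradient w.r.t. the k-th target coefficient,
    evaluated at (fixed effects + u).  For the power model with the density
    dummy on the height exponent this is f*ln(LH) and f*ln(LH)*P1.
    """
    lh = np.atleast_1d(np.asarray(lh, dtype=float))
    if (lh <= 0).any():
        raise ValidationError("lh must be positive")
    q = fit.re_config.q
    theta = fit.fixed_effects.copy()
    if u is not None:
        u = np.asarray(u, dtype=float)
        if u.shape != (q,):
            raise ValidationError(f"u must have shape ({q},)")
        theta[fit.re_config.indices(fit.form)] += u
    G = mean_gradient(fit.form, theta, lh, lcd, p1)
    return G[:, fit.re_config.indices(fit.form)]


def _group_arrays(data: Dataset, indices) -> tuple:
    frame = data.frame
    ix = np.asarray(indices, dtype=int)
    sub = frame.iloc[ix]
    y = sub["dbh"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("calibration records must carry dbh")
    return (y, sub["lh"].to_numpy(dtype=float), sub["lcd"].to_numpy(dtype=float),
            sub["p1"].to_numpy(dtype=float))


def eblup(fit: GenotypeMixedResults, calibration: Dataset | dict,
          tol: float = 1e-6, max_iter: int = 50,
          fixed_passes: int | None = None) -> CalibrationResult:
    """Predict genotype random effects from calibration trees.

    Parameters
    ----------
    fit : GenotypeMixedResults
        A fitted (or preset) genotype mixed model.
    calibration : Dataset or mapping genotype_id -> Dataset
        Trees with measured dbh used for calibration, grouped by genotype.
    tol, max_iter
        Max-norm convergence tolerance and iteration cap, starting from
        u* = 0.
    fixed_passes : int, optional
        Run exactly this many update passes instead of iterating to
        convergence.
    """
    if isinstance(calibration, Dataset):
        groups = {g: (calibration, ix) for g, ix in calibration.groups.items()}
    else:
        groups = {g: (ds, np.arange(len(ds))) for g, ds in calibration.items()}

    q = fit.re_config.q
    psi = fit.psi
    theta0 = fit.fixed_effects
    t_ix = fit.re_config.indices(fit.form)
    x_name = fit.variance.covariate

    u_hat: dict[str, np.ndarray] = {}
    n_iter: dict[str, int] = {}
    calib_trees: dict[str, np.ndarray] = {}
    all_converged = True

    for g, (ds, ix) in groups.items():
        ix = np.asarray(ix, dtype=int)
        calib_trees[g] = ix
        if ix.size == 0:
            u_hat[g] = np.zeros(q)
            n_iter[g] = 0
            continue
        y, lh, lcd, p1 = _group_arrays(ds, ix)
        x = lh if x_name == "lh" else lcd
        R = np.diag(variance_weights(fit.variance, x))

        u = np.zeros(q)
        n_pass = fixed_passes if fixed_passes is not None else max_iter
        converged_g = fixed_passes is not None
        it = 0
        for it in range(1, n_pass + 1):
            theta = theta0.copy()
            theta[t_ix] += u
            f = mean_function(fit.form, theta, lh, lcd, p1)
            Z = mean_gradient(fit.form, theta, lh, lcd, p1)[:, t_ix]
            e_work = y - f + Z @ u
            A = R + Z @ psi @ Z.T
            try:
                cf = cho_factor(A, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ValidationError(
                    f"singular calibration system for genotype {g!r}"
                ) from exc
            u_new = psi @ Z.T @ cho_solve(cf, e_work)
            delta = float(np.max(np.abs(u_new - u)))
            u = u_new
            if fixed_passes is None and delta < tol:
                converged_g = True
                break
        if not converged_g:
            logger.warning("EBLUP for genotype %r did not converge in %d iterations", g, max_iter)
            all_converged = False
        u_hat[g] = u
        n_iter[g] = it

    return CalibrationResult(u_hat=u_hat, n_iter=n_iter,
                             converged=all_converged,
                             calibration_trees=calib_trees)


def predict_dbh(fit: GenotypeMixedResults, data: Dataset,
                calibration: CalibrationResult | None = None) -> np.ndarray:
    """Predict DBH for every record: population level (u = 0) without
    calibration, subject-specific (u = u_hat of the record's genotype)
    with it.  Genotypes absent from the calibration map fall back to u = 0.
    """
    frame = data.frame
    lh = frame["lh"].to_numpy(dtype=float)
    lcd = frame["lcd"].to_numpy(dtype=float)
    p1 = frame["p1"].to_numpy(dtype=float)
    t_ix = fit.re_config.indices(fit.form)
    theta0 = fit.fixed_effects

    out = np.empty(len(data))
    for g, ix in data.groups.items():
        theta = theta0.copy()
        if calibration is not None and g in calibration.u_hat:
            theta[t_ix] += calibration.u_hat[g]
        elif calibration is not None:
            logger.info("genotype %r not in calibration map; population prediction used", g)
        out[ix] = mean_function(fit.form, theta, lh[ix], lcd[ix], p1[ix])
    return out
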