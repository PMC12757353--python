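"""Fit and evaluation statistics, and information criteria.

Every model stage is judged with the same bundle: mean prediction error
e-bar, error variance (N-1 denominator), total relative error
TRE = 100 * sum(e^2) / sum(y^2), coefficient of determination R^2, and
RMSE = sqrt(e-bar^2 + error variance).  Model complexity is compared with
AIC = 2k - 2 lnL and BIC = k ln(n) - 2 lnL, where k counts *all* estimated
quantities: mean-function coefficients, the residual scale, every
variance-covariance component of the random effects, and each
variance-function parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class FitStatistics:
    """Evaluation bundle for one set of (observed, predicted) DBH pairs."""

    mean_error: float
    error_variance: float
    tre: float
    r2: float
    rmse: float
    n: int

    def __post_init__(self):
        # rmse^2 = mean_error^2 + error_variance is definitional
        lhs = self.rmse**2
        rhs = self.mean_error**2 + self.error_variance
        if not math.isclose(lhs, rhs, rel_tol=1e-10, abs_tol=1e-12):
            raise ValidationError("rmse^2 != mean_error^2 + error_variance")

    def as_dict(self) -> dict:
        return {
            "mean_error": self.mean_error,
            "error_variance": self.error_variance,
            "tre": self.tre,
            "r2": self.r2,
            "rmse": self.rmse,
            "n": self.n,
        }


def fit_statistics(observed, predicted) -> FitStatistics:
    """Compute the evaluation bundle for paired observed/predicted values.

    Raises :class:`DegenerateInputError` when a denominator vanishes
    (all-zero observations for TRE, constant observations for R^2) rather
    than silently returning NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError(
            f"observed and predicted must be equal-length 1-D vectors, "
            f"got shapes {obs.shape} and {pred.shape}"
        )
    n = obs.size
    if n < 2:
        raise ValidationError("need at least 2 observations")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValidationError("observed/predicted must be finite")

    e = obs - pred
    ebar = float(np.mean(e))
    var = float(np.sum((e - ebar) ** 2) / (n - 1))
    sse = float(np.sum(e**2))

    denom_tre = float(np.sum(obs**2))
    if denom_tre == 0.0:
        raise DegenerateInputError("TRE undefined: all observed values are zero")
    denom_r2 = float(np.sum((obs - np.mean(obs)) ** 2))
    if denom_r2 == 0.0:
        raise DegenerateInputError("R^2 undefined: observed values are constant")

    return FitStatistics(
        mean_error=ebar,
        error_variance=var,
        tre=100.0 * sse / denom_tre,
        r2=1.0 - sse / denom_r2,
        rmse=math.sqrt(ebar**2 + var),
        n=n,
    )


@dataclass(frozen=True)
class InformationCriteria:
    k: int
    n: int
    loglik: float
    aic: float
    bic: float

    def as_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "loglik": self.loglik,
                "aic": self.aic, "bic": self.bic}


def information_criteria(loglik: float, k: int, n: int) -> InformationCriteria:
    """AIC = 2k - 2 lnL and BIC = k ln(n) - 2 lnL.

    ``n`` is the number of tree records (not genotype groups).  The two
    criteria always satisfy BIC - AIC = k (ln n - 2).
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not math.isfinite(loglik):
        raise ValidationError("loglik must be finite")
    return InformationCriteria(
        k=k, n=n, loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        bic=k * math.log(n) - 2.0 * loglik,
    )


def percent_improvements(base, new) -> dict[str, float]:
    """Relative-change columns versus a baseline fit.

    RMSE and TRE improve downward: 100*(base-new)/base; R^2 improves
    upward: 100*(new-base)/base.  Accepts :class:`FitStatistics` or any
    objects with ``rmse``, ``r2``, ``tre`` attributes, or mappings.
    """
    def get(obj, name):
        if isinstance(obj, dict):
            return float(obj[name])
        return float(getattr(obj, name))

    def change(b, v, sign):
        if b == 0.0:
            if v == b:
                return 0.0
            raise DegenerateInputError("relative change undefined: baseline is zero")
        return sign * 100.0 * (v - b) / b

    out = {}
    for name, key in (("rmse", "rmse_reduction_pct"), ("tre", "tre_reduction_pct")):
        out[key] = change(get(base, name), get(new, name), -1.0)
    out["r2_gain_pct"] = change(get(base, "r2"), get(new, "r2"), 1.0)
    return out
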