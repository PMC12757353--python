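"""Genotype-random-effect nonlinear mixed-effects estimation.

The model for tree j of genotype i is

    y_ij = f(beta + B u_i; x_ij) + eps_ij,     u_i ~ N(0, Psi),
    eps_i ~ N(0, R_i),   R_i = sigma^2 G_i (no within-group autocorrelation),

where f is an allometric mean function (:mod:`allomix.forms`), u_i perturbs
a chosen subset of the coefficients, Psi is unstructured, and G_i is
diagonal with entries from a variance function of a covariate x (power:
x^(2 gamma); exponential: exp(2 gamma x); constant: 1).

Estimation is maximum likelihood by alternating two steps in the style of
Lindstrom & Bates: (a) penalized nonlinear least squares in (beta, {u_i})
at the current variance parameters, solved by Gauss-Newton with step
halving; (b) a linear mixed-effects step on the model linearized at the
current estimates, updating (Psi, sigma, gamma) by profiled ML over a
log-Cholesky parameterization of Psi/sigma^2 (which keeps Psi symmetric
positive semi-definite by construction).  The reported log-likelihood is
the marginal Gaussian likelihood of the working linearized model at
convergence — the standard approximation for this class of estimator.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .allometric import AllometricModel
from .data import Dataset
from .exceptions import ConvergenceError, ValidationError
from .forms import ModelForm, ModelParams, mean_function, mean_gradient
from .metrics import (FitStatistics, fit_statistics, information_criteria)

logger = logging.getLogger(__name__)

VARIANCE_KINDS = ("constant", "power", "exponential")

_LOGD_MIN, _LOGD_MAX = -13.0, 8.0   # bounds on log-Cholesky diagonals
_GAMMA_MAX = 5.0


# ---------------------------------------------------------------------------
# configuration types

@dataclass(frozen=True)
class RandomEffectConfig:
    """Which mean-function coefficients receive genotype random effects."""

    targets: tuple[str, ...]

    def __post_init__(self):
        if len(self.targets) == 0:
            raise ValidationError("at least one random-effect target required")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError("random-effect targets must be distinct")

    @property
    def q(self) -> int:
        return len(self.targets)

    def indices(self, form: ModelForm) -> np.ndarray:
        names = form.param_names
        try:
            return np.asarray([names.index(t) for t in self.targets], dtype=int)
        except ValueError as exc:
            raise ValidationError(
                f"random-effect target not in {form.label()} coefficients: {exc}"
            ) from exc


def enumerate_re_configs(form) -> list[RandomEffectConfig]:
    """All 2^p - 1 non-empty coefficient subsets, by size then lexicographic.

    Accepts a :class:`ModelForm` or a plain sequence of coefficient names.
    """
    names = form.param_names if isinstance(form, ModelForm) else tuple(form)
    configs = []
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            configs.append(RandomEffectConfig(targets=combo))
    configs.sort(key=lambda c: (c.q, c.targets))
    return configs


@dataclass(frozen=True)
class VarianceSpec:
    """Residual variance model: var(eps) = sigma^2 * x^(2 gamma) (power),
    sigma^2 * exp(2 gamma x) (exponential), or sigma^2 (constant)."""

    kind: str = "constant"
    covariate: str = "lh"
    sigma: float = 1.0
    gamma: float = 0.0

    def __post_init__(self):
        if self.kind not in VARIANCE_KINDS:
            raise ValidationError(f"unknown variance kind {self.kind!r}")
        if self.covariate not in ("lh", "lcd"):
            raise ValidationError(f"variance covariate must be 'lh' or 'lcd'")
        if not (self.sigma > 0):
            raise ValidationError("sigma must be positive")
        if not math.isfinite(self.gamma):
            raise ValidationError("gamma must be finite")

    def sd_multipliers(self, x) -> np.ndarray:
        """w such that sd(eps) = sigma * w."""
        x = np.asarray(x, dtype=float)
        if self.kind == "constant":
            return np.ones_like(x)
        if self.kind == "power":
            if (x <= 0).any():
                raise ValidationError("power variance function requires positive covariate")
            return x**self.gamma
        return np.exp(self.gamma * x)


def variance_weights(spec: VarianceSpec, x) -> np.ndarray:
    """Per-observation residual variances sigma^2 * w(x)^2."""
    w = spec.sd_multipliers(x)
    return spec.sigma**2 * w**2


# ---------------------------------------------------------------------------
# log-Cholesky packing of D = Psi / sigma^2

def _pack_chol(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(math.log(max(L[i, i], 1e-300)) if i == j else L[i, j])
    return np.asarray(out)


def _unpack_chol(vec: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, i] = math.exp(min(max(vec[k], _LOGD_MIN), _LOGD_MAX))
            else:
                L[i, j] = min(max(vec[k], -1e3), 1e3)
            k += 1
    return L


# ---------------------------------------------------------------------------
# results object

class GenotypeMixedResults:
    """Fitted genotype mixed model: fixed effects, Psi, variance function,
    per-genotype predicted random effects (BLUPs) and fit summaries."""

    def __init__(self, *, form: ModelForm, params: ModelParams,
                 re_config: RandomEffectConfig, psi: np.ndarray,
                 variance: VarianceSpec, ranef: dict[str, np.ndarray],
                 llf: float, nobs: int, converged: bool = True,
                 n_iter: int = 0, model: "GenotypeMixedModel | None" = None,
                 fitstats: FitStatistics | None = None):
        self.model = model
        self.form = form
        self.params = params
        self.re_config = re_config
        self.psi = np.asarray(psi, dtype=float)
        if self.psi.shape != (re_config.q, re_config.q):
            raise ValidationError("psi shape does not match random-effect dimension")
        if not np.allclose(self.psi, self.psi.T, atol=1e-12):
            raise ValidationError("psi must be symmetric")
        eig = np.linalg.eigvalsh(self.psi)
        if eig.min() < -1e-10 * max(np.trace(self.psi), 1e-30):
            raise ValidationError("psi must be positive semi-definite")
        self.variance = variance
        self.sigma = variance.sigma
        self.gamma = variance.gamma
        self.ranef = {g: np.asarray(u, dtype=float) for g, u in ranef.items()}
        self.llf = float(llf)
        self.nobs = int(nobs)
        self.k = (form.n_params + 1 + re_config.q * (re_config.q + 1) // 2
                  + (1 if variance.kind != "constant" else 0))
        ic = information_criteria(self.llf, self.k, self.nobs)
        self.aic, self.bic = ic.aic, ic.bic
        self.ic = ic
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.fitstats = fitstats

    # -- prediction (delegates to the calibration module) ------------------
    def predict(self, data: Dataset, calibration=None) -> np.ndarray:
        from .calibration import predict_dbh
        return predict_dbh(self, data, calibration)

    def calibrate(self, calibration_data: Dataset, **kwargs):
        from .calibration import eblup
        return eblup(self, calibration_data, **kwargs)

    @property
    def fixed_effects(self) -> np.ndarray:
        return self.params.to_array(self.form)

    def summary(self) -> str:
        lines = [
            f"Genotype mixed-effects model: {self.form.label()}",
            f"  random effects on: {', '.join(self.re_config.targets)} (q={self.re_config.q})",
            f"  variance function: {self.variance.kind} in {self.variance.covariate}",
            f"  n = {self.nobs}, genotypes = {len(self.ranef)}, "
            f"converged = {self.converged}, outer iterations = {self.n_iter}",
            "  Fixed effects:",
        ]
        for name, val in zip(self.form.param_names, self.fixed_effects):
            lines.append(f"    {name:>4s} = {val: .4f}")
        lines.append("  Psi (random-effect covariance):")
        for row in self.psi:
            lines.append("    [" + "  ".join(f"{v: .4e}" for v in row) + "]")
        lines.append(f"  sigma = {self.sigma:.4f}" +
                     (f"  gamma = {self.gamma:.4f}" if self.variance.kind != "constant" else ""))
        if self.fitstats is not None:
            s = self.fitstats
            lines.append(f"  RMSE = {s.rmse:.4f}  R2 = {s.r2:.4f}  TRE = {s.tre:.4f}")
        lines.append(f"  logLik = {self.llf:.4f}  k = {self.k}  "
                     f"AIC = {self.aic:.4f}  BIC = {self.bic:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "form": {"family": self.form.family, "dummy_slot": self.form.dummy_slot},
            "params": self.params.as_dict(),
            "re_targets": list(self.re_config.targets),
            "psi": self.psi.tolist(),
            "variance": {"kind": self.variance.kind, "covariate": self.variance.covariate,
                         "sigma": self.sigma, "gamma": self.gamma},
            "ranef": {g: u.tolist() for g, u in self.ranef.items()},
            "loglik": self.llf, "k": self.k, "n": self.nobs,
            "aic": self.aic, "bic": self.bic,
            "converged": self.converged, "n_iter": self.n_iter,
            "stats": self.fitstats.as_dict() if self.fitstats is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypeMixedResults":
        form = ModelForm(**d["form"])
        variance = VarianceSpec(**d["variance"])
        return cls(
            form=form,
            params=ModelParams(**d["params"]),
            re_config=RandomEffectConfig(targets=tuple(d["re_targets"])),
            psi=np.asarray(d["psi"]),
            variance=variance,
            ranef={g: np.asarray(u) for g, u in d.get("ranef", {}).items()},
            llf=d["loglik"], nobs=d["n"],
            converged=d.get("converged", True), n_iter=d.get("n_iter", 0),
        )


def published_catalpa_fit() -> GenotypeMixedResults:
    """The final published genotype mixed model, loadable without fitting.

    Power mean with the density dummy on the height exponent, random
    effects on (b1, b2), unstructured Psi, and a power variance function of
    LH: fixed effects (0.8403, 1.1829, -0.1427, 0.2726), Psi =
    [[7.763e-3, -4.857e-3], [-4.857e-3, 5.401e-3]], sigma = 0.3482,
    gamma = 0.8415; log-likelihood -4183.37 on 2,899 trees.
    """
    form = ModelForm("power", "on_b")
    return GenotypeMixedResults(
        form=form,
        params=ModelParams(a1=0.8403, b1=1.1829, b2=-0.1427, c1=0.2726),
        re_config=RandomEffectConfig(targets=("b1", "b2")),
        psi=np.array([[7.763e-3, -4.857e-3], [-4.857e-3, 5.401e-3]]),
        variance=VarianceSpec(kind="power", covariate="lh",
                              sigma=0.3482, gamma=0.8415),
        ranef={},
        llf=-4183.37, nobs=2899, converged=True,
    )


# ---------------------------------------------------------------------------
# the model / estimator

class GenotypeMixedModel:
    """Nonlinear mixed-effects DBH model with genotype random effects."""

    def __init__(self, data: Dataset, form: ModelForm,
                 random_effects: RandomEffectConfig | tuple | list,
                 variance: VarianceSpec | str = "constant",
                 variance_covariate: str = "lh"):
        if not isinstance(random_effects, RandomEffectConfig):
            random_effects = RandomEffectConfig(targets=tuple(random_effects))
        if isinstance(variance, str):
            variance = VarianceSpec(kind=variance, covariate=variance_covariate)
        self.data = data
        self.form = form
        self.re_config = random_effects
        self.variance_kind = variance.kind
        self.variance_covariate = variance.covariate

        frame = data.frame
        if frame["dbh"].isna().any():
            raise ValidationError("all records must have dbh for fitting")
        self.y = frame["dbh"].to_numpy(dtype=float)
        self.lh = frame["lh"].to_numpy(dtype=float)
        self.lcd = frame["lcd"].to_numpy(dtype=float)
        self.p1 = frame["p1"].to_numpy(dtype=float)
        self.x_var = self.lh if variance.covariate == "lh" else self.lcd
        if variance.kind == "power" and (self.x_var <= 0).any():
            raise ValidationError("power variance function requires positive covariate")
        self.groups = data.groups
        self.group_ids = list(self.groups.keys())
        self.group_ix = [self.groups[g] for g in self.group_ids]
        if min(len(ix) for ix in self.group_ix) < 1:
            raise ValidationError("every genotype needs at least one tree")
        self.t_ix = random_effects.indices(form)
        self.p = form.n_params
        self.q = random_effects.q
        self.M = len(self.group_ids)
        self.N = len(data)

    # -- helpers -----------------------------------------------------------
    def _coef_matrix(self, beta: np.ndarray, u: np.ndarray) -> list[np.ndarray]:
        """Per-group coefficient vectors beta + B u_i."""
        out = []
        for i in range(self.M):
            c = beta.copy()
            c[self.t_ix] += u[i]
            out.append(c)
        return out

    def _mean_and_grad(self, beta, u):
        f = np.empty(self.N)
        G = np.empty((self.N, self.p))
        for i, ix in enumerate(self.group_ix):
            c = beta.copy()
            c[self.t_ix] += u[i]
            f[ix] = mean_function(self.form, c, self.lh[ix], self.lcd[ix], self.p1[ix])
            G[ix] = mean_gradient(self.form, c, self.lh[ix], self.lcd[ix], self.p1[ix])
        return f, G

    def _weights(self, gamma: float) -> np.ndarray:
        spec = VarianceSpec(kind=self.variance_kind, covariate=self.variance_covariate,
                            sigma=1.0, gamma=gamma)
        return spec.sd_multipliers(self.x_var)

    # -- step (a): penalized nonlinear least squares ------------------------
    def _pnls(self, beta, u, L, gamma, max_iter=60, tol=1e-10):
        """Minimize sum ((y-f)/w)^2 + sum_i |Linv u_i|^2 over (beta, u)."""
        w = self._weights(gamma)
        Linv = solve_triangular(L, np.eye(self.q), lower=True)
        n_pen = self.M * self.q
        ncol = self.p + n_pen

        def objective(beta_, u_):
            f, _ = self._mean_and_grad(beta_, u_)
            r = (self.y - f) / w
            pen = u_ @ Linv.T
            return float(r @ r + np.sum(pen * pen)), f

        S, f = objective(beta, u)
        for _ in range(max_iter):
            _, G = self._mean_and_grad(beta, u)
            r = (self.y - f) / w
            J = np.zeros((self.N + n_pen, ncol))
            rhs = np.empty(self.N + n_pen)
            # step d solves min |J d - rhs|^2 with J the Jacobian of the
            # model part (+G/w) and rhs the current residuals, so that the
            # data block targets r and the penalty block targets -Linv u
            Gw = G / w[:, None]
            J[: self.N, : self.p] = Gw
            rhs[: self.N] = r
            for i, ix in enumerate(self.group_ix):
                c0 = self.p + i * self.q
                J[ix, c0: c0 + self.q] = Gw[ix][:, self.t_ix]
                J[self.N + i * self.q: self.N + (i + 1) * self.q, c0: c0 + self.q] = Linv
                rhs[self.N + i * self.q: self.N + (i + 1) * self.q] = -Linv @ u[i]
            d, *_ = np.linalg.lstsq(J, rhs, rcond=None)
            step = 1.0
            improved = False
            for _ in range(12):
                beta_try = beta + step * d[: self.p]
                u_try = u + step * d[self.p:].reshape(self.M, self.q)
                S_try, f_try = objective(beta_try, u_try)
                if np.isfinite(S_try) and S_try < S:
                    beta, u, f = beta_try, u_try, f_try
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            if S - S_try < tol * (1.0 + S):
                S = S_try
                break
            S = S_try
        return beta, u

    # -- step (b): profiled linear mixed-effects likelihood -----------------
    def _linearize(self, beta, u):
        f, G = self._mean_and_grad(beta, u)
        ystar = self.y - f + G @ beta
        for i, ix in enumerate(self.group_ix):
            ystar[ix] += G[ix][:, self.t_ix] @ u[i]
        return G, ystar

    def _profiled_llf(self, theta, X, ystar):
        """Profiled marginal loglik of the working LMM at variance params theta.

        Returns (llf, beta_gls, sigma2); -inf on numerical failure.
        """
        nc = self.q * (self.q + 1) // 2
        L = _unpack_chol(theta[:nc], self.q)
        gamma = (min(max(theta[nc], -_GAMMA_MAX), _GAMMA_MAX)
                 if self.variance_kind != "constant" else 0.0)
        try:
            w2 = self._weights(gamma) ** 2
        except ValidationError:
            return -np.inf, None, None
        D = L @ L.T
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        c = 0.0
        logdet = 0.0
        try:
            for ix in self.group_ix:
                Z = X[ix][:, self.t_ix]
                V = np.diag(w2[ix]) + Z @ D @ Z.T
                cf = cho_factor(V, lower=True)
                logdet += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
                Xi, yi = X[ix], ystar[ix]
                VX = cho_solve(cf, Xi)
                Vy = cho_solve(cf, yi)
                A += Xi.T @ VX
                b += Xi.T @ Vy
                c += float(yi @ Vy)
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        rss = c - float(beta @ b)
        if not np.isfinite(rss) or rss <= 0:
            return -np.inf, None, None
        sigma2 = rss / self.N
        llf = -0.5 * (self.N * math.log(2.0 * math.pi * sigma2) + self.N + logdet)
        return llf, beta, sigma2

    # -- the alternating fit -------------------------------------------------
    def fit(self, start: ModelParams | None = None,
            start_psi: np.ndarray | None = None,
            start_sigma: float | None = None, start_gamma: float = 0.5,
            maxiter: int = 200, tol_llf: float = 1e-8, tol_param: float = 1e-6,
            inner_maxiter: int | None = None) -> GenotypeMixedResults:
        # starting values: fixed-effects fit of the same mean function
        if start is None or start_sigma is None:
            fixed = AllometricModel(self.data, self.form).fit()
            beta = fixed.theta.copy() if start is None else start.to_array(self.form)
            sigma2 = fixed.sigma2_ml if start_sigma is None else start_sigma**2
        else:
            beta = start.to_array(self.form)
            sigma2 = start_sigma**2
        if start_psi is None:
            scale = np.maximum(np.abs(beta[self.t_ix]), 0.1)
            psi0 = np.diag((0.1 * scale) ** 2)
        else:
            psi0 = np.asarray(start_psi, dtype=float)
        D0 = psi0 / sigma2
        L0 = np.linalg.cholesky(D0 + 1e-12 * np.eye(self.q))
        theta = _pack_chol(L0)
        if self.variance_kind != "constant":
            theta = np.append(theta, start_gamma)
        nc = self.q * (self.q + 1) // 2

        u = np.zeros((self.M, self.q))
        llf_prev = -np.inf
        beta_prev = beta.copy()
        theta_prev = theta.copy()
        converged = False
        n_outer = 0
        llf = -np.inf
        sigma2_hat = sigma2
        beta_gls = beta
        stall = 0

        for n_outer in range(1, maxiter + 1):
            L = _unpack_chol(theta[:nc], self.q)
            gamma = float(theta[nc]) if self.variance_kind != "constant" else 0.0
            beta, u = self._pnls(beta, u, L, gamma)
            X, ystar = self._linearize(beta, u)

            def neg(th):
                val, _, _ = self._profiled_llf(th, X, ystar)
                return -val if np.isfinite(val) else 1e12

            opts = {"maxiter": (inner_maxiter or 250 * len(theta)),
                    "xatol": 1e-7, "fatol": 1e-9}
            res = minimize(neg, theta, method="Nelder-Mead", options=opts)
            theta = res.x
            llf, beta_gls, sigma2_hat = self._profiled_llf(theta, X, ystar)
            if beta_gls is None:
                raise ConvergenceError("variance step failed (singular working model)")
            d_llf = abs(llf - llf_prev)
            d_par = max(np.max(np.abs(beta_gls - beta_prev)),
                        np.max(np.abs(theta - theta_prev)))
            beta_prev, theta_prev = beta_gls.copy(), theta.copy()
            llf_small = d_llf < tol_llf * (1.0 + abs(llf))
            if llf_small and d_par < tol_param:
                converged = True
                beta = beta_gls
                break
            stall = stall + 1 if llf_small else 0
            if stall >= 3:  # parameters wobbling below likelihood resolution
                converged = True
                beta = beta_gls
                break
            llf_prev = llf
            beta = beta_gls

        # final modal random effects at the converged variance parameters
        L = _unpack_chol(theta[:nc], self.q)
        gamma = float(theta[nc]) if self.variance_kind != "constant" else 0.0
        beta, u = self._pnls(beta, u, L, gamma)
        X, ystar = self._linearize(beta, u)
        llf_f, beta_f, sigma2_f = self._profiled_llf(theta, X, ystar)
        if beta_f is not None and np.isfinite(llf_f):
            llf, sigma2_hat = llf_f, sigma2_f

        D = L @ L.T
        psi = sigma2_hat * D
        psi = 0.5 * (psi + psi.T)
        if np.min(np.diag(psi)) < 1e-10 * max(sigma2_hat, 1.0):
            logger.warning("Psi is at or near the boundary (nearly singular)")
        sigma = math.sqrt(sigma2_hat)
        variance = VarianceSpec(kind=self.variance_kind,
                                covariate=self.variance_covariate,
                                sigma=sigma, gamma=gamma)
        ranef = {g: u[i].copy() for i, g in enumerate(self.group_ids)}
        f_hat, _ = self._mean_and_grad(beta, u)
        stats_ = fit_statistics(self.y, f_hat)
        result = GenotypeMixedResults(
            form=self.form, params=ModelParams.from_array(self.form, beta),
            re_config=self.re_config, psi=psi, variance=variance,
            ranef=ranef, llf=llf, nobs=self.N, converged=converged,
            n_iter=n_outer, model=self, fitstats=stats_,
        )
        return result


# ---------------------------------------------------------------------------
# functional wrappers

def fit_nlme(data: Dataset, form: ModelForm,
             re_config: RandomEffectConfig | tuple | list,
             variance: VarianceSpec | str = "constant",
             variance_covariate: str = "lh",
             init: ModelParams | None = None, **fit_kwargs) -> GenotypeMixedResults:
    model = GenotypeMixedModel(data, form, re_config, variance, variance_covariate)
    return model.fit(start=init, **fit_kwargs)


@dataclass
class ModelSearchResult:
    results: list = field(default_factory=list)
    report: pd.DataFrame | None = None
    winner: GenotypeMixedResults | None = None
    skipped: list = field(default_factory=list)


def search_random_effects(data: Dataset, form: ModelForm,
                          variance: VarianceSpec | str = "constant",
                          variance_covariate: str = "lh",
                          configs: list[RandomEffectConfig] | None = None,
                          **fit_kwargs) -> ModelSearchResult:
    """Fit every random-effect subset and rank by AIC (then BIC, then q)."""
    if configs is None:
        configs = enumerate_re_configs(form)
    fitted, skipped, rows = [], [], []
    for cfg in configs:
        try:
            res = fit_nlme(data, form, cfg, variance, variance_covariate, **fit_kwargs)
        except (ConvergenceError, np.linalg.LinAlgError, ValidationError) as exc:
            logger.warning("config %s skipped: %s", cfg.targets, exc)
            skipped.append((cfg, str(exc)))
            continue
        fitted.append(res)
        rows.append({
            "config": "+".join(cfg.targets), "q": cfg.q, "k": res.k,
            "loglik": res.llf, "aic": res.aic, "bic": res.bic,
            "converged": res.converged,
        })
    if not fitted:
        raise ConvergenceError("no random-effect configuration converged")
    order = sorted(range(len(fitted)),
                   key=lambda i: (fitted[i].aic, fitted[i].bic, fitted[i].re_config.q))
    fitted = [fitted[i] for i in order]
    report = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    return ModelSearchResult(results=fitted, report=report,
                             winner=fitted[0], skipped=skipped)


def likelihood_ratio_test(nested, full) -> tuple[float, int, float]:
    """Chi-square LRT of two nested fits: (statistic, df, p-value)."""
    ll0, k0 = float(nested.llf), int(nested.k)
    ll1, k1 = float(full.llf), int(full.k)
    if k0 >= k1:
        raise ValidationError("nested model must have fewer parameters than the full model")
    stat = 2.0 * (ll1 - ll0)
    if stat < -1e-6 * (1.0 + abs(ll1)):
        raise ValidationError(
            f"negative LRT statistic ({stat:.4g}): fits are not nested or not converged"
        )
    stat = max(stat, 0.0)
    df = k1 - k0
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p
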