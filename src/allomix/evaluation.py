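"""Calibration-sampling strategies and leave-one-genotype-out validation.

Four schemes choose the k = 1..10 calibration trees per genotype: the k
smallest by DBH, the k largest, k random trees of medium size (strictly
between the genotype's 20th and 80th DBH percentiles), and k fully random
trees.  Each (scheme, k) is scored by calibrating the mixed model with the
selected trees and evaluating the pooled prediction statistics — by default
on the non-calibration trees, so calibration data never score themselves.

Leave-one-genotype-out cross-validation refits the model with one genotype
held out, calibrates on a small random subsample of the held-out genotype,
and scores its remaining trees; every genotype is validation exactly once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import eblup, predict_dbh
from .data import Dataset
from .exceptions import ConvergenceError, ValidationError
from .forms import ModelForm, ModelParams
from .metrics import FitStatistics, fit_statistics
from .mixed import (GenotypeMixedModel, GenotypeMixedResults,
                    RandomEffectConfig, VarianceSpec)

logger = logging.getLogger(__name__)

STRATEGY_KINDS = ("smallest", "largest", "medium", "random")


@dataclass(frozen=True)
class SamplingStrategy:
    """Calibration-subsample design for one genotype group."""

    kind: str
    k: int
    lower_pct: float = 20.0
    upper_pct: float = 80.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in STRATEGY_KINDS:
            raise ValidationError(f"unknown strategy kind {self.kind!r}")
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if not (0 <= self.lower_pct < self.upper_pct <= 100):
            raise ValidationError("need 0 <= lower_pct < upper_pct <= 100")


def select_calibration_trees(dbh, strategy: SamplingStrategy,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """Positional indices of the calibration trees within one genotype group.

    Ties are broken by original record order (stable sort); k is clipped to
    the group size.  The medium scheme samples uniformly among trees with
    DBH strictly inside the (20th, 80th) percentile band
    (linear-interpolation percentiles); if fewer than k are eligible, all
    eligible trees are returned with a warning.
    """
    dbh = np.asarray(dbh, dtype=float)
    if dbh.size == 0:
        raise ValidationError("group is empty")
    if np.isnan(dbh).any():
        raise ValidationError("calibration selection requires dbh for every tree")
    if rng is None:
        rng = np.random.default_rng(strategy.seed)
    k = min(strategy.k, dbh.size)

    if strategy.kind == "smallest":
        return np.argsort(dbh, kind="stable")[:k]
    if strategy.kind == "largest":
        order = np.argsort(-dbh, kind="stable")
        return order[:k]
    if strategy.kind == "medium":
        lo = np.percentile(dbh, strategy.lower_pct)  # linear interpolation
        hi = np.percentile(dbh, strategy.upper_pct)
        eligible = np.flatnonzero((dbh > lo) & (dbh < hi))
        if eligible.size < k:
            warnings.warn(
                f"only {eligible.size} trees strictly between the "
                f"{strategy.lower_pct:g}th and {strategy.upper_pct:g}th percentiles; "
                f"returning all of them"
            )
            return eligible
        return rng.choice(eligible, size=k, replace=False)
    # random
    return rng.choice(dbh.size, size=k, replace=False)


def _calibration_subset(data: Dataset, kind: str, k: int,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Global record indices of calibration trees, per genotype."""
    frame = data.frame
    out = {}
    for g, ix in data.groups.items():
        strat = SamplingStrategy(kind=kind, k=k)
        local = select_calibration_trees(frame["dbh"].to_numpy()[ix], strat, rng=rng)
        out[g] = ix[np.asarray(local, dtype=int)]
    return out


def evaluate_strategies(fit: GenotypeMixedResults, data: Dataset,
                        kinds=STRATEGY_KINDS, k_range=range(1, 11),
                        seed: int = 0, repeats: int = 10,
                        scope: str = "non_calibration") -> pd.DataFrame:
    """Score every (sampling scheme, k) pair on ``data``.

    Stochastic schemes (medium, random) are averaged over ``repeats``
    seeded replicates; deterministic ones run once.  ``scope`` is
    ``"non_calibration"`` (default; calibration trees are excluded from
    scoring) or ``"all"``.
    """
    if scope not in ("non_calibration", "all"):
        raise ValidationError(f"unknown scope {scope!r}")
    frame = data.frame
    if frame["dbh"].isna().any():
        raise ValidationError("evaluation requires dbh for every record")
    dbh = frame["dbh"].to_numpy(dtype=float)
    smallest_group = min(len(ix) for ix in data.groups.values())

    rows = []
    for kind in kinds:
        stochastic = kind in ("medium", "random")
        for k in k_range:
            if k > smallest_group and scope == "non_calibration":
                logger.info("k=%d exceeds the smallest group (%d); clipped there",
                            k, smallest_group)
            reps = repeats if stochastic else 1
            metrics = []
            for rep in range(reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence((seed, STRATEGY_KINDS.index(kind), k, rep)))
                calib_ix = _calibration_subset(data, kind, k, rng)
                calib_map = {g: data.subset(ix) for g, ix in calib_ix.items()}
                result = eblup(fit, calib_map)
                pred = predict_dbh(fit, data, result)
                if scope == "non_calibration":
                    used = np.concatenate(list(calib_ix.values()))
                    mask = np.ones(len(data), dtype=bool)
                    mask[used] = False
                else:
                    mask = np.ones(len(data), dtype=bool)
                if mask.sum() < 2:
                    raise ValidationError(
                        f"k={k} leaves fewer than 2 evaluation trees under scope "
                        f"{scope!r}")
                metrics.append(fit_statistics(dbh[mask], pred[mask]))
            rows.append({
                "kind": kind, "k": k,
                "rmse": float(np.mean([m.rmse for m in metrics])),
                "r2": float(np.mean([m.r2 for m in metrics])),
                "tre": float(np.mean([m.tre for m in metrics])),
                "mean_error": float(np.mean([m.mean_error for m in metrics])),
                "n_eval": int(np.mean([m.n for m in metrics])),
                "repeats": reps, "scope": scope, "seed": seed,
            })
    return pd.DataFrame(rows)


def population_baseline(fit: GenotypeMixedResults, data: Dataset) -> FitStatistics:
    """Prediction statistics at u = 0 (no calibration)."""
    pred = predict_dbh(fit, data, None)
    return fit_statistics(data.frame["dbh"].to_numpy(dtype=float), pred)


@dataclass
class LoocvResult:
    per_fold: pd.DataFrame
    pooled: FitStatistics | None
    n_folds: int
    skipped: list


def loocv_by_genotype(data: Dataset, form: ModelForm,
                      re_config: RandomEffectConfig | tuple,
                      variance: VarianceSpec | str = "constant",
                      variance_covariate: str = "lh",
                      calibration_kind: str = "random", calibration_k: int = 2,
                      seed: int = 0, fast: bool = False,
                      global_fit: GenotypeMixedResults | None = None,
                      **fit_kwargs) -> LoocvResult:
    """Leave-one-genotype-out cross-validation.

    Each genotype in turn is held out; the mixed model is refit on the
    remaining genotypes (warm-started from a single global fit), the
    held-out genotype is calibrated on ``calibration_k`` trees chosen by
    ``calibration_kind`` (fold seed = ``seed`` + fold index), and its
    remaining trees are scored.  ``calibration_k=0`` scores the pure
    population-level prediction.  ``fast=True`` keeps the global fit's
    variance components and refits only the fixed effects per fold.
    """
    if data.n_genotypes < 3:
        raise ValidationError("need at least 3 genotypes for leave-one-genotype-out")
    frame = data.frame
    if frame["dbh"].isna().any():
        raise ValidationError("LOOCV requires dbh for every record")
    dbh = frame["dbh"].to_numpy(dtype=float)

    if global_fit is None:
        global_fit = GenotypeMixedModel(
            data, form, re_config, variance, variance_covariate).fit(**fit_kwargs)
    warm = dict(
        start=global_fit.params,
        start_psi=global_fit.psi,
        start_sigma=global_fit.sigma,
        start_gamma=global_fit.gamma if global_fit.variance.kind != "constant" else 0.5,
    )

    obs_all, pred_all = [], []
    fold_rows, skipped = [], []
    genotypes = data.genotype_ids
    for fold, g in enumerate(genotypes):
        test_ix = data.groups[g]
        train_ix = np.setdiff1d(np.arange(len(data)), test_ix)
        train = data.subset(train_ix)
        try:
            if fast:
                fold_fit = _refit_fixed_only(train, form, re_config, global_fit)
            else:
                fold_fit = GenotypeMixedModel(
                    train, form, re_config, variance, variance_covariate
                ).fit(**{**warm, **fit_kwargs})
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            logger.warning("fold %r skipped: %s", g, exc)
            skipped.append((g, str(exc)))
            continue

        rng = np.random.default_rng(seed + fold)
        if calibration_k > 0:
            strat = SamplingStrategy(kind=calibration_kind, k=calibration_k)
            local = select_calibration_trees(dbh[test_ix], strat, rng=rng)
            calib_global = test_ix[np.asarray(local, dtype=int)]
            calib = eblup(fold_fit, {g: data.subset(calib_global)})
            eval_ix = np.setdiff1d(test_ix, calib_global)
        else:
            calib = None
            eval_ix = test_ix
        if eval_ix.size == 0:
            skipped.append((g, "no evaluation trees left after calibration"))
            continue
        pred = predict_dbh(fold_fit, data.subset(eval_ix), calib)
        obs = dbh[eval_ix]
        obs_all.append(obs)
        pred_all.append(pred)
        row = {"genotype": g, "n_eval": int(eval_ix.size),
               "mean_error": float(np.mean(obs - pred)),
               "rmse_fold": float(np.sqrt(np.mean((obs - pred) ** 2)))}
        fold_rows.append(row)

    pooled = None
    if obs_all:
        pooled = fit_statistics(np.concatenate(obs_all), np.concatenate(pred_all))
    return LoocvResult(per_fold=pd.DataFrame(fold_rows), pooled=pooled,
                       n_folds=len(genotypes), skipped=skipped)


def _refit_fixed_only(train: Dataset, form: ModelForm, re_config,
                      global_fit: GenotypeMixedResults) -> GenotypeMixedResults:
    """Fast LOOCV mode: keep (Psi, sigma, gamma) from the global fit and
    re-estimate only beta and the training random effects by one PNLS pass."""
    model = GenotypeMixedModel(train, form, re_config,
                               global_fit.variance.kind, global_fit.variance.covariate)
    sigma2 = global_fit.sigma**2
    D = global_fit.psi / sigma2
    L = np.linalg.cholesky(D + 1e-12 * np.eye(model.q))
    beta0 = global_fit.fixed_effects.copy()
    u0 = np.zeros((model.M, model.q))
    beta, u = model._pnls(beta0, u0, L, global_fit.gamma)
    ranef = {g: u[i].copy() for i, g in enumerate(model.group_ids)}
    return GenotypeMixedResults(
        form=form, params=ModelParams.from_array(form, beta),
        re_config=model.re_config, psi=global_fit.psi,
        variance=global_fit.variance, ranef=ranef,
        llf=global_fit.llf, nobs=model.N, converged=True, model=model,
    )
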