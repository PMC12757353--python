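"""Synthetic genotype-structured stands with known ground truth.

The generator emulates the statistical structure the analysis assumes: ~78
genotypes of ~37 trees each, LiDAR height drawn from a truncated normal
matched to the field marginals (mean 3.97 m, SD 1.78 m, range 1.3-10.6 m),
LiDAR crown diameter linearly linked to height, a within-genotype block of
high-density trees, genotype random effects on the height exponents drawn
from the published Psi, and power-of-height residual heteroscedasticity.
Field H and CD are emitted through noisy linear links so that descriptive
summaries resemble real tables.  Ground truth (all latent u_i and the
generating parameters) is returned alongside the data for
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import Dataset
from .exceptions import ValidationError
from .forms import ModelForm, ModelParams, mean_function
from .mixed import RandomEffectConfig, VarianceSpec

# Field-measurement link constants (calibration constants of the generator,
# chosen so the emitted H and CD marginals and their R^2 against LH and LCD
# resemble the field tables: R^2 ~ 0.92 for H~LH, ~ 0.76 for CD~LCD).
_H_SLOPE, _H_INTERCEPT, _H_NOISE_SD = 0.8366, 0.369, 0.4295
_CD_SLOPE, _CD_INTERCEPT, _CD_NOISE_SD = 0.7748, 0.2134, 0.304


@lru_cache(maxsize=16)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Solve for (loc, scale) so the truncated normal on [lo, hi] has the
    requested mean and SD (the field table reports the observed moments of
    the already-range-limited sample, not the latent ones)."""

    def moments(x):
        loc, log_scale = x
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        dist = stats.truncnorm(a, b, loc=loc, scale=scale)
        return [dist.mean() - mean, dist.std() - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:
        raise ValidationError(
            f"cannot match a truncated normal on [{lo}, {hi}] to mean {mean}, sd {sd}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))

_DEFAULT_FIXED = ModelParams(a1=0.8403, b1=1.1829, b2=-0.1427, c1=0.2726)
_DEFAULT_PSI = ((7.763e-3, -4.857e-3), (-4.857e-3, 5.401e-3))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating process for one synthetic stand."""

    n_genotypes: int = 78
    trees_per_genotype: int | tuple[int, int] = 37
    high_density_fraction: float = 1.0 / 3.0  # one of three plots is 2m x 2m
    per_tree_density: bool = False
    lh_mean: float = 3.97
    lh_sd: float = 1.78
    lh_bounds: tuple[float, float] = (1.3, 10.6)
    # LCD ~ LH link: calibration constants giving LCD mean ~1.9 m with a
    # realistic height-crown correlation; understates the field LCD spread
    # (a documented limitation of the generator)
    lcd_intercept: float = 0.7
    lcd_slope: float = 0.3
    lcd_noise_sd: float = 0.45
    lcd_bounds: tuple[float, float] = (0.05, 6.0)
    form: ModelForm = field(default_factory=lambda: ModelForm("power", "on_b"))
    re_targets: tuple[str, ...] = ("b1", "b2")
    true_fixed: ModelParams = field(default_factory=lambda: _DEFAULT_FIXED)
    true_psi: tuple = _DEFAULT_PSI
    true_sigma: float = 0.3482
    true_gamma: float = 0.8415
    variance_kind: str = "power"
    variance_covariate: str = "lh"
    emit_field_measurements: bool = True
    dbh_floor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.high_density_fraction <= 1.0):
            raise ValidationError("high_density_fraction must be in [0, 1]")
        if self.lh_bounds[0] >= self.lh_bounds[1] or self.lcd_bounds[0] >= self.lcd_bounds[1]:
            raise ValidationError("truncation bounds must be ordered low < high")
        psi = np.asarray(self.true_psi, dtype=float)
        if np.linalg.eigvalsh(psi).min() < -1e-12:
            raise ValidationError("true_psi must be positive semi-definite")
        lo, hi = self.lh_bounds
        if not (lo < self.lh_mean + 6 * self.lh_sd and hi > self.lh_mean - 6 * self.lh_sd):
            raise ValidationError("lh truncation leaves (almost) empty support")

    @property
    def variance(self) -> VarianceSpec:
        return VarianceSpec(kind=self.variance_kind, covariate=self.variance_covariate,
                            sigma=self.true_sigma, gamma=self.true_gamma)


@dataclass
class StandTruth:
    """Latent state of a simulated stand."""

    config: SimulationConfig
    u: dict[str, np.ndarray]
    fixed: np.ndarray
    psi: np.ndarray
    sigma: float
    gamma: float

    def to_dict(self) -> dict:
        return {
            "u": {g: v.tolist() for g, v in self.u.items()},
            "fixed": self.fixed.tolist(),
            "psi": self.psi.tolist(),
            "sigma": self.sigma,
            "gamma": self.gamma,
        }


def simulate_stand(config: SimulationConfig | None = None,
                   seed: int | None = None,
                   **overrides) -> tuple[Dataset, StandTruth]:
    """Draw one synthetic stand; returns (Dataset, truth record).

    ``seed`` overrides ``config.seed`` when given.  Trees whose drawn DBH
    falls at or below ``dbh_floor`` have their residual redrawn (rejection,
    not clipping, so the variance function is not distorted); after 100
    attempts a :class:`ValidationError` is raised.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise ValidationError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    form = config.form
    fixed = config.true_fixed.to_array(form)
    psi = np.asarray(config.true_psi, dtype=float)
    q = len(config.re_targets)
    t_ix = RandomEffectConfig(targets=config.re_targets).indices(form)
    spec = config.variance

    lo, hi = config.lh_bounds
    # loc/scale matched so the *truncated* LH marginal has the target moments
    loc, scale = _truncnorm_params(config.lh_mean, config.lh_sd, lo, hi)
    a, b = (lo - loc) / scale, (hi - loc) / scale

    rows = []
    u_map: dict[str, np.ndarray] = {}
    width = len(str(config.n_genotypes))
    for gi in range(config.n_genotypes):
        g = f"G{gi + 1:0{width}d}"
        if isinstance(config.trees_per_genotype, int):
            n_g = config.trees_per_genotype
        else:
            lo_t, hi_t = config.trees_per_genotype
            n_g = int(rng.integers(lo_t, hi_t + 1))
        u_g = (rng.multivariate_normal(np.zeros(q), psi) if psi.any()
               else np.zeros(q))
        u_map[g] = u_g

        lh = stats.truncnorm.rvs(a, b, loc=loc, scale=scale,
                                 size=n_g, random_state=rng)
        lcd = np.clip(config.lcd_intercept + config.lcd_slope * lh
                      + rng.normal(0.0, config.lcd_noise_sd, size=n_g),
                      *config.lcd_bounds)
        if config.per_tree_density:
            p1 = (rng.random(n_g) < config.high_density_fraction).astype(int)
        else:
            n_high = int(round(config.high_density_fraction * n_g))
            p1 = np.zeros(n_g, dtype=int)
            p1[:n_high] = 1  # the genotype's high-density plot block

        theta = fixed.copy()
        theta[t_ix] += u_g
        mean = mean_function(form, theta, lh, lcd, p1)
        sd = spec.sigma * spec.sd_multipliers(lh if spec.covariate == "lh" else lcd)
        dbh = mean + rng.normal(0.0, 1.0, size=n_g) * sd
        bad = dbh <= config.dbh_floor
        attempts = 0
        while bad.any():
            attempts += 1
            if attempts > 100:
                raise ValidationError(
                    "could not draw positive DBH after 100 attempts; "
                    "generating parameters are inconsistent")
            dbh[bad] = mean[bad] + rng.normal(0.0, 1.0, size=int(bad.sum())) * sd[bad]
            bad = dbh <= config.dbh_floor

        if config.emit_field_measurements:
            h = np.maximum(_H_INTERCEPT + _H_SLOPE * lh
                           + rng.normal(0.0, _H_NOISE_SD, size=n_g), 0.31)
            cd = np.maximum(_CD_INTERCEPT + _CD_SLOPE * lcd
                            + rng.normal(0.0, _CD_NOISE_SD, size=n_g), 0.05)
        else:
            h = cd = np.full(n_g, np.nan)

        for j in range(n_g):
            rows.append({"genotype_id": g, "p1": int(p1[j]), "dbh": dbh[j],
                         "h": h[j], "cd": cd[j], "lh": lh[j], "lcd": lcd[j]})

    data = Dataset(pd.DataFrame(rows))
    truth = StandTruth(config=config, u=u_map, fixed=fixed, psi=psi,
                       sigma=spec.sigma, gamma=spec.gamma)
    return data, truth


_FIXTURES: Mapping[str, tuple[int, int, int]] = {
    # name -> (n_genotypes, trees_per_genotype, seed)
    "tiny": (3, 5, 101),
    "small": (10, 30, 202),
    "study_scale": (78, 37, 303),
}


def make_fixture(name: str, return_truth: bool = False):
    """Deterministic preset stands for tests and examples.

    ``tiny`` (3 genotypes x 5 trees), ``small`` (10 x 30) and
    ``study_scale`` (78 x 37, matching the scale of the original survey).
    """
    if name not in _FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    n_g, n_t, seed = _FIXTURES[name]
    config = SimulationConfig(n_genotypes=n_g, trees_per_genotype=n_t, seed=seed)
    data, truth = simulate_stand(config)
    return (data, truth) if return_truth else data
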