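"""Allometric mean functions and their analytic gradients.

Four base families relate DBH (cm) to LiDAR height LH and crown diameter
LCD (m):

    logistic     DBH = a1 / (1 + b1 exp(-(c1 LH + d1 LCD)))
    exponential  DBH = a1 exp(-b1 LH - c1 LCD)
    power        DBH = a1 LH^b1 LCD^c1
    richards     DBH = a1 (1 - exp(-b1 LH - c1 LCD))

The power family additionally supports a planting-density dummy P1 shifting
one coefficient:

    on_a  DBH = (a1 + a2 P1) LH^b1 LCD^c1
    on_b  DBH = a1 LH^(b1 + b2 P1) LCD^c1
    on_c  DBH = a1 LH^b1 LCD^(c1 + c2 P1)

The exponential (decaying) and richards forms are used exactly as written;
the exponential's coefficients may fit negative to describe growth, and the
richards form carries no shape exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .exceptions import ValidationError

FAMILIES = ("logistic", "exponential", "power", "richards")
DUMMY_SLOTS = ("none", "on_a", "on_b", "on_c")

_BASE_PARAMS = {
    "logistic": ("a1", "b1", "c1", "d1"),
    "exponential": ("a1", "b1", "c1"),
    "power": ("a1", "b1", "c1"),
    "richards": ("a1", "b1", "c1"),
}
_DUMMY_PARAM = {"on_a": "a2", "on_b": "b2", "on_c": "c2"}
# dummy coefficient sits right after the base coefficient it shifts
_DUMMY_ORDER = {
    "on_a": ("a1", "a2", "b1", "c1"),
    "on_b": ("a1", "b1", "b2", "c1"),
    "on_c": ("a1", "b1", "c1", "c2"),
}


@dataclass(frozen=True)
class ModelForm:
    """A mean-function family plus an optional density-dummy slot."""

    family: str = "power"
    dummy_slot: str = "none"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.dummy_slot not in DUMMY_SLOTS:
            raise ValidationError(f"unknown dummy_slot {self.dummy_slot!r}")
        if self.dummy_slot != "none" and self.family != "power":
            raise ValidationError("dummy extensions are defined for the power family only")

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.dummy_slot == "none":
            return _BASE_PARAMS[self.family]
        return _DUMMY_ORDER[self.dummy_slot]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def label(self) -> str:
        if self.dummy_slot == "none":
            return self.family
        return f"{self.family}-dummy-{self.dummy_slot}"


@dataclass(frozen=True)
class ModelParams:
    """Named coefficient set; only the fields of the chosen form are used."""

    a1: float | None = None
    b1: float | None = None
    c1: float | None = None
    d1: float | None = None
    a2: float | None = None
    b2: float | None = None
    c2: float | None = None

    @classmethod
    def from_array(cls, form: ModelForm, values) -> "ModelParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (form.n_params,):
            raise ValidationError(
                f"expected {form.n_params} values for {form.label()}, got shape {values.shape}"
            )
        return cls(**dict(zip(form.param_names, values.tolist())))

    def to_array(self, form: ModelForm) -> np.ndarray:
        out = []
        for name in form.param_names:
            v = getattr(self, name)
            if v is None:
                raise ValidationError(f"params incomplete for {form.label()}: missing {name}")
            out.append(float(v))
        return np.asarray(out)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) is not None}


def _pow_safe(base: np.ndarray, expo: np.ndarray) -> np.ndarray:
    """base**expo with base >= 0, defining 0^0 = 1 and 0^positive = 0."""
    base = np.asarray(base, dtype=float)
    expo = np.broadcast_to(np.asarray(expo, dtype=float), base.shape)
    out = np.empty_like(base)
    pos = base > 0
    out[pos] = base[pos] ** expo[pos]
    z = ~pos
    out[z & (expo == 0)] = 1.0
    out[z & (expo > 0)] = 0.0
    out[z & (expo < 0)] = np.inf
    return out


def _as_arrays(lh, lcd, p1):
    lh = np.atleast_1d(np.asarray(lh, dtype=float))
    lcd = np.atleast_1d(np.asarray(lcd, dtype=float))
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    lh, lcd, p1 = np.broadcast_arrays(lh, lcd, p1)
    if (lh <= 0).any():
        raise ValidationError("lh must be positive")
    if (lcd < 0).any():
        raise ValidationError("lcd must be non-negative")
    return lh, lcd, p1


def mean_function(form: ModelForm, theta, lh, lcd, p1=0) -> np.ndarray:
    """Deterministic mean DBH at coefficient vector ``theta`` (form order)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (form.n_params,):
        raise ValidationError(f"theta must have {form.n_params} entries for {form.label()}")
    lh, lcd, p1 = _as_arrays(lh, lcd, p1)
    fam, slot = form.family, form.dummy_slot

    if fam == "logistic":
        a, b, c, d = theta
        return a / (1.0 + b * np.exp(-(c * lh + d * lcd)))
    if fam == "exponential":
        a, b, c = theta
        return a * np.exp(-b * lh - c * lcd)
    if fam == "richards":
        a, b, c = theta
        return a * (1.0 - np.exp(-b * lh - c * lcd))

    # power family
    if slot == "none":
        a, b, c = theta
        a_eff, b_eff, c_eff = a, b, np.full_like(lh, c)
    elif slot == "on_a":
        a, a2, b, c = theta
        a_eff, b_eff, c_eff = a + a2 * p1, b, np.full_like(lh, c)
    elif slot == "on_b":
        a, b, b2, c = theta
        a_eff, b_eff, c_eff = a, b + b2 * p1, np.full_like(lh, c)
    else:  # on_c
        a, b, c, c2 = theta
        a_eff, b_eff, c_eff = a, b, c + c2 * p1
    return a_eff * lh**b_eff * _pow_safe(lcd, c_eff)


def mean_gradient(form: ModelForm, theta, lh, lcd, p1=0) -> np.ndarray:
    """(n, p) matrix of partial derivatives of the mean w.r.t. each coefficient.

    Analytic for every family.  For the power family with lcd = 0 the
    derivative w.r.t. the LCD exponent is taken as 0 (the mean is
    identically 0 there).
    """
    theta = np.asarray(theta, dtype=float)
    lh, lcd, p1 = _as_arrays(lh, lcd, p1)
    f = mean_function(form, theta, lh, lcd, p1)
    fam, slot = form.family, form.dummy_slot
    n = lh.size

    if fam == "logistic":
        a, b, c, d = theta
        E = np.exp(-(c * lh + d * lcd))
        den = 1.0 + b * E
        g = np.empty((n, 4))
        g[:, 0] = 1.0 / den
        g[:, 1] = -a * E / den**2
        g[:, 2] = a * b * E * lh / den**2
        g[:, 3] = a * b * E * lcd / den**2
        return g
    if fam == "exponential":
        a = theta[0]
        g = np.empty((n, 3))
        g[:, 0] = f / a if a != 0 else np.exp(-theta[1] * lh - theta[2] * lcd)
        g[:, 1] = -f * lh
        g[:, 2] = -f * lcd
        return g
    if fam == "richards":
        a, b, c = theta
        E = np.exp(-b * lh - c * lcd)
        g = np.empty((n, 3))
        g[:, 0] = 1.0 - E
        g[:, 1] = a * E * lh
        g[:, 2] = a * E * lcd
        return g

    # power family; ln(lcd) contribution vanishes where lcd == 0 (f = 0)
    loglh = np.log(lh)
    loglcd = np.where(lcd > 0, np.log(np.where(lcd > 0, lcd, 1.0)), 0.0)
    if slot == "none":
        a = theta[0]
        g = np.empty((n, 3))
        g[:, 0] = f / a if a != 0 else lh ** theta[1] * _pow_safe(lcd, theta[2])
        g[:, 1] = f * loglh
        g[:, 2] = f * loglcd
        return g
    if slot == "on_a":
        a, a2 = theta[0], theta[1]
        base = lh ** theta[2] * _pow_safe(lcd, theta[3])
        g = np.empty((n, 4))
        g[:, 0] = base
        g[:, 1] = base * p1
        g[:, 2] = f * loglh
        g[:, 3] = f * loglcd
        return g
    if slot == "on_b":
        a = theta[0]
        g = np.empty((n, 4))
        g[:, 0] = f / a if a != 0 else 0.0
        g[:, 1] = f * loglh
        g[:, 2] = f * loglh * p1
        g[:, 3] = f * loglcd
        return g
    # on_c
    a = theta[0]
    g = np.empty((n, 4))
    g[:, 0] = f / a if a != 0 else 0.0
    g[:, 1] = f * loglh
    g[:, 2] = f * loglcd
    g[:, 3] = f * loglcd * p1
    return g


def predict_mean(form: ModelForm, params: ModelParams, lh, lcd, p1=0):
    """Public mean prediction; scalar in, scalar out."""
    theta = params.to_array(form)
    if form.family == "power" and form.dummy_slot == "none" and theta[0] <= 0:
        raise ValidationError("power-family scale coefficient a1 must be positive")
    scalar = np.isscalar(lh) and np.isscalar(lcd)
    out = mean_function(form, theta, lh, lcd, p1)
    return float(out[0]) if scalar and out.size == 1 else out
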