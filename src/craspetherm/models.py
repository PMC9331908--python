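"""Thermal performance curve (TPC) model catalog.

The centrepiece is the Boatman sine-family model

    rate(T) = r_max * [sin(pi * u**a)]**b,   u = (T - t_min) / (t_max - t_min)

with ``u`` clipped to [0, 1] so the rate is exactly zero at and beyond the
critical temperatures.  ``a`` skews the curve (a > 1 shifts the optimum
towards t_max, the usual left-skewed ectotherm shape) and ``b`` sharpens or
flattens the peak.  The analytic optimum is

    T_opt = t_min + (t_max - t_min) * (1/2)**(1/a)

independent of ``b`` (the sine attains 1 at u**a = 1/2 regardless of the
outer power).

Alongside it the module ships a battery of standard published TPC forms
(gaussian, quadratic, Briere-2, Lactin-2, Ratkowsky, Weibull,
Sharpe-Schoolfield high-temperature) so that information-criterion model
selection can be exercised.  Every model is wrapped in a :class:`ModelSpec`
exposing a uniform evaluate / bounds / start-value contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "BoatmanParams",
    "ModelSpec",
    "evaluate_boatman",
    "boatman_topt",
    "model_catalog",
    "get_model",
    "catalog_json",
]

# Boltzmann constant in eV/K, used by the Sharpe-Schoolfield model.
_K_EV = 8.617333262e-5
# Reference temperature (degC) at which the Sharpe-Schoolfield rate
# parameter is anchored.
_SS_TREF = 20.0


@dataclass(frozen=True)
class BoatmanParams:
    """Parameters of the Boatman sine-family TPC.

    r_max : maximal activity rate (pulsations min^-1), > 0
    t_min, t_max : lower/upper critical temperatures (degC), t_max > t_min
    a : skewness shape parameter, > 0
    b : kurtosis shape parameter, > 0
    """

    r_max: float
    t_min: float
    t_max: float
    a: float
    b: float

    def __post_init__(self):
        vals = (self.r_max, self.t_min, self.t_max, self.a, self.b)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite Boatman parameter in {vals}")
        if self.r_max <= 0:
            raise InvalidInputError(f"r_max must be > 0, got {self.r_max}")
        if self.t_max <= self.t_min:
            raise InvalidInputError(
                f"t_max ({self.t_max}) must exceed t_min ({self.t_min})"
            )
        if self.a <= 0 or self.b <= 0:
            raise InvalidInputError(f"shape parameters must be > 0, got a={self.a}, b={self.b}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_max, self.t_min, self.t_max, self.a, self.b])


def evaluate_boatman(params: BoatmanParams, temperature) -> np.ndarray | float:
    """Boatman rate at one or many temperatures (degC).

    Zero at and beyond the critical temperatures; bounded by [0, r_max].
    """
    if not isinstance(params, BoatmanParams):
        params = BoatmanParams(*params)
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("temperature must be finite")
    rate = _boatman_eval(params.as_array(), t)
    if np.isscalar(temperature) or t.ndim == 0:
        return float(rate)
    return rate


def _boatman_eval(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    r_max, t_min, t_max, a, b = theta
    u = (t - t_min) / (t_max - t_min)
    inside = (u > 0.0) & (u < 1.0)
    u = np.clip(u, 0.0, 1.0)
    s = np.sin(np.pi * u**a)
    # sin(pi) leaves ~1e-16 residue which b < 1 would amplify; the rate is
    # exactly zero at and beyond the critical temperatures by definition
    s = np.clip(s, 0.0, 1.0)
    return np.where(inside, r_max * s**b, 0.0)


def boatman_topt(params: BoatmanParams) -> float:
    """Analytic optimum temperature of the Boatman curve (degC)."""
    if not isinstance(params, BoatmanParams):
        params = BoatmanParams(*params)
    return params.t_min + (params.t_max - params.t_min) * 0.5 ** (1.0 / params.a)


def _boatman_topt_theta(theta: np.ndarray) -> float:
    _, t_min, t_max, a, _ = theta
    return float(t_min + (t_max - t_min) * 0.5 ** (1.0 / a))


def _boatman_eval_batch(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate B parameter vectors (B, 5) on matching temperatures (B, n)."""
    r_max, t_min, t_max, a, b = (theta[:, i][:, None] for i in range(5))
    u = (t - t_min) / (t_max - t_min)
    inside = (u > 0.0) & (u < 1.0)
    u = np.clip(u, 0.0, 1.0)
    s = np.clip(np.sin(np.pi * u**a), 0.0, 1.0)
    return np.where(inside, r_max * s**b, 0.0)


def _boatman_jac_batch(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Analytic Jacobian for batched fits: (B, n, 5), orders as param_names.

    Partials are taken as 0 in the clipped (zero-rate) region and guarded
    where sin -> 0 so negative powers stay finite.
    """
    r_max, t_min, t_max, a, b = (theta[:, i][:, None] for i in range(5))
    d = t_max - t_min
    u = (t - t_min) / d
    interior = (u > 1e-12) & (u < 1.0 - 1e-12)
    u_safe = np.clip(u, 1e-12, 1.0 - 1e-12)
    w = u_safe**a
    s = np.sin(np.pi * w)
    s_safe = np.clip(s, 1e-300, 1.0)
    c = np.cos(np.pi * w)
    sb = s_safe**b
    # common factor of all shape/temperature partials
    g = r_max * b * s_safe ** (b - 1.0) * np.pi * c
    dw_da = w * np.log(u_safe)
    dw_du = a * w / u_safe
    du_dtmin = (u_safe - 1.0) / d
    du_dtmax = -u_safe / d
    jac = np.empty(t.shape + (5,))
    jac[..., 0] = np.where(interior, sb, 0.0)
    jac[..., 1] = np.where(interior, g * dw_du * du_dtmin, 0.0)
    jac[..., 2] = np.where(interior, g * dw_du * du_dtmax, 0.0)
    jac[..., 3] = np.where(interior, g * dw_da, 0.0)
    jac[..., 4] = np.where(interior, r_max * sb * np.log(s_safe), 0.0)
    return jac


@dataclass(frozen=True)
class ModelSpec:
    """Uniform wrapper around one battery member.

    ``evaluate(theta, temps)`` returns finite, non-negative rates for any
    in-bounds parameter vector and finite temperatures.  ``bounds`` /
    ``start`` accept the observed data so box constraints and the heuristic
    start vector can adapt to its scale; called with no data they fall back
    to generic defaults (rates up to 150, temperatures 2-28 degC).
    """

    model_id: str
    param_names: tuple
    _evaluate: Callable = field(repr=False)
    _bounds: Callable = field(repr=False)
    _start: Callable = field(repr=False)
    # analytic optimum, if the form has one (used to avoid grid searches)
    topt_fn: Optional[Callable] = field(default=None, repr=False)
    # names of explicit critical-temperature parameters, if any
    ct_param_names: Optional[tuple] = None
    # batched evaluate (B, k) x (B, n) -> (B, n) and matching analytic
    # Jacobian (B, n, k); present only where a fast bootstrap path exists
    eval_batch: Optional[Callable] = field(default=None, repr=False)
    jac_batch: Optional[Callable] = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def evaluate(self, theta, temps):
        theta = np.asarray(theta, dtype=float)
        t = np.asarray(temps, dtype=float)
        if theta.shape != (self.n_params,):
            raise InvalidInputError(
                f"{self.model_id} expects {self.n_params} parameters, got shape {theta.shape}"
            )
        with np.errstate(over="ignore", invalid="ignore", under="ignore"):
            rate = self._evaluate(theta, t)
        rate = np.nan_to_num(rate, nan=0.0, posinf=0.0, neginf=0.0)
        return np.clip(rate, 0.0, None)

    def bounds(self, temps=None, rates=None):
        temps, rates = _default_data(temps, rates)
        return self._bounds(np.asarray(temps, float), np.asarray(rates, float))

    def start(self, temps=None, rates=None):
        temps, rates = _default_data(temps, rates)
        return np.asarray(self._start(np.asarray(temps, float), np.asarray(rates, float)), float)


def _default_data(temps, rates):
    if temps is None:
        temps = np.array([2.0, 28.0])
    if rates is None:
        rates = np.array([0.0, 150.0])
    return temps, rates


# ---------------------------------------------------------------------------
# battery member definitions


def _boatman_bounds(t, r):
    rmax = max(r.max(), 1e-6)
    return [
        (1e-6, 10.0 * rmax),
        (-20.0, float(t.min())),
        (float(t.max()), 60.0),
        (1e-3, 20.0),
        (1e-3, 20.0),
    ]


def _boatman_start(t, r):
    return [max(r.max(), 1.0), t.min() - 2.0, t.max() + 2.0, 1.0, 1.0]


def _gaussian_eval(theta, t):
    rmax, topt, sigma = theta
    return rmax * np.exp(-0.5 * ((t - topt) / sigma) ** 2)


def _gaussian_bounds(t, r):
    rmax = max(r.max(), 1e-6)
    return [(1e-6, 10.0 * rmax), (t.min() - 10.0, t.max() + 10.0), (0.1, 40.0)]


def _gaussian_start(t, r):
    return [max(r.max(), 1.0), float(t[np.argmax(r)]), (t.max() - t.min()) / 2.0 + 0.5]


def _quadratic_eval(theta, t):
    c0, c1, c2 = theta
    return c0 + c1 * t + c2 * t * t


def _quadratic_bounds(t, r):
    rmax = max(r.max(), 1.0)
    return [(-100.0 * rmax, 100.0 * rmax), (-50.0 * rmax, 50.0 * rmax), (-10.0 * rmax, -1e-9)]


def _quadratic_start(t, r):
    # concave parabola peaking at the observed maximum
    tm = float(t[np.argmax(r)])
    c2 = -max(r.max(), 1.0) / max((t.max() - t.min()) ** 2, 1.0)
    c1 = -2.0 * c2 * tm
    c0 = r.max() - c1 * tm - c2 * tm * tm
    return [c0, c1, c2]


def _briere2_eval(theta, t):
    a, t_min, t_max, b = theta
    span = np.clip(t - t_min, 0.0, None) * np.clip(t_max - t, 0.0, None) ** (1.0 / b)
    return a * t * span


def _briere2_bounds(t, r):
    rmax = max(r.max(), 1e-6)
    return [(1e-9, rmax), (-20.0, float(t.min())), (float(t.max()), 60.0), (0.1, 20.0)]


def _briere2_start(t, r):
    t_min, t_max = t.min() - 2.0, t.max() + 2.0
    tm = float(t[np.argmax(r)])
    denom = max(tm * (tm - t_min) * max(t_max - tm, 0.1) ** 0.5, 1e-6)
    return [max(r.max(), 1.0) / denom, t_min, t_max, 2.0]


def _lactin2_eval(theta, t):
    a, t_max, delta, b = theta
    return np.exp(a * t) - np.exp(a * t_max - (t_max - t) / delta) + b


def _lactin2_bounds(t, r):
    return [(1e-4, 0.5), (float(t.max()), 60.0), (0.1, 60.0), (-60.0, 60.0)]


def _lactin2_start(t, r):
    return [np.log(max(r.max(), 2.0)) / max(t.max(), 1.0), t.max() + 2.0, 5.0, 0.0]


def _ratkowsky_eval(theta, t):
    a, b, t_min, t_max = theta
    inside = (t > t_min) & (t < t_max)
    core = a * (t - t_min) * (1.0 - np.exp(b * (t - t_max)))
    return np.where(inside, core * core, 0.0)


def _ratkowsky_bounds(t, r):
    return [(1e-6, 100.0), (1e-4, 5.0), (-20.0, float(t.min())), (float(t.max()), 60.0)]


def _ratkowsky_start(t, r):
    t_min, t_max = t.min() - 2.0, t.max() + 2.0
    a = math.sqrt(max(r.max(), 1.0)) / max(t_max - t_min, 1.0)
    return [a, 0.3, t_min, t_max]


def _weibull_eval(theta, t):
    a, topt, b, c = theta
    f = (c - 1.0) / c
    z = (t - topt) / b + f ** (1.0 / c)
    z = np.clip(z, 0.0, None)
    return a * f ** (-f) * z ** (c - 1.0) * np.exp(-(z**c) + f)


def _weibull_bounds(t, r):
    rmax = max(r.max(), 1e-6)
    return [(1e-6, 10.0 * rmax), (t.min() - 10.0, t.max() + 10.0), (0.5, 60.0), (1.01, 20.0)]


def _weibull_start(t, r):
    return [max(r.max(), 1.0), float(t[np.argmax(r)]), (t.max() - t.min()) / 2.0 + 0.5, 2.0]


def _sharpeschoolhigh_eval(theta, t):
    r_tref, e, eh, th = theta
    inv_ref = 1.0 / (_SS_TREF + 273.15)
    inv_t = 1.0 / (t + 273.15)
    rise = r_tref * np.exp(e / _K_EV * (inv_ref - inv_t))
    inact = 1.0 + np.exp(eh / _K_EV * (1.0 / (th + 273.15) - inv_t))
    return rise / inact


def _sharpeschoolhigh_bounds(t, r):
    rmax = max(r.max(), 1e-6)
    return [(1e-6, 10.0 * rmax), (0.01, 4.0), (0.02, 30.0), (0.0, 60.0)]


def _sharpeschoolhigh_start(t, r):
    ref_rate = float(np.interp(_SS_TREF, t, r)) if t.min() <= _SS_TREF <= t.max() else r.max() / 2.0
    return [max(ref_rate, 0.5), 0.6, 3.0, t.max()]


def _make_catalog() -> list:
    specs = [
        ModelSpec(
            "boatman_2017",
            ("r_max", "t_min", "t_max", "a", "b"),
            _boatman_eval,
            _boatman_bounds,
            _boatman_start,
            topt_fn=_boatman_topt_theta,
            ct_param_names=("t_min", "t_max"),
            eval_batch=_boatman_eval_batch,
            jac_batch=_boatman_jac_batch,
        ),
        ModelSpec(
            "gaussian",
            ("r_max", "t_opt", "sigma"),
            _gaussian_eval,
            _gaussian_bounds,
            _gaussian_start,
            topt_fn=lambda theta: float(theta[1]),
        ),
        ModelSpec(
            "quadratic",
            ("c0", "c1", "c2"),
            _quadratic_eval,
            _quadratic_bounds,
            _quadratic_start,
            topt_fn=lambda theta: float(-theta[1] / (2.0 * theta[2])),
        ),
        ModelSpec(
            "briere2",
            ("a", "t_min", "t_max", "b"),
            _briere2_eval,
            _briere2_bounds,
            _briere2_start,
            ct_param_names=("t_min", "t_max"),
        ),
        ModelSpec(
            "lactin2",
            ("a", "t_max", "delta", "b"),
            _lactin2_eval,
            _lactin2_bounds,
            _lactin2_start,
        ),
        ModelSpec(
            "ratkowsky",
            ("a", "b", "t_min", "t_max"),
            _ratkowsky_eval,
            _ratkowsky_bounds,
            _ratkowsky_start,
            ct_param_names=("t_min", "t_max"),
        ),
        ModelSpec(
            "weibull",
            ("a", "t_opt", "b", "c"),
            _weibull_eval,
            _weibull_bounds,
            _weibull_start,
        ),
        ModelSpec(
            "sharpe_schoolfield_high",
            ("r_tref", "e", "eh", "th"),
            _sharpeschoolhigh_eval,
            _sharpeschoolhigh_bounds,
            _sharpeschoolhigh_start,
        ),
    ]
    return specs


_CATALOG = _make_catalog()
_BY_ID = {m.model_id: m for m in _CATALOG}


def model_catalog() -> list:
    """The full model battery (boatman_2017 always first)."""
    return list(_CATALOG)


def get_model(model_id: str) -> ModelSpec:
    try:
        return _BY_ID[model_id]
    except KeyError:
        raise InvalidInputError(
            f"unknown model {model_id!r}; available: {sorted(_BY_ID)}"
        ) from None


def catalog_json() -> str:
    """JSON document describing the battery (ids, parameter names, generic bounds)."""
    doc = [
        {
            "model_id": m.model_id,
            "param_names": list(m.param_names),
            "bounds": [list(bl) for bl in m.bounds()],
        }
        for m in _CATALOG
    ]
    return json.dumps(doc, indent=2)
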