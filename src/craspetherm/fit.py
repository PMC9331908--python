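"""Bounded multi-start nonlinear least-squares TPC fitting and AIC ranking.

Each model in the battery is fitted by scipy's trust-region-reflective
least-squares from ``n_starts`` start vectors (one data-informed heuristic
plus seeded uniform draws within the box constraints); the best residual sum
of squares wins.  Models are then ranked by the Gaussian-likelihood AIC,

    AIC = n ln(2 pi RSS / n) + n + 2 (k + 1),

which counts the error variance as an estimated parameter so rankings remain
comparable across models of different dimension.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    NonConvergenceError,
)
from .models import ModelSpec, get_model

__all__ = [
    "ActivityDataset",
    "FitResult",
    "ModelComparison",
    "fit_model",
    "gaussian_aic",
    "compare_models",
]

# interval on which derived traits (T_opt, CT_min, CT_max) are searched
_TRAIT_SEARCH = (-20.0, 60.0)
# a fitted curve is "zero" below this fraction of its maximum
_CT_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ActivityDataset:
    """Paired (temperature degC, activity rate pulsations min^-1) records."""

    temperatures: np.ndarray
    rates: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise InvalidInputError("temperatures and rates must be 1-D arrays of equal length")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(r)):
            raise InvalidInputError("non-finite temperature or rate in dataset")
        if np.any(r < 0):
            raise InvalidInputError("negative activity rate in dataset")
        if np.unique(t).size < 2:
            raise InvalidInputError("need at least 2 distinct temperatures")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "rates", r)

    @property
    def n(self) -> int:
        return self.temperatures.size

    @classmethod
    def from_csv(cls, path, label: Optional[str] = None) -> "ActivityDataset":
        """Read a two-column CSV with header ``temperature,rate``."""
        df = pd.read_csv(path)
        missing = {"temperature", "rate"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"{path}: missing column(s) {sorted(missing)}")
        return cls(df["temperature"].to_numpy(), df["rate"].to_numpy(),
                   label=label if label is not None else str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame({"temperature": self.temperatures, "rate": self.rates}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class FitResult:
    """One fitted model with diagnostics and derived thermal traits."""

    model_id: str
    theta_hat: np.ndarray
    rss: float
    n: int
    k: int
    aic: float
    converged: bool
    t_opt: float
    r_max_hat: float
    ct_min: Optional[float]
    ct_max: Optional[float]
    n_starts: int = 0
    n_converged: int = 0

    @property
    def model(self) -> ModelSpec:
        return get_model(self.model_id)

    def predict(self, temperatures):
        """Fitted rate at one or many temperatures (degC)."""
        t = np.asarray(temperatures, dtype=float)
        out = self.model.evaluate(self.theta_hat, t)
        return float(out) if t.ndim == 0 else out

    def params_by_name(self) -> dict:
        return dict(zip(self.model.param_names, (float(v) for v in self.theta_hat)))

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "theta_hat": self.params_by_name(),
            "rss": self.rss,
            "n": self.n,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "t_opt": self.t_opt,
            "r_max_hat": self.r_max_hat,
            "ct_min": self.ct_min,
            "ct_max": self.ct_max,
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
        }


@dataclass(frozen=True)
class ModelComparison:
    """Battery fits ranked by AIC (ascending); failures listed, not dropped."""

    rows: tuple
    failures: tuple = ()

    @property
    def delta_aic(self) -> np.ndarray:
        aics = np.array([r.aic for r in self.rows])
        return aics - aics[0]

    @property
    def best(self) -> FitResult:
        return self.rows[0]

    def to_dict(self) -> dict:
        delta = self.delta_aic
        return {
            "rows": [
                {**r.to_dict(), "delta_aic": float(d)} for r, d in zip(self.rows, delta)
            ],
            "failures": [
                {"model_id": mid, "error": msg} for mid, msg in self.failures
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC with the error variance counted as a parameter.

    Returns ``-inf`` (with a warning) for a perfect fit (rss = 0).
    """
    if rss < 0 or n <= 0 or k < 1:
        raise InvalidInputError(f"invalid AIC inputs rss={rss}, n={n}, k={k}")
    if rss == 0:
        warnings.warn("rss=0: perfect fit, AIC is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (k + 1)


def _starts_matrix(model, dataset, n_starts, seed):
    lo, hi = zip(*model.bounds(dataset.temperatures, dataset.rates))
    lo = np.asarray(lo)
    hi = np.asarray(hi)
    heur = np.clip(model.start(dataset.temperatures, dataset.rates), lo, hi)
    rng = np.random.default_rng(seed)
    extra = rng.uniform(lo, hi, size=(max(n_starts - 1, 0), lo.size))
    return np.vstack([heur[None, :], extra]), (lo, hi)


def fit_model(
    dataset: ActivityDataset,
    model: ModelSpec | str,
    n_starts: int = 50,
    seed: int = 0,
    xtol: float = 1e-10,
    max_nfev: int = 10_000,
) -> FitResult:
    """Fit one model by bounded multi-start least squares.

    Deterministic for fixed (dataset, model, n_starts, seed).  Raises
    :class:`InsufficientDataError` when n < k + 2 and
    :class:`NonConvergenceError` when no start converges.
    """
    if isinstance(model, str):
        model = get_model(model)
    if n_starts < 1:
        raise InvalidInputError("n_starts must be >= 1")
    if dataset.n < model.n_params + 2:
        raise InsufficientDataError(
            f"{model.model_id} needs at least {model.n_params + 2} observations, "
            f"dataset has {dataset.n}"
        )

    t, r = dataset.temperatures, dataset.rates

    def residuals(theta):
        return model.evaluate(theta, t) - r

    starts, (lo, hi) = _starts_matrix(model, dataset, n_starts, seed)
    best = None
    best_rss = np.inf
    n_conv = 0
    diagnostics = []
    for x0 in starts:
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore", RuntimeWarning)
                sol = least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf",
                    xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=max_nfev,
                )
        except Exception as exc:  # singular jacobians etc.
            diagnostics.append({"start": x0.tolist(), "status": -99, "message": str(exc)})
            continue
        diagnostics.append({"start": x0.tolist(), "status": sol.status, "message": sol.message})
        if sol.status <= 0:
            continue
        n_conv += 1
        rss = float(2.0 * sol.cost)
        if rss < best_rss:
            best_rss = rss
            best = sol
    if best is None:
        raise NonConvergenceError(
            f"no start converged for {model.model_id}", diagnostics=diagnostics
        )

    theta = best.x
    t_opt = _find_topt(model, theta)
    r_max_hat = float(model.evaluate(theta, np.array(t_opt)))
    ct_min, ct_max = _find_ct(model, theta, t_opt, r_max_hat)
    aic = gaussian_aic(best_rss, dataset.n, model.n_params) if best_rss > 0 else -math.inf
    if best_rss == 0:
        warnings.warn("rss=0: perfect fit, AIC is -inf", RuntimeWarning, stacklevel=2)
    return FitResult(
        model_id=model.model_id,
        theta_hat=theta,
        rss=best_rss,
        n=dataset.n,
        k=model.n_params,
        aic=aic,
        converged=True,
        t_opt=t_opt,
        r_max_hat=r_max_hat,
        ct_min=ct_min,
        ct_max=ct_max,
        n_starts=n_starts,
        n_converged=n_conv,
    )


def _find_topt(model: ModelSpec, theta: np.ndarray, coarse: int = 2001) -> float:
    """Argmax of the fitted curve on the trait search interval.

    Uses the model's analytic optimum when available, otherwise a coarse
    grid followed by bounded scalar refinement.
    """
    if model.topt_fn is not None:
        return float(model.topt_fn(theta))
    lo, hi = _TRAIT_SEARCH
    grid = np.linspace(lo, hi, coarse)
    vals = model.evaluate(theta, grid)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, coarse - 1)]
    res = minimize_scalar(
        lambda x: -float(model.evaluate(theta, np.array(x))),
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _find_ct(model, theta, t_opt, r_max_hat):
    """Critical temperatures where the fitted curve reaches zero.

    Models that carry explicit critical-temperature parameters report them
    directly; otherwise the outermost crossings of 1e-3 * r_max_hat on the
    search interval are located by bisection.  ``None`` marks a side where
    the curve never falls to zero within the interval.
    """
    if model.ct_param_names is not None:
        names = list(model.param_names)
        vals = [float(theta[names.index(p)]) for p in model.ct_param_names]
        return min(vals), max(vals)
    if r_max_hat <= 0:
        return None, None
    thresh = _CT_THRESHOLD * r_max_hat
    lo, hi = _TRAIT_SEARCH

    def below(x):
        return float(model.evaluate(theta, np.array(x))) < thresh

    ct_min = _bisect_edge(model, theta, thresh, lo, t_opt, side="min") if below(lo) else None
    ct_max = _bisect_edge(model, theta, thresh, t_opt, hi, side="max") if below(hi) else None
    return ct_min, ct_max


def _bisect_edge(model, theta, thresh, a, b, side, iters=60):
    # invariant: curve >= thresh at the t_opt end, < thresh at the far end
    for _ in range(iters):
        m = 0.5 * (a + b)
        val = float(model.evaluate(theta, np.array(m)))
        if side == "min":
            if val < thresh:
                a = m
            else:
                b = m
        else:
            if val < thresh:
                b = m
            else:
                a = m
    return 0.5 * (a + b)


def compare_models(
    dataset: ActivityDataset,
    models: Sequence[ModelSpec | str],
    n_starts: int = 50,
    seed: int = 0,
) -> ModelComparison:
    """Fit every model and rank by AIC (ties: smaller k, then model_id)."""
    if not models:
        raise InvalidInputError("models list must be non-empty")
    rows = []
    failures = []
    for m in models:
        spec = get_model(m) if isinstance(m, str) else m
        try:
            rows.append(fit_model(dataset, spec, n_starts=n_starts, seed=seed))
        except (NonConvergenceError, InsufficientDataError) as exc:
            failures.append((spec.model_id, str(exc)))
    if not rows:
        raise NonConvergenceError("all models failed to converge or were inadmissible")
    rows.sort(key=lambda r: (r.aic, r.k, r.model_id))
    return ModelComparison(rows=tuple(rows), failures=tuple(failures))
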