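"""Bootstrap inference around a fitted TPC.

Case resampling (the default) redraws (temperature, rate) pairs with
replacement; residual resampling redraws centered residuals and adds them to
the fitted values.  Every replicate is refitted by bounded least squares
starting from the original point estimate, giving percentile confidence
intervals for the derived traits (T_opt, r_max) and a percentile prediction
band for the curve itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .errors import BootstrapFailureError, InvalidInputError
from .fit import ActivityDataset, FitResult, _find_topt
from .models import ModelSpec, get_model

__all__ = ["BootstrapResult", "bootstrap_fit", "prediction_band"]


@dataclass(frozen=True)
class BootstrapResult:
    model_id: str
    replicates: np.ndarray  # (n_ok, n_params) refitted parameter vectors
    n_requested: int
    n_failed: int
    level: float
    trait_cis: dict  # {"t_opt": (lo, hi), "r_max_hat": (lo, hi)}
    trait_draws: dict  # {"t_opt": array, "r_max_hat": array}

    @property
    def model(self) -> ModelSpec:
        return get_model(self.model_id)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n_requested": self.n_requested,
            "n_replicates": int(self.replicates.shape[0]),
            "n_failed": self.n_failed,
            "level": self.level,
            "trait_cis": {k: [float(v[0]), float(v[1])] for k, v in self.trait_cis.items()},
        }


def _refit_batch(model, theta0, lo, hi, temps, rates,
                 ftol=1e-8, xtol=1e-8, gtol=1e-8, max_iter=1000):
    """Projected Levenberg-Marquardt refit of B replicates at once.

    ``temps``/``rates`` are (B, n); every replicate starts from ``theta0``.
    Uses the model's batched analytic Jacobian; steps are damped per
    replicate (Marquardt diagonal scaling) and projected onto the box
    constraints.  Returns (theta (B, k), converged mask (B,)).
    """
    B, _ = temps.shape
    k = theta0.size
    theta = np.tile(theta0, (B, 1))
    lam = np.full(B, 1e-3)
    nu = np.full(B, 2.0)
    done = np.zeros(B, dtype=bool)
    eye = np.eye(k)

    def cost_of(th, t_, r_):
        f = model.eval_batch(th, t_) - r_
        return 0.5 * np.einsum("bn,bn->b", f, f)

    cost = cost_of(theta, temps, rates)
    for _ in range(max_iter):
        active = ~done
        if not active.any():
            break
        th_a = theta[active]
        t_a = temps[active]
        r_a = rates[active]
        f = model.eval_batch(th_a, t_a) - r_a
        J = model.jac_batch(th_a, t_a)
        g = np.einsum("bnk,bn->bk", J, f)
        A = np.einsum("bnj,bnk->bjk", J, J)
        diag = np.maximum(np.einsum("bkk->bk", A), 1e-12)
        lam_a = lam[active]
        Ad = A + lam_a[:, None, None] * diag[:, None, :] * eye
        try:
            delta = np.linalg.solve(Ad, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack([np.linalg.lstsq(m_, -v, rcond=None)[0]
                              for m_, v in zip(Ad, g)])
        trial = np.clip(th_a + delta, lo, hi)
        step_vec = trial - th_a
        new_cost = cost_of(trial, t_a, r_a)
        actual = cost[active] - new_cost
        # predicted reduction of the damped quadratic model
        pred = 0.5 * np.einsum(
            "bk,bk->b", step_vec, lam_a[:, None] * diag * step_vec - g
        )
        rho = np.clip(actual / np.maximum(pred, 1e-300), -1e3, 1e3)
        improved = actual >= 0.0
        # Nielsen damping update: smooth decrease on good gain ratios,
        # doubling escalation on rejected steps (avoids accept/reject cycles)
        rel_drop = actual / np.maximum(cost[active], 1e-300)
        step = np.abs(step_vec).max(axis=1) / (1.0 + np.abs(th_a).max(axis=1))
        gnorm = np.abs(g).max(axis=1) / (1.0 + cost[active])
        conv = (improved & ((rel_drop < ftol) | (step < xtol))) | (gnorm < gtol)
        conv |= (~improved) & (step < xtol)

        idx = np.nonzero(active)[0]
        theta[idx[improved]] = trial[improved]
        cost[idx[improved]] = new_cost[improved]
        factor = np.maximum(1.0 / 3.0, 1.0 - (2.0 * rho[improved] - 1.0) ** 3)
        lam[idx[improved]] = np.maximum(lam[idx[improved]] * factor, 1e-14)
        nu[idx[improved]] = 2.0
        lam[idx[~improved]] *= nu[idx[~improved]]
        nu[idx[~improved]] *= 2.0
        done[idx[conv]] = True
        # damping beyond this means no representable step can improve the
        # cost: the point is numerically stationary
        done |= lam > 1e12
    return theta, done


def _refit(model, theta0, lo, hi, t, r, max_nfev=2000):
    def residuals(theta):
        return model.evaluate(theta, t) - r

    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = least_squares(
            residuals, theta0, bounds=(lo, hi), method="trf",
            xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=max_nfev,
        )
    if sol.status <= 0:
        raise RuntimeError(sol.message)
    return sol.x


def bootstrap_fit(
    dataset: ActivityDataset,
    model: ModelSpec | str,
    fit: FitResult,
    n_boot: int = 1999,
    method: str = "case",
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Resample, refit and summarize. Deterministic given ``seed``.

    Raises :class:`BootstrapFailureError` when more than half of the
    replicate refits fail.
    """
    if isinstance(model, str):
        model = get_model(model)
    if fit.model_id != model.model_id:
        raise InvalidInputError(
            f"fit is for {fit.model_id!r}, not {model.model_id!r}"
        )
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"level must be in (0, 1), got {level}")
    if n_boot < 1:
        raise InvalidInputError("n_boot must be >= 1")
    if method not in ("case", "residual"):
        raise InvalidInputError(f"method must be 'case' or 'residual', got {method!r}")

    t, r = dataset.temperatures, dataset.rates
    n = dataset.n
    fitted = model.evaluate(fit.theta_hat, t)
    resid = r - fitted
    resid_centered = resid - resid.mean()
    lo_b, hi_b = map(np.asarray, zip(*model.bounds(t, r)))
    theta0 = np.clip(fit.theta_hat, lo_b, hi_b)

    # materialize every resampled dataset first so the draw stream is
    # identical whichever refit path runs
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    if method == "case":
        temps_b, rates_b = t[idx], r[idx]
    else:
        temps_b = np.tile(t, (n_boot, 1))
        rates_b = np.clip(fitted[None, :] + resid_centered[idx], 0.0, None)

    if model.eval_batch is not None and model.jac_batch is not None:
        thetas, ok = _refit_batch(model, theta0, lo_b, hi_b, temps_b, rates_b)
        replicates = thetas[ok]
        n_failed = int(n_boot - ok.sum())
    else:
        reps = []
        n_failed = 0
        for tb, rb in zip(temps_b, rates_b):
            try:
                reps.append(_refit(model, theta0, lo_b, hi_b, tb, rb))
            except Exception:
                n_failed += 1
        replicates = np.asarray(reps)
    if n_failed > 0.5 * n_boot:
        raise BootstrapFailureError(
            f"{n_failed}/{n_boot} bootstrap refits failed"
        )

    topts = np.array([_find_topt(model, th) for th in replicates])
    rmaxs = np.array(
        [float(model.evaluate(th, np.array(to))) for th, to in zip(replicates, topts)]
    )
    alpha = (1.0 - level) / 2.0
    qs = (alpha, 1.0 - alpha)
    trait_draws = {"t_opt": topts, "r_max_hat": rmaxs}
    trait_cis = {
        name: tuple(np.quantile(draws, qs)) for name, draws in trait_draws.items()
    }
    return BootstrapResult(
        model_id=model.model_id,
        replicates=replicates,
        n_requested=n_boot,
        n_failed=n_failed,
        level=level,
        trait_cis=trait_cis,
        trait_draws=trait_draws,
    )


def prediction_band(result: BootstrapResult, grid) -> tuple[np.ndarray, np.ndarray]:
    """Percentile envelope of the replicate curves over a temperature grid.

    Returns (lower, upper) rate arrays; lower is never negative because the
    battery models are.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("grid must be non-empty")
    if result.replicates.shape[0] < 2:
        raise InvalidInputError("need at least 2 bootstrap replicates for a band")
    model = result.model
    curves = np.vstack([model.evaluate(th, grid) for th in result.replicates])
    alpha = (1.0 - result.level) / 2.0
    lower = np.quantile(curves, alpha, axis=0)
    upper = np.quantile(curves, 1.0 - alpha, axis=0)
    return lower, upper


def band_to_csv(result: BootstrapResult, grid, path) -> None:
    """Write the prediction band as CSV ``temperature,lower,upper``."""
    import pandas as pd

    lower, upper = prediction_band(result, grid)
    pd.DataFrame({"temperature": np.asarray(grid, float), "lower": lower, "upper": upper}).to_csv(
        path, index=False
    )
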