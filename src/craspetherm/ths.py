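"""Thermal Habitat Suitability (THS) index.

A fitted TPC is turned into a [0, 1] probability-of-presence proxy by
normalizing the fitted activity rate by its maximum:

    THS(T) = rate(T) / r_max_hat, clipped to [0, 1], and 0 outside the
    critical temperatures.

THS is 1 at the thermal optimum, 0 at and beyond the critical temperatures,
and is classified into suitability bands: low [0, 0.2], moderate (0.2, 0.6],
optimal (0.6, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fit import FitResult

__all__ = ["THSCurve", "ths_at", "classify_ths", "ths_curve", "LOW_MAX", "OPTIMAL_MIN"]

LOW_MAX = 0.2  # upper edge (inclusive) of the low-suitability band
OPTIMAL_MIN = 0.6  # THS strictly above this is optimal


def ths_at(fit: FitResult, temperature):
    """THS index at one or many temperatures (degC)."""
    if not fit.converged:
        raise InvalidInputError("fit did not converge")
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("temperature must be finite")
    if fit.r_max_hat <= 0:
        raise InvalidInputError("fitted curve has non-positive maximum")
    v = np.clip(fit.predict(t) / fit.r_max_hat, 0.0, 1.0)
    if fit.ct_min is not None:
        v = np.where(t <= fit.ct_min, 0.0, v)
    if fit.ct_max is not None:
        v = np.where(t >= fit.ct_max, 0.0, v)
    return float(v) if t.ndim == 0 else v


def classify_ths(ths):
    """Suitability band for a THS value (or array): low / moderate / optimal."""
    v = np.asarray(ths, dtype=float)
    if np.any((v < 0) | (v > 1) | ~np.isfinite(v)):
        raise InvalidInputError("THS values must lie in [0, 1]")
    bands = np.where(v > OPTIMAL_MIN, "optimal", np.where(v > LOW_MAX, "moderate", "low"))
    return str(bands) if v.ndim == 0 else bands


@dataclass(frozen=True)
class THSCurve:
    """THS evaluated on a temperature grid, with band labels."""

    model_id: str
    grid: np.ndarray
    values: np.ndarray
    bands: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temperature": self.grid, "ths": self.values, "band": self.bands})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ths_curve(fit: FitResult, grid) -> THSCurve:
    """Vectorized THS + band classification over a temperature grid."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise InvalidInputError("grid must be non-empty")
    values = ths_at(fit, grid)
    return THSCurve(
        model_id=fit.model_id, grid=grid, values=values, bands=classify_ths(values)
    )
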