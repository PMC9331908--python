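"""Seeded synthetic-data generators.

Three generators make every pipeline stage testable without downloads:

* :func:`generate_dataset` — temperature-activity datasets from any battery
  model plus truncated Gaussian noise;
* :func:`thomas_fixture` — the canonical 28-point medusa-activity dataset
  (noiseless Boatman evaluations anchored to the published thermal traits:
  optimum 28.7 degC at 119 pulsations min^-1, cessation at 36 degC);
* :func:`generate_climate_stack` — idealized global monthly temperature
  stacks with a quadratic latitudinal profile, hemisphere-phased seasonal
  cycle, and uniform SSP-style warming offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .fit import ActivityDataset
from .models import BoatmanParams, ModelSpec, evaluate_boatman, get_model
from .rasters import GridGeometry, TemperatureRasterStack

__all__ = [
    "CANONICAL_PARAMS",
    "THOMAS_OBSERVED_RANGE",
    "ClimateSpec",
    "ScenarioOffset",
    "generate_dataset",
    "thomas_fixture",
    "generate_climate_stack",
    "scenario_offset",
]

# Canonical Boatman parameter set behind the fixture: upper critical
# temperature at the published 36 degC cessation point, maximum rate at the
# published 119 pulsations min^-1, and skewness solved so the analytic
# optimum t_min + (t_max - t_min) * (1/2)^(1/a) lands exactly on 28.7 degC.
_CANONICAL_TOPT = 28.7
_CANONICAL_TMAX = 36.0
_CANONICAL_A = math.log(2.0) / math.log(_CANONICAL_TMAX / _CANONICAL_TOPT)
CANONICAL_PARAMS = BoatmanParams(
    r_max=119.0, t_min=0.0, t_max=_CANONICAL_TMAX, a=_CANONICAL_A, b=1.0
)

# Documentation constant: the published observed activity range of the
# source dataset (0.9 pulsations min^-1 at 2 degC up to 120 at 28 degC).
# The fixture does not attempt to reproduce the cold-tail value — the raw
# observations were never deposited — so this pair is reference metadata,
# not fixture data.
THOMAS_OBSERVED_RANGE = {"rate_at_2C": 0.9, "rate_at_28C": 120.0}

_OFFSETS = {
    ("current", "none"): 0.0,
    ("2050", "SSP126"): 0.5,
    ("2050", "SSP585"): 2.0,
    ("2100", "SSP126"): 1.0,
    ("2100", "SSP585"): 4.0,
}


@dataclass(frozen=True)
class ScenarioOffset:
    """Uniform warming offset (degC) for an epoch/SSP combination."""

    epoch: str
    ssp: str
    delta: float


def scenario_offset(epoch: str, ssp: str = "none") -> ScenarioOffset:
    """Warming offset: +1 degC (SSP126) / +4 degC (SSP585) by 2100, half by 2050."""
    key = (str(epoch), ssp)
    if key not in _OFFSETS:
        raise InvalidInputError(
            f"unknown epoch/scenario combination {key}; valid: {sorted(_OFFSETS)}"
        )
    return ScenarioOffset(epoch=key[0], ssp=ssp, delta=_OFFSETS[key])


def generate_dataset(
    model: ModelSpec | str,
    params,
    temps,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> ActivityDataset:
    """Model evaluations plus Normal(0, noise_sd^2) noise, truncated at 0."""
    if isinstance(model, str):
        model = get_model(model)
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    temps = np.asarray(temps, dtype=float)
    theta = params.as_array() if isinstance(params, BoatmanParams) else np.asarray(params, float)
    rates = model.evaluate(theta, temps)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = rates + rng.normal(0.0, noise_sd, size=temps.shape)
    return ActivityDataset(temps, np.clip(rates, 0.0, None), label=label)


def thomas_fixture() -> ActivityDataset:
    """Canonical 28-point medusa activity dataset on [2, 28] degC (noiseless)."""
    temps = np.linspace(2.0, 28.0, 28)
    rates = evaluate_boatman(CANONICAL_PARAMS, temps)
    return ActivityDataset(temps, rates, label="thomas1950-canonical")


@dataclass(frozen=True)
class ClimateSpec:
    """Idealized global monthly climate.

    Cell temperature for latitude phi (degrees) and month m (1..12):

        T = t_eq - (t_eq - t_pole) * (phi/90)^2
            + amplitude * (|phi|/90) * cos(2 pi (m - peak_month(phi)) / 12)
            + delta(epoch, ssp) + eta

    with the peak month chosen by hemisphere and eta ~ Normal(0, noise_sd^2)
    drawn once per pixel (shared across months), so same-seed stacks for two
    scenarios differ by exactly the scenario delta.
    """

    nrows: int = 72
    ncols: int = 144
    cellsize: float = 2.5
    xll: float = -180.0
    yll: float = -90.0
    t_eq: float = 27.0
    t_pole: float = -20.0
    amplitude: float = 20.0
    peak_month_north: int = 7
    peak_month_south: int = 1
    epoch: str = "current"
    ssp: str = "none"
    noise_sd: float = 0.5

    def __post_init__(self):
        if self.t_eq <= self.t_pole:
            raise InvalidInputError("t_eq must exceed t_pole")
        if self.amplitude < 0:
            raise InvalidInputError("amplitude must be >= 0")
        for m in (self.peak_month_north, self.peak_month_south):
            if not 1 <= m <= 12:
                raise InvalidInputError(f"peak month {m} outside 1..12")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.nrows < 1 or self.ncols < 1 or self.cellsize <= 0:
            raise InvalidInputError("grid dimensions must be positive")


def generate_climate_stack(spec: ClimateSpec, seed: int = 0) -> TemperatureRasterStack:
    """Render a :class:`ClimateSpec` into a 12-layer temperature stack."""
    geom = GridGeometry(
        nrows=spec.nrows, ncols=spec.ncols, xll=spec.xll, yll=spec.yll, cellsize=spec.cellsize
    )
    lats = geom.cell_center_lats()  # (nrows,)
    delta = scenario_offset(spec.epoch, spec.ssp).delta

    phi = lats / 90.0
    annual = spec.t_eq - (spec.t_eq - spec.t_pole) * phi**2  # (nrows,)
    seas_amp = spec.amplitude * np.abs(phi)
    peak = np.where(lats >= 0.0, spec.peak_month_north, spec.peak_month_south)

    months = np.arange(1, 13)[:, None]  # (12, 1)
    cyc = np.cos(2.0 * np.pi * (months - peak[None, :]) / 12.0)  # (12, nrows)
    t_rows = annual[None, :] + seas_amp[None, :] * cyc + delta  # (12, nrows)
    layers = np.repeat(t_rows[:, :, None], spec.ncols, axis=2)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        eta = rng.normal(0.0, spec.noise_sd, size=(spec.nrows, spec.ncols))
        layers = layers + eta[None, :, :]

    return TemperatureRasterStack(
        layers=layers,
        geometry=geom,
        epoch_label=spec.epoch,
        scenario_label=spec.ssp,
    )
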