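"""Pixel-level THS projection and latitude-band seasonal summaries.

Projection is purely cell-local: every non-nodata temperature cell is pushed
through the THS transform of one fitted TPC.  Summaries aggregate the
monthly maps into latitude bands (default 10 deg, closed-open, ordered
south to north, membership by cell-center latitude), reporting the mean THS
and the fraction of pixels in the optimal band (THS > 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fit import FitResult
from .rasters import TemperatureRasterStack, THSMapSet
from .ths import OPTIMAL_MIN, ths_at

__all__ = [
    "project_ths",
    "monthly_latband_summary",
    "optimal_months",
    "LatBandSummary",
]


def project_ths(fit: FitResult, stack: TemperatureRasterStack) -> THSMapSet:
    """Apply the THS transform to every cell of a monthly temperature stack."""
    mask = stack.mask
    # nodata cells carry the sentinel (-9999 degC); evaluate everything and
    # restore the sentinel afterwards — the transform is finite everywhere.
    values = ths_at(fit, stack.layers)
    layers = np.where(mask, stack.nodata, values).astype(np.float32)
    return THSMapSet(
        layers=layers,
        geometry=stack.geometry,
        nodata=stack.nodata,
        model_id=fit.model_id,
        epoch_label=stack.epoch_label,
        scenario_label=stack.scenario_label,
    )


@dataclass(frozen=True)
class LatBandSummary:
    """Latitude band x month table of mean THS and optimal-pixel fraction.

    Empty bands (no non-nodata pixel) are kept with ``n_pixels = 0`` and NaN
    statistics rather than dropped.
    """

    table: pd.DataFrame  # band_lower, band_upper, month, mean_ths, optimal_fraction, n_pixels
    band_width: float
    epoch_label: str = "current"
    scenario_label: str = "none"

    def band(self, lower: float, upper: float) -> pd.DataFrame:
        rows = self.table[
            np.isclose(self.table["band_lower"], lower)
            & np.isclose(self.table["band_upper"], upper)
        ]
        if rows.empty:
            raise InvalidInputError(f"band [{lower}, {upper}) not present in summary")
        return rows

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, band_width=None) -> "LatBandSummary":
        df = pd.read_csv(path)
        bw = band_width if band_width is not None else float(
            (df["band_upper"] - df["band_lower"]).iloc[0]
        )
        return cls(table=df, band_width=bw)


def monthly_latband_summary(maps: THSMapSet, band_width: float = 10.0) -> LatBandSummary:
    """Aggregate a THS map set into latitude bands per month.

    Bands are [lower, lower + band_width) from -90 northwards; ``band_width``
    must divide 180 evenly.  Means are area-unweighted pixel means; nodata
    pixels are excluded.
    """
    n_bands = 180.0 / band_width
    if abs(n_bands - round(n_bands)) > 1e-9:
        raise InvalidInputError(f"band_width {band_width} does not divide 180 evenly")
    n_bands = int(round(n_bands))
    lats = maps.geometry.cell_center_lats()  # per row, north -> south
    band_idx = np.floor((lats + 90.0) / band_width).astype(int)
    band_idx = np.clip(band_idx, 0, n_bands - 1)
    mask = maps.mask  # (12, nrows, ncols)

    records = []
    for b in range(n_bands):
        lower = -90.0 + b * band_width
        upper = lower + band_width
        rows = np.nonzero(band_idx == b)[0]
        for month in range(1, 13):
            if rows.size:
                vals = maps.layers[month - 1, rows, :]
                ok = ~mask[month - 1, rows, :]
                sel = vals[ok]
            else:
                sel = np.empty(0)
            if sel.size:
                records.append(
                    (lower, upper, month, float(sel.mean()),
                     float(np.mean(sel > OPTIMAL_MIN)), int(sel.size))
                )
            else:
                records.append((lower, upper, month, np.nan, np.nan, 0))
    table = pd.DataFrame(
        records,
        columns=["band_lower", "band_upper", "month", "mean_ths", "optimal_fraction", "n_pixels"],
    )
    return LatBandSummary(
        table=table,
        band_width=band_width,
        epoch_label=maps.epoch_label,
        scenario_label=maps.scenario_label,
    )


def optimal_months(
    summary: LatBandSummary,
    band: tuple[float, float],
    threshold: float = 0.5,
) -> list[int]:
    """Months (1..12, ascending) whose optimal-pixel fraction exceeds ``threshold``."""
    rows = summary.band(*band)
    hit = rows[rows["optimal_fraction"] > threshold]
    return sorted(int(m) for m in hit["month"])
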