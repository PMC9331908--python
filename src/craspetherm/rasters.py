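"""Geographic raster containers and ESRI ASCII grid I/O.

Grids are geographic (WGS84 lat/lon), stored row-major north-to-south as in
the ESRI ASCII (.asc) interchange format used throughout the species
distribution modelling ecosystem.  A stack is 12 monthly layers sharing one
geotransform (lower-left corner + square cell size in degrees) and one
nodata sentinel (default -9999).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import RasterFormatError

__all__ = [
    "GridGeometry",
    "TemperatureRasterStack",
    "THSMapSet",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster_stack",
    "write_stack",
]

NODATA_DEFAULT = -9999.0
# physically plausible range for monthly mean air temperature (degC)
_TEMP_RANGE = (-90.0, 60.0)


@dataclass(frozen=True)
class GridGeometry:
    """Lower-left corner (degrees) and square cell size of a lat/lon grid."""

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float
    crs: str = "EPSG:4326"

    def cell_center_lats(self) -> np.ndarray:
        """Latitude of each row's cell centers, north (row 0) to south."""
        top = self.yll + self.nrows * self.cellsize
        return top - self.cellsize * (np.arange(self.nrows) + 0.5)

    def matches(self, other: "GridGeometry") -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )


def _validate_stack(layers, geometry, nodata, value_range=None):
    if layers.shape[0] != 12:
        raise RasterFormatError(f"stack must have exactly 12 monthly layers, got {layers.shape[0]}")
    if layers.shape[1:] != (geometry.nrows, geometry.ncols):
        raise RasterFormatError(
            f"layer shape {layers.shape[1:]} does not match geometry "
            f"({geometry.nrows}, {geometry.ncols})"
        )
    data = layers[layers != nodata]
    if not np.all(np.isfinite(data)):
        raise RasterFormatError("non-finite value in non-nodata cells")
    if value_range is not None and data.size:
        lo, hi = value_range
        if data.min() < lo or data.max() > hi:
            raise RasterFormatError(
                f"values outside plausible range [{lo}, {hi}]: "
                f"[{data.min():.2f}, {data.max():.2f}]"
            )


@dataclass(frozen=True)
class TemperatureRasterStack:
    """12 monthly mean-temperature grids (degC) on one geometry."""

    layers: np.ndarray  # (12, nrows, ncols)
    geometry: GridGeometry
    nodata: float = NODATA_DEFAULT
    epoch_label: str = "current"
    scenario_label: str = "none"

    def __post_init__(self):
        layers = np.asarray(self.layers, dtype=float)
        object.__setattr__(self, "layers", layers)
        _validate_stack(layers, self.geometry, self.nodata, _TEMP_RANGE)

    @property
    def mask(self) -> np.ndarray:
        """Boolean nodata mask, shape (12, nrows, ncols)."""
        return self.layers == self.nodata

    def with_offset(self, delta: float) -> "TemperatureRasterStack":
        """Uniform warming: add ``delta`` degC to every non-nodata cell."""
        layers = np.where(self.mask, self.nodata, self.layers + delta)
        return replace(self, layers=layers)

    def crop(self, rows: slice, cols: slice) -> "TemperatureRasterStack":
        sub = self.layers[:, rows, cols]
        r0 = rows.indices(self.geometry.nrows)[0]
        c0 = cols.indices(self.geometry.ncols)[0]
        g = self.geometry
        geom = GridGeometry(
            nrows=sub.shape[1],
            ncols=sub.shape[2],
            xll=g.xll + c0 * g.cellsize,
            yll=g.yll + (g.nrows - r0 - sub.shape[1]) * g.cellsize,
            cellsize=g.cellsize,
            crs=g.crs,
        )
        return TemperatureRasterStack(
            sub, geom, self.nodata, self.epoch_label, self.scenario_label
        )


@dataclass(frozen=True)
class THSMapSet:
    """12 monthly THS grids in [0, 1]; nodata mask mirrors the input stack."""

    layers: np.ndarray
    geometry: GridGeometry
    nodata: float = NODATA_DEFAULT
    model_id: str = ""
    epoch_label: str = "current"
    scenario_label: str = "none"

    def __post_init__(self):
        layers = np.asarray(self.layers, dtype=np.float32)
        object.__setattr__(self, "layers", layers)
        _validate_stack(layers, self.geometry, np.float32(self.nodata), (0.0, 1.0))

    @property
    def mask(self) -> np.ndarray:
        return self.layers == np.float32(self.nodata)

    def crop(self, rows: slice, cols: slice) -> "THSMapSet":
        sub = self.layers[:, rows, cols]
        r0 = rows.indices(self.geometry.nrows)[0]
        c0 = cols.indices(self.geometry.ncols)[0]
        g = self.geometry
        geom = GridGeometry(
            nrows=sub.shape[1],
            ncols=sub.shape[2],
            xll=g.xll + c0 * g.cellsize,
            yll=g.yll + (g.nrows - r0 - sub.shape[1]) * g.cellsize,
            cellsize=g.cellsize,
            crs=g.crs,
        )
        return THSMapSet(
            sub, geom, self.nodata, self.model_id, self.epoch_label, self.scenario_label
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry, float]:
    """Read a single .asc grid -> (array, geometry, nodata)."""
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise RasterFormatError(f"cannot read {path}: {exc}") from exc
    header = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"{path}: missing header field(s) {missing}")
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    try:
        data = np.loadtxt(lines[body_start:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: malformed grid body: {exc}") from exc
    if data.shape != (nrows, ncols):
        raise RasterFormatError(
            f"{path}: body shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    geom = GridGeometry(
        nrows=nrows, ncols=ncols,
        xll=header["xllcorner"], yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    return data, geom, nodata


def write_ascii_grid(path, array, geometry: GridGeometry, nodata=NODATA_DEFAULT) -> None:
    """Write one grid as .asc; values serialized at float32 precision."""
    array = np.asarray(array)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"ncols {geometry.ncols}\nnrows {geometry.nrows}\n"
            f"xllcorner {geometry.xll:.10g}\nyllcorner {geometry.yll:.10g}\n"
            f"cellsize {geometry.cellsize:.10g}\nNODATA_value {nodata:.10g}\n"
        )
        np.savetxt(fh, array.astype(np.float32), fmt="%.9g")


def read_raster_stack(
    paths: Sequence,
    epoch_label: str = "current",
    scenario_label: str = "none",
    scale: float = 1.0,
) -> TemperatureRasterStack:
    """Assemble 12 monthly .asc files (Jan..Dec order) into a stack.

    ``scale`` divides values on read (e.g. 10 for temperatures stored in
    tenths of a degree).  Per-file nodata sentinels are harmonized to -9999.
    """
    paths = list(paths)
    if len(paths) != 12:
        raise RasterFormatError(f"expected 12 monthly files, got {len(paths)}")
    layers = []
    geom0 = None
    for p in paths:
        data, geom, nodata = read_ascii_grid(p)
        if geom0 is None:
            geom0 = geom
        elif not geom.matches(geom0):
            raise RasterFormatError(f"{p}: geometry does not match first layer")
        mask = data == nodata
        data = np.where(mask, NODATA_DEFAULT, data / scale)
        layers.append(data)
    return TemperatureRasterStack(
        np.stack(layers), geom0, NODATA_DEFAULT, epoch_label, scenario_label
    )


def write_stack(stack, directory, prefix: str) -> list:
    """Write 12 monthly .asc files ``<prefix>_01.asc`` .. ``_12.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for m in range(12):
        p = directory / f"{prefix}_{m + 1:02d}.asc"
        write_ascii_grid(p, stack.layers[m], stack.geometry, stack.nodata)
        out.append(p)
    return out
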