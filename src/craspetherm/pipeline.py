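"""End-to-end pipeline: fit -> compare -> bootstrap -> THS -> project -> summarize.

Driven by a single YAML config.  A run writes, under one output directory:
the ranked model comparison (JSON), the best fit (JSON), bootstrap trait
CIs (JSON) and prediction band (CSV), the THS curve (CSV), 12 monthly THS
maps per configured climate, latitude-band summary CSVs, and a manifest
recording the config hash, seed and artifact checksums.  Reruns with the
same config and seed reproduce all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bootstrap import band_to_csv, bootstrap_fit
from .errors import ConfigError
from .fit import ActivityDataset, compare_models
from .models import model_catalog, get_model
from .projection import monthly_latband_summary, project_ths
from .rasters import read_raster_stack, write_stack
from .synth import ClimateSpec, generate_climate_stack, thomas_fixture
from .ths import ths_curve

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("craspetherm.pipeline")


@dataclass(frozen=True)
class ClimateEntry:
    """One epoch/scenario climate input: 12 raster paths or a synthetic spec."""

    name: str
    epoch: str = "current"
    ssp: str = "none"
    paths: tuple = ()
    synthetic: bool = True
    climate_overrides: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    dataset: str = "synthetic:fixture"  # or a CSV path
    models: tuple = ()  # empty -> full battery
    n_starts: int = 50
    n_boot: int = 499
    bootstrap_method: str = "case"
    level: float = 0.95
    curve_grid: tuple = (-5.0, 45.0, 0.25)  # start, stop, step (degC)
    climates: tuple = ()
    band_width: float = 10.0
    output_dir: str = "craspetherm_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        climates = tuple(
            ClimateEntry(**c) if isinstance(c, dict) else c
            for c in raw.get("climates", ())
        )
        kwargs = {k: v for k, v in raw.items() if k != "climates"}
        if "models" in kwargs:
            kwargs["models"] = tuple(kwargs["models"])
        if "curve_grid" in kwargs:
            kwargs["curve_grid"] = tuple(kwargs["curve_grid"])
        return cls(climates=climates, **kwargs)

    def validate(self) -> None:
        if self.dataset != "synthetic:fixture" and not Path(self.dataset).exists():
            raise ConfigError(f"dataset path does not exist: {self.dataset}")
        for m in self.models:
            get_model(m)  # raises for unknown ids
        for entry in self.climates:
            if not entry.synthetic:
                if len(entry.paths) != 12:
                    raise ConfigError(
                        f"climate {entry.name!r}: expected 12 raster paths, got {len(entry.paths)}"
                    )
                for p in entry.paths:
                    if not Path(p).exists():
                        raise ConfigError(f"climate {entry.name!r}: missing raster {p}")
        if not (0 < self.level < 1):
            raise ConfigError(f"level must be in (0, 1), got {self.level}")

    def to_canonical_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    completed = []
    manifest_path = out / "manifest.json"

    def record(stage, *paths):
        completed.append(stage)
        artifacts.extend(paths)
        log.info("stage %s done (seed=%d): %s", stage, config.seed,
                 ", ".join(str(p) for p in paths))

    try:
        return _run_stages(config, out, artifacts, completed, record, manifest_path)
    except Exception:
        # record how far the run got before propagating
        partial = {
            "config_sha256": hashlib.sha256(config.to_canonical_yaml().encode()).hexdigest(),
            "seed": config.seed,
            "completed_stages": completed,
            "failed": True,
            "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
        }
        manifest_path.write_text(json.dumps(partial, indent=2))
        raise


def _run_stages(config, out, artifacts, completed, record, manifest_path):
    # --- dataset
    if config.dataset == "synthetic:fixture":
        dataset = thomas_fixture()
    else:
        dataset = ActivityDataset.from_csv(config.dataset)
    ds_path = out / "dataset.csv"
    dataset.to_csv(ds_path)
    record("dataset", ds_path)

    # --- model comparison
    battery = list(config.models) if config.models else [m.model_id for m in model_catalog()]
    comparison = compare_models(dataset, battery, n_starts=config.n_starts, seed=config.seed)
    cmp_path = out / "model_comparison.json"
    comparison.to_json(cmp_path)
    best = comparison.best
    fit_path = out / "best_fit.json"
    fit_path.write_text(json.dumps(best.to_dict(), indent=2))
    record("compare", cmp_path, fit_path)

    # --- bootstrap
    boot = bootstrap_fit(
        dataset, best.model, best,
        n_boot=config.n_boot, method=config.bootstrap_method,
        level=config.level, seed=config.seed,
    )
    boot_path = out / "bootstrap.json"
    boot_path.write_text(json.dumps(boot.to_dict(), indent=2))
    lo, hi, step = config.curve_grid
    grid = np.arange(lo, hi + step / 2, step)
    band_path = out / "prediction_band.csv"
    band_to_csv(boot, grid, band_path)
    record("bootstrap", boot_path, band_path)

    # --- THS curve
    curve = ths_curve(best, grid)
    curve_path = out / "ths_curve.csv"
    curve.to_csv(curve_path)
    record("ths", curve_path)

    # --- projection + summaries
    for entry in config.climates:
        if entry.synthetic:
            spec = ClimateSpec(epoch=entry.epoch, ssp=entry.ssp, **entry.climate_overrides)
            stack = generate_climate_stack(spec, seed=config.seed)
        else:
            stack = read_raster_stack(entry.paths, epoch_label=entry.epoch,
                                      scenario_label=entry.ssp)
        maps = project_ths(best, stack)
        map_paths = write_stack(maps, out / "maps", f"ths_{entry.name}")
        summary = monthly_latband_summary(maps, band_width=config.band_width)
        sum_path = out / f"latband_{entry.name}.csv"
        summary.to_csv(sum_path)
        record(f"project:{entry.name}", *map_paths, sum_path)

    manifest = {
        "config_sha256": hashlib.sha256(config.to_canonical_yaml().encode()).hexdigest(),
        "seed": config.seed,
        "completed_stages": completed,
        "best_model": best.model_id,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
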