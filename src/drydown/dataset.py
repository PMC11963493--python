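"""In-memory container and CSV layout for a drydown-rewatering dataset.

One experiment is a directory of plain CSV files (RFC-4180, ISO-8601
timestamps, UTF-8) plus a YAML manifest recording the generating / loading
configuration and seed:

    manifest.yaml        config, seed, start_date
    meteorology.csv      timestamp, temperature, rh, irradiance, vpd
    sensors_<tree>.csv   timestamp, heat_velocity, heat_velocity_quality,
                         stem_water_content, stem_water_content_quality
    water_potential.csv  day, tree_id, psi_pd, psi_md   (replicate rows)
    soil_moisture.csv    day, tree_id, depth_cm, vwc_pct
    isotopes.csv         day, tree_id, medium, depth_cm, dD, d18O
    gas_exchange.csv     day, tree_id, period, assimilation, stomatal_conductance
    leaf_loss.csv        day, tree_id, area_cm2
    sapwood.csv          tree_id, sapwood_area_cm2

Unknown columns in any table are preserved untouched through a load/save
cycle.  Column names can be aliased through an optional ``aliases`` mapping
in the manifest so deposited datasets with different headers load without
code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sensor_processing import SensorSeries

__all__ = ["Dataset", "SchemaError", "load_dataset", "save_dataset"]

_REQUIRED_TABLES = {
    "water_potential": ("day", "tree_id", "psi_pd", "psi_md"),
    "soil_moisture": ("day", "tree_id", "depth_cm", "vwc_pct"),
    "isotopes": ("day", "tree_id", "medium", "depth_cm", "dD", "d18O"),
    "leaf_loss": ("day", "tree_id", "area_cm2"),
    "sapwood": ("tree_id", "sapwood_area_cm2"),
}
_OPTIONAL_TABLES = {
    "gas_exchange": ("day", "tree_id", "assimilation", "stomatal_conductance"),
}
_MET_COLUMNS = ("timestamp", "temperature", "rh", "irradiance", "vpd")

_SENSOR_UNITS = {"heat_velocity": "cm h-1", "stem_water_content": "%"}


class SchemaError(ValueError):
    """A dataset file violates the expected schema."""


@dataclass
class Dataset:
    """All tables of one experiment, plus the manifest that produced them."""

    manifest: dict
    meteorology: pd.DataFrame
    sensors: dict
    water_potential: pd.DataFrame
    soil_moisture: pd.DataFrame
    isotopes: pd.DataFrame
    leaf_loss: pd.DataFrame
    sapwood: pd.DataFrame
    gas_exchange: pd.DataFrame | None = None
    truth_daily: pd.DataFrame | None = None

    @property
    def trees(self) -> list:
        return sorted(self.sensors.keys())

    def sapwood_area(self, tree_id: str) -> float:
        sub = self.sapwood[self.sapwood["tree_id"] == tree_id]
        if not len(sub):
            raise ValueError(f"missing sapwood area for tree {tree_id!r}")
        return float(sub["sapwood_area_cm2"].iloc[0])

    def save(self, directory) -> list:
        return save_dataset(self, directory)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    try:
        # %.17g keeps float64 round-trips lossless
        frame.to_csv(path, index=False, lineterminator="\r\n",
                     float_format="%.17g")
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed writing {path}: {exc}") from exc


def save_dataset(ds: Dataset, directory) -> list:
    """Write every table to ``directory``; returns the file list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    path = directory / "manifest.yaml"
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(ds.manifest, fh, sort_keys=True)
    written.append(path)

    met = ds.meteorology.reset_index()
    met = met.rename(columns={met.columns[0]: "timestamp"})
    met["timestamp"] = pd.DatetimeIndex(met["timestamp"]).strftime(
        "%Y-%m-%dT%H:%M:%S")
    _write_csv(met, directory / "meteorology.csv")
    written.append(directory / "meteorology.csv")

    for tree in sorted(ds.sensors):
        frames = {}
        index = None
        for var, series in sorted(ds.sensors[tree].items()):
            frames[var] = series.values
            frames[f"{var}_quality"] = series.quality
            index = series.timestamps
        frame = pd.DataFrame(frames)
        frame.insert(0, "timestamp", index.strftime("%Y-%m-%dT%H:%M:%S"))
        path = directory / f"sensors_{tree}.csv"
        _write_csv(frame, path)
        written.append(path)

    tables = dict(_REQUIRED_TABLES)
    tables.update(_OPTIONAL_TABLES)
    for name in tables:
        frame = getattr(ds, name, None)
        if frame is None:
            continue
        path = directory / f"{name}.csv"
        _write_csv(frame, path)
        written.append(path)
    if ds.truth_daily is not None:
        path = directory / "truth_daily.csv"
        _write_csv(ds.truth_daily, path)
        written.append(path)
    return written


def _check_columns(frame: pd.DataFrame, required, path: Path) -> None:
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def load_dataset(directory) -> Dataset:
    """Load a dataset directory written by :func:`save_dataset`.

    The manifest must be present and schema-valid; unknown columns in any
    table are preserved untouched.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise SchemaError(
            f"no manifest.yaml in {directory}; not a dataset directory"
        )
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "config" not in manifest:
        raise SchemaError(f"{manifest_path}: manifest must map 'config'")
    for key in ("start_date", "seed"):
        if key not in manifest:
            raise SchemaError(f"{manifest_path}: manifest missing {key!r}")
    aliases = manifest.get("aliases", {}) or {}

    def read(name, required, optional=False):
        path = directory / f"{name}.csv"
        if not path.exists():
            if optional:
                return None
            raise SchemaError(f"missing dataset file {path}")
        frame = pd.read_csv(path, float_precision="round_trip")
        frame = frame.rename(columns=aliases.get(name, {}))
        _check_columns(frame, required, path)
        for col in required:
            if col in ("tree_id", "medium", "timestamp", "period"):
                continue
            if col == "day":
                frame[col] = frame[col].astype("int64")
            else:
                frame[col] = frame[col].astype("float64")
        return frame

    met = read("meteorology", _MET_COLUMNS)
    met["timestamp"] = pd.to_datetime(met["timestamp"])
    met = met.set_index("timestamp")

    sensors = {}
    for path in sorted(directory.glob("sensors_*.csv")):
        tree = path.stem[len("sensors_"):]
        frame = pd.read_csv(path, float_precision="round_trip")
        _check_columns(frame, ("timestamp",), path)
        ts = pd.DatetimeIndex(pd.to_datetime(frame["timestamp"]))
        sensors[tree] = {}
        for var, unit in _SENSOR_UNITS.items():
            if var not in frame.columns:
                continue
            qual_col = f"{var}_quality"
            quality = (frame[qual_col].to_numpy(dtype="<U8")
                       if qual_col in frame.columns else None)
            sensors[tree][var] = SensorSeries(
                tree_id=tree, variable=var, unit=unit, timestamps=ts,
                values=frame[var].to_numpy(dtype=float), quality=quality,
            )

    ds = Dataset(
        manifest=manifest,
        meteorology=met,
        sensors=sensors,
        water_potential=read("water_potential",
                             _REQUIRED_TABLES["water_potential"]),
        soil_moisture=read("soil_moisture", _REQUIRED_TABLES["soil_moisture"]),
        isotopes=read("isotopes", _REQUIRED_TABLES["isotopes"]),
        leaf_loss=read("leaf_loss", _REQUIRED_TABLES["leaf_loss"]),
        sapwood=read("sapwood", _REQUIRED_TABLES["sapwood"]),
        gas_exchange=read("gas_exchange",
                          _OPTIONAL_TABLES["gas_exchange"], optional=True),
        truth_daily=read("truth_daily", ("day",), optional=True),
    )
    _validate(ds, directory)
    return ds


def _validate(ds: Dataset, directory: Path) -> None:
    for name in ("water_potential", "soil_moisture", "isotopes", "leaf_loss"):
        frame = getattr(ds, name)
        days = frame["day"]
        bad = days[(days < 0) | (days != days.astype(int))]
        if len(bad):
            row = int(bad.index[0])
            raise SchemaError(
                f"{directory / (name + '.csv')}: column 'day' row {row}: "
                f"invalid day value {bad.iloc[0]!r}"
            )
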