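"""Shared domain types, unit conversions, CSV I/O, configuration and logging.

Canonical internal units: time in minutes, length in cm, volume in cm^3,
concentration in mg/L, pressure in Pa, mass in g.  Public results are also
reported in the SI-style units conventional for each quantity (diffusivity in
cm^2/s, water-vapour permeability in g m^-1 s^-1 Pa^-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UnitError",
    "ValidationError",
    "ParseError",
    "CoatingCondition",
    "TimeSeries",
    "TimeSeriesSchema",
    "convert",
    "registered_units",
    "read_timeseries",
    "write_timeseries",
    "load_config",
    "validate_config",
    "get_logger",
    "configure_logging",
]


class UnitError(ValueError):
    """Raised for unknown units or dimensionally incompatible conversions."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant (ordering, sign, ...)."""


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Unit registry
# ---------------------------------------------------------------------------
# unit name -> (dimension, multiplicative factor to the canonical unit of that
# dimension).  Conversion between units of the same dimension is exact:
# value * factor[from] / factor[to].
_UNITS: dict[str, tuple[str, float]] = {
    # time (canonical: min)
    "s": ("time", 1.0 / 60.0),
    "min": ("time", 1.0),
    "h": ("time", 60.0),
    "day": ("time", 1440.0),
    # length (canonical: cm)
    "um": ("length", 1e-4),
    "mm": ("length", 0.1),
    "cm": ("length", 1.0),
    "m": ("length", 100.0),
    # area (canonical: cm2)
    "mm2": ("area", 0.01),
    "cm2": ("area", 1.0),
    "m2": ("area", 1e4),
    # volume (canonical: cm3)
    "cm3": ("volume", 1.0),
    "ml": ("volume", 1.0),
    "L": ("volume", 1000.0),
    "m3": ("volume", 1e6),
    # concentration (canonical: mg/L)
    "mg/L": ("concentration", 1.0),
    "g/L": ("concentration", 1000.0),
    # pressure (canonical: Pa)
    "Pa": ("pressure", 1.0),
    "kPa": ("pressure", 1000.0),
    # mass (canonical: g)
    "mg": ("mass", 1e-3),
    "g": ("mass", 1.0),
    "kg": ("mass", 1000.0),
    # force
    "N": ("force", 1.0),
    # mass flux (canonical: g m-2 s-1)
    "g/m2/s": ("mass_flux", 1.0),
    "g/m2/h": ("mass_flux", 1.0 / 3600.0),
    "g/m2/day": ("mass_flux", 1.0 / 86400.0),
    # diffusivity (canonical: cm2/s)
    "cm2/s": ("diffusivity", 1.0),
    "cm2/min": ("diffusivity", 1.0 / 60.0),
    # rate constants (canonical: 1/min)
    "1/min": ("rate", 1.0),
    "1/h": ("rate", 1.0 / 60.0),
    "1/day": ("rate", 1.0 / 1440.0),
    # dimensionless / passthrough
    "percent": ("dimensionless_pct", 1.0),
    "fraction": ("dimensionless_pct", 100.0),
    "au": ("arbitrary", 1.0),
    "1/cm": ("wavenumber", 1.0),
}


def registered_units() -> dict[str, str]:
    """Map of unit name -> dimension for every registered unit."""
    return {name: dim for name, (dim, _) in _UNITS.items()}


def convert(value, from_unit: str, to_unit: str):
    """Convert ``value`` between two registered units of the same dimension.

    Accepts scalars or array-likes; the exact ratio of registry factors is
    applied, so round-trips are exact to floating point.
    """
    if from_unit not in _UNITS:
        raise UnitError(f"unknown unit {from_unit!r}")
    if to_unit not in _UNITS:
        raise UnitError(f"unknown unit {to_unit!r}")
    dim_a, fac_a = _UNITS[from_unit]
    dim_b, fac_b = _UNITS[to_unit]
    if dim_a != dim_b:
        raise UnitError(
            f"incompatible dimensions: {from_unit!r} is {dim_a}, {to_unit!r} is {dim_b}"
        )
    return np.multiply(value, fac_a / fac_b)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CoatingCondition:
    """One experimental coating condition: dip steps and water-annealing time.

    Water annealing (exposure of the silk film to water vapour under vacuum)
    raises the crystalline beta-sheet fraction of the fibroin, which in turn
    tightens the film's gas and water-vapour barrier.
    """

    dip_steps: int
    annealing_hours: float
    beta_sheet_pct: float
    thickness_um: float

    def __post_init__(self):
        if self.dip_steps < 1:
            raise ValidationError("dip_steps must be >= 1")
        if not 0.0 <= self.beta_sheet_pct <= 100.0:
            raise ValidationError("beta_sheet_pct must be in [0, 100]")
        if self.thickness_um <= 0:
            raise ValidationError("thickness_um must be positive")

    @property
    def label(self) -> str:
        return f"D{self.dip_steps}-{self.beta_sheet_pct:.0f}%"


@dataclass
class TimeSeries:
    """A measured quantity sampled at strictly increasing times.

    ``t_unit`` must be one of the registered time units (min | h | day | s);
    values are stored as given, not silently converted.
    """

    t: np.ndarray
    y: np.ndarray
    t_unit: str = "min"
    y_unit: str = "au"
    replicate_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1 or self.t.size != self.y.size:
            raise ValidationError("t and y must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValidationError("a TimeSeries needs at least 2 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("time stamps must be strictly increasing")
        if np.any(~np.isfinite(self.y)) or np.any(~np.isfinite(self.t)):
            raise ValidationError("missing or non-finite values are not allowed")
        if _UNITS.get(self.t_unit, ("",))[0] != "time":
            raise UnitError(f"{self.t_unit!r} is not a registered time unit")

    def __len__(self) -> int:
        return self.t.size

    def to_time_unit(self, unit: str) -> "TimeSeries":
        return TimeSeries(
            convert(self.t, self.t_unit, unit), self.y, unit, self.y_unit, self.replicate_id
        )


@dataclass(frozen=True)
class TimeSeriesSchema:
    """Declares the CSV columns and units for :func:`read_timeseries`."""

    time_col: str
    value_col: str
    time_unit: str = "min"
    value_unit: str = "au"
    # unit the series should be converted to on read (canonical by default)
    to_time_unit: str | None = None
    to_value_unit: str | None = None


# ---------------------------------------------------------------------------
# CSV I/O  (comma-separated, UTF-8, one header row, "." decimal point)
# ---------------------------------------------------------------------------
def read_timeseries(path: str | Path, schema: TimeSeriesSchema) -> TimeSeries:
    """Read a two-column CSV time series, validate and convert units.

    Raises :class:`ParseError` naming the offending line for malformed rows and
    :class:`ValidationError` for non-monotone time stamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        header = [h.strip() for h in header]
        for col in (schema.time_col, schema.value_col):
            if col not in header:
                raise ParseError(f"column {col!r} not found in header {header}", line=1)
        i_t = header.index(schema.time_col)
        i_y = header.index(schema.value_col)
        t, y = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(parts)}", line=lineno
                )
            try:
                t.append(float(parts[i_t]))
                y.append(float(parts[i_y]))
            except ValueError as exc:
                raise ParseError(f"could not parse number: {exc}", line=lineno) from exc
    series = TimeSeries(np.array(t), np.array(y), schema.time_unit, schema.value_unit)
    if schema.to_time_unit:
        series = series.to_time_unit(schema.to_time_unit)
    if schema.to_value_unit:
        series = TimeSeries(
            series.t,
            convert(series.y, schema.value_unit, schema.to_value_unit),
            series.t_unit,
            schema.to_value_unit,
            series.replicate_id,
        )
    return series


def write_timeseries(series: TimeSeries, path: str | Path, schema: TimeSeriesSchema) -> None:
    """Write a TimeSeries as CSV with the schema's column names, full precision."""
    df = pd.DataFrame({schema.time_col: series.t, schema.value_col: series.y})
    df.to_csv(Path(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Configuration (YAML key-value tree with a light schema check)
# ---------------------------------------------------------------------------
_CONFIG_SCHEMA: dict[str, type] = {
    "seed": int,
    "geometry": dict,
    "scenario": dict,
    "output_dir": str,
}


def validate_config(cfg: Mapping) -> dict:
    """Check top-level config keys against the expected types; return a dict."""
    if not isinstance(cfg, Mapping):
        raise ValidationError("config root must be a mapping")
    out = dict(cfg)
    for key, value in out.items():
        expected = _CONFIG_SCHEMA.get(key)
        if expected is not None and not isinstance(value, expected):
            raise ValidationError(
                f"config key {key!r} must be {expected.__name__}, got {type(value).__name__}"
            )
    return out


def load_config(path: str | Path) -> dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        return validate_config(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------
_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"


def configure_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=level, format=_LOG_FORMAT, handlers=handlers, force=True)


def get_logger(stage: str) -> logging.Logger:
    return logging.getLogger(f"silkcoat.{stage}")
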