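"""Device CSV import via a registry of declarative per-device dialects.

Wearable light loggers all export delimited text, but no two agree on
delimiter, decimal mark, header, timestamp format or column names.  Each
supported device is described by one YAML *dialect* shipped with the
package (``luxtrace/dialects/``); :func:`import_files` turns exports into
:class:`~luxtrace.core.LightSeries` using only the dialect, so adding a
device means adding a config, not a parser.

The dialect layouts are declarative stand-ins exercised against generated
fixtures (see :mod:`luxtrace.synthetic`); faithfulness to each vendor's
real export is deferred until real sample files are available.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import LightSeries, dominant_epoch


class UnknownDeviceError(KeyError):
    pass


class PreprocessingRequiredError(RuntimeError):
    """Raised for devices whose raw exports need external preprocessing."""


@dataclass(frozen=True)
class ChannelSpec:
    column: object  # name, or integer position for headerless files
    name: str
    unit: str = "lx"


@dataclass(frozen=True)
class DeviceDialect:
    """Declarative description of one device's CSV export."""

    name: str
    manufacturer: str
    delimiter: str = ","
    skip_rows: int = 0
    header: bool = True
    decimal_mark: str = "."
    timestamp_columns: tuple = ("Datetime",)
    timestamp_format: str | None = None  # None -> ISO-8601
    timezone_policy: str = "supplied"  # or "embedded"
    channels: tuple = ()
    id_column: object | None = None
    requires_preprocessing: bool = False
    preprocessing_note: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp_columns:
            raise ValueError(f"dialect {self.name!r}: needs a timestamp column")
        if not self.channels:
            raise ValueError(f"dialect {self.name!r}: needs at least one light channel")
        if self.timezone_policy not in ("embedded", "supplied"):
            raise ValueError(f"dialect {self.name!r}: bad timezone policy")

    @classmethod
    def from_dict(cls, raw: dict) -> "DeviceDialect":
        ts = raw.get("timestamp", {})
        cols = ts.get("columns") or [ts.get("column", "Datetime")]
        return cls(
            name=raw["name"],
            manufacturer=raw.get("manufacturer", ""),
            delimiter=raw.get("delimiter", ","),
            skip_rows=int(raw.get("skip_rows", 0)),
            header=bool(raw.get("header", True)),
            decimal_mark=raw.get("decimal_mark", "."),
            timestamp_columns=tuple(cols),
            timestamp_format=ts.get("format"),
            timezone_policy=ts.get("timezone", "supplied"),
            channels=tuple(
                ChannelSpec(c["column"], c["name"], c.get("unit", "lx"))
                for c in raw.get("channels", [])
            ),
            id_column=raw.get("id_column"),
            requires_preprocessing=bool(raw.get("requires_preprocessing", False)),
            preprocessing_note=raw.get("preprocessing_note", ""),
        )


@dataclass
class ImportReport:
    """Bookkeeping of one import run; rows_parsed = rows_emitted + dropped."""

    files: list = field(default_factory=list)
    rows_parsed: int = 0
    rows_emitted: int = 0
    rows_dropped: Counter = field(default_factory=Counter)
    epoch: float | None = None
    ids: list = field(default_factory=list)
    time_range: tuple | None = None
    interval_histogram: Counter = field(default_factory=Counter)

    @property
    def total_dropped(self) -> int:
        return sum(self.rows_dropped.values())

    def to_dict(self) -> dict:
        return {
            "files": [str(f) for f in self.files],
            "rows_parsed": self.rows_parsed,
            "rows_emitted": self.rows_emitted,
            "rows_dropped": dict(self.rows_dropped),
            "epoch_seconds": self.epoch,
            "ids": self.ids,
            "time_range": [str(t) for t in self.time_range] if self.time_range else None,
            "interval_histogram_seconds": {
                str(k): v for k, v in sorted(self.interval_histogram.items())
            },
        }


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_registry: dict[str, DeviceDialect] | None = None


def _load_registry() -> dict[str, DeviceDialect]:
    global _registry
    if _registry is None:
        _registry = {}
        root = resources.files("luxtrace") / "dialects"
        for entry in sorted(root.iterdir(), key=lambda p: p.name):
            if entry.name.endswith(".yaml"):
                dialect = DeviceDialect.from_dict(yaml.safe_load(entry.read_text()))
                if dialect.name in _registry:
                    raise ValueError(f"duplicate dialect name {dialect.name!r}")
                _registry[dialect.name] = dialect
    return _registry


def list_supported_devices() -> list[str]:
    """Names of all registered device dialects, sorted."""
    return sorted(_load_registry())


def get_dialect(device_name: str) -> DeviceDialect:
    registry = _load_registry()
    if device_name not in registry:
        raise UnknownDeviceError(
            f"unknown device {device_name!r}; supported devices: "
            + ", ".join(sorted(registry))
        )
    return registry[device_name]


def register_dialect(dialect: DeviceDialect) -> None:
    _load_registry()[dialect.name] = dialect


def unregister_dialect(device_name: str) -> DeviceDialect:
    return _load_registry().pop(device_name)


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------


def _exact_float(text) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        return float("nan")


def _parse_timestamps(table: pd.DataFrame, dialect: DeviceDialect, tz: str | None):
    parts = table[list(dialect.timestamp_columns)].astype(str)
    text = parts.iloc[:, 0].str.cat(parts.iloc[:, 1:], sep=" ") if parts.shape[1] > 1 else parts.iloc[:, 0]
    if dialect.timezone_policy == "embedded":
        parsed = pd.to_datetime(text, errors="coerce", utc=True)
        if tz is not None:
            parsed = parsed.dt.tz_convert(tz)
        return parsed
    parsed = pd.to_datetime(text, format=dialect.timestamp_format, errors="coerce")
    if tz is None:
        raise ValueError(
            f"device {dialect.name!r} exports naive timestamps; a timezone is required"
        )
    return parsed.dt.tz_localize(tz)


def import_files(
    paths,
    device_name: str,
    tz: str | None = None,
    id_pattern: str | None = None,
    preprocessed: bool = False,
) -> tuple[list[LightSeries], ImportReport]:
    """Import device exports into one LightSeries per detected id.

    The id comes from an in-file column when the dialect declares one,
    otherwise from the filename via *id_pattern* (a regex whose first
    group is the id; default: the file stem).  Rows with unparseable
    timestamps are dropped and counted; more than 50% dropped raises.
    Duplicate timestamps within an id keep the first occurrence.
    """
    dialect = get_dialect(device_name)
    if dialect.requires_preprocessing and not preprocessed:
        raise PreprocessingRequiredError(
            f"{dialect.name} exports must be preprocessed externally before import "
            f"({dialect.preprocessing_note}); pass preprocessed=True once that is done"
        )
    if isinstance(paths, (str, Path)):
        paths = [paths]
    report = ImportReport(files=[Path(p) for p in paths])
    pieces: dict[str, list[pd.DataFrame]] = {}

    for path in report.files:
        if not path.exists():
            raise FileNotFoundError(path)
        as_str = {c: str for c in dialect.timestamp_columns}
        if dialect.decimal_mark != ".":
            # parse non-dot decimals by hand: pandas' locale decimal parser
            # is not exact to the last ulp, which would break round-trips
            as_str.update({c.column: str for c in dialect.channels})
        table = pd.read_csv(
            path,
            sep=dialect.delimiter,
            skiprows=dialect.skip_rows,
            header=0 if dialect.header else None,
            dtype=as_str,
            float_precision="round_trip",
        )
        report.rows_parsed += len(table)
        if len(table) == 0:
            continue
        when = _parse_timestamps(table, dialect, tz)
        bad = when.isna()
        report.rows_dropped["unparseable timestamp"] += int(bad.sum())
        table, when = table[~bad], when[~bad]

        frame = pd.DataFrame(index=pd.DatetimeIndex(when))
        for ch in dialect.channels:
            col = table[ch.column] if dialect.header else table[int(ch.column)]
            if dialect.decimal_mark != ".":
                col = col.str.replace(dialect.decimal_mark, ".", regex=False)
                # float() round-trips repr() exactly; pd.to_numeric does not
                frame[ch.name] = col.map(_exact_float).to_numpy()
            else:
                frame[ch.name] = pd.to_numeric(col, errors="coerce").to_numpy()
        if dialect.id_column is not None:
            ids = table[dialect.id_column].astype(str).to_numpy()
        else:
            pattern = id_pattern or r"(.+)"
            match = re.search(pattern, path.stem)
            if not match:
                raise ValueError(f"id pattern {pattern!r} does not match {path.name!r}")
            ids = np.full(len(frame), match.group(1), dtype=object)
        frame["_id"] = ids
        for sid, sub in frame.groupby("_id", sort=False):
            pieces.setdefault(str(sid), []).append(sub.drop(columns="_id"))

    series_out = []
    for sid, frames in pieces.items():
        merged = pd.concat(frames).sort_index(kind="stable")
        dup = merged.index.duplicated(keep="first")
        report.rows_dropped["duplicate timestamp"] += int(dup.sum())
        merged = merged[~dup]
        series_out.append(LightSeries(id=sid, data=merged))
        report.interval_histogram.update(
            (np.diff(merged.index.asi8) / 1e9).tolist()
        )

    report.rows_emitted = sum(s.n for s in series_out)
    if report.rows_parsed and report.total_dropped > 0.5 * report.rows_parsed:
        raise ValueError(
            f"more than half of the rows were dropped "
            f"({report.total_dropped}/{report.rows_parsed}); wrong device dialect?"
        )
    report.ids = sorted(pieces)
    if series_out:
        all_ts = [t for s in series_out for t in (s.timestamps[0], s.timestamps[-1])]
        report.time_range = (min(all_ts), max(all_ts))
        epochs = [s.epoch for s in series_out if s.epoch is not None]
        if epochs:
            report.epoch = Counter(epochs).most_common(1)[0][0]
    return series_out, report


# ---------------------------------------------------------------------------
# writing (fixture generation support)
# ---------------------------------------------------------------------------


def _format_number(value: float, decimal_mark: str) -> str:
    if np.isnan(value):
        return ""
    text = repr(float(value))
    return text.replace(".", decimal_mark) if decimal_mark != "." else text


def write_dialect_csv(series: LightSeries, dialect: DeviceDialect, path) -> None:
    """Write a series as a file conforming to the dialect (inverse of
    :func:`import_files`); used by the synthetic fixture generator."""
    lines = []
    for i in range(dialect.skip_rows):
        lines.append(f"# {dialect.name} export preamble line {i + 1}")
    n_ts = len(dialect.timestamp_columns)
    if dialect.header:
        cols = list(dialect.timestamp_columns) + [str(c.column) for c in dialect.channels]
        if dialect.id_column is not None:
            cols.append(str(dialect.id_column))
        lines.append(dialect.delimiter.join(cols))

    naive = series.timestamps.tz_localize(None)
    for i, ts in enumerate(series.timestamps):
        if dialect.timezone_policy == "embedded":
            ts_fields = [ts.isoformat()]
        else:
            fmt = dialect.timestamp_format or "%Y-%m-%d %H:%M:%S"
            stamp = naive[i].strftime(fmt)
            ts_fields = stamp.split(" ", n_ts - 1) if n_ts > 1 else [stamp]
        row = list(ts_fields)
        for j, ch in enumerate(dialect.channels):
            # match by channel name, else positionally among numeric channels
            if ch.name in series.data:
                value = series.data[ch.name].iloc[i]
            elif j < len(series.numeric_channels):
                value = series.data[series.numeric_channels[j]].iloc[i]
            else:
                value = np.nan
            row.append(_format_number(float(value), dialect.decimal_mark))
        if dialect.id_column is not None:
            row.append(series.id)
        lines.append(dialect.delimiter.join(row))
    Path(path).write_text("\n".join(lines) + "\n")
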