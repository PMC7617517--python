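"""Canonical time-series data model for wearable light-exposure records.

A wearable light logger produces one row per *epoch* (its fixed sampling
interval, e.g. 10 s or 1 min): a timestamp plus one or more light channels
(photopic illuminance or melanopic EDI, both in lux).  :class:`LightSeries`
is the in-memory container every other module operates on; it wraps a
pandas DataFrame with a timezone-aware, strictly increasing DatetimeIndex.

Conventions (applied uniformly across the package):

* a timestamp marks the **start** of its epoch, so every duration metric is
  an exact integer multiple of the epoch length;
* missing observations are carried explicitly as NaN — implicitly missing
  rows (absent timestamps) are materialised by :func:`regularize`;
* each series carries a single IANA timezone and all time-of-day
  computations use local wall time.  DST-duplicated or skipped wall hours
  are kept as recorded, never resampled.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Relative tolerance (fraction of the epoch) within which an input
#: timestamp is considered on-grid; absorbs device clock jitter without
#: silently resampling.
GRID_ALIGNMENT_TOL = 0.01

SECONDS_PER_DAY = 86_400


class EpochError(ValueError):
    """Raised when a sampling epoch cannot be inferred or is invalid."""


# ---------------------------------------------------------------------------
# small value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class TimeOfDay:
    """A clock time as seconds since local midnight, wrapping modulo 24 h."""

    seconds: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "seconds", float(self.seconds) % SECONDS_PER_DAY)

    @classmethod
    def from_string(cls, text: str) -> "TimeOfDay":
        """Parse ``"HH:MM"`` or ``"HH:MM:SS"``."""
        parts = [float(p) for p in text.split(":")]
        while len(parts) < 3:
            parts.append(0.0)
        h, m, s = parts
        return cls(h * 3600 + m * 60 + s)

    def shifted(self, delta_seconds: float) -> "TimeOfDay":
        return TimeOfDay(self.seconds + delta_seconds)

    @property
    def hours(self) -> float:
        return self.seconds / 3600.0

    def __str__(self) -> str:
        total = int(round(self.seconds)) % SECONDS_PER_DAY
        h, rem = divmod(total, 3600)
        m, s = divmod(rem, 60)
        return f"{h:02d}:{m:02d}:{s:02d}"


@dataclass(frozen=True)
class ThresholdSpec:
    """Comparator shared by every threshold-family metric.

    ``above`` means value >= lower, ``below`` means value <= lower and
    ``within`` means lower <= value <= upper (closed interval).  Bounds are
    in the series' light units (lux or melanopic-EDI lux).
    """

    mode: str
    lower: float
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("above", "below", "within"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "within":
            if self.upper is None:
                raise ValueError("mode 'within' requires an upper bound")
            if self.lower > self.upper:
                raise ValueError("'within' requires lower <= upper")

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Boolean qualification mask; NaN inputs yield False."""
        x = np.asarray(values, dtype=float)
        if self.mode == "above":
            return x >= self.lower
        if self.mode == "below":
            return x <= self.lower
        return (x >= self.lower) & (x <= self.upper)


# ---------------------------------------------------------------------------
# the series container
# ---------------------------------------------------------------------------


@dataclass
class LightSeries:
    """Per-participant ordered light-exposure time series.

    Parameters
    ----------
    id:
        Participant / device identifier.
    data:
        DataFrame indexed by timezone-aware timestamps (strictly
        increasing), one column per light channel; NaN marks a missing
        observation.  Non-numeric columns (e.g. a ``State`` channel joined
        from a sleep diary) are allowed and ignored by numeric validation.
    epoch:
        Dominant sampling interval in seconds.  Inferred from the
        timestamps when omitted (requires >= 2 rows).
    """

    id: str
    data: pd.DataFrame
    epoch: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("LightSeries requires a DatetimeIndex")
        if self.data.index.tz is None:
            raise ValueError("LightSeries timestamps must be timezone-aware")
        if len(self.data) > 1 and not self.data.index.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        for col in self.numeric_channels:
            vals = self.data[col].to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"negative light value in channel {col!r}")
        if self.epoch is None and len(self.data) >= 2:
            self.epoch = dominant_epoch(self.data.index)
        if self.epoch is not None and self.epoch <= 0:
            raise EpochError("epoch must be positive")

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def numeric_channels(self) -> list[str]:
        return [c for c in self.data.columns if pd.api.types.is_numeric_dtype(self.data[c])]

    @property
    def main_channel(self) -> str:
        """First numeric channel; the default input of every metric."""
        numeric = self.numeric_channels
        if not numeric:
            raise ValueError(f"series {self.id!r} has no numeric channel")
        return numeric[0]

    @property
    def tz(self):
        return self.data.index.tz

    def values(self, channel: str | None = None) -> np.ndarray:
        return self.data[channel or self.main_channel].to_numpy(dtype=float)

    def missing_fraction(self, channel: str | None = None) -> float:
        if self.n == 0:
            return 0.0
        return float(np.isnan(self.values(channel)).mean())

    def time_of_day_seconds(self) -> np.ndarray:
        """Local wall-clock seconds since midnight of each epoch start."""
        naive = self.data.index.tz_localize(None)
        return (naive - naive.normalize()).total_seconds().to_numpy()

    def local_dates(self) -> np.ndarray:
        return self.data.index.tz_localize(None).normalize().date

    def with_data(self, data: pd.DataFrame, epoch: float | None = None) -> "LightSeries":
        return LightSeries(id=self.id, data=data, epoch=epoch if epoch is not None else self.epoch)

    def split_days(self) -> "list[tuple[object, LightSeries]]":
        """Split at local-midnight boundaries into (date, sub-series) pairs."""
        out = []
        for date, frame in self.data.groupby(self.data.index.tz_localize(None).normalize().date):
            out.append((date, self.with_data(frame)))
        return out

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


# ---------------------------------------------------------------------------
# epoch inference and grid regularization
# ---------------------------------------------------------------------------


def dominant_epoch(timestamps: Sequence | pd.DatetimeIndex) -> float:
    """Modal successive timestamp difference, in seconds.

    Wearable exports are nominally regular but contain implicit gaps, so
    the epoch is the *mode* of the successive differences; ties break
    toward the smaller duration (a gap is a multiple of the true epoch,
    never a fraction of it).
    """
    idx = pd.DatetimeIndex(timestamps)
    if len(idx) < 2:
        raise EpochError("cannot infer epoch: need at least 2 timestamps")
    diffs = np.diff(idx.asi8) / 1e9
    counts = Counter(diffs)
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return float(best[0])


def _grid_positions(index: pd.DatetimeIndex, start: pd.Timestamp, epoch: float) -> np.ndarray:
    """Integer grid slot of each timestamp; raises on the first misaligned one."""
    offsets = (index.asi8 - start.value) / 1e9
    slots = np.round(offsets / epoch)
    resid = np.abs(offsets - slots * epoch)
    bad = np.nonzero(resid > GRID_ALIGNMENT_TOL * epoch)[0]
    if bad.size:
        raise ValueError(
            f"timestamp {index[bad[0]]} is not aligned to the {epoch:g}-s grid"
        )
    return slots.astype(np.int64)


def regularize(series: LightSeries, epoch: float | None = None) -> LightSeries:
    """Expand a series onto the complete epoch grid from first to last row.

    Grid instants absent from the input become explicit missing rows (NaN
    in every channel); rows present in the input are carried through
    unchanged.  Input timestamps must sit on the grid to within
    ``GRID_ALIGNMENT_TOL`` of the epoch, else a ``ValueError`` names the
    first offending timestamp.  Idempotent.
    """
    if epoch is None:
        epoch = series.epoch
    if epoch is None or epoch <= 0:
        raise EpochError("epoch must be positive")
    if series.n == 0:
        return series.with_data(series.data.copy(), epoch=epoch)
    start = series.timestamps[0]
    slots = _grid_positions(series.timestamps, start, epoch)
    n_grid = int(slots[-1]) + 1
    # grid instants only fill the holes; rows present in the input keep
    # their recorded (possibly jittered) timestamps and values verbatim
    grid = start + pd.to_timedelta(np.arange(n_grid) * epoch, unit="s")
    index = np.array(grid, dtype=object)
    index[slots] = np.array(series.timestamps, dtype=object)
    out = series.data.reindex(pd.DatetimeIndex(index, tz=series.tz))
    return series.with_data(out, epoch=epoch)


# ---------------------------------------------------------------------------
# canonical on-disk form
# ---------------------------------------------------------------------------


def write_tidy_csv(series_list: Iterable[LightSeries], path) -> None:
    """Write series to the canonical tidy CSV: Id, Datetime (ISO-8601 with
    offset), one column per channel; missing as empty field."""
    frames = []
    for s in series_list:
        frame = s.data.copy()
        frame.insert(0, "Id", s.id)
        frame.insert(1, "Datetime", s.timestamps.map(lambda t: t.isoformat()))
        frames.append(frame.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tidy_csv(path, tz: str | None = None) -> list[LightSeries]:
    """Read the canonical tidy CSV back into one LightSeries per Id."""
    table = pd.read_csv(path)
    out = []
    for sid, group in table.groupby("Id", sort=False):
        idx = pd.DatetimeIndex(pd.to_datetime(group["Datetime"], utc=True))
        if tz is not None:
            idx = idx.tz_convert(tz)
        frame = group.drop(columns=["Id", "Datetime"]).set_axis(idx)
        out.append(LightSeries(id=str(sid), data=frame))
    return out
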