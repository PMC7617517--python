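"""Preprocessing of light-exposure series.

Covers the steps a dosimetry analyst runs between import and metrics:
finding and handling implicitly missing data (wear gaps), aggregating to
coarser epochs, filtering by date / time of day, annotating epochs with
states from an interval table (e.g. a sleep diary) and combining several
series onto one grid.

All interval semantics are closed-start / open-end, matching the
epoch-start attribution of :mod:`luxtrace.core`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import LightSeries, _grid_positions, regularize

GAP_COLUMNS = ["Id", "Start", "End", "DurationSeconds", "Epochs"]
INTERVAL_COLUMNS = ["Id", "State", "Start", "End"]

#: provenance channel added by :func:`fill_gaps`
FILLED_CHANNEL = "Filled"


# ---------------------------------------------------------------------------
# implicit gaps
# ---------------------------------------------------------------------------


def find_gaps(series: LightSeries) -> pd.DataFrame:
    """Maximal runs of grid instants absent from the series.

    Returns a GapTable DataFrame (Id, Start, End, DurationSeconds, Epochs)
    with non-overlapping, ordered gaps; Start is the first missing epoch
    start, End the open end (Start + Epochs x epoch).
    """
    epoch = series.epoch
    if epoch is None:
        raise ValueError("series has no inferred epoch")
    if series.n == 0:
        return pd.DataFrame(columns=GAP_COLUMNS)
    start = series.timestamps[0]
    slots = _grid_positions(series.timestamps, start, epoch)
    present = np.zeros(int(slots[-1]) + 1, dtype=bool)
    present[slots] = True
    missing = ~present
    rows = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
    for lo, hi in zip(edges[::2], edges[1::2]):
        n_epochs = int(hi - lo)
        gap_start = start + pd.to_timedelta(lo * epoch, unit="s")
        rows.append(
            {
                "Id": series.id,
                "Start": gap_start,
                "End": gap_start + pd.to_timedelta(n_epochs * epoch, unit="s"),
                "DurationSeconds": n_epochs * epoch,
                "Epochs": n_epochs,
            }
        )
    return pd.DataFrame(rows, columns=GAP_COLUMNS)


def fill_gaps(
    series: LightSeries,
    policy: str = "missing",
    max_span: int | None = None,
) -> LightSeries:
    """Complete the epoch grid, filling inserted rows per *policy*.

    policy:
        ``"missing"`` (default) — inserted rows stay NaN;
        ``"zero"`` — inserted rows get 0 in every numeric channel;
        ``"locf"`` — last observation carried forward into inserted rows,
        at most *max_span* consecutive epochs (unfillable rows, e.g. a gap
        at the series start, stay NaN).

    A boolean provenance channel ``Filled`` marks every inserted row.
    """
    if policy not in ("missing", "zero", "locf"):
        raise ValueError(f"unknown gap-fill policy {policy!r}")
    if policy == "locf" and (max_span is None or max_span < 1):
        raise ValueError("locf requires max_span >= 1 (epochs)")
    reg = regularize(series)
    inserted = ~reg.timestamps.isin(series.timestamps)
    frame = reg.data.copy()
    numeric = [c for c in frame.columns if pd.api.types.is_numeric_dtype(frame[c])]
    if policy == "zero":
        frame.loc[inserted, numeric] = 0.0
    elif policy == "locf":
        filled = frame[numeric].ffill(limit=max_span)
        frame.loc[inserted, numeric] = filled.loc[inserted, numeric]
    frame[FILLED_CHANNEL] = inserted
    return reg.with_data(frame)


# ---------------------------------------------------------------------------
# aggregation and filtering
# ---------------------------------------------------------------------------


def _local_bins(index: pd.DatetimeIndex, width_seconds: float) -> pd.DatetimeIndex:
    """Floor local wall time into windows of *width_seconds* anchored at
    local midnight (day-based metrics need midnight alignment)."""
    naive = index.tz_localize(None)
    since_midnight = (naive - naive.normalize()).total_seconds().to_numpy()
    binned = naive.normalize() + pd.to_timedelta(
        np.floor(since_midnight / width_seconds) * width_seconds, unit="s"
    )
    return binned.tz_localize(index.tz)


def aggregate(
    series: LightSeries,
    target_epoch: float,
    numeric_agg: str = "mean",
) -> LightSeries:
    """Aggregate to a coarser epoch with midnight-anchored windows.

    Numeric channels combine by *numeric_agg* (``mean`` default, or any
    pandas aggregation name such as ``median``/``sum``/``max``);
    categorical channels take the modal value.  An all-missing window
    yields a missing value.
    """
    if series.epoch is None:
        raise ValueError("series has no inferred epoch")
    ratio = target_epoch / series.epoch
    if target_epoch < series.epoch or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("target_epoch must be an integer multiple of the series epoch")
    bins = _local_bins(series.timestamps, target_epoch)
    grouped = series.data.groupby(bins)
    pieces = {}
    for col in series.data.columns:
        if pd.api.types.is_numeric_dtype(series.data[col]):
            pieces[col] = grouped[col].agg(numeric_agg)
        else:
            pieces[col] = grouped[col].agg(
                lambda s: s.mode().iloc[0] if s.notna().any() else None
            )
    out = pd.DataFrame(pieces)
    out.index.name = None
    return series.with_data(out, epoch=float(target_epoch))


def filter_time(
    series: LightSeries,
    date_range: tuple | None = None,
    time_of_day_range: tuple | None = None,
) -> LightSeries:
    """Keep rows by local date and/or local time of day.

    Both ranges are closed-start / open-end.  *date_range* is a pair of
    dates (or parseable strings); *time_of_day_range* a pair of
    :class:`~luxtrace.core.TimeOfDay` (or ``"HH:MM"`` strings) and may wrap
    midnight, e.g. ``("22:00", "06:00")``.
    """
    from .core import TimeOfDay

    mask = np.ones(series.n, dtype=bool)
    if date_range is not None:
        start = pd.Timestamp(date_range[0]).normalize()
        end = pd.Timestamp(date_range[1]).normalize()
        local = series.timestamps.tz_localize(None).normalize()
        mask &= (local >= start) & (local < end)
    if time_of_day_range is not None:
        lo, hi = (
            t if isinstance(t, TimeOfDay) else TimeOfDay.from_string(t)
            for t in time_of_day_range
        )
        tod = series.time_of_day_seconds()
        if lo.seconds < hi.seconds:
            mask &= (tod >= lo.seconds) & (tod < hi.seconds)
        else:  # wraps midnight
            mask &= (tod >= lo.seconds) | (tod < hi.seconds)
    return series.with_data(series.data.loc[mask])


# ---------------------------------------------------------------------------
# interval (sleep-diary) joining
# ---------------------------------------------------------------------------


def read_intervals(path, tz: str | None = None) -> pd.DataFrame:
    """Read an IntervalTable CSV (Id, State, Start, End; ISO-8601)."""
    table = pd.read_csv(path)
    for col in ("Start", "End"):
        parsed = pd.DatetimeIndex(pd.to_datetime(table[col], utc=True))
        table[col] = parsed.tz_convert(tz) if tz else parsed
    return validate_intervals(table)


def write_intervals(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in ("Start", "End"):
        out[col] = [t.isoformat() for t in out[col]]
    out.to_csv(path, index=False)


def validate_intervals(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTERVAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"interval table lacks columns {missing}")
    if (pd.to_datetime(table["Start"]) >= pd.to_datetime(table["End"])).any():
        raise ValueError("interval table has rows with Start >= End")
    return table


def interval_to_state(
    series: LightSeries,
    intervals: pd.DataFrame,
    default_state: str = "default",
    state_channel: str = "State",
) -> LightSeries:
    """Annotate each epoch with the state of the interval covering its
    start instant (closed-start / open-end), else *default_state*.

    Intervals for one id must not overlap; an overlap raises a
    ``ValueError`` naming the first overlapping pair.
    """
    validate_intervals(intervals)
    rows = intervals[intervals["Id"].astype(str) == str(series.id)]
    rows = rows.sort_values("Start").reset_index(drop=True)
    starts = pd.DatetimeIndex(rows["Start"])
    ends = pd.DatetimeIndex(rows["End"])
    for i in range(1, len(rows)):
        if starts[i] < ends[i - 1]:
            raise ValueError(
                f"overlapping intervals for id {series.id!r}: "
                f"[{starts[i - 1]}, {ends[i - 1]}) overlaps [{starts[i]}, {ends[i]})"
            )
    labels = np.full(series.n, default_state, dtype=object)
    if len(rows):
        pos = np.searchsorted(starts.asi8, series.timestamps.asi8, side="right") - 1
        valid = pos >= 0
        covered = valid.copy()
        covered[valid] &= series.timestamps.asi8[valid] < ends.asi8[pos[valid]]
        labels[covered] = rows["State"].to_numpy()[pos[covered]]
    frame = series.data.copy()
    frame[state_channel] = labels
    return series.with_data(frame)


# ---------------------------------------------------------------------------
# combining series
# ---------------------------------------------------------------------------


def join_series(series_list: Sequence[LightSeries]) -> LightSeries:
    """Outer-join several series onto one grid.

    Each series is first brought to the coarsest epoch among the inputs
    (finer series are aggregated with midnight-anchored means; the coarse
    epoch must be an integer multiple of each input epoch).  Channels that
    collide across sources are suffixed with the source id.  The joined
    series takes the first input's id.
    """
    if not series_list:
        raise ValueError("join_series needs at least one series")
    coarse = max(s.epoch for s in series_list)
    aligned = [
        aggregate(s, coarse) if s.epoch < coarse else s for s in series_list
    ]
    frames, seen = [], set()
    for s in aligned:
        frame = s.data.copy()
        frame.columns = [
            f"{c}_{s.id}" if c in seen else c for c in frame.columns
        ]
        seen.update(frame.columns)
        frames.append(frame)
    joined = pd.concat(frames, axis=1, join="outer").sort_index()
    return LightSeries(id=series_list[0].id, data=joined, epoch=coarse)
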