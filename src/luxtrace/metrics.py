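"""Metric engine for personal light-exposure series.

Implements the field's standard exposure metrics — threshold durations and
timing (TAT/MLiT-style), longest periods and pulses above/below/within a
threshold, brightest/darkest rolling windows (M10/L5-style), centroid and
midpoint of cumulative exposure, interdaily stability (IS) and intradaily
variability (IV), exponential moving-average smoothing, disparity index,
cumulative dose, the Barroso lighting-regularity family, and modelled
non-visual direct (nvRD) and circadian (nvRC) responses to melanopic
light — 61 metrics across 17 families, enumerated by
:func:`metric_registry`.

Every metric operates on one :class:`~luxtrace.core.LightSeries` (one id;
:func:`compute_metrics` drives them over ids and local days) and returns
:class:`MetricResult` objects.  All metrics accept an ``ignore_missing``
flag (default: missing epochs are ignored and their fraction reported);
an empty qualifying set or zero-variance input yields a typed *undefined*
result carrying a reason, never a silent number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    SECONDS_PER_DAY,
    LightSeries,
    ThresholdSpec,
    TimeOfDay,
)

# ---------------------------------------------------------------------------
# result and parameter types
# ---------------------------------------------------------------------------


@dataclass
class MetricResult:
    """Named scalar (or TimeOfDay / duration) emitted by a metric."""

    family: str
    metric: str
    value: object  # float | TimeOfDay | None when undefined
    units: str
    parameters: dict = field(default_factory=dict)
    missing_fraction: float = 0.0
    reason: str | None = None  # set when value is undefined

    @property
    def defined(self) -> bool:
        return self.value is not None

    def numeric(self) -> float:
        """Value as a float (TimeOfDay -> seconds since midnight)."""
        if self.value is None:
            return math.nan
        if isinstance(self.value, TimeOfDay):
            return self.value.seconds
        return float(self.value)


@dataclass(frozen=True)
class PulseSpec:
    """Pulse detection parameters: comparator plus shape constraints.

    A pulse is a maximal run of qualifying epochs in which non-qualifying
    interruptions no longer than ``max_interrupt`` seconds do not break the
    run, kept only if its total duration (interruptions included) is at
    least ``min_duration`` seconds.
    """

    threshold: ThresholdSpec
    min_duration: float = 1800.0
    max_interrupt: float = 300.0

    def __post_init__(self) -> None:
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if self.max_interrupt < 0:
            raise ValueError("max_interrupt must be nonnegative")


@dataclass(frozen=True)
class SmoothingSpec:
    """Exponential smoothing by half-life.

    The per-epoch weight is ``lambda = 1 - 2**(-epoch/half_life)``, so the
    smoothed response to a unit step reaches 0.5 one half-life after the
    step (within one epoch of discretisation).
    """

    half_life: float = 1800.0  # seconds

    def weight(self, epoch: float) -> float:
        lam = 1.0 - 2.0 ** (-epoch / self.half_life)
        if not 0.0 < lam <= 1.0:
            raise ValueError("smoothing weight outside (0, 1]")
        return lam


@dataclass(frozen=True)
class ResponseParams:
    """Parameters of the modelled non-visual light responses.

    The direct response is a Hill function of exponentially-filtered
    melanopic light history; the circadian response additionally modulates
    it by a sinusoidal sensitivity over the day.
    """

    hill_exponent: float = 2.0  # n_h
    half_max: float = 100.0  # C50, melanopic-EDI lux
    history_half_life: float = 3600.0  # tau_h, seconds
    sensitivity_amplitude: float = 0.5  # a in [0, 1]
    peak_phase: TimeOfDay = TimeOfDay(3 * 3600)  # phi

    def __post_init__(self) -> None:
        if self.hill_exponent <= 0 or self.half_max <= 0:
            raise ValueError("hill_exponent and half_max must be positive")
        if not 0.0 <= self.sensitivity_amplitude <= 1.0:
            raise ValueError("sensitivity_amplitude must be in [0, 1]")


@dataclass(frozen=True)
class BinningSpec:
    """Clock-time binning for IS/IV: *bins_per_cycle* bins of *bin_width*
    seconds per cycle (default 24 x 1 h)."""

    cycle: float = float(SECONDS_PER_DAY)
    bin_width: float = 3600.0

    def __post_init__(self) -> None:
        ratio = self.cycle / self.bin_width
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("cycle must be divisible by bin_width")

    @property
    def bins_per_cycle(self) -> int:
        return int(round(self.cycle / self.bin_width))


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _prep(series: LightSeries, channel: str | None, ignore_missing: bool):
    """Common entry: values, time-of-day, epoch, missingness bookkeeping."""
    if series.n == 0:
        raise ValueError(f"series {series.id!r} is empty")
    if series.epoch is None:
        raise ValueError("series has no inferred epoch")
    x = series.values(channel)
    miss = np.isnan(x)
    frac = float(miss.mean())
    tod = series.time_of_day_seconds()
    return x, miss, frac, tod, float(series.epoch)


def _undefined(family, metric, units, reason, frac, **params) -> MetricResult:
    return MetricResult(family, metric, None, units, dict(params), frac, reason)


def _check_missing(ignore_missing: bool, miss: np.ndarray) -> str | None:
    """Reason string when missingness forbids computation, else None."""
    if miss.all():
        return "all input epochs missing"
    if not ignore_missing and miss.any():
        return "missing epochs present and ignore_missing=False"
    return None


def _mean_tod(seconds: np.ndarray, circular: bool) -> TimeOfDay:
    if circular:
        ang = seconds / SECONDS_PER_DAY * 2 * np.pi
        mean = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        return TimeOfDay(mean / (2 * np.pi) * SECONDS_PER_DAY)
    return TimeOfDay(float(np.mean(seconds)))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap_epochs: int) -> list[tuple[int, int]]:
    """Merge runs separated by interruptions of <= max_gap_epochs epochs."""
    merged: list[list[int]] = []
    for lo, hi in runs:
        if merged and lo - merged[-1][1] <= max_gap_epochs:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


# ---------------------------------------------------------------------------
# threshold family metrics
# ---------------------------------------------------------------------------

DURATION_FAMILY = "Duration above threshold"
TIMING_FAMILY = "Timing above threshold"
PERIOD_FAMILY = "Period above threshold"
FREQUENCY_FAMILY = "Frequency crossing threshold"
THRESHOLD_FOR_DURATION_FAMILY = "Threshold for duration"
PULSES_FAMILY = "Pulses above threshold"


def duration_above_threshold(
    series: LightSeries,
    spec: ThresholdSpec,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """Total time spent satisfying the comparator: qualifying epochs x epoch."""
    x, miss, frac, _, epoch = _prep(series, channel, ignore_missing)
    name = f"duration_{spec.mode}"
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(DURATION_FAMILY, name, "s", reason, frac, threshold=spec)
    q = spec.apply(x) & ~miss
    return MetricResult(
        DURATION_FAMILY, name, float(q.sum()) * epoch, "s", {"threshold": spec}, frac
    )


def timing_above_threshold(
    series: LightSeries,
    spec: ThresholdSpec,
    channel: str | None = None,
    circular: bool = False,
    ignore_missing: bool = True,
) -> MetricResult:
    """Mean local clock time of qualifying epoch starts (MLiT-style)."""
    x, miss, frac, tod, _ = _prep(series, channel, ignore_missing)
    name = f"timing_{spec.mode}"
    params = {"threshold": spec, "circular": circular}
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(TIMING_FAMILY, name, "time of day", reason, frac, **params)
    q = spec.apply(x) & ~miss
    if not q.any():
        return _undefined(
            TIMING_FAMILY, name, "time of day", "no qualifying epochs", frac, **params
        )
    return MetricResult(
        TIMING_FAMILY, name, _mean_tod(tod[q], circular), "time of day", params, frac
    )


def period_above_threshold(
    series: LightSeries,
    spec: ThresholdSpec,
    max_interrupt: float = 0.0,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """Longest continuous period satisfying the comparator.

    Interruptions (non-qualifying or missing stretches) no longer than
    *max_interrupt* seconds do not break a period; the returned duration
    includes any bridged interruptions.
    """
    x, miss, frac, _, epoch = _prep(series, channel, ignore_missing)
    name = f"period_{spec.mode}"
    params = {"threshold": spec, "max_interrupt": max_interrupt}
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(PERIOD_FAMILY, name, "s", reason, frac, **params)
    q = spec.apply(x) & ~miss
    if not q.any():
        return _undefined(PERIOD_FAMILY, name, "s", "no qualifying epochs", frac, **params)
    merged = _merge_runs(_runs(q), int(max_interrupt // epoch))
    longest = max(hi - lo for lo, hi in merged)
    return MetricResult(PERIOD_FAMILY, name, longest * epoch, "s", params, frac)


def frequency_crossing_threshold(
    series: LightSeries,
    spec: ThresholdSpec,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """Number of changes of the comparator outcome between successive
    non-missing epochs (comparisons bridge missing epochs)."""
    x, miss, frac, _, _ = _prep(series, channel, ignore_missing)
    params = {"threshold": spec}
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(FREQUENCY_FAMILY, "frequency_crossing", "count", reason, frac, **params)
    q = spec.apply(x[~miss])
    crossings = int(np.count_nonzero(np.diff(q.view(np.int8)))) if q.size >= 2 else 0
    return MetricResult(FREQUENCY_FAMILY, "frequency_crossing", crossings, "count", params, frac)


def threshold_for_duration(
    series: LightSeries,
    duration: float,
    mode: str = "above",
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """Light level such that the series spends at least *duration* above
    (below) it: the k-th largest (smallest) value, k = round(duration/epoch).
    """
    if mode not in ("above", "below"):
        raise ValueError("mode must be 'above' or 'below'")
    x, miss, frac, _, epoch = _prep(series, channel, ignore_missing)
    name = f"threshold_{mode}"
    params = {"duration": duration, "mode": mode}
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(THRESHOLD_FOR_DURATION_FAMILY, name, "lx", reason, frac, **params)
    vals = np.sort(x[~miss])
    k = int(round(duration / epoch))
    if k < 1 or k > vals.size:
        raise ValueError(
            f"duration {duration} s outside the series span ({vals.size} epochs of {epoch:g} s)"
        )
    value = vals[-k] if mode == "above" else vals[k - 1]
    return MetricResult(THRESHOLD_FOR_DURATION_FAMILY, name, float(value), "lx", params, frac)


PULSE_METRICS = (
    "count",
    "mean_level",
    "mean_duration",
    "total_duration",
    "mean_onset",
    "mean_midpoint",
    "mean_offset",
)


def pulses_above_threshold(
    series: LightSeries,
    spec: PulseSpec,
    channel: str | None = None,
    circular: bool = False,
    ignore_missing: bool = True,
) -> dict[str, MetricResult]:
    """Detect light pulses and summarise them with 7 metrics.

    Qualifying runs separated by interruptions <= ``spec.max_interrupt``
    are merged (interruptions count toward pulse duration); merged runs
    shorter than ``spec.min_duration`` are discarded.  Returns count, mean
    level within pulses, mean and total pulse duration, and mean onset /
    midpoint / offset clock times.  Zero pulses: count is 0, the other
    metrics are undefined.
    """
    x, miss, frac, tod, epoch = _prep(series, channel, ignore_missing)
    mode = spec.threshold.mode
    params = {"pulse": spec, "circular": circular}

    def name(m: str) -> str:
        return f"pulse_{m}_{mode}"

    units = {
        "count": "count",
        "mean_level": "lx",
        "mean_duration": "s",
        "total_duration": "s",
        "mean_onset": "time of day",
        "mean_midpoint": "time of day",
        "mean_offset": "time of day",
    }
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return {
            m: _undefined(PULSES_FAMILY, name(m), units[m], reason, frac, **params)
            for m in PULSE_METRICS
        }
    q = spec.threshold.apply(x) & ~miss
    merged = _merge_runs(_runs(q), int(spec.max_interrupt // epoch))
    min_epochs = int(math.ceil(spec.min_duration / epoch))
    pulses = [(lo, hi) for lo, hi in merged if hi - lo >= min_epochs]

    out = {
        "count": MetricResult(
            PULSES_FAMILY, name("count"), len(pulses), "count", params, frac
        )
    }
    if not pulses:
        for m in PULSE_METRICS[1:]:
            out[m] = _undefined(
                PULSES_FAMILY, name(m), units[m], "no pulses detected", frac, **params
            )
        return out

    durations = np.array([(hi - lo) * epoch for lo, hi in pulses])
    inside = np.zeros_like(q)
    for lo, hi in pulses:
        inside[lo:hi] = True
    level = float(np.nanmean(x[inside]))
    onsets = np.array([tod[lo] for lo, _ in pulses])
    midpoints = (onsets + durations / 2) % SECONDS_PER_DAY
    offsets = (onsets + durations - epoch) % SECONDS_PER_DAY

    scalars = {
        "mean_level": (level, "lx"),
        "mean_duration": (float(durations.mean()), "s"),
        "total_duration": (float(durations.sum()), "s"),
    }
    for m, (v, u) in scalars.items():
        out[m] = MetricResult(PULSES_FAMILY, name(m), v, u, params, frac)
    for m, vec in (("mean_onset", onsets), ("mean_midpoint", midpoints), ("mean_offset", offsets)):
        out[m] = MetricResult(
            PULSES_FAMILY, name(m), _mean_tod(vec, circular), "time of day", params, frac
        )
    return out


# ---------------------------------------------------------------------------
# brightest / darkest rolling windows
# ---------------------------------------------------------------------------

BRIGHT_DARK_FAMILY = "Bright-dark period"

BRIGHT_WINDOW_DEFAULT = 10 * 3600.0
DARK_WINDOW_DEFAULT = 5 * 3600.0


def bright_dark_period(
    series: LightSeries,
    period: str = "bright",
    window: float | None = None,
    loop: bool = False,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> dict[str, MetricResult]:
    """Rolling window of duration *window* with the extreme mean level.

    ``period="bright"`` finds the window maximising the mean (M10-style,
    default 10 h); ``"dark"`` the minimising one (L5-style, default 5 h).
    ``loop=True`` treats the day circularly so windows may wrap midnight.
    Ties resolve to the earliest onset.  Returns mean level plus onset /
    midpoint / offset clock times of the winning window.
    """
    if period not in ("bright", "dark"):
        raise ValueError("period must be 'bright' or 'dark'")
    if window is None:
        window = BRIGHT_WINDOW_DEFAULT if period == "bright" else DARK_WINDOW_DEFAULT
    x, miss, frac, tod, epoch = _prep(series, channel, ignore_missing)
    params = {"window": window, "loop": loop}
    prefix = "brightest" if period == "bright" else "darkest"
    names = {m: f"{prefix}_{m}" for m in ("mean_level", "onset", "midpoint", "offset")}
    units = {"mean_level": "lx", "onset": "time of day", "midpoint": "time of day", "offset": "time of day"}

    def undef(reason):
        return {
            m: _undefined(BRIGHT_DARK_FAMILY, names[m], units[m], reason, frac, **params)
            for m in names
        }

    reason = _check_missing(ignore_missing, miss)
    if reason:
        return undef(reason)
    w = int(round(window / epoch))
    if w < 1 or w > series.n:
        return undef(f"window of {w} epochs does not fit series of {series.n}")

    vals = np.where(miss, 0.0, x)
    cnt = (~miss).astype(float)
    if loop:
        vals = np.concatenate([vals, vals[: w - 1]])
        cnt = np.concatenate([cnt, cnt[: w - 1]])
        n_windows = series.n
    else:
        n_windows = series.n - w + 1
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0.0], np.cumsum(cnt)))
    sums = csum[w:] - csum[:-w]
    counts = ccnt[w:] - ccnt[:-w]
    sums, counts = sums[:n_windows], counts[:n_windows]
    with np.errstate(invalid="ignore"):
        means = sums / counts  # all-missing window -> NaN, never selected
    if np.isnan(means).all():
        return undef("every candidate window is all-missing")
    best = int(np.nanargmax(means) if period == "bright" else np.nanargmin(means))

    onset = tod[best]
    out = {
        "mean_level": MetricResult(
            BRIGHT_DARK_FAMILY, names["mean_level"], float(means[best]), "lx", params, frac
        ),
        "onset": MetricResult(
            BRIGHT_DARK_FAMILY, names["onset"], TimeOfDay(onset), "time of day", params, frac
        ),
        "midpoint": MetricResult(
            BRIGHT_DARK_FAMILY, names["midpoint"], TimeOfDay(onset + window / 2), "time of day", params, frac
        ),
        "offset": MetricResult(
            BRIGHT_DARK_FAMILY, names["offset"], TimeOfDay(onset + window - epoch), "time of day", params, frac
        ),
    }
    return out


# ---------------------------------------------------------------------------
# exposure timing
# ---------------------------------------------------------------------------

CENTROID_FAMILY = "Centroid of light exposure"
MIDPOINT_FAMILY = "Midpoint of cumulative exposure"


def centroid_of_exposure(
    series: LightSeries,
    channel: str | None = None,
    circular: bool = False,
    ignore_missing: bool = True,
) -> MetricResult:
    """Light-weighted mean clock time: sum(tod_i * x_i) / sum(x_i)."""
    x, miss, frac, tod, _ = _prep(series, channel, ignore_missing)
    params = {"circular": circular}
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(CENTROID_FAMILY, "centroid", "time of day", reason, frac, **params)
    ok = ~miss
    total = float(x[ok].sum())
    if total <= 0:
        return _undefined(
            CENTROID_FAMILY, "centroid", "time of day", "zero total exposure", frac, **params
        )
    if circular:
        ang = tod[ok] / SECONDS_PER_DAY * 2 * np.pi
        mean = math.atan2(
            float((x[ok] * np.sin(ang)).sum()), float((x[ok] * np.cos(ang)).sum())
        )
        value = TimeOfDay(mean / (2 * np.pi) * SECONDS_PER_DAY)
    else:
        value = TimeOfDay(float((tod[ok] * x[ok]).sum() / total))
    return MetricResult(CENTROID_FAMILY, "centroid", value, "time of day", params, frac)


def midpoint_cumulative_exposure(
    series: LightSeries,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """Earliest epoch at which the running dose reaches half the total."""
    x, miss, frac, tod, _ = _prep(series, channel, ignore_missing)
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(MIDPOINT_FAMILY, "midpoint_ce", "time of day", reason, frac)
    cum = np.nancumsum(x)
    total = cum[-1]
    if total <= 0:
        return _undefined(
            MIDPOINT_FAMILY, "midpoint_ce", "time of day", "zero total exposure", frac
        )
    idx = int(np.argmax(cum >= total / 2))
    return MetricResult(MIDPOINT_FAMILY, "midpoint_ce", TimeOfDay(tod[idx]), "time of day", {}, frac)


# ---------------------------------------------------------------------------
# rhythm regularity: IS and IV
# ---------------------------------------------------------------------------

IS_FAMILY = "Interdaily stability"
IV_FAMILY = "Intradaily variability"


def _bin_to_clock(series: LightSeries, binning: BinningSpec, channel: str | None):
    """Binned values with their clock-bin index (bins anchored at local
    midnight); NaN bins dropped."""
    from .preprocess import aggregate

    binned = series if series.epoch == binning.bin_width else aggregate(series, binning.bin_width)
    x = binned.values(channel if channel in binned.channels else None)
    tod = binned.time_of_day_seconds()
    clock_bin = np.floor(tod / binning.bin_width).astype(int) % binning.bins_per_cycle
    ok = ~np.isnan(x)
    return x[ok], clock_bin[ok]


def interdaily_stability(
    series: LightSeries,
    binning: BinningSpec = BinningSpec(),
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """IS: variance of the mean 24-h profile over total variance.

    With x binned to p clock bins per cycle, h indexing clock bins and
    xbar_h the across-days mean of bin h::

        IS = (n * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2)

    1 means the daily profile repeats perfectly; ~0 means no stable
    profile.  Undefined on constant input (zero variance).
    """
    _, miss, frac, _, _ = _prep(series, channel, ignore_missing)
    params = {"binning": binning}
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(IS_FAMILY, "interdaily_stability", "ratio", reason, frac, **params)
    x, clock = _bin_to_clock(series, binning, channel)
    n = x.size
    xbar = x.mean()
    denom = float(((x - xbar) ** 2).sum())
    if denom == 0 or n < 2:
        return _undefined(
            IS_FAMILY, "interdaily_stability", "ratio", "zero variance", frac, **params
        )
    profile = pd.Series(x).groupby(clock).mean()
    num = float(((profile - xbar) ** 2).sum())
    value = (n * num) / (binning.bins_per_cycle * denom)
    return MetricResult(IS_FAMILY, "interdaily_stability", value, "ratio", params, frac)


def intradaily_variability(
    series: LightSeries,
    binning: BinningSpec = BinningSpec(),
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """IV: mean squared successive difference over variance on the binned
    series::

        IV = (n * sum_{i>=2} (x_i - x_{i-1})^2) / ((n-1) * sum_i (x_i - xbar)^2)

    ~0 for a smooth rhythm, exactly 4 for strict alternation (even n).
    Undefined on constant input.
    """
    _, miss, frac, _, _ = _prep(series, channel, ignore_missing)
    params = {"binning": binning}
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(IV_FAMILY, "intradaily_variability", "ratio", reason, frac, **params)
    x, _ = _bin_to_clock(series, binning, channel)
    n = x.size
    if n < 2:
        return _undefined(IV_FAMILY, "intradaily_variability", "ratio", "fewer than 2 bins", frac, **params)
    xbar = x.mean()
    denom = float(((x - xbar) ** 2).sum())
    if denom == 0:
        return _undefined(IV_FAMILY, "intradaily_variability", "ratio", "zero variance", frac, **params)
    num = float((np.diff(x) ** 2).sum())
    value = (n * num) / ((n - 1) * denom)
    return MetricResult(IV_FAMILY, "intradaily_variability", value, "ratio", params, frac)


# ---------------------------------------------------------------------------
# smoothing, disparity, dose
# ---------------------------------------------------------------------------

EMA_FAMILY = "Exponential moving average"
DISPARITY_FAMILY = "Disparity index"
DOSE_FAMILY = "Dose"


def exponential_moving_average(
    series: LightSeries,
    smoothing: SmoothingSpec = SmoothingSpec(),
    channel: str | None = None,
    out_channel: str | None = None,
) -> LightSeries:
    """Exponentially smoothed copy of a channel (series-valued metric).

    s_1 = x_1; s_i = lam*x_i + (1-lam)*s_{i-1} with lam from the half-life.
    A missing x_i leaves the state unchanged and emits a missing output.
    """
    x, _, _, _, epoch = _prep(series, channel, True)
    lam = smoothing.weight(epoch)
    out = np.empty_like(x)
    state = math.nan
    for i, xi in enumerate(x):
        if math.isnan(xi):
            out[i] = math.nan
        else:
            state = xi if math.isnan(state) else lam * xi + (1 - lam) * state
            out[i] = state
    frame = series.data.copy()
    frame[out_channel or f"{channel or series.main_channel}_ema"] = out
    return series.with_data(frame)


def disparity_index(
    series: LightSeries,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """Mean absolute log-ratio of successive (value + 1): quantifies how
    strongly the level jumps between neighbouring epochs."""
    x, miss, frac, _, _ = _prep(series, channel, ignore_missing)
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(DISPARITY_FAMILY, "disparity_index", "ratio", reason, frac)
    vals = x[~miss]
    if vals.size < 2:
        return _undefined(DISPARITY_FAMILY, "disparity_index", "ratio", "fewer than 2 epochs", frac)
    value = float(np.abs(np.diff(np.log(vals + 1.0))).mean())
    return MetricResult(DISPARITY_FAMILY, "disparity_index", value, "ratio", {}, frac)


def dose(
    series: LightSeries,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> MetricResult:
    """Cumulative light dose: sum of x_i * epoch, in lux-hours."""
    x, miss, frac, _, epoch = _prep(series, channel, ignore_missing)
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return _undefined(DOSE_FAMILY, "dose", "lx*h", reason, frac)
    value = float(np.nansum(x)) * epoch / 3600.0
    return MetricResult(DOSE_FAMILY, "dose", value, "lx*h", {}, frac)


# ---------------------------------------------------------------------------
# Barroso lighting-regularity family
# ---------------------------------------------------------------------------

BARROSO_FAMILY = "Barroso"

BARROSO_METRICS = (
    "bright_threshold",
    "dark_threshold",
    "bright_mean_level",
    "dark_mean_level",
    "bright_cluster",
    "dark_cluster",
    "circadian_variation",
)


def barroso_metrics(
    series: LightSeries,
    bright_percentile: float = 90.0,
    dark_percentile: float = 10.0,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> dict[str, MetricResult]:
    """Percentile-based bright/dark structure of the exposure pattern.

    Per local day: the bright (dark) threshold is the 90th (10th)
    percentile of the day's values; mean level and longest cluster
    (run duration) are taken at-or-above (at-or-below) that threshold.
    Daily values are averaged across days.  ``circadian_variation`` is the
    coefficient of variation (sd/mean) of the daily mean levels, requiring
    at least two days.  Percentiles are parameters, not constants.
    """
    _, miss, frac, _, epoch = _prep(series, channel, ignore_missing)
    params = {"bright_percentile": bright_percentile, "dark_percentile": dark_percentile}
    units = {
        "bright_threshold": "lx",
        "dark_threshold": "lx",
        "bright_mean_level": "lx",
        "dark_mean_level": "lx",
        "bright_cluster": "s",
        "dark_cluster": "s",
        "circadian_variation": "ratio",
    }
    reason = _check_missing(ignore_missing, miss)
    if reason:
        return {
            m: _undefined(BARROSO_FAMILY, m, units[m], reason, frac, **params)
            for m in BARROSO_METRICS
        }
    daily: dict[str, list[float]] = {m: [] for m in BARROSO_METRICS[:6]}
    day_means = []
    for _, day in series.split_days():
        vals = day.values(channel if channel in day.channels else None)
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        v = vals[ok]
        bright_thr = float(np.percentile(v, bright_percentile))
        dark_thr = float(np.percentile(v, dark_percentile))
        daily["bright_threshold"].append(bright_thr)
        daily["dark_threshold"].append(dark_thr)
        daily["bright_mean_level"].append(float(v[v >= bright_thr].mean()))
        daily["dark_mean_level"].append(float(v[v <= dark_thr].mean()))
        bright_runs = _runs(np.nan_to_num(vals, nan=-np.inf) >= bright_thr)
        dark_runs = _runs(np.nan_to_num(vals, nan=np.inf) <= dark_thr)
        daily["bright_cluster"].append(max(hi - lo for lo, hi in bright_runs) * epoch)
        daily["dark_cluster"].append(max(hi - lo for lo, hi in dark_runs) * epoch)
        day_means.append(float(v.mean()))
    out = {
        m: MetricResult(BARROSO_FAMILY, m, float(np.mean(vs)), units[m], params, frac)
        for m, vs in daily.items()
    }
    if len(day_means) >= 2 and np.mean(day_means) > 0:
        cv = float(np.std(day_means, ddof=1) / np.mean(day_means))
        out["circadian_variation"] = MetricResult(
            BARROSO_FAMILY, "circadian_variation", cv, "ratio", params, frac
        )
    else:
        out["circadian_variation"] = _undefined(
            BARROSO_FAMILY,
            "circadian_variation",
            "ratio",
            "needs >= 2 days with nonzero mean",
            frac,
            **params,
        )
    return out


# ---------------------------------------------------------------------------
# modelled non-visual responses (nvRD / nvRC)
# ---------------------------------------------------------------------------

NVRD_FAMILY = "nvRD"
NVRC_FAMILY = "nvRC"


def nvrd(
    series: LightSeries,
    params: ResponseParams = ResponseParams(),
    channel: str | None = None,
) -> tuple[LightSeries, MetricResult]:
    """Modelled non-visual direct response to melanopic light.

    Effective light E(t) is the exponential-history filter of the input
    (half-life ``history_half_life``); the response is the Hill function
    R_D = E^n / (E^n + C50^n), in [0, 1].  Returns the response series
    (channel ``nvRD``) and the cumulative response sum(R_D * epoch) in
    response-hours.
    """
    smoothed = exponential_moving_average(
        series,
        SmoothingSpec(half_life=params.history_half_life),
        channel=channel,
        out_channel="_effective",
    )
    e = smoothed.values("_effective")
    n_h, c50 = params.hill_exponent, params.half_max
    with np.errstate(invalid="ignore"):
        r = np.where(np.isnan(e), np.nan, e**n_h / (e**n_h + c50**n_h))
    frame = series.data.copy()
    frame["nvRD"] = r
    out = series.with_data(frame)
    frac = float(np.isnan(series.values(channel)).mean())
    cumulative = MetricResult(
        NVRD_FAMILY,
        "cumulative_response",
        float(np.nansum(r)) * float(series.epoch) / 3600.0,
        "response*h",
        {"params": params},
        frac,
    )
    return out, cumulative


def nvrc(
    series: LightSeries,
    params: ResponseParams = ResponseParams(),
    channel: str | None = None,
) -> LightSeries:
    """Modelled non-visual circadian response to melanopic light.

    Modulates the direct response by a sinusoidal circadian sensitivity
    peaking at ``peak_phase``::

        C(t) = R_D(t) * (1 + a*cos(2*pi*(tod - phi)/24h)) / (1 + a)

    clipped to [0, 1]; emitted as channel ``nvRC``.
    """
    response, _ = nvrd(series, params, channel)
    r = response.values("nvRD")
    tod = series.time_of_day_seconds()
    a, phi = params.sensitivity_amplitude, params.peak_phase.seconds
    gain = (1.0 + a * np.cos(2 * np.pi * (tod - phi) / SECONDS_PER_DAY)) / (1.0 + a)
    c = np.clip(r * gain, 0.0, 1.0)
    frame = series.data.copy()
    frame["nvRC"] = c
    return series.with_data(frame)


def nvrc_compare(
    response: LightSeries,
    reference: LightSeries,
    channel: str = "nvRC",
    reference_channel: str | None = None,
) -> dict[str, MetricResult]:
    """Compare a circadian response against a reference curve on the same
    grid: circadian disturbance CD = mean|C - Cref|, circadian bias
    CB = mean(C - Cref), relative amplitude error
    RAE = |amp(C) - amp(Cref)| / amp(Cref) with amp = max - min."""
    if len(response.timestamps) != len(reference.timestamps) or not (
        response.timestamps == reference.timestamps
    ).all():
        raise ValueError("response and reference are on different time grids")
    c = response.values(channel)
    ref = reference.values(reference_channel or channel)
    ok = ~(np.isnan(c) | np.isnan(ref))
    frac = float(1 - ok.mean())
    if not ok.any():
        reason = "all epochs missing"
        return {
            m: _undefined(NVRC_FAMILY, m, u, reason, frac)
            for m, u in (
                ("circadian_disturbance", "response"),
                ("circadian_bias", "response"),
                ("relative_amplitude_error", "ratio"),
            )
        }
    diff = c[ok] - ref[ok]
    out = {
        "circadian_disturbance": MetricResult(
            NVRC_FAMILY, "circadian_disturbance", float(np.abs(diff).mean()), "response", {}, frac
        ),
        "circadian_bias": MetricResult(
            NVRC_FAMILY, "circadian_bias", float(diff.mean()), "response", {}, frac
        ),
    }
    amp_ref = float(ref[ok].max() - ref[ok].min())
    amp_c = float(c[ok].max() - c[ok].min())
    if amp_ref == 0:
        out["relative_amplitude_error"] = _undefined(
            NVRC_FAMILY, "relative_amplitude_error", "ratio", "reference amplitude is zero", frac
        )
    else:
        out["relative_amplitude_error"] = MetricResult(
            NVRC_FAMILY, "relative_amplitude_error", abs(amp_c - amp_ref) / amp_ref, "ratio", {}, frac
        )
    return out


# ---------------------------------------------------------------------------
# registry and driver
# ---------------------------------------------------------------------------


def metric_registry() -> pd.DataFrame:
    """Enumerate every implemented metric exactly once.

    Returns a DataFrame with columns Family, Metric, Units, Kind
    (scalar / duration / time_of_day / count / series) and Function.
    """
    rows: list[tuple[str, str, str, str, Callable]] = []

    def add(family, metric, units, kind, func):
        rows.append((family, metric, units, kind, func))

    for m in BARROSO_METRICS:
        units = "lx" if "threshold" in m or "level" in m else ("s" if "cluster" in m else "ratio")
        kind = "duration" if "cluster" in m else "scalar"
        add(BARROSO_FAMILY, m, units, kind, barroso_metrics)
    for side in ("brightest", "darkest"):
        add(BRIGHT_DARK_FAMILY, f"{side}_mean_level", "lx", "scalar", bright_dark_period)
        for m in ("onset", "midpoint", "offset"):
            add(BRIGHT_DARK_FAMILY, f"{side}_{m}", "time of day", "time_of_day", bright_dark_period)
    add(CENTROID_FAMILY, "centroid", "time of day", "time_of_day", centroid_of_exposure)
    add(DISPARITY_FAMILY, "disparity_index", "ratio", "scalar", disparity_index)
    for mode in ("above", "below", "within"):
        add(DURATION_FAMILY, f"duration_{mode}", "s", "duration", duration_above_threshold)
    add(EMA_FAMILY, "exponential_moving_average", "lx", "series", exponential_moving_average)
    add(FREQUENCY_FAMILY, "frequency_crossing", "count", "count", frequency_crossing_threshold)
    add(IV_FAMILY, "intradaily_variability", "ratio", "scalar", intradaily_variability)
    add(IS_FAMILY, "interdaily_stability", "ratio", "scalar", interdaily_stability)
    add(MIDPOINT_FAMILY, "midpoint_ce", "time of day", "time_of_day", midpoint_cumulative_exposure)
    add(NVRC_FAMILY, "nvrc", "response", "series", nvrc)
    add(NVRC_FAMILY, "circadian_disturbance", "response", "scalar", nvrc_compare)
    add(NVRC_FAMILY, "circadian_bias", "response", "scalar", nvrc_compare)
    add(NVRC_FAMILY, "relative_amplitude_error", "ratio", "scalar", nvrc_compare)
    add(NVRD_FAMILY, "nvrd", "response", "series", nvrd)
    add(NVRD_FAMILY, "cumulative_response", "response*h", "scalar", nvrd)
    for mode in ("above", "below", "within"):
        add(PERIOD_FAMILY, f"period_{mode}", "s", "duration", period_above_threshold)
    for mode in ("above", "below", "within"):
        for m in PULSE_METRICS:
            units = {
                "count": "count",
                "mean_level": "lx",
                "mean_duration": "s",
                "total_duration": "s",
            }.get(m, "time of day")
            kind = {
                "count": "count",
                "mean_level": "scalar",
                "mean_duration": "duration",
                "total_duration": "duration",
            }.get(m, "time_of_day")
            add(PULSES_FAMILY, f"pulse_{m}_{mode}", units, kind, pulses_above_threshold)
    for mode in ("above", "below"):
        add(THRESHOLD_FOR_DURATION_FAMILY, f"threshold_{mode}", "lx", "scalar", threshold_for_duration)
    for mode in ("above", "below", "within"):
        add(TIMING_FAMILY, f"timing_{mode}", "time of day", "time_of_day", timing_above_threshold)
    add(DOSE_FAMILY, "dose", "lx*h", "scalar", dose)

    table = pd.DataFrame(rows, columns=["Family", "Metric", "Units", "Kind", "Function"])
    assert not table["Metric"].duplicated().any()
    return table


@dataclass(frozen=True)
class MetricDefaults:
    """Default parameters used by the :func:`compute_metrics` driver.

    The 250-lx threshold follows the daytime melanopic-EDI recommendation
    common in the field; ``within`` spans the 10-250 lx intermediate range.
    """

    threshold: float = 250.0
    within: tuple[float, float] = (10.0, 250.0)
    pulse_min_duration: float = 1800.0
    pulse_max_interrupt: float = 300.0
    period_max_interrupt: float = 0.0
    duration_for_threshold: float = 3600.0
    binning: BinningSpec = BinningSpec()
    smoothing: SmoothingSpec = SmoothingSpec()
    response: ResponseParams = ResponseParams()

    def threshold_spec(self, mode: str) -> ThresholdSpec:
        if mode == "within":
            return ThresholdSpec("within", self.within[0], self.within[1])
        return ThresholdSpec(mode, self.threshold)


#: metric -> whole-series (not per-day) computation in the driver
_WHOLE_SERIES_METRICS = {
    "interdaily_stability",
    "intradaily_variability",
} | set(BARROSO_METRICS)


def compute_metrics(
    series_list: Sequence[LightSeries],
    metrics: Sequence[str] | None = None,
    defaults: MetricDefaults = MetricDefaults(),
    per_day: bool = True,
    channel: str | None = None,
    ignore_missing: bool = True,
) -> pd.DataFrame:
    """Map scalar-valued metrics over ids (and local days).

    Returns the long-format table (Id, Day, Family, Metric, Value, Units,
    Params, MissingFraction); Value holds numbers (time-of-day values as
    seconds since local midnight), empty when undefined.  Metrics needing
    an external reference (nvRC comparisons) and series-valued metrics are
    not driven here; call their functions directly.
    """
    registry = metric_registry()
    available = registry[~registry["Kind"].eq("series")]
    available = available[~available["Metric"].isin(
        ["circadian_disturbance", "circadian_bias", "relative_amplitude_error"]
    )]
    if metrics is None:
        wanted = list(available["Metric"])
    else:
        unknown = set(metrics) - set(registry["Metric"])
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        wanted = [m for m in metrics if m in set(available["Metric"])]

    rows = []

    def emit(day, result: MetricResult, sid: str):
        params = {
            k: str(v) for k, v in result.parameters.items()
        }
        if result.reason:
            params["undefined_reason"] = result.reason
        rows.append(
            {
                "Id": sid,
                "Day": day,
                "Family": result.family,
                "Metric": result.metric,
                "Value": result.numeric(),
                "Units": result.units,
                "Params": str(params),
                "MissingFraction": result.missing_fraction,
            }
        )

    for series in series_list:
        whole = [m for m in wanted if m in _WHOLE_SERIES_METRICS]
        daily = [m for m in wanted if m not in _WHOLE_SERIES_METRICS]
        for name in whole:
            for res in _evaluate(series, name, defaults, channel, ignore_missing):
                emit("all", res, series.id)
        targets = series.split_days() if per_day else [("all", series)]
        for day, sub in targets:
            for name in daily:
                for res in _evaluate(sub, name, defaults, channel, ignore_missing):
                    emit(day, res, series.id)
    return pd.DataFrame(
        rows,
        columns=["Id", "Day", "Family", "Metric", "Value", "Units", "Params", "MissingFraction"],
    )


def _evaluate(series, name, d: MetricDefaults, channel, ignore_missing):
    """Run one named scalar metric with the driver defaults."""
    kw = {"channel": channel, "ignore_missing": ignore_missing}
    if name.startswith("duration_"):
        mode = name.split("_", 1)[1]
        return [duration_above_threshold(series, d.threshold_spec(mode), **kw)]
    if name.startswith("timing_"):
        mode = name.split("_", 1)[1]
        return [timing_above_threshold(series, d.threshold_spec(mode), **kw)]
    if name.startswith("period_"):
        mode = name.split("_", 1)[1]
        return [
            period_above_threshold(
                series, d.threshold_spec(mode), max_interrupt=d.period_max_interrupt, **kw
            )
        ]
    if name == "frequency_crossing":
        return [frequency_crossing_threshold(series, d.threshold_spec("above"), **kw)]
    if name.startswith("threshold_"):
        mode = name.split("_", 1)[1]
        try:
            return [threshold_for_duration(series, d.duration_for_threshold, mode, **kw)]
        except ValueError as exc:
            return [
                _undefined(
                    THRESHOLD_FOR_DURATION_FAMILY, name, "lx", str(exc),
                    series.missing_fraction(channel), duration=d.duration_for_threshold,
                )
            ]
    if name.startswith("pulse_"):
        mode = name.rsplit("_", 1)[1]
        sub = name[len("pulse_"): -(len(mode) + 1)]
        spec = PulseSpec(d.threshold_spec(mode), d.pulse_min_duration, d.pulse_max_interrupt)
        return [pulses_above_threshold(series, spec, **kw)[sub]]
    if name.startswith("brightest_") or name.startswith("darkest_"):
        side, sub = name.split("_", 1)
        return [bright_dark_period(series, period="bright" if side == "brightest" else "dark", **kw)[sub]]
    if name == "centroid":
        return [centroid_of_exposure(series, **kw)]
    if name == "midpoint_ce":
        return [midpoint_cumulative_exposure(series, **kw)]
    if name == "interdaily_stability":
        return [interdaily_stability(series, d.binning, **kw)]
    if name == "intradaily_variability":
        return [intradaily_variability(series, d.binning, **kw)]
    if name == "disparity_index":
        return [disparity_index(series, **kw)]
    if name == "dose":
        return [dose(series, **kw)]
    if name in BARROSO_METRICS:
        return [barroso_metrics(series, channel=channel, ignore_missing=ignore_missing)[name]]
    if name == "cumulative_response":
        return [nvrd(series, d.response, channel=channel)[1]]
    raise ValueError(f"metric {name!r} cannot be driven here")
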