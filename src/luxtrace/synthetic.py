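"""Ground-truthed synthetic light-exposure datasets.

Real wearable light-logger data cannot ship with the package, so this
module emulates its essential features: multi-day per-participant series
at a fixed epoch, nonnegative levels spanning ~0-100,000 lx with a diurnal
profile, wear gaps (missing timestamps), sleep-diary intervals, and
per-device CSV fixture files.  Every dataset is deterministic under its
seed and comes with a ground-truth record (true gaps, true daily doses,
true photoperiod pulse blocks) that downstream operations can be checked
against exactly.

The diurnal template is deliberately simple — piecewise-constant (or a
half-sine) photoperiod — because exact ground truth matters more here
than verisimilitude; noise is multiplicative log-normal on (value + 1),
which preserves nonnegativity and the decades-wide spread of field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SECONDS_PER_DAY, LightSeries, TimeOfDay
from .devices import DeviceDialect, get_dialect, write_dialect_csv
from .preprocess import INTERVAL_COLUMNS


@dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic recording campaign.

    Defaults describe a plausible field recording: three days per
    participant at a 1-min epoch, a 08:00-18:00 photoperiod at 1000 lx
    over a 1-lx night, moderate multiplicative noise, and a 23:00-07:00
    sleep diary with half-hour jitter.
    """

    n_ids: int = 1
    days: int = 3
    epoch: float = 60.0
    tz: str = "Europe/Berlin"
    start_date: str = "2024-05-06"
    photoperiod_start: str = "08:00"
    photoperiod_end: str = "18:00"
    day_level: float = 1000.0
    night_level: float = 1.0
    template: str = "rectangular"  # or "sinusoidal"
    noise_sd: float = 0.15
    n_gaps: int = 0
    gap_epochs: tuple[int, int] = (5, 60)
    with_sleep_diary: bool = True
    sleep_start: str = "23:00"
    sleep_end: str = "07:00"
    sleep_jitter: float = 1800.0  # seconds
    channel: str = "MEDI"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_level < 0 or self.night_level < 0:
            raise ValueError("light levels must be nonnegative")
        if self.night_level > self.day_level:
            raise ValueError("night level must not exceed day level")
        if SECONDS_PER_DAY % self.epoch:
            raise ValueError("epoch must divide 24 h")
        if self.template not in ("rectangular", "sinusoidal"):
            raise ValueError(f"unknown template {self.template!r}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "gap_epochs" in raw:
            raw["gap_epochs"] = tuple(raw["gap_epochs"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Per-id truth record, consistent with the emitted data by construction."""

    gaps: dict = field(default_factory=dict)  # id -> list of (start, n_epochs)
    daily_dose: dict = field(default_factory=dict)  # id -> {date: lx*h}
    pulse_blocks: dict = field(default_factory=dict)  # id -> list of (onset, offset_open)


@dataclass
class SyntheticDataset:
    scenario: ScenarioSpec
    series: list
    intervals: pd.DataFrame
    truth: GroundTruth


def _template_values(tod: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    ps = TimeOfDay.from_string(spec.photoperiod_start).seconds
    pe = TimeOfDay.from_string(spec.photoperiod_end).seconds
    inside = (tod >= ps) & (tod < pe)
    if spec.template == "rectangular":
        return np.where(inside, spec.day_level, spec.night_level)
    phase = np.clip((tod - ps) / max(pe - ps, 1e-9), 0.0, 1.0)
    lobe = np.sin(np.pi * phase)
    return spec.night_level + (spec.day_level - spec.night_level) * np.where(inside, lobe, 0.0)


def generate(spec: ScenarioSpec) -> SyntheticDataset:
    """Generate the scenario's series, sleep diary and ground truth."""
    truth = GroundTruth()
    series_out = []
    diary_rows = []
    n_per_day = int(SECONDS_PER_DAY // spec.epoch)
    n = n_per_day * spec.days
    start = pd.Timestamp(spec.start_date, tz=spec.tz)
    grid = start + pd.to_timedelta(np.arange(n) * spec.epoch, unit="s")
    naive = grid.tz_localize(None)
    tod = (naive - naive.normalize()).total_seconds().to_numpy()
    dates = naive.normalize().date

    for k in range(spec.n_ids):
        sid = f"P{k + 1:02d}"
        rng = np.random.default_rng([spec.seed, k])
        values = _template_values(tod, spec)
        if spec.noise_sd > 0:
            values = np.maximum(
                (values + 1.0) * np.exp(rng.normal(0.0, spec.noise_sd, n)) - 1.0, 0.0
            )
        frame = pd.DataFrame({spec.channel: values}, index=grid)

        # truth before any rows are removed
        day_frame = pd.Series(values).groupby(dates).sum() * spec.epoch / 3600.0
        truth.daily_dose[sid] = {d: float(v) for d, v in day_frame.items()}
        ps = TimeOfDay.from_string(spec.photoperiod_start).seconds
        pe = TimeOfDay.from_string(spec.photoperiod_end).seconds
        blocks = []
        for d in range(spec.days):
            base = start + pd.to_timedelta(d, unit="D")
            blocks.append(
                (base + pd.to_timedelta(ps, unit="s"), base + pd.to_timedelta(pe, unit="s"))
            )
        truth.pulse_blocks[sid] = blocks

        # wear gaps: non-overlapping interior runs of removed timestamps
        keep = np.ones(n, dtype=bool)
        gaps = []
        attempts = 0
        while len(gaps) < spec.n_gaps and attempts < 1000:
            attempts += 1
            length = int(rng.integers(spec.gap_epochs[0], spec.gap_epochs[1] + 1))
            lo = int(rng.integers(1, n - length))  # keep first and last epoch
            if keep[lo - 1 : lo + length + 1].all():
                keep[lo : lo + length] = False
                gaps.append((grid[lo], length))
        if len(gaps) < spec.n_gaps:
            raise ValueError("could not place the requested gaps without overlap")
        truth.gaps[sid] = sorted(gaps, key=lambda g: g[0])
        series_out.append(LightSeries(id=sid, data=frame[keep], epoch=spec.epoch))

        if spec.with_sleep_diary:
            bed_base = TimeOfDay.from_string(spec.sleep_start).seconds
            rise_base = TimeOfDay.from_string(spec.sleep_end).seconds
            for d in range(spec.days):
                base = start + pd.to_timedelta(d, unit="D")
                bed = base + pd.to_timedelta(
                    bed_base + rng.uniform(-spec.sleep_jitter, spec.sleep_jitter), unit="s"
                )
                rise = base + pd.to_timedelta(
                    SECONDS_PER_DAY + rise_base + rng.uniform(-spec.sleep_jitter, spec.sleep_jitter),
                    unit="s",
                )
                diary_rows.append({"Id": sid, "State": "sleep", "Start": bed, "End": rise})

    intervals = pd.DataFrame(diary_rows, columns=INTERVAL_COLUMNS)
    return SyntheticDataset(spec, series_out, intervals, truth)


def write_fixture(
    series: LightSeries,
    dialect: DeviceDialect | str,
    path,
    corrupt_rows: int = 0,
    seed: int = 0,
) -> Path:
    """Write a series as a device-dialect fixture file.

    ``corrupt_rows`` > 0 replaces that many data rows' timestamps with
    unparseable text (deterministically under *seed*), to exercise the
    importer's drop-and-count behaviour.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    path = Path(path)
    write_dialect_csv(series, dialect, path)
    if corrupt_rows:
        lines = path.read_text().splitlines()
        first_data = dialect.skip_rows + (1 if dialect.header else 0)
        data_idx = list(range(first_data, len(lines)))
        rng = np.random.default_rng(seed)
        chosen = rng.choice(data_idx, size=min(corrupt_rows, len(data_idx)), replace=False)
        n_ts = len(dialect.timestamp_columns)
        for i in sorted(int(c) for c in chosen):
            fields = lines[i].split(dialect.delimiter)
            for j in range(min(n_ts, len(fields))):
                fields[j] = "corrupted"
            lines[i] = dialect.delimiter.join(fields)
        path.write_text("\n".join(lines) + "\n")
    return path
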