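# luxtrace

Import, preprocessing and metrics for **wearable personal light-exposure
data** (light dosimetry).

Chronobiology, sleep research, vision science and lighting-design studies
increasingly record the light a person is actually exposed to, using
wearable loggers that emit one row per sampling epoch (10 s–5 min) with
photopic illuminance and/or melanopic equivalent daylight illuminance
(melanopic EDI), in lux, over days to weeks.  These files arrive in
as many CSV dialects as there are devices, with implicit gaps where the
device was not worn, and the literature summarises them with a large and
scattered set of exposure metrics.  `luxtrace` standardises that
workflow for researchers handling such data:

* **Import** — a registry of 17 declarative device dialects (delimiter,
  decimal mark, timestamp format, channel map as YAML config, not code)
  turns exports into a common timezone-aware series container, with a
  full accounting of parsed/dropped rows.
* **Preprocess** — implicit-gap discovery and filling, midnight-anchored
  aggregation to coarser epochs, date/time-of-day filtering, sleep-diary
  interval joining, and combining series (e.g. personal exposure with
  environmental daylight availability) onto one grid.
* **Metrics** — an engine of **17 families / 61 metrics** behind one
  consistent interface: time/duration/timing above-below-within
  thresholds, longest periods and pulses (bouts with brief interruptions
  allowed), brightest/darkest rolling windows, centroid and midpoint of
  cumulative exposure, interdaily stability (IS), intradaily variability
  (IV), exponential moving average, disparity index, cumulative dose,
  the Barroso lighting-regularity family and modelled non-visual direct
  (nvRD) and circadian (nvRC) responses to melanopic light.
* **Synthetic data** — a ground-truthed scenario generator (diurnal
  template + log-normal noise + wear gaps + sleep diary), so the whole
  pipeline is testable without any real device export.
* **CLI & plot** — `luxtrace import|validate|metrics|plot`, including a
  day-faceted exposure figure with log-axis light and sleep shading.

Key conventions (see `docs/methods.md` for the full account): a
timestamp marks the **start** of its epoch, so durations are exact
multiples of the epoch Δt; intervals are closed-start/open-end;
*above* means ≥, *below* ≤, *within* a closed interval; missing epochs
are explicit, ignored by default and always reported as a fraction;
degenerate inputs yield typed *undefined* results, never silent zeros.

The two rhythm metrics at the package's core, on values binned to p
clock bins per 24-h cycle:

    IS = (n · Σ_h (x̄_h − x̄)²) / (p · Σ_i (x_i − x̄)²)
    IV = (n · Σ_{i≥2} (x_i − x_{i−1})²) / ((n−1) · Σ_i (x_i − x̄)²)

IS → 1 when the daily profile repeats perfectly; IV = 4 exactly for
strict alternation and ≈ 0 for a smooth rhythm.

## Worked example

```python
import luxtrace as lt
from luxtrace import ScenarioSpec, ThresholdSpec

ds = lt.generate(ScenarioSpec(n_ids=1, days=3, epoch=60.0, n_gaps=2, seed=42))
s = ds.series[0]
print(f"{s.id}: {s.n} epochs of {s.epoch:g} s, channel {s.main_channel}")

gaps = lt.find_gaps(s)
print(f"wear gaps: {len(gaps)}, total {gaps['DurationSeconds'].sum()/60:g} min missing")

spec = ThresholdSpec("above", 250.0)
tat = lt.duration_above_threshold(s, spec)
mlit = lt.timing_above_threshold(s, spec)
print(f"time above 250 lx: {tat.value/3600:.2f} h, mean timing {mlit.value}")

table = lt.compute_metrics([s], metrics=["dose", "centroid", "interdaily_stability"])
print(table[["Id", "Day", "Metric", "Value", "Units"]].to_string(index=False))
```

prints

```
P01: 4277 epochs of 60 s, channel MEDI
wear gaps: 2, total 43 min missing
time above 250 lx: 30.00 h, mean timing 12:59:30
 Id        Day               Metric        Value       Units
P01        all interdaily_stability     0.999431       ratio
P01 2024-05-06                 dose 10072.345364        lx*h
P01 2024-05-07                 dose 10106.044699        lx*h
...
```

The scenario is three days of a 08:00–18:00, 1000-lx photoperiod with
moderate noise: 4277 of 4320 grid epochs are present (two wear gaps,
43 min), time above 250 lx is 30 h (10 h/day), its mean clock time is
about 13:00 (the photoperiod midpoint), each day's dose is ≈ 10,000
lux-hours (10 h × 1000 lx, plus noise), and IS ≈ 1 because the three
days repeat the same profile.  Time-of-day values in the long table are
seconds since local midnight.

From the shell, the same pipeline runs as:

```sh
luxtrace import export1.csv --device "ActLumus" --tz Europe/Berlin --out-dir out/
luxtrace validate out/light_series.csv --tz Europe/Berlin --out-dir out/
luxtrace metrics out/light_series.csv --tz Europe/Berlin --out-dir out/
luxtrace plot out/light_series.csv --intervals diary.csv --tz Europe/Berlin --out-dir out/
```

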