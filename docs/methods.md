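# Methods

## Scope and data model

`luxtrace` analyses personal light-exposure time series recorded by
wearable loggers (dosimeters): per participant, one row per *epoch* (the
device's fixed sampling interval, typically 10 s to 5 min) holding one or
more light channels — photopic illuminance or melanopic equivalent
daylight illuminance (melanopic EDI), both in lux.  The pipeline is
device import → preprocessing (gaps, aggregation, filtering, state
joining) → a metric engine of 17 families / 61 metrics → a day-faceted
plot.

Three conventions are applied uniformly and deliberately:

* **Epoch-start attribution.**  A timestamp marks the start of the epoch
  it covers; every duration metric is therefore an exact integer multiple
  of the epoch Δt (count of qualifying epochs × Δt), which makes the
  metrics exactly testable.  Interval semantics are closed-start /
  open-end everywhere (sleep-diary rows, date and time-of-day filters,
  gap extents), matching this attribution.
* **Explicit missingness.**  Implicitly missing rows (absent timestamps,
  i.e. wear gaps) are materialised as NaN by `regularize`; every metric
  takes an `ignore_missing` flag (default: ignore) and reports the
  missing fraction alongside its value.  An all-missing or otherwise
  degenerate input (zero variance, empty qualifying set, zero total
  exposure) yields a typed *undefined* result carrying a reason — never a
  silent zero.
* **Local wall time.**  Each series carries one IANA timezone;
  time-of-day metrics and midnight-anchored windows use local wall time.
  DST-duplicated or skipped wall hours are kept as recorded; no
  resampling is done across transitions.

The epoch is inferred as the modal successive timestamp difference, with
ties broken toward the smaller value (a wear gap is a multiple of the
true epoch, never a fraction).  Grid alignment tolerates deviations up to
1% of the epoch, absorbing device clock jitter without resampling;
tolerated-but-jittered timestamps pass through `regularize` unchanged.

## Device dialects

No vendor publishes a stable machine-readable description of its export
format, so each of the 17 supported devices is described by a declarative
YAML dialect (delimiter, rows to skip, header flag, decimal mark,
timestamp columns/format, timezone policy, channel map, optional in-file
id column).  The layouts shipped here are plausible synthetic stand-ins
exercised against generated fixtures; the tested surface is the registry
and parsing machinery, and a dialect can be corrected for a real export
without touching code.  GENEActiv is registered but refuses raw imports
with an explanatory error, because its raw output requires external
(GGIR-style) preprocessing; `preprocessed=True` accepts the processed
layout.  Duplicate timestamps within an id keep the first occurrence and
are counted; rows with unparseable timestamps are dropped and counted,
and an import aborts if more than half the rows drop.  Numeric parsing
uses round-trip float conversion so that fixture → import is bit-exact.

## Metric definitions and parameters

Comparator semantics are uniform across all threshold families:
*above* means ≥ lower bound, *below* means ≤ lower bound, *within* means
the closed interval [lower, upper].  Thresholds are in the series' light
units; the driver's defaults (250 lx, intermediate range 10–250 lx)
follow the melanopic-EDI daytime/evening recommendations common in the
field and are configuration, not constants.

* **Duration / timing / period / frequency above threshold.**  Duration
  is qualifying-epoch count × Δt.  Timing is the (optionally circular)
  mean of qualifying epoch-start clock times.  Period is the longest run
  of qualifying epochs, where non-qualifying interruptions no longer than
  `max_interrupt` do not break the run and are included in its duration.
  Frequency counts changes of comparator outcome between successive
  non-missing epochs (comparison bridges missing epochs).
* **Threshold for duration.**  The k-th largest (above) or smallest
  (below) value with k = round(d/Δt): the most extreme threshold still
  sustained for duration d.
* **Pulses.**  Runs are merged across interruptions ≤ `I_max` (default
  5 min) and kept if the merged duration (interruptions included) is
  ≥ `D_min` (default 30 min); seven summaries (count, mean level, mean
  and total duration, mean onset/midpoint/offset clock time) × three
  comparator modes.  Onset is the first epoch's start; offset the last
  epoch's start; midpoint onset + duration/2.
* **Brightest/darkest period.**  Rolling mean over windows of 10 h
  (bright) / 5 h (dark); `loop=True` evaluates circular windows wrapping
  midnight; ties take the earliest onset; all-missing windows are never
  selected.
* **Centroid / midpoint of cumulative exposure.**  Light-weighted mean
  clock time, and the earliest epoch at which the running dose reaches
  half the total (earliest-≥ rule).
* **IS / IV.**  Computed on values binned to p clock bins per 24-h cycle
  (default 24 × 1 h, midnight-anchored).
  IS = (n·Σ_h(x̄_h − x̄)²)/(p·Σ_i(x_i − x̄)²);
  IV = (n·Σ(Δx)²)/((n−1)·Σ(x − x̄)²).  Strict alternation gives IV = 4
  exactly; duplicated identical days give IS = 1 exactly; constant input
  is undefined.
* **EMA.**  s₁ = x₁, sᵢ = λxᵢ + (1−λ)sᵢ₋₁ with λ = 1 − 2^(−Δt/t½)
  (default t½ = 30 min), so a unit step reaches 0.5 exactly one
  half-life later.  Missing input carries the state and emits missing.
* **Disparity index.**  Mean |ln((xᵢ₊₁+1)/(xᵢ+1))| over successive
  epochs.
* **Dose.**  Σ x·Δt in lux-hours; the aggregation step conserves it on
  complete windows (checked to 1e-9 relative).
* **Barroso family.**  Per local day: bright/dark thresholds are the
  90th/10th percentiles of the day's values (parameters, not constants);
  mean levels and longest clusters at-or-beyond those thresholds; daily
  values averaged across days; circadian variation is the coefficient of
  variation (sample sd / mean) of daily means, needing ≥ 2 days.  These
  percentile-based definitions are this package's concrete choice for a
  family whose original formulation is not reproduced here.
* **nvRD / nvRC.**  The non-visual direct response is a Hill function of
  exponentially filtered melanopic light history:
  E(t) = EMA(melanopic EDI; t½ = τ_h), R_D = Eⁿ/(Eⁿ + C50ⁿ) ∈ [0,1];
  defaults n_h = 2, C50 = 100 melanopic-EDI lx, τ_h = 60 min.  The
  circadian response modulates R_D by a sinusoidal sensitivity with
  amplitude a = 0.5 peaking at 03:00:
  C = R_D·(1 + a·cos(2π(tod − φ)/24 h))/(1 + a), clipped to [0,1].
  Against a reference curve on the same grid: circadian disturbance
  CD = mean|C − C_ref|, bias CB = mean(C − C_ref) (so CD ≥ |CB| always),
  and relative amplitude error RAE = |amp(C) − amp(C_ref)|/amp(C_ref)
  with amp = max − min.  This parameter-exposed formalisation is a
  deliberately simple response model: it captures saturation, history
  dependence and time-of-day gating, and makes no claim of numerical
  equality with any published calibration.
* **Registry.**  `metric_registry()` enumerates all 61 metrics across the
  17 families exactly once.  Sixteen families are the field-standard set
  above; the seventeenth is the one-metric cumulative **Dose** family,
  included because time-integrated exposure is a standard dosimetry
  quantity that the threshold families do not cover.

The metric driver maps day-type metrics over local-midnight days
(incomplete first/last days are included; their missing fraction flags
them) and whole-series metrics (IS, IV, Barroso) over the full recording.

## Synthetic data

The generator emulates what matters for exercising the pipeline:
multi-day, multi-participant series at a fixed epoch (default 3 days at
1 min), a rectangular (or half-sine) photoperiod template (default
08:00–18:00 at 1000 lx over a 1-lx night), multiplicative log-normal
noise on (value + 1) (default sd 0.15; preserves nonnegativity and the
decades-wide dynamic range of field data), interior wear gaps with
recorded extents, and a jittered 23:00–07:00 sleep diary.  Everything is
deterministic under the scenario seed, and the ground-truth record (gap
positions, daily doses, photoperiod pulse blocks) is computed from the
same arrays that are emitted, so recovery checks are exact by
construction.

What the generator does **not** emulate: realistic spectral composition,
behaviourally driven intra-day structure (commutes, screens), seasonal
photoperiod drift, sensor saturation or soiling, or device-specific
quirks beyond the declarative dialect layer.  Passing tests therefore
demonstrate that the machinery is correct on data with known structure,
not that any scientific conclusion transfers to field recordings.

## Numerical choices

* Grid tolerance 1% of the epoch; misalignment beyond it is an error
  naming the first offending timestamp, never a silent resample.
* Tie-breaks: modal epoch → smaller duration; brightest/darkest window →
  earliest onset; duplicate timestamps → first occurrence.
* Circular means use the vector (atan2) mean of clock angles; arithmetic
  means are the default because most published timing metrics are
  arithmetic.
* CSV floats are written with `repr` and read with round-trip precision;
  decimal-comma dialects are converted textually before exact parsing.
* Problem sizes in the test and acceptance runs (hundreds of random
  series of length ≤ 200 for the pulse oracle, 200 series for the
  threshold-duration property, 10 days × 24 h for IS simulations) were
  chosen as the smallest sizes at which the checked properties are
  non-trivial.

## Known limitations

* Dialect layouts are synthetic stand-ins until real exports are
  available; only the parsing machinery is validated.
* No imputation beyond zero/LOCF; no actigraphy modelling, spectral
  reconstruction, circadian phase estimation (e.g. DLMO), or sleep
  scoring.
* The Barroso and non-visual-response families use this package's own
  parameterised definitions; numerical agreement with other
  implementations is not claimed.
* Aggregation across DST transitions groups by wall-clock windows; a
  duplicated wall hour contributes twice to its window.
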