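name: LightWatcher
manufacturer: Object-Tracker
delimiter: "\t"
skip_rows: 2
timestamp:
  timezone: supplied
  columns:
  - Date
  - Time
  format: '%d.%m.%Y %H:%M:%S'
channels:
- column: Light
  name: LIGHT
  unit: lx
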