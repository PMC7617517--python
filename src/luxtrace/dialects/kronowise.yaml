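name: Kronowise
manufacturer: Kronohealth
delimiter: "\t"
timestamp:
  timezone: supplied
  column: DateTime
  format: '%Y/%m/%d %H:%M:%S'
channels:
- column: Light
  name: LIGHT
  unit: lx
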