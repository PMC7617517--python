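name: VEET
manufacturer: Meta Reality Labs
delimiter: "\t"
timestamp:
  timezone: supplied
  column: time_stamp
  format: '%Y-%m-%d %H:%M:%S'
channels:
- column: lux
  name: LIGHT
  unit: lx
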