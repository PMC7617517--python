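name: Speccy
manufacturer: Monash University Malaysia
delimiter: ','
timestamp:
  timezone: supplied
  column: Datetime
  format: '%Y-%m-%d %H:%M:%S'
channels:
- column: Lux
  name: LIGHT
  unit: lx
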