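name: LYS Button
manufacturer: LYS Technologies
delimiter: ','
timestamp:
  timezone: embedded
  column: timestamp
channels:
- column: lux
  name: LIGHT
  unit: lx
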