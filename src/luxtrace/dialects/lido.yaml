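name: Lido
manufacturer: Lucerne University of Applied Sciences and Arts
delimiter: ;
timestamp:
  timezone: embedded
  column: UTC Timestamp
channels:
- column: Illuminance [lx]
  name: LIGHT
  unit: lx
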