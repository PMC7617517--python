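name: DeLux
manufacturer: Intelligent Automation Inc.
delimiter: ','
timestamp:
  timezone: embedded
  column: timestamp
channels:
- column: mEDI_lux
  name: MEDI
  unit: melanopic-EDI lx
- column: photopic_lux
  name: LIGHT
  unit: lx
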