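name: OcuWEAR
manufacturer: Ocutune
delimiter: ','
timestamp:
  timezone: embedded
  column: utc_datetime
channels:
- column: medi
  name: MEDI
  unit: melanopic-EDI lx
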