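name: SpectraWear
manufacturer: University of Manchester
delimiter: ','
timestamp:
  timezone: supplied
  column: datetime
  format: '%Y-%m-%d %H:%M:%S'
channels:
- column: mEDI
  name: MEDI
  unit: melanopic-EDI lx
id_column: participant
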