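name: ActTrust
manufacturer: Condor Instruments
delimiter: ;
decimal_mark: ','
timestamp:
  timezone: supplied
  column: DATE/TIME
  format: '%d/%m/%Y %H:%M:%S'
channels:
- column: LIGHT
  name: LIGHT
  unit: lx
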