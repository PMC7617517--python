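name: melanopiQ Circadian Eye
manufacturer: Max Planck Institute for Biological Cybernetics
delimiter: ','
timestamp:
  timezone: embedded
  column: Datetime
channels:
- column: Mel_EDI
  name: MEDI
  unit: melanopic-EDI lx
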