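name: LIMO
manufacturer: Ecole nationale des travaux publics de l'Etat (ENTPE)
delimiter: ','
timestamp:
  timezone: supplied
  column: time
  format: '%Y-%m-%dT%H:%M:%S'
channels:
- column: mel_EDI
  name: MEDI
  unit: melanopic-EDI lx
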