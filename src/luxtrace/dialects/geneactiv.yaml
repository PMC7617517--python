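name: GENEActiv
manufacturer: Activeinsights
delimiter: ','
timestamp:
  timezone: supplied
  column: timestamp
  format: '%Y-%m-%d %H:%M:%S'
channels:
- column: light
  name: LIGHT
  unit: lx
requires_preprocessing: true
preprocessing_note: raw GENEActiv binaries must first be processed with the GGIR pipeline
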