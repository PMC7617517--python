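name: XL-500 BLE
manufacturer: NanoLambda
delimiter: ','
header: false
timestamp:
  column: 0
  timezone: supplied
  format: '%Y-%m-%d %H:%M:%S'
channels:
- column: 1
  name: LIGHT
  unit: lx
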