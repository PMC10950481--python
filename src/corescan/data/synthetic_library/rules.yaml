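composite_rules:
- dependent: DPE
  anchor: dInr
  spacing_window:
  - 28
  - 33
- dependent: MTE
  anchor: dInr
  spacing_window:
  - 18
  - 22
- dependent: Bridge
  anchor: dInr
  spacing_window:
  - 18
  - 20
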