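compartments:
- C
- M2
- T2
- L2
observed:
- M2
- T2
- L2
edges:
- from: C
  to: M2
  rate: k_CM2
- from: M2
  to: C
  rate: k_M2C
- from: C
  to: T2
  rate: k_CT2
- from: T2
  to: C
  rate: k_T2C
- from: C
  to: L2
  rate: k_CL2
- from: L2
  to: C
  rate: k_L2C
dose_compartment: C
elimination:
  compartment: C
  rate: k_C0
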