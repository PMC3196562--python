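compartments:
- C
- M1
- M2
- M3
- L1
- L2
- L3
- T2
- T3
observed:
- M2
- T2
- L2
edges:
- from: C
  to: M1
  rate: k_CM1
- from: M1
  to: M2
  rate: k_M1M2
- from: M2
  to: M3
  rate: k_M2M3
- from: M3
  to: M2
  rate: k_M3M2
- from: M2
  to: M1
  rate: k_M2M1
- from: M1
  to: C
  rate: k_M1C
- from: C
  to: L1
  rate: k_CL1
- from: L1
  to: T2
  rate: k_L1T2
- from: T2
  to: T3
  rate: k_T2T3
- from: T3
  to: T2
  rate: k_T3T2
- from: T2
  to: L1
  rate: k_T2L1
- from: L1
  to: L2
  rate: k_L1L2
- from: L2
  to: L3
  rate: k_L2L3
- from: L3
  to: L2
  rate: k_L3L2
- from: L2
  to: L1
  rate: k_L2L1
- from: L1
  to: C
  rate: k_L1C
dose_compartment: C
elimination:
  compartment: C
  rate: k_C0
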