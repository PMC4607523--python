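# Default three-population demography: African population of constant
# size, out-of-Africa bottleneck, larger present-day sizes for the two
# non-African populations.  Times are generations ago; sizes are effective
# diploid population sizes.  These are editable defaults, not estimates.
populations: [YRI, CEU, CHBJPT]
epochs:
  YRI:
    - [0, 12000]
  CEU:
    - [0, 20000]
    - [800, 1500]
  CHBJPT:
    - [0, 25000]
    - [800, 1200]
  OOA:
    - [0, 1800]
  ANC:
    - [0, 10000]
splits:
  - {time: 1600, derived: [CEU, CHBJPT], ancestral: OOA}
  - {time: 3500, derived: [YRI, OOA], ancestral: ANC}
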