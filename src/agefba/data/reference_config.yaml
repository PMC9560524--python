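strategy:
  first: max_growth
  second: null
  epsilon1: 0.0
  epsilon2: 0.05
  parsimonious: true
regulation:
  regulation_factor: 0.04
ageing:
  f_m: 0.05
  f0: 0.0001
  r0: 0.0005
  retention: 0.55
  division_biomass: 0.45
  ngam0: 0.2
  ngam_slope: 10.0
  dt: 0.01
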