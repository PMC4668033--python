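# Published mixed-effects coefficient set for maritime pine (Pinus pinaster
# Ait.) in Asturias, NW Spain: variable-exponent profile with random effects
# on a1 and b3 at plot and tree level, power-of-DBH variance function
# (SD-scale weight g = d^delta), no within-tree serial correlation, fitted
# by REML to the whole 420-tree dataset.
label: asturias-mm3
params:
  a0: 1.050
  a1: 0.9427
  a2: 0.04734
  b1: 0.3619
  b2: -0.6907
  b3: 0.5847
  b4: 1.126
  b5: 0.02271
  b6: -0.05812
active: [a0, a1, a2, b1, b2, b3, b4, b5, b6]
random:
  expanded: [a1, b3]
  D_p:
    - [1.263e-5, -1.104e-5]
    - [-1.104e-5, 8.273e-4]
  D_t:
    - [1.205e-4, 3.847e-5]
    - [3.847e-5, 3.095e-3]
  sigma2: 6.117e-3
  delta: 0.7405
  phi: null
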