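# Published fixed-effects coefficient set for maritime pine (Pinus pinaster
# Ait.) in Asturias, NW Spain: variable-exponent profile fitted by ordinary
# least squares to the whole 420-tree felled-tree dataset.
label: asturias-ols
params:
  a0: 0.9891
  a1: 0.9633
  a2: 0.04585
  b1: 0.3672
  b2: -0.3350
  b3: 0.5192
  b4: 0.8471
  b5: 0.01777
  b6: -0.02647
active: [a0, a1, a2, b1, b2, b3, b4, b5, b6]
sigma2: 1.555
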