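# Mouse physiology (~20 g tumor-bearing animal).
# Plasma flows from the rodent literature; organ volumes from gravimetric
# measurement at a tissue density of 1.18 g/mL. Q_li is hepatic portal vein
# flow; Q_he is hepatic artery flow. Blood and lung flow both equal cardiac
# output.
species: mouse
Q_L_per_h:
  bl: 0.48
  lu: 0.48
  li: 0.108
  sp: 0.0054
  ht: 0.0168
  kd: 0.078
  tu: 0.00102
  rm: 0.27618
Q_he_L_per_h: 0.021
V_L:
  bl: 0.0017
  lu: 0.00010
  li: 0.0015
  sp: 0.0000847
  ht: 0.0000678
  kd: 0.00027
  tu: 0.0016
  rm: 0.013
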