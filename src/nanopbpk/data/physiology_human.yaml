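# Human physiology for a 70 kg adult. Tumor row describes a breast tumor
# whose plasma flow was determined macroscopically.
species: human
Q_L_per_h:
  bl: 336.0
  lu: 336.0
  li: 87.0
  sp: 4.62
  ht: 14.4
  kd: 74.4
  tu: 3.2
  rm: 157.0
Q_he_L_per_h: 82.38
V_L:
  bl: 5.2
  lu: 1.17
  li: 1.69
  sp: 0.192
  ht: 0.31
  kd: 0.28
  tu: 0.00419
  rm: 55.9
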