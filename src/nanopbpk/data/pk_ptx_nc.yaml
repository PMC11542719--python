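# Fitted disposition parameters for bare paclitaxel nanocrystals.
formulation: ptx-nc
K:
  li: 10.99
  sp: 1.04
  ht: 0.26
  kd: 0.41
  lu: 0.58
  tu: 0.28
  rm: 1.0
K_rm_assumed: true
CL_L_per_h: 0.0026
cv_percent:
  li: 19.98
  sp: 35.63
  ht: 7.12
  kd: 17.02
  lu: 20.43
  tu: 19.00
  CL: 0.0052
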