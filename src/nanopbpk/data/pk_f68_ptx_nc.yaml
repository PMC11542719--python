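# Fitted disposition parameters for Pluronic F-68 coated paclitaxel
# nanocrystals. The coating prolongs circulation: clearance is ~25x lower
# than the other two formulations and tumor partitioning is the highest.
formulation: f68-ptx-nc
K:
  li: 6.92
  sp: 0.32
  ht: 0.036
  kd: 0.18
  lu: 0.25
  tu: 0.65
  rm: 1.0
K_rm_assumed: true
CL_L_per_h: 0.000091
cv_percent:
  li: 7.95
  sp: 15.61
  ht: 9.11
  kd: 10.67
  lu: 0.0012
  tu: 23.43
  CL: 0.00083
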