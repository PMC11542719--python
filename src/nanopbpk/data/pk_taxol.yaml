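# Fitted disposition parameters for solubilised paclitaxel (Taxol).
# K values are unitless tissue:blood partition coefficients; CL is linear
# hepatic clearance. The remainder-compartment partition coefficient was
# never reported by the source study; the default of 1.0 is an assumption
# and is flagged as such.
formulation: taxol
K:
  li: 2.15
  sp: 0.13
  ht: 0.17
  kd: 0.75
  lu: 0.21
  tu: 0.27
  rm: 1.0
K_rm_assumed: true
CL_L_per_h: 0.0023
cv_percent:
  li: 23.64
  sp: 9.79
  ht: 9.86
  kd: 12.06
  lu: 9.98
  tu: 14.35
  CL: 0.06
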