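# Tumor-growth PD parameter sets. Growth rates come from control-cohort
# fits (12 saline-treated mice): exponential rate 0.51 /day (+/- 0.56 SD
# across animals), linear rate 0.17 g/day (+/- 0.11 SD). Kill coefficient
# k_d and transit rate tau are per-formulation treatment fits.
#
# w0 (initial tumor weight) and w_b (exponential-to-linear switch weight)
# were never reported; defaults here are back-calculated assumptions and
# are flagged as such in provenance: w_b = k_lin/k_exp makes the growth
# input continuous at the switch; mouse w0 = 0.3 g reproduces the reported
# ~270 % untreated 5-day growth; human w0 = 2.06 g reproduces the reported
# 41.2 % untreated 5-day growth under linear-phase kinetics.
growth:
  k_exp_per_day: 0.51
  k_exp_sd: 0.56
  k_lin_g_per_day: 0.17
  k_lin_sd: 0.11
w0_g:
  mouse: 0.3
  human: 2.06
treatment:
  taxol:      {k_d_ml_per_ng_day: 0.0039, tau_per_day: 0.93}
  ptx-nc:     {k_d_ml_per_ng_day: 0.0037, tau_per_day: 0.96}
  f68-ptx-nc: {k_d_ml_per_ng_day: 0.0038, tau_per_day: 0.95}
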