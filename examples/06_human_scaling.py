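"""Scale the mouse-fitted model to a 70 kg human.

Keeps the mouse-fitted partition coefficients, swaps in human physiology
and the literature human clearance (25.81 L/h for all formulations), and
simulates a 316 mg IV bolus for 3 h. Prints tumor AUC and the per-organ
relative-mass table, then couples the exposure into the human PD run.
"""

from nanopbpk import run_human_pd, run_human_scaling

print("human tumor AUC over 3 h (ug/mL*h), K_rm assumed = 1:")
for form in ("taxol", "ptx-nc", "f68-ptx-nc"):
    res = run_human_scaling(form)
    print(f"  {form:>10}: {res['tumor_auc_ug_ml_h']:.2f}")

res = run_human_scaling("f68-ptx-nc")
print("\nF68-coated nanocrystals, relative mass (AUC convention, blood = 100 %):")
for organ, pct in res["relative_mass_auc"].items():
    print(f"  {organ:>4}: {pct:8.2f} %")

print("\n5-day human PD (growth parameters from the mouse fits, w0 = 2.06 g):")
for form in ("taxol", "ptx-nc", "f68-ptx-nc"):
    pd = run_human_pd(form)
    print(f"  {form:>10}: untreated {pd['percent_growth_untreated']:+.1f} %, "
          f"treated {pd['percent_growth_treated']:+.1f} %")
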