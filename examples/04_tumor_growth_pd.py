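"""Coupled PK/PD: tumor growth under one dose of each formulation.

Simulates mouse tumor growth for 5 days with and without treatment,
driving the transit-compartment kill model with the PBPK tumor
concentration, then fits growth rates back from a synthetic control
cohort to close the loop.
"""

from nanopbpk import (fit_growth_control, load_pd_parameters, run_mouse_pd,
                      generate_growth_cohort)
from nanopbpk.synthetic import GrowthCohortDesign

print("5-day mouse tumor growth (w0 = 0.3 g, growth rates from control fits):")
control = run_mouse_pd(None)
print(f"  untreated: {control['percent_growth_untreated']:+.1f} %")
for form in ("taxol", "ptx-nc", "f68-ptx-nc"):
    res = run_mouse_pd(form)
    print(f"  {form:>10}: {res['percent_growth_treated']:+.1f} %")
print("(treated tumors always stay at or below the untreated curve)")

# close the loop on the control cohort: generate 12 animals around the
# published growth-rate moments, refit, compare cohort means
days = (0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 11.0, 14.0, 17.0, 20.0, 23.0)
base = load_pd_parameters(None, species="mouse").with_overrides(w0=0.05)
cohort, _ = generate_growth_cohort(GrowthCohortDesign(days=days, seed=7), base)
summary = fit_growth_control(cohort)
print(f"\ncontrol cohort refit (12 synthetic animals, 23 days):")
print(f"  k_exp {summary.mean_k_exp:.2f} +/- {summary.sd_k_exp:.2f} /day "
      "(population mean 0.51 +/- 0.56)")
print(f"  k_lin {summary.mean_k_lin:.2f} +/- {summary.sd_k_lin:.2f} g/day "
      "(population mean 0.17 +/- 0.11)")
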