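# Methods

This note records the model structure, the numerical choices, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the known limitations. It is the package's own account
of decisions that were genuinely open.

## Disposition model

The PBPK system is linear and perfusion-limited. State: eight
concentrations (µg/mL ≡ mg/L) plus the cumulative eliminated amount
(µg). Flows are plasma flows in L/h, volumes in L, time in hours.
Structural choices, all localised in `pbpk.system_matrix` so that
alternatives can be swapped:

- **Single blood pool.** No venous/arterial split; the IV bolus is an
  initial condition on blood, `C_bl(0) = dose/V_bl`.
- **Portal accounting.** `Q_li` is total portal flow. The splenic share
  `Q_sp` reaches the liver at the spleen's venous concentration
  `C_sp/K_sp`; the rest (`Q_li − Q_sp`) arrives at arterial
  concentration, as does the hepatic artery flow `Q_he`. The combined
  hepatic outflow `(Q_li + Q_he)·C_li/K_li` joins the venous return.
- **Lung.** Collects the venous return of all organ paths and feeds
  blood at `Q_lu·C_lu/K_lu`, with `Q_lu` = cardiac output.
- **Clearance.** Linear, hepatic, acting on the liver venous
  concentration: elimination rate `CL·C_li/K_li`.

**Flow imbalance.** The bundled mouse table's venous return sums to
≈0.501 L/h against a 0.48 L/h cardiac output (the human table is
imbalanced too); the printed values are used verbatim. Summing the
compartment equations shows every inter-compartment flux cancels
exactly, so total drug mass obeys `d/dt Σ V_i C_i = −CL·C_li/K_li`
*identically, imbalanced flows or not*: the imbalance shifts
steady-state concentration ratios, not the mass budget.
`mass_balance_residual` therefore measures solver error (~1e-14 in
practice) and is kept as a regression diagnostic. A corollary worth
stating: a spatially uniform concentration is an equilibrium of the
CL = 0, K = 1 system only when the flows balance; conservation unit
tests use a synthetic balanced physiology for that reason.

**Solvers.** Default integration is LSODA with the analytic Jacobian,
rtol 1e-8, atol 1e-12, output grid 0.01 h. Because the system is
linear, an exact eigendecomposition propagator (`method="expm"`) is also
provided; the two agree to ~1e-8 relative (tested), and the exact route
is used wherever smooth derivatives matter (estimation residuals,
finite-difference sensitivities) so that solver noise cannot leak into
Jacobians. Tiny negative excursions are clipped with a warning
threshold.

**Exposure metrics.** Trapezoidal AUC on the output grid; Cmax/Tmax are
grid maxima. The human 3 h scenario has an initial distribution spike
with time constant ~`V_bl/ΣQ ≈ 0.01 h`; the human-scaling grid default
is 0.0005 h, which keeps the tumor AUC within ~0.05 % of its
grid-converged value.

**Relative tissue mass.** The published mouse/human comparison
normalises organ drug mass "relative to blood = 100 %", without
defining the accumulation window or metric. Two conventions are
implemented and both reported: `auc_mass`
(100·V_o·AUC_o / (V_bl·AUC_bl), blood ≡ 100 %) and `terminal_mass`
(100·V_o·C_o(T)/dose, percent of injected dose in the organ at the
horizon). Neither reproduces the published liver percentages exactly;
the rank statements (liver is the dominant depot; F68 > Taxol liver
burden in mice) hold under both.

## Key parameter gaps and how they were closed

- **K_rm (remainder partition) — the one that matters.** Not printed,
  although the sensitivity figure's "eight PK parameters" implies it was
  fitted. Default: 1.0, flagged `assumed` in every output. The choice
  dominates absolute exposures because V_rm is the largest volume in
  both species. At K_rm = 1 the model overshoots the published human
  tumor AUCs and mouse sweep Cmax values by ≈55–95 %; a grid scan shows
  a single K_rm ≈ 2.4–2.7 reconciles all six printed values to ≈1 %
  simultaneously (per-formulation best values 2.3–4.0), strong evidence
  that the original fits used a remainder partition near 2.5. The
  default is nevertheless kept at 1.0 — an uncertain parameter should
  not be back-tuned to the outputs it is supposed to predict — and the
  acceptance tests carry both the at-default comparison (which fails
  the ±35 % band, documented, not hidden) and the reconciliation scan
  (which passes within ±10 %).
- **Mouse body weight.** Not printed; 20 g (blood volume 1.7 mL is
  consistent), so 20 mg/kg → 400 µg. Configurable.
- **AUC horizon of the sweep table.** Not stated; default 24 h,
  configurable. Published sweep AUCs are not reproducible at any single
  horizon with K_rm = 1; Cmax (horizon-insensitive) is used for
  comparisons.
- **Human dose.** The text's 316 mg for a 70 kg adult is the default;
  the figure caption's "20 mg/kg" is available as an override.

## Tumor-growth model

- **Three transit states.** w₁ (proliferating) plus two damage stages
  w₂, w₃; cells leave w₃ at rate τ and are removed. τ is a *rate*
  (day⁻¹), matching its printed units.
- **Growth-rate labels.** The source text assigns k₁/k₂ inconsistently
  between its equation prose and its results. Fields here are
  positional: `k_exp` = 0.51 /day (exponential phase), `k_lin` =
  0.17 g/day (linear phase), the assignment consistent with the printed
  units and SDs.
- **Switch weight w_b.** Never printed. Default `w_b = k_lin/k_exp`
  (0.333 g at the default rates), the unique value making the growth
  input continuous at the switch; hard threshold, no smoothing.
- **Initial weights.** Never printed. Mouse w0 = 0.3 g, back-calculated
  from the reported ~270 % untreated 5-day growth (the model gives
  +283 %); human w0 = 2.06 g, back-calculated from the reported 41.2 %
  untreated 5-day growth under linear-phase kinetics (the model gives
  +41.3 %). Both flagged `assumed` in provenance; no quantitative test
  depends on them, only orderings.
- **PK→PD boundary.** PK runs in hours and µg/mL, PD in days and ng/mL;
  the factor-24 and factor-1000 conversions live in exactly one place
  (`tumor.pk_to_pd_concentration`). For multi-day PD the PK model is
  integrated out to the PD horizon (how the original 3 h human PK was
  extended is unstated; re-integrating the same linear model is the
  simplest choice and is recorded in provenance).
- **Treated-mouse caveat.** At K_rm = 1 the mouse tumor exposure is
  high enough that the published k_d values predict near-eradication
  (−93 % at day 5) rather than the reported partial inhibition — the
  same K_rm overestimate propagated through the PD coupling.

## Estimation

- Unweighted least squares on concentrations (optional 1/ŷ² weighting);
  free parameters in log space, which enforces positivity without
  constraints. Convergence tolerances 1e-8–1e-10; optional multi-start
  (log-normal perturbations, factor ~1.5) against local minima.
- CVs are asymptotic: with log-parameters, `s²(JᵀJ)⁻¹` has relative
  variances on its diagonal, so CV % = 100·√diag directly.
- Control growth fits use the piecewise closed form of the untreated
  model per animal, with (k_exp, k_lin, w0) free and bounded at zero;
  if the fitted trajectory never visits the exponential phase, k_exp is
  unidentified and reported as 0. Animals with <3 points are excluded
  with a warning.
- Treatment fits free (k_d, τ) *and one w0 per animal*: anchoring w0 to
  the noisy day-0 observation propagates that single measurement's
  error through the whole predicted trajectory and biases τ by ~5–10 %
  at 5 % noise (observed before the change). The whole cohort is
  integrated as one stacked ODE system; the Jacobian is block-sparse
  (each w0 touches only its own animal), so grouped finite differences
  need ~3 model evaluations per Jacobian. The finite-difference step
  (1e-4 on log parameters) is set well above the integrator's noise
  floor — with the default √eps step the Jacobian is dominated by
  solver error and the optimiser stalls.

## Synthetic data

The generator emulates the study's *unpublished* measurements, with
known ground truth:

- **PK:** destructive-sampling schedule (0.083, 0.5, 1, 3, 6, 24, 48 h;
  seven tissues; 3 replicates per point, i.e. three animals per
  timepoint), noise `y = C(1+ε_prop) + ε_add` with ε normal,
  CV 10 %, additive floor 0.01 µg/mL, clipped at zero.
- **PD:** cohorts of 12 animals (the published control-group size) with
  per-animal growth rates drawn from truncated normals around the
  published moments (0.51 ± 0.56 /day, 0.17 ± 0.11 g/day — truncation
  at zero is forced by SD > mean; resamples are counted in provenance),
  caliper schedule denser early (days 0–23), 5 % multiplicative
  residual noise.

It does **not** emulate LLOQ censoring, batch effects, assay drift, or
inter-animal PK variability; passing recovery tests therefore
demonstrates estimator correctness under the stated error model, not
robustness to real bioanalytical artifacts. Because the real study's
design and weighting are unknown, the synthetic design's information
content differs from the original: the Monte-Carlo empirical CV of the
liver partition (≈4 % at 10 % noise) is well below the published
23.64 %, which likely reflects sparser or more variable real data — the
published CVs are treated as plausibility anchors, not targets (the
published clearance "CVs" of 0.06–0.00083 % are not credible as NLS
coefficients of variation on any reading).

## Sensitivity analysis

Central differences with 1 % relative step (0.1 % agrees within 1 %,
tested); signed derivative integrated over the window by trapezoid; raw
(unnormalised) values by default, with an elasticity-style normalised
variant (`θ/C̄ · ∫∂C/∂θ dt`) available. Rankings use absolute values,
ties broken lexicographically. Flows are addressable parameters
(`Q_tu`, `Q_he`, …; `Q_lu` moves cardiac output as a whole). Only
*orderings* are treated as reproducible claims — the published
heat-map colour scales depend on unstated step/normalisation choices.
A caution on raw derivatives: parameters with small magnitudes (mouse
CL ≈ 0.0023 L/h) get proportionally large raw derivatives; this is
faithful to the published maps, which show the same scale effects.

## Problem sizes

Defaults were chosen so the whole pipeline runs interactively on one
core: PK grids of 300–24 000 points per simulation, 100-seed Monte-Carlo
for recovery statistics, 12-animal cohorts, and flux-balance horizons of
10 terminal half-lives (up to 2 000 h for the slow-clearing F68
formulation, still a single linear solve). The full test suite runs in
well under a minute; the acceptance script in seconds.

## Known limitations

- No permeability-limited or lymphatic sub-models, no nanocrystal
  dissolution kinetics, no plasma-protein binding: each formulation is
  characterised entirely by its fitted K/CL set, as in the source
  analysis.
- Tumor volume is fixed in the PK model (no PD→PK feedback).
- The human extrapolation inherits mouse-fitted partition coefficients
  and a literature clearance; it is a mathematical exercise about
  physiological differences, not a validated clinical prediction.
- Absolute agreement with the published exposure tables is limited by
  the unpublished K_rm (see above); orderings, trends, conservation
  identities and recovery properties are the reproducible content.
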