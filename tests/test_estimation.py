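"""NLS parameter estimation: recovery, identifiability, reproducibility."""

import numpy as np
import pytest

from nanopbpk import (DoseEvent, PDParameters, TISSUES, fit_growth_control, fit_pbpk,
                      fit_treatment, pk_to_pd_concentration, simulate)
from nanopbpk.estimation import ObservedGrowthDataset, _pk_get
from nanopbpk.synthetic import (GrowthCohortDesign, PKDesign, generate_growth_cohort,
                                generate_pk_dataset)


@pytest.fixture(scope="module")
def noise_free_taxol_data(mouse, taxol, mouse_dose):
    design = PKDesign(cv=0.0, sd_additive=0.0, replicates=1)
    return generate_pk_dataset(taxol, mouse, mouse_dose, design)


def blind_init(pk):
    return pk.with_overrides(K={c: 1.0 for c in TISSUES}, CL=0.01)


class TestFitPBPK:
    def test_noise_free_recovery_is_exact(self, mouse, taxol, noise_free_taxol_data):
        fit = fit_pbpk(noise_free_taxol_data, mouse, blind_init(taxol))
        assert fit.converged
        for name, est in fit.estimates.items():
            assert est == pytest.approx(_pk_get(taxol, name), rel=1e-3)

    def test_all_fixed_echoes_init_and_evaluates_residual(self, mouse, taxol,
                                                          noise_free_taxol_data):
        fit = fit_pbpk(noise_free_taxol_data, mouse, taxol, free=())
        assert fit.estimates == {}
        assert fit.fixed["CL"] == taxol.CL
        # data were generated at exactly these parameters
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_residual_never_worse_than_initial_point(self, mouse, taxol, mouse_dose):
        data = generate_pk_dataset(taxol, mouse, mouse_dose, PKDesign(cv=0.15, seed=7))
        init = blind_init(taxol)
        at_init = fit_pbpk(data, mouse, init, free=())
        fitted = fit_pbpk(data, mouse, init, free=("K_li", "CL"))
        assert fitted.rss <= at_init.rss

    def test_reproducible_for_identical_inputs(self, mouse, taxol, mouse_dose):
        data = generate_pk_dataset(taxol, mouse, mouse_dose, PKDesign(cv=0.1, seed=3))
        one = fit_pbpk(data, mouse, blind_init(taxol))
        two = fit_pbpk(data, mouse, blind_init(taxol))
        assert one.estimates == two.estimates and one.rss == two.rss

    def test_asymptotic_cvs_reported_for_free_parameters_only(self, mouse, taxol,
                                                              mouse_dose):
        data = generate_pk_dataset(taxol, mouse, mouse_dose, PKDesign(cv=0.1, seed=1))
        fit = fit_pbpk(data, mouse, blind_init(taxol), free=("K_li", "CL"))
        assert set(fit.cv_percent) == {"K_li", "CL"}
        assert all(cv >= 0 for cv in fit.cv_percent.values())

    def test_cv_shrinks_with_replication(self, mouse, taxol, mouse_dose):
        cvs = []
        for reps in (2, 8):
            data = generate_pk_dataset(taxol, mouse, mouse_dose,
                                       PKDesign(cv=0.1, replicates=reps, seed=11))
            fit = fit_pbpk(data, mouse, blind_init(taxol), free=("K_li",))
            cvs.append(fit.cv_percent["K_li"])
        assert cvs[1] < cvs[0]


class TestFitGrowthControl:
    def test_noise_free_exponential_animal_matches_log_linear_regression(self):
        t = np.linspace(0.0, 3.0, 8)
        w = 0.05 * np.exp(0.4 * t)  # stays below the switch weight
        ds = ObservedGrowthDataset("a", t, w)
        summary = fit_growth_control([ds])
        # independent oracle: straight-line fit of log w against t
        slope = np.polyfit(t, np.log(w), 1)[0]
        assert summary.mean_k_exp == pytest.approx(slope, abs=1e-6)

    def test_constant_series_gives_zero_rates(self):
        ds = ObservedGrowthDataset("flat", np.arange(6.0), np.full(6, 0.4))
        summary = fit_growth_control([ds])
        assert summary.mean_k_exp == pytest.approx(0.0, abs=1e-6)
        assert summary.mean_k_lin == pytest.approx(0.0, abs=1e-6)

    def test_short_series_excluded_with_warning(self):
        good = ObservedGrowthDataset("ok", np.arange(5.0), 0.1 * np.exp(0.3 * np.arange(5.0)))
        bad = ObservedGrowthDataset("short", np.array([0.0, 1.0]), np.array([0.1, 0.2]))
        with pytest.warns(RuntimeWarning, match="excluded"):
            summary = fit_growth_control([good, bad])
        assert summary.excluded == ["short"]
        assert len(summary.per_animal) == 1

    def test_cohort_mean_recovery_from_synthetic_population(self, control_pd):
        days = (0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 11.0, 14.0, 17.0, 20.0, 23.0)
        design = GrowthCohortDesign(days=days, seed=0)
        base = control_pd.with_overrides(w0=0.05)
        cohort, prov = generate_growth_cohort(design, base)
        summary = fit_growth_control(cohort)
        two_se_exp = 2.0 * design.k_exp_sd / np.sqrt(design.n_animals)
        two_se_lin = 2.0 * design.k_lin_sd / np.sqrt(design.n_animals)
        assert abs(summary.mean_k_exp - design.k_exp_mean) < two_se_exp
        assert abs(summary.mean_k_lin - design.k_lin_mean) < two_se_lin


@pytest.fixture(scope="module")
def mouse_tumor_exposure(mouse, taxol, mouse_dose):
    prof = simulate(mouse, taxol, mouse_dose, 11 * 24.0, grid=0.02)
    return pk_to_pd_concentration(prof, "tu")


TREATMENT_DAYS = tuple(np.concatenate([np.arange(0.0, 6.01, 0.5),
                                       np.arange(7.0, 10.01, 1.0)]))


class TestFitTreatment:
    def test_planted_kill_and_transit_recovered(self, mouse_tumor_exposure):
        base = PDParameters(k_exp=0.51, k_lin=0.17, w0=0.3, k_d=0.0038, tau=0.95)
        design = GrowthCohortDesign(days=TREATMENT_DAYS, k_exp_sd=0.0, k_lin_sd=0.0,
                                    residual_cv=0.05, seed=0)
        cohort, _ = generate_growth_cohort(design, base, mouse_tumor_exposure)
        fit = fit_treatment(cohort, (0.51, 0.17), mouse_tumor_exposure, tol=1e-8)
        assert fit.estimates["k_d"] == pytest.approx(0.0038, rel=0.05)
        assert fit.estimates["tau"] == pytest.approx(0.95, rel=0.05)

    def test_zero_kill_truth_not_significant(self, mouse_tumor_exposure):
        base = PDParameters(k_exp=0.51, k_lin=0.17, w0=0.3, k_d=0.0, tau=0.95)
        design = GrowthCohortDesign(days=TREATMENT_DAYS, k_exp_sd=0.0, k_lin_sd=0.0,
                                    residual_cv=0.05, seed=1)
        cohort, _ = generate_growth_cohort(design, base, mouse_tumor_exposure)
        fit = fit_treatment(cohort, (0.51, 0.17), mouse_tumor_exposure,
                            init=(1e-4, 1.0), tol=1e-8)
        kd = fit.estimates["k_d"]
        # estimated effect is indistinguishable from no effect: the implied
        # survival reduction over the study is within the 5 % noise floor
        total_exposure = np.trapezoid([mouse_tumor_exposure(t) for t in
                                       np.linspace(0, 10, 2001)], dx=10 / 2000)
        assert kd * total_exposure < 0.05 or fit.cv_percent["k_d"] > 100.0

    def test_recovery_invariant_under_exposure_scaling(self, mouse_tumor_exposure):
        base = PDParameters(k_exp=0.51, k_lin=0.17, w0=0.3, k_d=0.0038, tau=0.95)
        estimates = []
        for scale in (1.0, 2.0):
            conc = lambda t, s=scale: s * mouse_tumor_exposure(t)
            design = GrowthCohortDesign(days=TREATMENT_DAYS, k_exp_sd=0.0,
                                        k_lin_sd=0.0, residual_cv=0.0, seed=0)
            cohort, _ = generate_growth_cohort(design, base, conc)
            fit = fit_treatment(cohort, (0.51, 0.17), conc, tol=1e-8)
            estimates.append((fit.estimates["k_d"], fit.estimates["tau"]))
        assert estimates[0] == pytest.approx(estimates[1], rel=1e-3)
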