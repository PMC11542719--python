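"""Nonlinear least-squares estimation of PK and PD parameters.

PK fitting minimises the unweighted (optionally 1/y^2-weighted) squared
residuals between simulated and observed tissue concentrations over any
subset of the partition coefficients and the hepatic clearance. Free
parameters are optimised in log space, which enforces positivity without
constraints. Uncertainty is reported as the asymptotic coefficient of
variation from the Jacobian at the optimum: with log-parameters the
diagonal of ``s^2 (J'J)^-1`` is directly the squared relative standard
error, so ``CV% = 100 * sqrt(cov_log_jj)``.

PD fitting is staged as in the source workflow: the control (saline)
cohort first yields per-animal growth rates ``(k_exp, k_lin)`` via the
closed-form untreated growth curve, then ``(k_d, tau)`` are fitted to
treated trajectories with the growth rates held fixed and the tumor
exposure supplied by the PK model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigurationError, ParameterError
from .parameters import DoseEvent, PDParameters, Physiology, PKParameters, TISSUES
from .pbpk import COMPARTMENTS, simulate
from .tumor import ConcFunc, control_weight, simulate_tumor

PK_PARAMETER_NAMES = tuple(f"K_{c}" for c in TISSUES) + ("CL",)


@dataclass
class ObservedPKDataset:
    """Tidy per-compartment concentration observations.

    ``data`` columns: ``compartment``, ``time_h``, ``conc_ug_per_ml`` and
    optionally ``weight``.
    """

    data: pd.DataFrame
    dose: DoseEvent
    formulation: str = ""

    def __post_init__(self) -> None:
        required = {"compartment", "time_h", "conc_ug_per_ml"}
        missing = required - set(self.data.columns)
        if missing:
            raise ConfigurationError(f"PK dataset missing columns {sorted(missing)}")
        if (self.data["time_h"] < 0).any():
            raise ParameterError("observation times must be non-negative")
        if (self.data["conc_ug_per_ml"] < 0).any():
            raise ParameterError("observed concentrations must be non-negative")
        unknown = set(self.data["compartment"]) - set(COMPARTMENTS)
        if unknown:
            raise ConfigurationError(f"unknown compartments in dataset: {sorted(unknown)}")

    @property
    def n_obs(self) -> int:
        return len(self.data)


@dataclass
class ObservedGrowthDataset:
    """One animal's tumor weight series (days, grams)."""

    animal_id: str
    times: np.ndarray
    weights: np.ndarray
    treatment: str = "control"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.times.shape != self.weights.shape:
            raise ConfigurationError("times and weights must have equal length")
        if not (self.weights > 0).all():
            raise ParameterError("tumor weights must be strictly positive")


@dataclass
class FitResult:
    """Outcome of one NLS fit."""

    estimates: dict[str, float]
    cv_percent: dict[str, float]
    rss: float
    converged: bool
    n_evaluations: int
    fixed: dict[str, float] = field(default_factory=dict)
    init: dict[str, float] = field(default_factory=dict)
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "cv_percent": dict(self.cv_percent),
            "rss": self.rss,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "fixed": dict(self.fixed),
            "init": dict(self.init),
            "message": self.message,
        }


def _pk_apply(init: PKParameters, names: Sequence[str], values: np.ndarray) -> PKParameters:
    K = {}
    CL = None
    for name, v in zip(names, values):
        if name == "CL":
            CL = float(v)
        elif name.startswith("K_"):
            K[name[2:]] = float(v)
        else:
            raise ConfigurationError(f"unknown PK parameter {name!r}")
    return init.with_overrides(K=K, CL=CL)


def _pk_get(pk: PKParameters, name: str) -> float:
    if name == "CL":
        return pk.CL
    if name.startswith("K_") and name[2:] in pk.K:
        return pk.K[name[2:]]
    raise ConfigurationError(f"unknown PK parameter {name!r}")


def _asymptotic_cv_log(jac, residuals: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    if hasattr(jac, "toarray"):  # sparse Jacobian from grouped differencing
        jac = jac.toarray()
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(residuals @ residuals) / dof
    JTJ = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        warnings.warn("near-singular Jacobian: parameters may be non-identifiable; using pseudo-inverse",
                      RuntimeWarning)
        cov = s2 * np.linalg.pinv(JTJ)
    diag = np.clip(np.diag(cov), 0.0, None)
    return {name: 100.0 * float(np.sqrt(d)) for name, d in zip(names, diag)}


def fit_pbpk(
    data: ObservedPKDataset,
    physiology: Physiology,
    init: PKParameters,
    free: Iterable[str] = PK_PARAMETER_NAMES,
    *,
    weighting: str | None = None,
    tol: float = 1e-10,
    multi_start: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Fit partition coefficients and/or clearance to concentration data.

    ``free`` names the parameters to optimise (``K_li`` ... ``K_rm``,
    ``CL``); the rest stay at ``init``. ``weighting=None`` is ordinary
    least squares; ``"1/y2"`` weights residuals by the observation.
    ``multi_start`` adds perturbed restarts (log-normal, factor ~1.5)
    to guard against local minima; the best solution is returned.
    """
    free = list(free)
    for name in free:
        if name not in PK_PARAMETER_NAMES:
            raise ConfigurationError(f"unknown free parameter {name!r}")
    obs = data.data.sort_values(["compartment", "time_h"]).reset_index(drop=True)
    comps = sorted(obs["compartment"].unique())
    t_all = np.unique(obs["time_h"].to_numpy())
    if t_all[0] == 0.0 and len(t_all) == 1:
        raise ConfigurationError("need at least one positive observation time")
    horizon = float(t_all.max())

    y = obs["conc_ug_per_ml"].to_numpy()
    if weighting is None:
        w = np.ones_like(y)
    elif weighting == "1/y2":
        w = 1.0 / np.maximum(y, np.percentile(y[y > 0], 5) if (y > 0).any() else 1.0)
    else:
        raise ConfigurationError(f"unknown weighting {weighting!r}")

    comp_rows = {c: obs.index[obs["compartment"] == c].to_numpy() for c in comps}
    comp_times = {c: obs.loc[comp_rows[c], "time_h"].to_numpy() for c in comps}

    def model_residuals(theta_log: np.ndarray) -> np.ndarray:
        pk = _pk_apply(init, free, np.exp(theta_log))
        prof = simulate(physiology, pk, data.dose, horizon, method="expm",
                        t_eval=np.concatenate([[0.0], t_all]) if t_all[0] > 0 else t_all)
        resid = np.empty(len(obs))
        for c in comps:
            model = np.interp(comp_times[c], prof.times, prof[c])
            resid[comp_rows[c]] = model - obs.loc[comp_rows[c], "conc_ug_per_ml"].to_numpy()
        return resid * w

    init_map = {name: _pk_get(init, name) for name in PK_PARAMETER_NAMES}
    fixed = {name: init_map[name] for name in PK_PARAMETER_NAMES if name not in free}

    if not free:
        resid = np.asarray(model_residuals(np.empty(0)))
        return FitResult(estimates={}, cv_percent={}, rss=float(resid @ resid),
                         converged=True, n_evaluations=1, fixed=fixed, init=dict(init_map),
                         message="all parameters fixed; direct evaluation")

    theta0 = np.log([init_map[name] for name in free])
    starts = [theta0]
    rng = np.random.default_rng(seed)
    for _ in range(multi_start):
        starts.append(theta0 + rng.normal(0.0, np.log(1.5), size=theta0.size))

    best = None
    for start in starts:
        res = least_squares(model_residuals, start, method="lm",
                            ftol=tol, xtol=tol, gtol=tol, max_nfev=20000)
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    estimates = dict(zip(free, np.exp(best.x)))
    cv = _asymptotic_cv_log(best.jac, best.fun, free)
    converged = bool(best.status > 0)
    if not converged:
        warnings.warn(f"PK fit did not converge: {best.message}", RuntimeWarning)
    return FitResult(
        estimates=estimates, cv_percent=cv, rss=float(2 * best.cost),
        converged=converged, n_evaluations=int(best.nfev),
        fixed=fixed, init=dict(init_map), message=str(best.message),
    )


@dataclass
class GrowthFitSummary:
    """Control-cohort growth fit: per-animal estimates and cohort moments."""

    per_animal: pd.DataFrame  # animal_id, k_exp, k_lin, w0, rss
    mean_k_exp: float
    sd_k_exp: float
    mean_k_lin: float
    sd_k_lin: float
    excluded: list[str] = field(default_factory=list)


def _fit_one_control(ds: ObservedGrowthDataset) -> tuple[float, float, float, float]:
    t, wobs = ds.times, ds.weights
    w0_init = float(wobs[0])
    span = float(t[-1] - t[0]) or 1.0
    slope = max(float((wobs[-1] - wobs[0]) / span), 0.0)
    # crude early-phase rate for initialisation
    k_exp_init = max(float(np.log(max(wobs[-1] / wobs[0], 1e-6)) / span), 1e-3)

    def resid(theta):
        k_exp, k_lin, w0 = theta
        pd_par = PDParameters(k_exp=k_exp, k_lin=k_lin, w0=w0)
        return control_weight(pd_par, t) - wobs

    res = least_squares(
        resid, x0=[k_exp_init, max(slope, 1e-6), w0_init],
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=10000,
    )
    k_exp, k_lin, w0 = res.x
    # if the fitted trajectory never visits the exponential phase, k_exp is
    # unidentified and is reported as 0 (no exponential growth observed)
    if k_exp > 0 and w0 >= k_lin / k_exp:
        k_exp = 0.0
    return float(k_exp), float(k_lin), float(w0), float(2 * res.cost)


def fit_growth_control(cohort: Sequence[ObservedGrowthDataset]) -> GrowthFitSummary:
    """Fit the untreated growth model per animal; report cohort mean +/- SD.

    Animals with fewer than three observations are excluded with a warning.
    """
    rows, excluded = [], []
    for ds in cohort:
        if len(ds.times) < 3:
            warnings.warn(f"animal {ds.animal_id!r} has <3 observations; excluded", RuntimeWarning)
            excluded.append(ds.animal_id)
            continue
        k_exp, k_lin, w0, rss = _fit_one_control(ds)
        rows.append({"animal_id": ds.animal_id, "k_exp": k_exp, "k_lin": k_lin,
                     "w0": w0, "rss": rss})
    if not rows:
        raise ConfigurationError("no animal had enough observations to fit")
    table = pd.DataFrame(rows)
    return GrowthFitSummary(
        per_animal=table,
        mean_k_exp=float(table["k_exp"].mean()),
        sd_k_exp=float(table["k_exp"].std(ddof=1)) if len(table) > 1 else 0.0,
        mean_k_lin=float(table["k_lin"].mean()),
        sd_k_lin=float(table["k_lin"].std(ddof=1)) if len(table) > 1 else 0.0,
        excluded=excluded,
    )


def fit_treatment(
    data: ObservedGrowthDataset | Sequence[ObservedGrowthDataset],
    growth: tuple[float, float],
    conc: ConcFunc,
    *,
    init: tuple[float, float] = (0.001, 1.0),
    tol: float = 1e-10,
) -> FitResult:
    """Fit ``(k_d, tau)`` to treated tumor trajectories, growth rates fixed.

    ``growth`` is ``(k_exp, k_lin)`` from the control fit; ``conc`` maps
    days to tumor drug concentration in ng/mL. Each animal's initial
    weight is a free nuisance parameter (initialised at its first
    observation) — anchoring it to the noisy day-0 measurement instead
    would propagate that observation's error through the whole predicted
    trajectory and bias ``tau``. Accepts one dataset or a cohort
    (residuals are stacked; the whole cohort is integrated as one ODE
    system).
    """
    cohort = [data] if isinstance(data, ObservedGrowthDataset) else list(data)
    k_exp, k_lin = growth
    horizon = max(float(ds.times.max()) for ds in cohort)
    n_animals = len(cohort)
    w_b = k_lin / k_exp if k_exp > 0 else np.inf
    t_eval = np.unique(np.concatenate([ds.times for ds in cohort]))
    if t_eval[0] > 0:
        t_eval = np.concatenate([[0.0], t_eval])

    from scipy.integrate import solve_ivp

    def resid(theta_log):
        k_d, tau = np.exp(theta_log[:2])
        w0s = np.exp(theta_log[2:])

        # one stacked system for the whole cohort: states (w1, w2, w3) per animal
        def rhs(t, y):
            w1, w2, w3 = y[:n_animals], y[n_animals:2 * n_animals], y[2 * n_animals:]
            w = w1 + w2 + w3
            g = np.where(w < w_b, k_exp * w, k_lin)
            kill = k_d * conc(t) * w1
            dw1 = np.where(w > 0, g * w1 / np.maximum(w, 1e-300), 0.0) - kill
            dw2 = kill - tau * w2
            dw3 = tau * (w2 - w3)
            return np.concatenate([dw1, dw2, dw3])

        y0 = np.concatenate([w0s, np.zeros(2 * n_animals)])
        sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA", t_eval=t_eval,
                        rtol=1e-8, atol=1e-10)
        w_tot = sol.y[:n_animals] + sol.y[n_animals:2 * n_animals] + sol.y[2 * n_animals:]
        out = []
        for i, ds in enumerate(cohort):
            out.append(np.interp(ds.times, sol.t, w_tot[i]) - ds.weights)
        return np.concatenate(out)

    w0_init = [float(ds.weights[0]) for ds in cohort]
    theta0 = np.log(np.concatenate([np.asarray(init, dtype=float), w0_init]))
    # each w0 column only touches its own animal's residuals, so grouped
    # finite differences need ~3 evaluations per Jacobian instead of 2+n
    n_res = sum(len(ds.times) for ds in cohort)
    sparsity = np.zeros((n_res, 2 + n_animals), dtype=int)
    sparsity[:, :2] = 1
    offset = 0
    for i, ds in enumerate(cohort):
        sparsity[offset:offset + len(ds.times), 2 + i] = 1
        offset += len(ds.times)
    # FD step well above the ODE-solver noise floor (solution rtol 1e-8)
    res = least_squares(resid, theta0, method="trf", jac_sparsity=sparsity,
                        diff_step=1e-4, ftol=tol, xtol=tol, gtol=tol, max_nfev=20000)
    k_d, tau = np.exp(res.x[:2])
    names = ["k_d", "tau"] + [f"w0_{ds.animal_id}" for ds in cohort]
    cv = _asymptotic_cv_log(res.jac, res.fun, names)
    converged = bool(res.status > 0)
    if not converged:
        warnings.warn(f"treatment fit did not converge: {res.message}", RuntimeWarning)
    return FitResult(
        estimates={"k_d": float(k_d), "tau": float(tau),
                   **{n: float(v) for n, v in zip(names[2:], np.exp(res.x[2:]))}},
        cv_percent=cv,
        rss=float(2 * res.cost), converged=converged, n_evaluations=int(res.nfev),
        fixed={"k_exp": k_exp, "k_lin": k_lin},
        init={"k_d": float(init[0]), "tau": float(init[1])}, message=str(res.message),
    )
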