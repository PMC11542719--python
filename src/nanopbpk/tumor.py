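"""Transit-compartment tumor growth model with drug-induced cell kill.

Untreated tumor mass grows exponentially at rate ``k_exp`` (1/day) while
total weight is below the cutoff ``w_b`` (g) and linearly at ``k_lin``
(g/day) above it — the classic exponential-to-linear growth pattern of
xenografts once angiogenesis and nutrient supply become limiting. Drug
exposure ``c(t)`` (ng/mL, tumor compartment) kills proliferating cells at
rate ``k_d * c``; damaged cells pass through two transit stages at rate
``tau`` before dying, producing the observed lag between exposure and
shrinkage. The three states are:

    dw1/dt = g(w) * w1 / w - k_d * c(t) * w1
    dw2/dt = k_d * c(t) * w1 - tau * w2
    dw3/dt = tau * (w2 - w3)

with ``w = w1 + w2 + w3``, ``g(w) = k_exp * w`` below ``w_b`` and
``k_lin`` above, and initial state ``(w0, 0, 0)``. Cells leave ``w3`` at
rate ``tau * w3`` and are removed.

PK/PD unit boundary (kept in exactly one place,
:func:`pk_to_pd_concentration`): PK runs in hours and ug/mL, PD in days
and ng/mL, so the coupling multiplies time by 24 and concentration by 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, NanoPBPKError, RangeError
from .parameters import PDParameters
from .pbpk import ConcentrationProfile

ConcFunc = Callable[[float], float]

#: hours per day and ng per ug — the only place the PK->PD units change.
_HOURS_PER_DAY = 24.0
_NG_PER_UG = 1000.0


def pk_to_pd_concentration(profile: ConcentrationProfile, compartment: str = "tu") -> ConcFunc:
    """Wrap a PK profile as the PD driving function ``t_days -> ng/mL``."""
    times_d = profile.times / _HOURS_PER_DAY
    values = profile[compartment] * _NG_PER_UG

    def conc(t_day: float) -> float:
        t = float(t_day)
        if t < times_d[0] or t > times_d[-1] * (1 + 1e-12):
            raise RangeError(
                f"PD requested exposure at day {t:.3g} outside the simulated PK range "
                f"[0, {times_d[-1]:.3g}] days"
            )
        return float(np.interp(t, times_d, values))

    return conc


@dataclass
class TumorTrajectory:
    """Tumor state over time: proliferating mass w1 and transit stages w2, w3 (g)."""

    times: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def w(self) -> np.ndarray:
        """Total tumor weight, g."""
        return self.w1 + self.w2 + self.w3

    def weight(self, day: float | np.ndarray) -> float | np.ndarray:
        day = np.asarray(day, dtype=float)
        if np.any(day < self.times[0]) or np.any(day > self.times[-1] * (1 + 1e-12)):
            raise RangeError(f"day outside trajectory range [0, {self.times[-1]:.3g}]")
        out = np.interp(day, self.times, self.w)
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_day": self.times, "w1_g": self.w1, "w2_g": self.w2,
             "w3_g": self.w3, "w_g": self.w}
        )


def _growth_input(pd_par: PDParameters, w: float) -> float:
    if w < pd_par.switch_weight:
        return pd_par.k_exp * w
    return pd_par.k_lin


def simulate_tumor(
    pd_par: PDParameters,
    conc: ConcFunc | None = None,
    horizon: float = 23.0,
    *,
    grid: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TumorTrajectory:
    """Integrate the PD system over ``[0, horizon]`` days.

    ``conc`` maps time in days to tumor drug concentration in ng/mL
    (``None`` means untreated). Negative concentrations are rejected.
    """
    if not horizon > 0:
        raise RangeError(f"horizon must be positive, got {horizon}")
    c = (lambda t: 0.0) if conc is None else conc

    def rhs(t, y):
        w1, w2, w3 = y
        ct = c(t)
        if ct < 0:
            raise NanoPBPKError(f"negative drug concentration {ct} at day {t}")
        w = w1 + w2 + w3
        kill = pd_par.k_d * ct * w1
        g = _growth_input(pd_par, w) if w > 0 else 0.0
        dw1 = (g * w1 / w if w > 0 else 0.0) - kill
        dw2 = kill - pd_par.tau * w2
        dw3 = pd_par.tau * (w2 - w3)
        return (dw1, dw2, dw3)

    n = max(int(round(horizon / grid)), 1)
    t_eval = np.linspace(0.0, horizon, n + 1)
    sol = solve_ivp(rhs, (0.0, horizon), (pd_par.w0, 0.0, 0.0),
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"PD integration failed: {sol.message}")
    w1, w2, w3 = np.clip(sol.y, 0.0, None)
    return TumorTrajectory(
        times=t_eval, w1=w1, w2=w2, w3=w3,
        provenance={
            "w0_g": pd_par.w0,
            "w_b_g": pd_par.switch_weight,
            "w_b_assumed": pd_par.w_b is None or pd_par.w_b_assumed,
            "treated": conc is not None and pd_par.k_d > 0,
        },
    )


def control_weight(pd_par: PDParameters, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form untreated tumor weight.

    Exponential from ``w0`` until the cutoff is reached, then linear. Used
    as the fast model in control-cohort fitting; the ODE route must agree
    with it (tested).
    """
    t = np.asarray(t, dtype=float)
    w_b = pd_par.switch_weight
    if pd_par.w0 >= w_b:
        out = pd_par.w0 + pd_par.k_lin * t
    elif pd_par.k_exp == 0:
        out = np.full_like(t, pd_par.w0)
    else:
        t_switch = np.log(w_b / pd_par.w0) / pd_par.k_exp
        out = np.where(
            t < t_switch,
            pd_par.w0 * np.exp(pd_par.k_exp * t),
            w_b + pd_par.k_lin * np.maximum(t - t_switch, 0.0),
        )
    return float(out) if out.ndim == 0 else out


def percent_growth(traj: TumorTrajectory, day: float) -> float:
    """Percent change of total tumor weight from day 0: 100*(w(day)-w(0))/w(0)."""
    w0 = float(traj.w[0])
    return 100.0 * (float(traj.weight(day)) - w0) / w0
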