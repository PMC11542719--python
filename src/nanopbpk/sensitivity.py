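"""Derivative-based one-at-a-time (OAT) local sensitivity analysis.

For a chosen model output (an organ concentration trajectory) and a
parameter ``theta``, the local sensitivity is ``dC(t)/dtheta`` evaluated
by a central finite difference with a relative step (default 1 %) and
then integrated over the treatment window, yielding one number per
(output, parameter) pair. Stacking all pairs gives the sensitivity
matrix; ranking a row by absolute value orders the parameters by impact
on that organ.

Admissible parameters are addressed uniformly by name: partition
coefficients ``K_li`` ... ``K_rm``, hepatic clearance ``CL``, organ
plasma flows ``Q_li``/``Q_sp``/``Q_ht``/``Q_kd``/``Q_tu``/``Q_rm``, the
hepatic artery flow ``Q_he``, and cardiac output ``Q_lu`` (which moves
the blood and lung flows together, since they are the same quantity).

Trajectories for the difference quotient come from the exact linear
propagator rather than an adaptive solver, so the differences are free of
integration-tolerance noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .errors import ConfigurationError
from .parameters import DoseEvent, Physiology, PKParameters, TISSUES
from .pbpk import simulate

#: Parameters addressable in the sensitivity analysis.
DEFAULT_PK_PARAMETERS = tuple(f"K_{c}" for c in TISSUES) + ("CL",)
FLOW_PARAMETERS = ("Q_li", "Q_sp", "Q_ht", "Q_kd", "Q_tu", "Q_rm", "Q_he", "Q_lu")


def _get_parameter(physiology: Physiology, pk: PKParameters, name: str) -> float:
    if name == "CL":
        return pk.CL
    if name.startswith("K_") and name[2:] in pk.K:
        return pk.K[name[2:]]
    if name == "Q_he":
        return physiology.Q_he
    if name.startswith("Q_") and name[2:] in physiology.Q:
        return physiology.Q[name[2:]]
    raise ConfigurationError(f"unknown sensitivity parameter {name!r}")


def _set_parameter(
    physiology: Physiology, pk: PKParameters, name: str, value: float
) -> tuple[Physiology, PKParameters]:
    if name == "CL":
        return physiology, pk.with_overrides(CL=value)
    if name.startswith("K_") and name[2:] in pk.K:
        return physiology, pk.with_overrides(K={name[2:]: value})
    if name == "Q_he":
        return physiology.with_overrides(Q_he=value), pk
    if name == "Q_lu":  # cardiac output: blood and lung flow move together
        return physiology.with_overrides(Q={"lu": value, "bl": value}), pk
    if name.startswith("Q_") and name[2:] in physiology.Q:
        return physiology.with_overrides(Q={name[2:]: value}), pk
    raise ConfigurationError(f"unknown sensitivity parameter {name!r}")


def local_sensitivity(
    physiology: Physiology,
    pk: PKParameters,
    dose: DoseEvent,
    theta: str,
    output: str,
    horizon: float,
    *,
    rel_step: float = 0.01,
    normalized: bool = False,
    grid: float = 0.01,
) -> float:
    """Time-integrated OAT sensitivity of one organ concentration to one parameter.

    Central difference ``[C(theta*(1+h)) - C(theta*(1-h))] / (2*theta*h)``
    integrated over ``[0, horizon]`` by the trapezoid rule. With
    ``normalized=True`` the integrated value is scaled by
    ``theta / mean(C)`` (time-averaged output), giving a dimensionless
    elasticity-style measure; the raw value is the default.
    """
    value = _get_parameter(physiology, pk, theta)
    if value == 0.0:
        warnings.warn(
            f"{theta} is zero; falling back to an absolute step of {rel_step}",
            RuntimeWarning,
        )
        step = rel_step
    else:
        step = abs(value) * rel_step

    def run(v: float) -> np.ndarray:
        phys2, pk2 = _set_parameter(physiology, pk, theta, v)
        return simulate(phys2, pk2, dose, horizon, method="expm", grid=grid)[output]

    hi = run(value + step)
    lo = run(value - step)
    diff = hi - lo
    scale = max(np.max(np.abs(hi)), np.max(np.abs(lo)))
    if scale > 0 and np.max(np.abs(diff)) < 1e-13 * scale:
        warnings.warn(
            f"difference for {theta} is at numerical noise level; consider a larger step",
            RuntimeWarning,
        )
    n = max(int(round(horizon / grid)), 1)
    times = np.linspace(0.0, horizon, n + 1)
    deriv = diff / (2.0 * step)
    integrated = float(trapezoid(deriv, times))
    if normalized:
        base = simulate(physiology, pk, dose, horizon, method="expm", grid=grid)[output]
        c_bar = float(trapezoid(base, times)) / horizon
        if c_bar == 0.0:
            return 0.0
        integrated *= value / c_bar
    return integrated


@dataclass
class SensitivityMatrix:
    """Outputs x parameters table of time-integrated sensitivities."""

    table: pd.DataFrame  # index: output compartments, columns: parameters
    horizon: float
    scheme: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="output")

    def __getitem__(self, key: tuple[str, str]) -> float:
        output, theta = key
        return float(self.table.loc[output, theta])


def sensitivity_matrix(
    physiology: Physiology,
    pk: PKParameters,
    dose: DoseEvent,
    parameters: tuple[str, ...] = DEFAULT_PK_PARAMETERS,
    outputs: tuple[str, ...] = ("bl", "lu", "li", "sp", "ht", "kd", "tu"),
    horizon: float = 3.0,
    *,
    rel_step: float = 0.01,
    normalized: bool = False,
    grid: float = 0.01,
) -> SensitivityMatrix:
    """Assemble the full OAT sensitivity matrix (deterministic)."""
    values = np.empty((len(outputs), len(parameters)))
    # one pair of perturbed simulations per parameter covers every output row
    n = max(int(round(horizon / grid)), 1)
    times = np.linspace(0.0, horizon, n + 1)
    base = None
    if normalized:
        base = simulate(physiology, pk, dose, horizon, method="expm", grid=grid)
    for j, theta in enumerate(parameters):
        value = _get_parameter(physiology, pk, theta)
        step = abs(value) * rel_step if value != 0 else rel_step
        phys_hi, pk_hi = _set_parameter(physiology, pk, theta, value + step)
        phys_lo, pk_lo = _set_parameter(physiology, pk, theta, value - step)
        hi = simulate(phys_hi, pk_hi, dose, horizon, method="expm", grid=grid)
        lo = simulate(phys_lo, pk_lo, dose, horizon, method="expm", grid=grid)
        for i, out in enumerate(outputs):
            deriv = (hi[out] - lo[out]) / (2.0 * step)
            s = float(trapezoid(deriv, times))
            if normalized:
                c_bar = float(trapezoid(base[out], times)) / horizon
                s = s * value / c_bar if c_bar != 0 else 0.0
            values[i, j] = s
    table = pd.DataFrame(values, index=list(outputs), columns=list(parameters))
    return SensitivityMatrix(
        table=table,
        horizon=horizon,
        scheme={"rel_step": rel_step, "normalized": normalized, "grid_h": grid,
                "difference": "central"},
    )


def rank_parameters(matrix: SensitivityMatrix, output: str) -> list[str]:
    """Parameters ordered by descending |integrated sensitivity| for one output.

    Ties are broken lexicographically by parameter name.
    """
    if output not in matrix.table.index:
        raise ConfigurationError(f"output {output!r} not present in the matrix")
    row = matrix.table.loc[output]
    return sorted(row.index, key=lambda p: (-abs(row[p]), p))
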