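"""Ground-truth-known synthetic datasets emulating the animal study.

The raw concentration-time and tumor-growth measurements behind the
source study were never published, so estimation is exercised against
synthetic data generated from the model at known ("planted") parameters:

- PK: the PBPK model is sampled at a sparse destructive-sampling schedule
  and perturbed with proportional-plus-additive Gaussian noise,
  ``y = C * (1 + eps_prop) + eps_add``, clipped at zero;
- PD: a cohort of animals with per-animal growth rates drawn from
  truncated normal distributions around the published cohort moments
  (truncation at zero is required — the published exponential-rate SD,
  0.56, exceeds its mean, 0.51) and multiplicative residual noise.

Both generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .parameters import DoseEvent, PDParameters, Physiology, PKParameters
from .pbpk import simulate
from .estimation import ObservedGrowthDataset, ObservedPKDataset
from .tumor import ConcFunc, simulate_tumor

#: Sparse sampling design typical of destructive tissue sampling.
DEFAULT_PK_TIMES = (0.083, 0.5, 1.0, 3.0, 6.0, 24.0, 48.0)
DEFAULT_PK_COMPARTMENTS = ("bl", "li", "sp", "ht", "lu", "kd", "tu")


@dataclass(frozen=True)
class PKDesign:
    """Sampling schedule and noise model for a synthetic PK study."""

    times: Sequence[float] = DEFAULT_PK_TIMES
    compartments: Sequence[str] = DEFAULT_PK_COMPARTMENTS
    replicates: int = 3
    cv: float = 0.10
    sd_additive: float = 0.01  # ug/mL floor noise
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if not (np.diff(t) > 0).all() or not (t > 0).all():
            raise ParameterError("sampling times must be positive and strictly increasing")
        if self.cv < 0 or self.sd_additive < 0:
            raise ParameterError("noise magnitudes must be non-negative")
        if self.replicates < 1:
            raise ParameterError("need at least one replicate per time point")


def generate_pk_dataset(
    truth: PKParameters,
    physiology: Physiology,
    dose: DoseEvent,
    design: PKDesign = PKDesign(),
) -> ObservedPKDataset:
    """Simulate at the planted truth and apply the measurement-noise model."""
    times = np.asarray(design.times, dtype=float)
    prof = simulate(physiology, truth, dose, float(times.max()), method="expm",
                    t_eval=np.concatenate([[0.0], times]))
    rng = np.random.default_rng(design.seed)
    rows = []
    for comp in design.compartments:
        clean = np.interp(times, prof.times, prof[comp])
        for _ in range(design.replicates):
            noisy = clean * (1.0 + rng.normal(0.0, design.cv, size=times.size))
            noisy = noisy + rng.normal(0.0, design.sd_additive, size=times.size)
            noisy = np.clip(noisy, 0.0, None)
            rows.append(pd.DataFrame({"compartment": comp, "time_h": times,
                                      "conc_ug_per_ml": noisy}))
    data = pd.concat(rows, ignore_index=True)
    return ObservedPKDataset(data=data, dose=dose, formulation=truth.formulation)


@dataclass(frozen=True)
class GrowthCohortDesign:
    """Cohort size, schedule, and variability of a synthetic growth study."""

    n_animals: int = 12
    days: Sequence[float] = tuple(float(d) for d in range(0, 24, 2))
    k_exp_mean: float = 0.51
    k_exp_sd: float = 0.56
    k_lin_mean: float = 0.17
    k_lin_sd: float = 0.11
    residual_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("cohort needs at least one animal")
        if min(self.k_exp_sd, self.k_lin_sd, self.residual_cv) < 0:
            raise ParameterError("variability parameters must be non-negative")


def _truncated_positive_normal(rng: np.random.Generator, mean: float, sd: float,
                               n: int) -> tuple[np.ndarray, int]:
    """Sample n strictly positive normal draws, resampling non-positive ones."""
    if sd == 0:
        if mean <= 0:
            raise ParameterError("degenerate distribution with non-positive mean")
        return np.full(n, mean), 0
    out = np.empty(n)
    rejected = 0
    for i in range(n):
        draw = rng.normal(mean, sd)
        while draw <= 0:
            rejected += 1
            draw = rng.normal(mean, sd)
        out[i] = draw
    return out, rejected


def generate_growth_cohort(
    design: GrowthCohortDesign,
    pd_base: PDParameters,
    conc: ConcFunc | None = None,
) -> tuple[list[ObservedGrowthDataset], dict]:
    """Per-animal trajectories at sampled growth rates, plus residual noise.

    Treatment parameters (``k_d``, ``tau``) and the initial weight come
    from ``pd_base``; if ``conc`` is given the animals are treated with
    that exposure. Returns the cohort and a provenance record (including
    the truncation-resample count).
    """
    rng = np.random.default_rng(design.seed)
    k_exp, rej_e = _truncated_positive_normal(rng, design.k_exp_mean, design.k_exp_sd,
                                              design.n_animals)
    k_lin, rej_l = _truncated_positive_normal(rng, design.k_lin_mean, design.k_lin_sd,
                                              design.n_animals)
    days = np.asarray(design.days, dtype=float)
    horizon = float(days.max()) if days.max() > 0 else 1.0
    cohort = []
    for i in range(design.n_animals):
        pd_i = pd_base.with_overrides(k_exp=float(k_exp[i]), k_lin=float(k_lin[i]), w_b=None)
        traj = simulate_tumor(pd_i, conc, horizon, grid=0.02)
        clean = np.interp(days, traj.times, traj.w)
        noisy = clean * (1.0 + rng.normal(0.0, design.residual_cv, size=days.size))
        noisy = np.maximum(noisy, 1e-6)  # weights must stay positive
        cohort.append(ObservedGrowthDataset(
            animal_id=f"animal_{i + 1:02d}", times=days, weights=noisy,
            treatment="control" if conc is None else "treated",
        ))
    provenance = {
        "seed": design.seed,
        "sampled_k_exp": k_exp.tolist(),
        "sampled_k_lin": k_lin.tolist(),
        "truncation_resamples": {"k_exp": rej_e, "k_lin": rej_l},
        "w0_g": pd_base.w0,
    }
    return cohort, provenance
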