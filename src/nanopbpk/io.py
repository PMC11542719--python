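"""Tabular I/O: tidy CSV artifacts with JSON provenance sidecars.

CSV dialect everywhere: comma-separated, UTF-8, header row, '.' decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .estimation import FitResult, ObservedGrowthDataset, ObservedPKDataset
from .parameters import DoseEvent
from .pbpk import ConcentrationProfile
from .tumor import TumorTrajectory


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".provenance.json")


def write_profile(profile: ConcentrationProfile, path, sidecar: bool = True) -> None:
    path = Path(path)
    profile.to_frame().to_csv(path, index=False)
    if sidecar:
        meta = {
            "physiology": profile.physiology.to_dict(),
            "pk": profile.pk.to_dict(),
            "dose_ug": profile.dose.amount,
            **profile.provenance,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_profile_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"time_h", "compartment", "concentration_ug_per_ml"}
    if not required <= set(frame.columns):
        raise ConfigurationError(f"profile CSV must have columns {sorted(required)}")
    return frame


def write_trajectory(traj: TumorTrajectory, path, sidecar: bool = True) -> None:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    if sidecar:
        _sidecar_path(path).write_text(json.dumps(traj.provenance, indent=2))


def write_pk_dataset(dataset: ObservedPKDataset, path) -> None:
    path = Path(path)
    dataset.data.to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps(
        {"dose_ug": dataset.dose.amount, "formulation": dataset.formulation}, indent=2))


def read_pk_dataset(path, dose_ug: float | None = None,
                    formulation: str = "") -> ObservedPKDataset:
    path = Path(path)
    data = pd.read_csv(path)
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        dose_ug = meta.get("dose_ug", dose_ug)
        formulation = meta.get("formulation", formulation)
    if dose_ug is None:
        raise ConfigurationError("dose_ug required (no provenance sidecar found)")
    return ObservedPKDataset(data=data, dose=DoseEvent(amount=float(dose_ug)),
                             formulation=formulation)


def write_growth_cohort(cohort: list[ObservedGrowthDataset], path) -> None:
    frames = [pd.DataFrame({"animal_id": ds.animal_id, "time_day": ds.times,
                            "weight_g": ds.weights, "treatment": ds.treatment})
              for ds in cohort]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def read_growth_cohort(path) -> list[ObservedGrowthDataset]:
    frame = pd.read_csv(path)
    required = {"animal_id", "time_day", "weight_g"}
    if not required <= set(frame.columns):
        raise ConfigurationError(f"growth CSV must have columns {sorted(required)}")
    cohort = []
    for animal, grp in frame.groupby("animal_id", sort=True):
        grp = grp.sort_values("time_day")
        cohort.append(ObservedGrowthDataset(
            animal_id=str(animal),
            times=grp["time_day"].to_numpy(dtype=float),
            weights=grp["weight_g"].to_numpy(dtype=float),
            treatment=str(grp["treatment"].iloc[0]) if "treatment" in grp else "control",
        ))
    return cohort


def write_fit_result(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))
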