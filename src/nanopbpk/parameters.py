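"""Typed parameter containers and the bundled species/formulation tables.

The whole-body model tracks eight compartments, addressed by two-letter
codes: ``bl`` blood, ``lu`` lung, ``li`` liver, ``sp`` spleen, ``ht`` heart,
``kd`` kidney, ``tu`` tumor, ``rm`` remainder (all lumped other tissue).
Flows are plasma flows in L/h, volumes in L. ``Q_li`` is the hepatic portal
vein flow and the hepatic artery flow is stored separately as ``Q_he``;
blood and lung flow both equal cardiac output.

Bundled presets (loaded by name through :func:`load_physiology`,
:func:`load_pk_parameters`, :func:`load_pd_parameters`) reproduce the
mouse and 70 kg human physiology tables and the fitted partition
coefficient / clearance sets of the three paclitaxel formulations
(``taxol``, ``ptx-nc``, ``f68-ptx-nc``) field for field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError, ParameterError

#: Canonical compartment order used for state vectors and tables.
COMPARTMENTS: tuple[str, ...] = ("bl", "lu", "li", "sp", "ht", "kd", "tu", "rm")

#: Compartments that carry a tissue:blood partition coefficient (all but blood).
TISSUES: tuple[str, ...] = ("lu", "li", "sp", "ht", "kd", "tu", "rm")

_BUNDLED_PHYSIOLOGY = {"mouse": "physiology_mouse.yaml", "human": "physiology_human.yaml"}
_BUNDLED_PK = {
    "taxol": "pk_taxol.yaml",
    "ptx-nc": "pk_ptx_nc.yaml",
    "f68-ptx-nc": "pk_f68_ptx_nc.yaml",
}


def _read_yaml(name_or_path: str | Path, bundled: Mapping[str, str]) -> dict:
    key = str(name_or_path)
    if key in bundled:
        text = resources.files("nanopbpk.data").joinpath(bundled[key]).read_text()
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ConfigurationError(
                f"{name_or_path!r} is neither a bundled preset "
                f"({', '.join(sorted(bundled))}) nor an existing file"
            )
        text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{name_or_path!r} did not parse to a mapping")
    return data


@dataclass(frozen=True)
class Physiology:
    """Species-specific plasma flows (L/h) and compartment volumes (L)."""

    species: str
    Q: Mapping[str, float]
    V: Mapping[str, float]
    Q_he: float

    def __post_init__(self) -> None:
        for comp in COMPARTMENTS:
            if comp not in self.Q:
                raise ParameterError(f"missing plasma flow for compartment {comp!r}")
            if comp not in self.V:
                raise ParameterError(f"missing volume for compartment {comp!r}")
        for comp in COMPARTMENTS:
            if not self.Q[comp] > 0:
                raise ParameterError(f"Q[{comp!r}] must be strictly positive, got {self.Q[comp]}")
            if not self.V[comp] > 0:
                raise ParameterError(f"V[{comp!r}] must be strictly positive, got {self.V[comp]}")
        if not self.Q_he > 0:
            raise ParameterError(f"Q_he must be strictly positive, got {self.Q_he}")
        if abs(self.Q["bl"] - self.Q["lu"]) > 1e-12 * self.Q["bl"]:
            raise ParameterError(
                "blood and lung flows must both equal cardiac output "
                f"(Q_bl={self.Q['bl']}, Q_lu={self.Q['lu']})"
            )
        object.__setattr__(self, "Q", dict(self.Q))
        object.__setattr__(self, "V", dict(self.V))

    @property
    def cardiac_output(self) -> float:
        return self.Q["bl"]

    @property
    def venous_return(self) -> float:
        """Total flow entering the lung: organ venous outflows plus hepatic paths.

        With the printed tables this does not equal cardiac output exactly
        (the literature flows were compiled independently); the model uses
        the printed values verbatim.
        """
        return self.Q_he + sum(self.Q[c] for c in ("li", "ht", "kd", "tu", "rm"))

    def with_overrides(self, *, Q: Mapping[str, float] | None = None,
                       V: Mapping[str, float] | None = None,
                       Q_he: float | None = None) -> "Physiology":
        newQ = {**self.Q, **(Q or {})}
        # cardiac output is a single quantity: overriding either of bl/lu
        # moves both unless the caller sets both explicitly
        if Q:
            if "bl" in Q and "lu" not in Q:
                newQ["lu"] = Q["bl"]
            elif "lu" in Q and "bl" not in Q:
                newQ["bl"] = Q["lu"]
        return Physiology(
            species=self.species,
            Q=newQ,
            V={**self.V, **(V or {})},
            Q_he=self.Q_he if Q_he is None else Q_he,
        )

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "Q_L_per_h": dict(self.Q),
            "Q_he_L_per_h": self.Q_he,
            "V_L": dict(self.V),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Physiology":
        try:
            return cls(
                species=data["species"],
                Q=dict(data["Q_L_per_h"]),
                V=dict(data["V_L"]),
                Q_he=float(data["Q_he_L_per_h"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"physiology table missing field {exc}") from exc


@dataclass(frozen=True)
class PKParameters:
    """Formulation-specific partition coefficients and hepatic clearance.

    ``K`` maps each non-blood compartment to its unitless tissue:blood
    partition coefficient. ``CL`` is the linear hepatic clearance in L/h,
    acting on the liver venous concentration ``C_li/K_li``. ``K_rm_assumed``
    records that the remainder partition was never reported and carries an
    assumed value.
    """

    formulation: str
    K: Mapping[str, float]
    CL: float
    K_rm_assumed: bool = False
    cv_percent: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for comp in TISSUES:
            if comp not in self.K:
                raise ParameterError(f"missing partition coefficient for {comp!r}")
            if not self.K[comp] > 0:
                raise ParameterError(f"K[{comp!r}] must be strictly positive, got {self.K[comp]}")
        if self.CL < 0:
            raise ParameterError(f"clearance must be non-negative, got {self.CL}")
        object.__setattr__(self, "K", dict(self.K))
        object.__setattr__(self, "cv_percent", dict(self.cv_percent))

    def with_overrides(self, *, K: Mapping[str, float] | None = None,
                       CL: float | None = None) -> "PKParameters":
        return replace(
            self,
            K={**self.K, **(K or {})},
            CL=self.CL if CL is None else CL,
            cv_percent={},
        )

    def to_dict(self) -> dict:
        out = {
            "formulation": self.formulation,
            "K": dict(self.K),
            "K_rm_assumed": self.K_rm_assumed,
            "CL_L_per_h": self.CL,
        }
        if self.cv_percent:
            out["cv_percent"] = dict(self.cv_percent)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "PKParameters":
        try:
            return cls(
                formulation=data["formulation"],
                K=dict(data["K"]),
                CL=float(data["CL_L_per_h"]),
                K_rm_assumed=bool(data.get("K_rm_assumed", False)),
                cv_percent=dict(data.get("cv_percent", {})),
            )
        except KeyError as exc:
            raise ConfigurationError(f"PK parameter table missing field {exc}") from exc


@dataclass(frozen=True)
class DoseEvent:
    """An intravenous bolus into the blood compartment.

    ``amount`` is the drug mass in micrograms, ``time`` in hours. Only a
    bolus at t=0 is supported by the simulator (it becomes the initial
    blood concentration).
    """

    amount: float
    time: float = 0.0
    route: str = "iv_bolus"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ParameterError(f"dose amount must be non-negative, got {self.amount}")
        if self.time < 0:
            raise ParameterError(f"dose time must be non-negative, got {self.time}")

    @classmethod
    def per_kg(cls, mg_per_kg: float, body_weight_g: float) -> "DoseEvent":
        """Dose scaled by body weight, e.g. 20 mg/kg for a 20 g mouse -> 400 ug."""
        return cls(amount=mg_per_kg * body_weight_g)


@dataclass(frozen=True)
class PDParameters:
    """Tumor growth/kill parameters for the transit-compartment PD model.

    The untreated tumor grows exponentially at rate ``k_exp`` (1/day) while
    its total weight is below the cutoff ``w_b`` (g) and linearly at
    ``k_lin`` (g/day) above it. Drug kill moves proliferating cells into
    two damage-transit stages traversed at rate ``tau`` (1/day); ``k_d``
    is the kill coefficient in mL/(ng*day) acting on the tumor drug
    concentration in ng/mL.

    The source study reports the two growth rates with swapped labels in
    different places; this container is positional — ``k_exp`` is always
    the exponential-phase rate and ``k_lin`` the linear-phase rate.
    """

    k_exp: float
    k_lin: float
    w0: float
    k_d: float = 0.0
    tau: float = 0.0
    w_b: float | None = None
    w_b_assumed: bool = True

    def __post_init__(self) -> None:
        for name in ("k_exp", "k_lin", "k_d", "tau"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not self.w0 > 0:
            raise ParameterError(f"w0 must be strictly positive, got {self.w0}")
        if self.w_b is not None and not self.w_b > 0:
            raise ParameterError(f"w_b must be strictly positive, got {self.w_b}")

    @property
    def switch_weight(self) -> float:
        """Effective growth-phase cutoff.

        Defaults to ``k_lin/k_exp``, the weight at which the exponential and
        linear growth inputs coincide, so the growth input is continuous.
        """
        if self.w_b is not None:
            return self.w_b
        if self.k_exp == 0:
            return float("inf")
        return self.k_lin / self.k_exp

    def with_overrides(self, **kwargs) -> "PDParameters":
        return replace(self, **kwargs)


def load_physiology(name_or_path: str | Path) -> Physiology:
    """Load a physiology table: bundled ``mouse``/``human`` or a YAML path."""
    return Physiology.from_dict(_read_yaml(name_or_path, _BUNDLED_PHYSIOLOGY))


def load_pk_parameters(name_or_path: str | Path) -> PKParameters:
    """Load a formulation table: bundled ``taxol``/``ptx-nc``/``f68-ptx-nc`` or a YAML path."""
    return PKParameters.from_dict(_read_yaml(name_or_path, _BUNDLED_PK))


def load_pd_parameters(formulation: str | None = None, species: str = "mouse",
                       path: str | Path | None = None) -> PDParameters:
    """Build a PD parameter set from the bundled defaults.

    With ``formulation=None`` the treatment terms are zero (control model).
    ``species`` selects the default initial tumor weight.
    """
    if path is not None:
        data = _read_yaml(path, {})
    else:
        data = yaml.safe_load(
            resources.files("nanopbpk.data").joinpath("pd_defaults.yaml").read_text()
        )
    growth = data["growth"]
    try:
        w0 = float(data["w0_g"][species])
    except KeyError as exc:
        raise ConfigurationError(f"no default initial tumor weight for species {species!r}") from exc
    k_d = tau = 0.0
    if formulation is not None:
        try:
            trt = data["treatment"][formulation]
        except KeyError as exc:
            raise ConfigurationError(f"no PD treatment preset for formulation {formulation!r}") from exc
        k_d = float(trt["k_d_ml_per_ng_day"])
        tau = float(trt["tau_per_day"])
    return PDParameters(
        k_exp=float(growth["k_exp_per_day"]),
        k_lin=float(growth["k_lin_g_per_day"]),
        w0=w0,
        k_d=k_d,
        tau=tau,
    )


def load_parameters(name_or_path: str | Path):
    """Load any bundled or on-disk parameter table, dispatching on content.

    Bundled names: ``mouse``, ``human`` (physiology); ``taxol``, ``ptx-nc``,
    ``f68-ptx-nc`` (PK). A YAML file is dispatched on its fields.
    """
    key = str(name_or_path)
    if key in _BUNDLED_PHYSIOLOGY:
        return load_physiology(key)
    if key in _BUNDLED_PK:
        return load_pk_parameters(key)
    data = _read_yaml(name_or_path, {})
    if "Q_L_per_h" in data:
        return Physiology.from_dict(data)
    if "K" in data:
        return PKParameters.from_dict(data)
    raise ConfigurationError(
        f"{name_or_path!r}: cannot tell physiology from PK parameters "
        "(expected a 'Q_L_per_h' or 'K' field)"
    )
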