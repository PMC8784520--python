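"""Model inputs: parameter registry, validation, and configuration I/O.

Every quantity the cost-effectiveness model consumes -- survival-function
shape parameters, hazard ratios, per-cycle discontinuation probabilities,
unit costs, utilities, disutilities, and patient characteristics -- is held
as a :class:`Parameter` with a point value, a deterministic-sensitivity
range, and a probabilistic-sensitivity distribution family.  A
:class:`ParameterSet` bundles the parameters for one histology
(non-squamous or squamous) together with the regimen definitions for the
two strategies being compared: pembrolizumab monotherapy (``pembro``) and
pembrolizumab plus platinum-doublet chemotherapy (``pembro_chemo``).

Two configuration files transcribing the published input table ship with
the package (``nonsquamous_table1.yaml`` and ``squamous_table1.yaml``) and
are loadable via :func:`load_bundled`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "ParameterError",
    "ValidationError",
    "MissingParameterError",
    "load_parameters",
    "load_bundled",
    "default_range",
    "ARMS",
]

#: Strategy labels used throughout the package.
ARMS = ("pembro_chemo", "pembro")

DIST_FAMILIES = {"lognormal", "beta", "gamma", "normal", "fixed"}
KINDS = {"probability", "utility", "cost", "hr", "other"}


class ParameterError(Exception):
    """Base class for configuration problems."""


class ValidationError(ParameterError):
    """A parameter value violates one of its invariants."""


class MissingParameterError(ParameterError):
    """The configuration omits parameters the model requires."""

    def __init__(self, missing: Iterable[str]):
        self.missing = sorted(missing)
        super().__init__(
            "configuration is missing required parameters: "
            + ", ".join(self.missing)
        )


def default_range(value: float) -> tuple[float, float]:
    """Plausible range for a parameter without a reported 95% CI.

    Sensitivity ranges default to +/-50% of the baseline value, the
    convention used when no interval estimate is available.
    """
    if not math.isfinite(value):
        raise ValidationError(f"cannot derive a range from non-finite value {value!r}")
    lo, hi = 0.5 * value, 1.5 * value
    return (min(lo, hi), max(lo, hi))


@dataclass(frozen=True)
class Parameter:
    """One model input with its DSA range and PSA distribution family.

    ``kind`` drives extra validation: probabilities and utilities must lie
    in [0, 1], costs must be non-negative, and hazard ratios positive.
    """

    name: str
    value: float
    low: float
    high: float
    dist_family: str = "fixed"
    kind: str = "other"

    def __post_init__(self):
        if self.dist_family not in DIST_FAMILIES:
            raise ValidationError(
                f"{self.name}: unknown distribution family {self.dist_family!r}"
            )
        if self.kind not in KINDS:
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if not (self.low <= self.value <= self.high):
            raise ValidationError(
                f"{self.name}: low <= value <= high violated "
                f"({self.low} <= {self.value} <= {self.high})"
            )
        if self.kind in ("probability", "utility"):
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValidationError(
                    f"{self.name}: {self.kind} out of [0,1] "
                    f"(range {self.low}-{self.high})"
                )
        if self.kind == "cost" and self.low < 0:
            raise ValidationError(f"{self.name}: cost must be >= 0")
        if self.kind == "hr" and self.low <= 0:
            raise ValidationError(f"{self.name}: hazard ratio must be > 0")

    @property
    def is_fixed(self) -> bool:
        return self.dist_family == "fixed" or self.low == self.high

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "low": self.low,
            "high": self.high,
            "dist": self.dist_family,
            "kind": self.kind,
        }


# Parameters every configuration must define, independent of histology.
# Regimen blocks may reference further (histology-specific) names, which
# are validated separately.
REQUIRED_PARAMETERS = [
    "theta_os",
    "kappa_os",
    "theta_pfs",
    "kappa_pfs",
    "hr_os",
    "hr_pfs",
    "price_pembrolizumab_mg",
    "price_carboplatin_mg",
    "price_cisplatin_mg",
    "infusion_first_hour",
    "infusion_additional_hour",
    "physician_visit",
    "imaging",
    "bsc_cost",
    "death_cost",
    "ae_cost_pembro",
    "ae_cost_pembro_chemo",
    "ae_duration_months",
    "subsequent_cost_pembro",
    "subsequent_cost_pembro_chemo",
    "subsequent_uptake",
    "u_ge12",
    "u_6_12",
    "u_1_6",
    "u_le1",
    "disutility_pembro",
    "disutility_pembro_chemo",
    "bsa",
    "crcl",
    "discount_rate",
    "fatal_ae_pembro",
    "fatal_ae_pembro_chemo",
    "start_age",
]

# Histology-specific drug prices that regimens rely on.
HISTOLOGY_REQUIRED = {
    "non_squamous": ["price_pemetrexed_mg"],
    "squamous": ["price_paclitaxel_mg", "price_nab_paclitaxel_mg"],
}


@dataclass
class ParameterSet:
    """All inputs for one histology, plus the two regimen definitions."""

    histology: str
    parameters: dict[str, Parameter]
    regimens: dict[str, "Regimen"] = field(default_factory=dict)

    def __post_init__(self):
        if self.histology not in ("non_squamous", "squamous"):
            raise ValidationError(f"unknown histology {self.histology!r}")

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self.parameters[name]
        except KeyError:
            raise MissingParameterError([name]) from None

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def value(self, name: str) -> float:
        return self[name].value

    def values(self) -> dict[str, float]:
        return {k: p.value for k, p in self.parameters.items()}

    def varied(self) -> list[Parameter]:
        """Parameters with a genuine range, in declaration order."""
        return [p for p in self.parameters.values() if not p.is_fixed]

    def validate(self) -> None:
        missing = [n for n in REQUIRED_PARAMETERS if n not in self.parameters]
        missing += [
            n
            for n in HISTOLOGY_REQUIRED.get(self.histology, [])
            if n not in self.parameters
        ]
        if missing:
            raise MissingParameterError(missing)
        if set(self.regimens) != set(ARMS):
            raise ValidationError(
                f"exactly one regimen per arm required; got {sorted(self.regimens)}"
            )
        for reg in self.regimens.values():
            for drug in reg.drugs:
                for ref in (drug.price_param, drug.discontinuation_param):
                    if ref not in self.parameters:
                        raise MissingParameterError([ref])

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "histology": self.histology,
            "parameters": {k: p.to_dict() for k, p in self.parameters.items()},
            "regimens": {k: r.to_dict() for k, r in self.regimens.items()},
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ParameterSet":
        from .costing import Regimen  # local import to avoid a cycle

        params: dict[str, Parameter] = {}
        for name, spec in (raw.get("parameters") or {}).items():
            if not isinstance(spec, Mapping):
                spec = {"value": float(spec)}
            value = float(spec["value"])
            if "low" in spec or "high" in spec:
                low = float(spec.get("low", value))
                high = float(spec.get("high", value))
            else:
                low = high = value
            params[name] = Parameter(
                name=name,
                value=value,
                low=low,
                high=high,
                dist_family=spec.get("dist", "fixed"),
                kind=spec.get("kind", "other"),
            )
        regimens = {
            arm: Regimen.from_dict(arm, spec)
            for arm, spec in (raw.get("regimens") or {}).items()
        }
        ps = cls(
            histology=raw.get("histology", "non_squamous"),
            parameters=params,
            regimens=regimens,
        )
        ps.validate()
        return ps


def load_parameters(path: str | Path) -> ParameterSet:
    """Read and validate a configuration file.

    Raises :class:`MissingParameterError` naming every absent required
    parameter, or :class:`ValidationError` naming the violated invariant.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ParameterError(f"configuration file {path} did not parse to a mapping")
    return ParameterSet.from_dict(raw)


def load_bundled(histology: str) -> ParameterSet:
    """Load one of the two configuration files shipped with the package."""
    name = {
        "non_squamous": "nonsquamous_table1.yaml",
        "squamous": "squamous_table1.yaml",
    }.get(histology)
    if name is None:
        raise ParameterError(f"unknown histology {histology!r}")
    with resources.as_file(resources.files("pembrocea.data") / name) as p:
        return load_parameters(p)
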