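"""Drug dosing, vial rounding, per-cycle regimen costs, and AE burden.

Doses follow standard oncology rules: flat milligrams (pembrolizumab),
milligrams per square metre of body surface area (pemetrexed,
paclitaxel), or a target AUC converted through the Calvert formula
(carboplatin).  Billed quantity is rounded up to the cheapest achievable
combination of single-use vials, charging the payer for wastage.  A
one-month model cycle accrues 30.44/21 administrations of a
three-weekly regimen as a continuous rate.

Infusion fees are billed per administration visit: the first hour at the
base rate and each additional (started) hour at the add-on rate, with
co-administered drugs sharing a single visit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DrugSpec",
    "Regimen",
    "AdverseEvent",
    "AEProfile",
    "carboplatin_dose",
    "bsa_dose",
    "round_to_vials",
    "required_dose_mg",
    "billed_dose_mg",
    "cycle_drug_cost",
    "visit_infusion_fee",
    "ae_burden",
    "DAYS_PER_MONTH",
]

#: Average month length used to convert q3w schedules to monthly cycles.
DAYS_PER_MONTH = 30.44

DOSE_TYPES = {"flat", "per_m2", "auc"}


def carboplatin_dose(target_auc: float, crcl: float) -> float:
    """Calvert formula: dose (mg) = AUC x (CrCl + 25)."""
    if not (target_auc > 0 and crcl > 0):
        raise ValueError("target AUC and creatinine clearance must be positive")
    return target_auc * (crcl + 25.0)


def bsa_dose(per_m2: float, bsa: float) -> float:
    """Body-surface-area dosing, unrounded milligrams."""
    if not (per_m2 > 0 and bsa > 0):
        raise ValueError("dose per m2 and BSA must be positive")
    return per_m2 * bsa


def round_to_vials(
    required: float, vials: Iterable[float]
) -> tuple[dict[float, int], float]:
    """Cheapest-wastage combination of single-use vials covering a dose.

    Minimizes billed milligrams subject to ``billed >= required``; ties are
    broken by the smaller vial count.  Returns ``(counts per vial size,
    billed mg)``.
    """
    sizes = sorted(set(float(v) for v in vials))
    if not sizes:
        raise ValueError("vial set is empty")
    if any(v <= 0 for v in sizes):
        raise ValueError("vial sizes must be positive")
    if required <= 0:
        return ({}, 0.0)

    # dynamic programme over integer-milligram totals (vials are marketed
    # in whole milligrams): min vial count to hit each achievable total
    need = int(math.ceil(required))
    cap = need + int(max(sizes))
    best = [math.inf] * (cap + 1)
    choice: list[float] = [0.0] * (cap + 1)
    best[0] = 0
    for total in range(1, cap + 1):
        for v in sizes:
            prev = total - int(v)
            if prev >= 0 and best[prev] + 1 < best[total]:
                best[total] = best[prev] + 1
                choice[total] = v
    total = next(t for t in range(need, cap + 1) if best[t] < math.inf)
    counts: dict[float, int] = {}
    t = total
    while t > 0:
        v = choice[t]
        counts[v] = counts.get(v, 0) + 1
        t -= int(v)
    return counts, float(total)


@dataclass(frozen=True)
class DrugSpec:
    """One drug inside a regimen.

    ``max_administrations`` of ``None`` means treatment continues until
    progression (e.g. pemetrexed maintenance); pembrolizumab caps at 35
    three-weekly administrations (two years).
    """

    name: str
    dose_type: str
    dose_value: float
    interval_days: float
    infusion_hours: float
    vial_sizes_mg: tuple[float, ...]
    price_param: str
    discontinuation_param: str
    max_administrations: Optional[float] = None

    def __post_init__(self):
        if self.dose_type not in DOSE_TYPES:
            raise ValueError(f"{self.name}: unknown dose type {self.dose_type!r}")
        if self.dose_value <= 0 or self.interval_days <= 0:
            raise ValueError(f"{self.name}: dose and schedule interval must be positive")
        if self.max_administrations is not None and self.max_administrations <= 0:
            raise ValueError(f"{self.name}: max administrations must be positive")

    @property
    def administrations_per_cycle(self) -> float:
        return DAYS_PER_MONTH / self.interval_days

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "dose": {"type": self.dose_type, "value": self.dose_value},
            "interval_days": self.interval_days,
            "infusion_hours": self.infusion_hours,
            "vial_sizes_mg": list(self.vial_sizes_mg),
            "price_param": self.price_param,
            "discontinuation_param": self.discontinuation_param,
        }
        if self.max_administrations is not None:
            d["max_administrations"] = self.max_administrations
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "DrugSpec":
        dose = raw["dose"]
        return cls(
            name=raw["name"],
            dose_type=dose["type"],
            dose_value=float(dose["value"]),
            interval_days=float(raw["interval_days"]),
            infusion_hours=float(raw["infusion_hours"]),
            vial_sizes_mg=tuple(float(v) for v in raw["vial_sizes_mg"]),
            price_param=raw["price_param"],
            discontinuation_param=raw["discontinuation_param"],
            max_administrations=(
                float(raw["max_administrations"])
                if raw.get("max_administrations") is not None
                else None
            ),
        )


@dataclass(frozen=True)
class Regimen:
    name: str
    drugs: tuple[DrugSpec, ...]

    def to_dict(self) -> dict:
        return {"drugs": [d.to_dict() for d in self.drugs]}

    @classmethod
    def from_dict(cls, name: str, raw: Mapping) -> "Regimen":
        return cls(name=name, drugs=tuple(DrugSpec.from_dict(d) for d in raw["drugs"]))


def required_dose_mg(drug: DrugSpec, bsa: float, crcl: float) -> float:
    """Milligrams per administration before vial rounding."""
    if drug.dose_type == "flat":
        return drug.dose_value
    if drug.dose_type == "per_m2":
        return bsa_dose(drug.dose_value, bsa)
    return carboplatin_dose(drug.dose_value, crcl)


def billed_dose_mg(drug: DrugSpec, bsa: float, crcl: float) -> float:
    """Vial-rounded milligrams billed per administration."""
    _, billed = round_to_vials(required_dose_mg(drug, bsa, crcl), drug.vial_sizes_mg)
    return billed


def _administrations_in_cycle(drug: DrugSpec, cycle_index: int) -> float:
    """Expected administrations during one monthly cycle, honouring the cap."""
    rate = drug.administrations_per_cycle
    if drug.max_administrations is None:
        return rate
    done = cycle_index * rate
    return min(rate, max(0.0, drug.max_administrations - done))


def visit_infusion_fee(
    hours: float, first_hour_fee: float, additional_hour_fee: float
) -> float:
    """Fee for one administration visit of ``hours`` total infusion time.

    The first hour (or any part of it) bills at the base rate; each further
    started hour adds the additional-hour rate.
    """
    if hours <= 0:
        return 0.0
    extra = max(0, math.ceil(hours) - 1)
    return first_hour_fee + additional_hour_fee * extra


def cycle_drug_cost(
    regimen: Regimen,
    cycle_index: int,
    on_drug_fractions: Mapping[str, float],
    prices: Mapping[str, float],
    bsa: float,
    crcl: float,
    first_hour_fee: float,
    additional_hour_fee: float,
) -> float:
    """Drug acquisition plus administration cost for one monthly cycle.

    ``on_drug_fractions`` gives, per drug, the cohort fraction still
    receiving it this cycle (progression-free and not yet discontinued).
    Drugs past their maximum administrations contribute nothing.  Drugs
    sharing the visit pool their infusion hours into a single fee whose
    attendance follows the longest-persisting active drug.
    """
    total = 0.0
    visit_hours = 0.0
    visit_rate = 0.0
    visit_fraction = 0.0
    for drug in regimen.drugs:
        frac = float(on_drug_fractions.get(drug.name, 0.0))
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{drug.name}: on-drug fraction {frac} outside [0,1]")
        admins = _administrations_in_cycle(drug, cycle_index)
        if admins <= 0:
            continue
        billed = billed_dose_mg(drug, bsa, crcl)
        total += billed * prices[drug.price_param] * frac * admins
        visit_hours += drug.infusion_hours
        visit_rate = max(visit_rate, admins)
        visit_fraction = max(visit_fraction, frac)
    if visit_hours > 0:
        fee = visit_infusion_fee(visit_hours, first_hour_fee, additional_hour_fee)
        total += fee * visit_rate * visit_fraction
    return total


# ---------------------------------------------------------------------------
# Adverse events


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    incidence: float
    unit_cost: float
    disutility: float
    duration_months: float

    def __post_init__(self):
        if not (0.0 <= self.incidence <= 1.0):
            raise ValueError(f"{self.name}: incidence outside [0,1]")
        if self.unit_cost < 0 or self.disutility < 0 or self.duration_months < 0:
            raise ValueError(f"{self.name}: costs, disutility, duration must be >= 0")


@dataclass(frozen=True)
class AEProfile:
    """Grade >=3 adverse events with incidence of at least 1%."""

    events: tuple[AdverseEvent, ...]

    @classmethod
    def from_events(cls, events: Sequence[AdverseEvent]) -> "AEProfile":
        """Keep only events meeting the inclusion rule (incidence >= 1%)."""
        return cls(tuple(e for e in events if e.incidence >= 0.01))


def ae_burden(profile: AEProfile) -> tuple[float, float]:
    """Frequency-weighted one-off AE cost and QALY decrement.

    cost = sum(incidence * unit cost); QALY decrement = sum(incidence *
    disutility * duration in months) / 12.
    """
    cost = sum(e.incidence * e.unit_cost for e in profile.events)
    qaly = sum(e.incidence * e.disutility * e.duration_months for e in profile.events) / 12.0
    return cost, qaly
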