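"""High-level model: one call from a parameter set to an ICER.

:class:`CostEffectivenessModel` wires the pieces together for one
histology and one survival-extrapolation mode:

``scenario1``
    pure parametric projection of the trial log-logistic curves over the
    whole 20-year horizon;
``base``
    parametric projection for the first five years, registry
    conditional-survival splice afterwards (applied to overall survival);
``scenario2``
    death driven by age-matched background mortality plus a one-off
    fatal-AE excess, progression still trial-based.

``run`` evaluates both strategies and the incremental comparison; an
``overrides`` mapping re-evaluates the model at alternative parameter
values without mutating the parameter set, which is what the sensitivity
analyses use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .costing import (
    Regimen,
    billed_dose_mg,
    visit_infusion_fee,
    _administrations_in_cycle,
)
from .markov import (
    AccrualInputs,
    CohortTrace,
    IcerResult,
    StrategyResult,
    TimeToDeathUtilities,
    accrue,
    build_trace,
    icer,
)
from .parameters import ARMS, ParameterSet
from .survival import (
    ConditionalSurvivalTable,
    LifeTable,
    LogLogisticParams,
    SurvivalCurve,
    apply_hazard_ratio,
    background_mortality_curve,
    loglogistic_curve,
    splice_with_registry,
)

__all__ = ["CostEffectivenessModel", "Comparison", "MODES"]

MODES = ("base", "scenario1", "scenario2")

#: Imaging accrues every third monthly cycle (quarterly).
IMAGING_INTERVAL = 3
SPLICE_MONTHS = 60.0


@dataclass
class Comparison:
    """Both arms plus their incremental comparison."""

    combination: StrategyResult
    monotherapy: StrategyResult
    incremental: IcerResult

    def by_arm(self) -> dict[str, StrategyResult]:
        return {"pembro_chemo": self.combination, "pembro": self.monotherapy}


class CostEffectivenessModel:
    def __init__(
        self,
        params: ParameterSet,
        mode: str = "base",
        registry: Optional[ConditionalSurvivalTable] = None,
        life_table: Optional[LifeTable] = None,
        horizon: int = 240,
        half_cycle: bool = False,
    ):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        if mode == "base" and registry is None:
            from .synthetic import default_registry_table

            registry = default_registry_table()
        if mode == "scenario2" and life_table is None:
            from .synthetic import default_life_table

            life_table = default_life_table()
        params.validate()
        self.params = params
        self.mode = mode
        self.registry = registry
        self.life_table = life_table
        self.horizon = horizon
        self.half_cycle = half_cycle

    # ---- survival -----------------------------------------------------

    def arm_curves(
        self, arm: str, v: Mapping[str, float]
    ) -> tuple[SurvivalCurve, SurvivalCurve]:
        """(OS, PFS) curves for an arm under parameter values ``v``."""
        os_par = loglogistic_curve(LogLogisticParams(v["theta_os"], v["kappa_os"]))
        pfs_par = loglogistic_curve(LogLogisticParams(v["theta_pfs"], v["kappa_pfs"]))
        if arm == "pembro":
            os_par = apply_hazard_ratio(os_par, v["hr_os"])
            pfs_par = apply_hazard_ratio(pfs_par, v["hr_pfs"])
        if self.mode == "scenario1":
            os_curve = os_par
        elif self.mode == "base":
            os_curve = splice_with_registry(os_par, self.registry, SPLICE_MONTHS)
        else:  # scenario2
            os_curve = background_mortality_curve(
                self.life_table,
                start_age=v["start_age"],
                fatal_ae_prob=v[f"fatal_ae_{arm}"],
                horizon=self.horizon,
            )
        return os_curve, pfs_par

    # ---- costing ------------------------------------------------------

    def _drug_cost_array(
        self, regimen: Regimen, trace: CohortTrace, v: Mapping[str, float]
    ) -> np.ndarray:
        """Cohort drug acquisition + infusion fees per cycle, vectorized."""
        t = trace.t
        n = len(t)
        total = np.zeros(n)
        visit_hours = np.zeros(n)
        visit_rate = np.zeros(n)
        visit_occ = np.zeros(n)
        for drug in regimen.drugs:
            billed = billed_dose_mg(drug, v["bsa"], v["crcl"])
            admins = np.array(
                [_administrations_in_cycle(drug, int(c)) for c in range(n)]
            )
            occ = trace.on_drug[drug.name]
            total += billed * v[drug.price_param] * occ * admins
            active = admins > 0
            visit_hours += np.where(active, drug.infusion_hours, 0.0)
            visit_rate = np.maximum(visit_rate, admins)
            visit_occ = np.maximum(visit_occ, np.where(active, occ, 0.0))
        fees = np.array(
            [
                visit_infusion_fee(h, v["infusion_first_hour"], v["infusion_additional_hour"])
                for h in visit_hours
            ]
        )
        total += fees * visit_rate * visit_occ
        return total

    # ---- evaluation ---------------------------------------------------

    def run_arm(self, arm: str, overrides: Optional[Mapping[str, float]] = None) -> StrategyResult:
        if arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        v = self.params.values()
        if overrides:
            v.update(overrides)
        os_curve, pfs_curve = self.arm_curves(arm, v)
        regimen = self.params.regimens[arm]
        disc_probs = {d.name: v[d.discontinuation_param] for d in regimen.drugs}
        trace = build_trace(os_curve, pfs_curve, disc_probs, self.horizon)
        inputs = AccrualInputs(
            drug_admin_cost=self._drug_cost_array(regimen, trace, v),
            visit_cost=v["physician_visit"],
            imaging_cost=v["imaging"],
            imaging_interval=IMAGING_INTERVAL,
            bsc_cost=v["bsc_cost"],
            subsequent_cost=v[f"subsequent_cost_{arm}"],
            subsequent_uptake=v["subsequent_uptake"],
            death_cost=v["death_cost"],
            ae_cost=v[f"ae_cost_{arm}"],
            ae_qaly_decrement=v[f"disutility_{arm}"] * v["ae_duration_months"] / 12.0,
        )
        utilities = TimeToDeathUtilities(
            u_le1=v["u_le1"], u_1_6=v["u_1_6"], u_6_12=v["u_6_12"], u_ge12=v["u_ge12"]
        )
        return accrue(
            trace,
            inputs,
            utilities,
            os_curve,
            discount_rate=v["discount_rate"],
            half_cycle=self.half_cycle,
        )

    def run(self, overrides: Optional[Mapping[str, float]] = None) -> Comparison:
        combo = self.run_arm("pembro_chemo", overrides)
        mono = self.run_arm("pembro", overrides)
        return Comparison(combo, mono, icer(combo, mono))
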