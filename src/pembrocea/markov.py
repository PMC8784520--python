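"""Cohort engine: state occupancy, utility accrual, discounting, ICER.

The model tracks four health states over monthly cycles: progression-free
on first-line therapy, progression-free after discontinuing first-line
therapy, progressive disease, and death.  Occupancy follows the
partitioned-survival construction -- the progression-free states together
occupy S_PFS(t), death occupies 1 - S_OS(t), and progressive disease the
difference -- which is the only arithmetic consistent with driving the
model directly from OS and PFS curves.

Quality of life uses a time-to-death weighting: a patient alive at t is
assigned the expected utility over the four windows (<=1, 1-6, 6-12 and
>=12 months before death), with window probabilities read off the arm's
own OS curve.  Costs and QALYs discount at an annual rate converted
continuously per month.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .survival import SurvivalCurve

__all__ = [
    "CohortTrace",
    "StrategyResult",
    "IcerResult",
    "TimeToDeathUtilities",
    "build_trace",
    "time_to_death_utility",
    "accrue",
    "icer",
    "AccrualInputs",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeToDeathUtilities:
    """Utility by proximity to death, in months."""

    u_le1: float
    u_1_6: float
    u_6_12: float
    u_ge12: float

    def __post_init__(self):
        for u in (self.u_le1, self.u_1_6, self.u_6_12, self.u_ge12):
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utility {u} outside [0,1]")


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and treatment exposure for one arm."""

    t: np.ndarray  # cycle-start times, months
    pfs_on: np.ndarray
    pfs_off: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    on_drug: dict[str, np.ndarray]  # cohort fraction on each drug
    new_progressions: np.ndarray
    new_deaths: np.ndarray

    @property
    def pfs(self) -> np.ndarray:
        return self.pfs_on + self.pfs_off

    @property
    def alive(self) -> np.ndarray:
        return self.pfs_on + self.pfs_off + self.pd

    def to_frame(self):
        """Occupancy trace as a DataFrame (one row per cycle)."""
        import pandas as pd

        cols = {
            "cycle_month": self.t,
            "pfs_on_treatment": self.pfs_on,
            "pfs_off_treatment": self.pfs_off,
            "progressive_disease": self.pd,
            "dead": self.dead,
            "new_progressions": self.new_progressions,
            "new_deaths": self.new_deaths,
        }
        for name, occ in self.on_drug.items():
            cols[f"on_{name}"] = occ
        return pd.DataFrame(cols)

    def check(self, atol: float = 1e-10) -> None:
        occ = self.pfs_on + self.pfs_off + self.pd + self.dead
        if not np.allclose(occ, 1.0, atol=atol):
            raise AssertionError("state occupancies do not sum to 1")
        if np.any(np.diff(self.dead) < -atol):
            raise AssertionError("dead occupancy is not monotone")


def build_trace(
    os_curve: SurvivalCurve,
    pfs_curve: SurvivalCurve,
    disc_probs: Mapping[str, float],
    horizon: int = 240,
) -> CohortTrace:
    """Partition OS and PFS curves into the four-state occupancy trace.

    ``disc_probs`` maps drug name to its per-cycle probability of
    discontinuation for toxicity; the on-treatment progression-free
    sub-state decays by the combined probability, and each drug's exposure
    by its own.  If the PFS curve crosses above OS the progressive-disease
    occupancy is clipped at zero (with a warning).
    """
    for name, p in disc_probs.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}: discontinuation probability outside [0,1]")
    t = np.arange(horizon, dtype=float)
    s_os = np.asarray(os_curve(t))
    s_pfs_raw = np.asarray(pfs_curve(t))
    if np.any(s_pfs_raw > s_os + 1e-12):
        log.warning("PFS curve exceeds OS at some cycles; clipping PD occupancy to 0")
    s_pfs = np.minimum(s_pfs_raw, s_os)

    combined_stay = np.prod([1.0 - p for p in disc_probs.values()]) if disc_probs else 1.0
    on_frac = np.power(combined_stay, t)
    pfs_on = s_pfs * on_frac
    pfs_off = s_pfs - pfs_on
    pd = np.maximum(s_os - s_pfs, 0.0)
    dead = 1.0 - s_os

    on_drug = {
        name: s_pfs * np.power(1.0 - p, t) for name, p in disc_probs.items()
    }

    new_deaths = np.diff(np.concatenate([[0.0], dead]))
    pfs_prev = np.concatenate([[1.0], s_pfs[:-1]])
    pd_prev = np.concatenate([[0.0], pd[:-1]])
    alive_prev = pfs_prev + pd_prev
    # deaths allocated to PFS/PD proportionally to prior occupancy; the
    # remaining PFS outflow is progression
    share = np.divide(pfs_prev, alive_prev, out=np.zeros_like(pfs_prev), where=alive_prev > 0)
    deaths_from_pfs = new_deaths * share
    new_progressions = np.maximum(0.0, pfs_prev - s_pfs - deaths_from_pfs)

    return CohortTrace(
        t=t,
        pfs_on=pfs_on,
        pfs_off=pfs_off,
        pd=pd,
        dead=dead,
        on_drug=on_drug,
        new_progressions=new_progressions,
        new_deaths=new_deaths,
    )


def time_to_death_utility(
    os_curve: SurvivalCurve, t: float, u: TimeToDeathUtilities
) -> float:
    """Expected utility of a patient alive at ``t`` months.

    Weights each utility window by the conditional probability of dying in
    it: P(death in (t+a, t+b] | alive at t) = (S(t+a) - S(t+b)) / S(t),
    and survives-past-12-months carries S(t+12)/S(t).
    """
    s0 = os_curve(t)
    if s0 <= 0:
        raise ZeroDivisionError(f"S({t}) = 0: utility undefined with no survivors")
    s1, s6, s12 = os_curve(t + 1.0), os_curve(t + 6.0), os_curve(t + 12.0)
    return (
        u.u_le1 * (s0 - s1) + u.u_1_6 * (s1 - s6) + u.u_6_12 * (s6 - s12) + u.u_ge12 * s12
    ) / s0


def _utility_profile(
    os_curve: SurvivalCurve, t: np.ndarray, u: TimeToDeathUtilities
) -> np.ndarray:
    s0 = np.asarray(os_curve(t))
    s1 = np.asarray(os_curve(t + 1.0))
    s6 = np.asarray(os_curve(t + 6.0))
    s12 = np.asarray(os_curve(t + 12.0))
    num = u.u_le1 * (s0 - s1) + u.u_1_6 * (s1 - s6) + u.u_6_12 * (s6 - s12) + u.u_ge12 * s12
    return np.divide(num, s0, out=np.zeros_like(num), where=s0 > 0)


@dataclass
class AccrualInputs:
    """Everything :func:`accrue` needs beyond the trace itself.

    ``drug_admin_cost`` is the pre-computed per-cycle drug acquisition plus
    infusion-fee cost for the whole cohort (already weighted by on-drug
    occupancy).  One-off quantities apply at model entry (AE burden), at
    each new progression (subsequent therapy for the uptake fraction, a
    best-supportive-care package for the rest), and at each new death
    (terminal care).
    """

    drug_admin_cost: np.ndarray
    visit_cost: float
    imaging_cost: float
    imaging_interval: int
    bsc_cost: float
    subsequent_cost: float
    subsequent_uptake: float
    death_cost: float
    ae_cost: float
    ae_qaly_decrement: float


@dataclass
class StrategyResult:
    """Discounted (and undiscounted) totals for one strategy."""

    cost: float
    qalys: float
    life_years: float
    qalys_pfs: float
    qalys_pd: float
    cost_undiscounted: float
    qalys_undiscounted: float
    life_years_undiscounted: float
    breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.cost < 0 or self.life_years < 0:
            raise ValueError("cost and life-years must be non-negative")


@dataclass(frozen=True)
class IcerResult:
    """Incremental comparison of strategy ``a`` against reference ``b``."""

    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    flag: Optional[str] = None  # 'dominated', 'dominant', 'equal_effect'

    @property
    def label(self) -> str:
        if self.flag == "dominated":
            return "Dominated"
        if self.flag == "dominant":
            return "Dominant"
        if self.flag == "equal_effect":
            return "Higher cost, equal effect"
        return f"{self.icer:,.0f}"


def accrue(
    trace: CohortTrace,
    inputs: AccrualInputs,
    utilities: TimeToDeathUtilities,
    os_curve: SurvivalCurve,
    discount_rate: float,
    half_cycle: bool = False,
) -> StrategyResult:
    """Sum discounted costs and QALYs over the trace.

    Routine follow-up (a monthly physician visit plus imaging every
    ``imaging_interval`` cycles) accrues for progression-free patients;
    progressed patients' care is captured by the subsequent-therapy /
    best-supportive-care packages at progression and the terminal-care
    cost at death.  With ``half_cycle`` the continuous state occupancies
    are averaged between cycle start and end.
    """
    t = trace.t
    disc = np.power(1.0 + discount_rate, -t / 12.0)
    uttd = _utility_profile(os_curve, t, utilities)

    pfs, pd_occ, alive = trace.pfs, trace.pd, trace.alive
    if half_cycle:
        nxt = lambda a: 0.5 * (a + np.concatenate([a[1:], a[-1:]]))
        pfs, pd_occ, alive = nxt(pfs), nxt(pd_occ), nxt(alive)

    imaging = np.where(t.astype(int) % inputs.imaging_interval == 0, inputs.imaging_cost, 0.0)
    followup = (inputs.visit_cost + imaging) * pfs
    one_off_prog = trace.new_progressions * (
        inputs.subsequent_uptake * inputs.subsequent_cost
        + (1.0 - inputs.subsequent_uptake) * inputs.bsc_cost
    )
    one_off_death = trace.new_deaths * inputs.death_cost

    cycle_cost = inputs.drug_admin_cost + followup + one_off_prog + one_off_death
    cost = float(np.sum(cycle_cost * disc)) + inputs.ae_cost
    cost_undisc = float(np.sum(cycle_cost)) + inputs.ae_cost

    q_pfs = pfs * uttd / 12.0
    q_pd = pd_occ * uttd / 12.0
    qalys = float(np.sum((q_pfs + q_pd) * disc)) - inputs.ae_qaly_decrement
    qalys_undisc = float(np.sum(q_pfs + q_pd)) - inputs.ae_qaly_decrement
    ly = float(np.sum(alive / 12.0 * disc))
    ly_undisc = float(np.sum(alive / 12.0))

    breakdown = {
        "drug_and_administration": float(np.sum(inputs.drug_admin_cost * disc)),
        "followup": float(np.sum(followup * disc)),
        "progression_one_offs": float(np.sum(one_off_prog * disc)),
        "terminal_care": float(np.sum(one_off_death * disc)),
        "adverse_events": inputs.ae_cost,
    }
    return StrategyResult(
        cost=cost,
        qalys=qalys,
        life_years=ly,
        qalys_pfs=float(np.sum(q_pfs * disc)),
        qalys_pd=float(np.sum(q_pd * disc)),
        cost_undiscounted=cost_undisc,
        qalys_undiscounted=qalys_undisc,
        life_years_undiscounted=ly_undisc,
        breakdown=breakdown,
    )


def icer(a: StrategyResult, b: StrategyResult, tol: float = 1e-9) -> IcerResult:
    """ICER of strategy ``a`` versus reference ``b``.

    Returns a dominance flag instead of a ratio when the signs of the
    increments make the ratio meaningless: ``dominated`` (more cost, fewer
    QALYs), ``dominant`` (less cost, more QALYs), or ``equal_effect``.
    """
    dc = a.cost - b.cost
    dq = a.qalys - b.qalys
    if abs(dq) < tol:
        flag = "equal_effect" if dc > 0 else ("dominant" if dc < 0 else None)
        return IcerResult(dc, dq, None if flag else 0.0, flag)
    if dq > 0 and dc <= 0:
        return IcerResult(dc, dq, None, "dominant")
    if dq < 0 and dc >= 0:
        return IcerResult(dc, dq, None, "dominated")
    return IcerResult(dc, dq, dc / dq, None)
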