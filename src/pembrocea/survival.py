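"""Survival curves and the transformations the cohort model applies to them.

The combination arm's overall and progression-free survival are
two-parameter log-logistic curves, ``S(t) = 1 / (1 + theta * t**kappa)``
with ``t`` in months, fitted to reconstructed trial data.  The monotherapy
arm is obtained by applying an indirectly-estimated hazard ratio on the
cumulative-hazard scale (``S**HR``).  Three long-term extrapolation
strategies are supported:

* pure parametric projection over the whole horizon;
* a registry splice -- parametric for the first five years, then annual
  conditional-survival probabilities from a cancer-registry-style table;
* background mortality -- an age-matched life table combined with a
  one-off excess probability for fatal treatment-related adverse events.

All curves satisfy ``S(0) = 1``, are non-increasing, and evaluate
vectorized over numpy arrays of month values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LogLogisticParams",
    "SurvivalCurve",
    "ConditionalSurvivalTable",
    "LifeTable",
    "HazardRatioEstimate",
    "CoverageError",
    "loglogistic_survival",
    "loglogistic_curve",
    "apply_hazard_ratio",
    "per_cycle_event_probability",
    "splice_with_registry",
    "background_mortality_curve",
    "bucher_indirect_hr",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class CoverageError(ValueError):
    """A tabulated input does not cover the times or ages requested."""


@dataclass(frozen=True)
class LogLogisticParams:
    """Shape of ``S(t) = 1/(1 + theta * t**kappa)``, t in months."""

    theta: float
    kappa: float

    def __post_init__(self):
        if not (self.theta > 0 and self.kappa > 0):
            raise ValueError(
                f"log-logistic parameters must be positive (theta={self.theta}, "
                f"kappa={self.kappa})"
            )

    @property
    def median(self) -> float:
        """Time at which S(t) = 0.5, i.e. (1/theta)**(1/kappa)."""
        return (1.0 / self.theta) ** (1.0 / self.kappa)


class SurvivalCurve:
    """A survival function S(t) over months with a provenance tag.

    Wraps a vectorized evaluator; values are clipped to [0, 1] and the
    domain is t >= 0.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], provenance: str):
        self._fn = fn
        self.provenance = provenance

    def __call__(self, t):
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0):
            raise ValueError("survival curves are defined for t >= 0 only")
        out = np.clip(self._fn(arr), 0.0, 1.0)
        return float(out) if np.isscalar(t) or arr.ndim == 0 else out

    def to_table(self, times: Sequence[float]) -> pd.DataFrame:
        times = np.asarray(times, dtype=float)
        return pd.DataFrame({"time_months": times, "survival": self(times)})

    def write(self, path: str | Path, times: Sequence[float]) -> None:
        self.to_table(times).to_csv(path, sep="\t", index=False)


def loglogistic_survival(params: LogLogisticParams, t) -> float | np.ndarray:
    """Evaluate the log-logistic survival function at ``t`` months."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be >= 0")
    out = 1.0 / (1.0 + params.theta * np.power(arr, params.kappa, where=arr > 0,
                                               out=np.zeros_like(arr)))
    out = np.where(arr == 0, 1.0, out)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def loglogistic_curve(params: LogLogisticParams) -> SurvivalCurve:
    return SurvivalCurve(lambda t: loglogistic_survival(params, t), "parametric")


def apply_hazard_ratio(base: SurvivalCurve, hr: float) -> SurvivalCurve:
    """Adjust a curve by a hazard ratio on the cumulative-hazard scale.

    ``S'(t) = S(t)**hr``: hr > 1 lowers survival everywhere, hr < 1 raises
    it.  This is the proportional-cumulative-hazard convention that
    published cost-effectiveness models use when transporting an HR onto a
    non-proportional-hazards baseline.
    """
    if not hr > 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    return SurvivalCurve(lambda t: np.power(base(t), hr), "hr_adjusted")


def per_cycle_event_probability(S: SurvivalCurve, t: float, dt: float) -> float:
    """Probability of the event during (t, t+dt] given event-free at t."""
    s_t = S(t)
    if s_t <= 0:
        raise ZeroDivisionError(
            f"S({t}) = 0: no one remains at risk, the state is degenerate"
        )
    p = 1.0 - S(t + dt) / s_t
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Tabulated inputs


@dataclass(frozen=True)
class ConditionalSurvivalTable:
    """Annual conditional survival probabilities from a registry.

    ``years[i]`` is the year index since diagnosis (e.g. 5 means the
    interval year 5 -> year 6) and ``probabilities[i]`` the probability of
    surviving that year given alive at its start.
    """

    years: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self):
        if len(self.years) == 0:
            raise ValueError("conditional survival table is empty")
        if len(self.years) != len(self.probabilities):
            raise ValueError("years and probabilities differ in length")
        if list(self.years) != list(range(self.years[0], self.years[0] + len(self.years))):
            raise CoverageError("conditional-survival years must be contiguous")
        for p in self.probabilities:
            if not (0.0 < p <= 1.0):
                raise ValueError(f"conditional survival {p} outside (0, 1]")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConditionalSurvivalTable":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(int(y) for y in df.iloc[:, 0]), tuple(float(p) for p in df.iloc[:, 1]))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"year": self.years, "conditional_survival": self.probabilities}
        ).to_csv(path, sep="\t", index=False)

    def conditional(self, year: int) -> float:
        """Annual conditional survival for a year index.

        Years beyond the table's last row reuse the final probability, so a
        finite registry extract still defines the tail of a long horizon.
        """
        if year < self.years[0]:
            raise CoverageError(
                f"year {year} precedes the table's first year {self.years[0]}"
            )
        i = min(year - self.years[0], len(self.probabilities) - 1)
        return self.probabilities[i]


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality probability by single year of age."""

    ages: tuple[int, ...]
    annual_mortality: tuple[float, ...]

    def __post_init__(self):
        if len(self.ages) == 0:
            raise ValueError("life table is empty")
        if len(self.ages) != len(self.annual_mortality):
            raise ValueError("ages and probabilities differ in length")
        if list(self.ages) != list(range(self.ages[0], self.ages[0] + len(self.ages))):
            raise CoverageError("life-table ages must be contiguous")
        for q in self.annual_mortality:
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"annual mortality {q} outside [0, 1]")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(int(a) for a in df.iloc[:, 0]), tuple(float(q) for q in df.iloc[:, 1]))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"age": self.ages, "annual_mortality": self.annual_mortality}
        ).to_csv(path, sep="\t", index=False)

    def mortality(self, age: float) -> float:
        i = int(math.floor(age)) - self.ages[0]
        if i < 0 or i >= len(self.annual_mortality):
            raise CoverageError(f"age {age} outside life table ({self.ages[0]}-{self.ages[-1]})")
        return self.annual_mortality[i]


def splice_with_registry(
    parametric: SurvivalCurve,
    table: ConditionalSurvivalTable,
    switch_time: float = 60.0,
) -> SurvivalCurve:
    """Trial-based curve up to ``switch_time``, registry survival after.

    Beyond the switch, survival is the value at the switch multiplied by
    the product of annual conditional survival probabilities, interpolated
    within each year at constant hazard, so the spliced curve is exactly
    continuous at the switch.
    """
    if not switch_time > 0:
        raise ValueError("switch_time must be > 0")
    first_year = int(round(switch_time / 12.0))
    if table.years[0] > first_year:
        raise CoverageError(
            f"registry table starts at year {table.years[0]} but the splice "
            f"needs year {first_year}"
        )
    s_switch = parametric(switch_time)

    def evaluate(t: np.ndarray) -> np.ndarray:
        out = np.asarray(parametric(t), dtype=float).copy()
        m = t > switch_time
        if np.any(m):
            years_in = (t[m] - switch_time) / 12.0
            yi = np.floor(years_in).astype(int)
            frac = years_in - yi
            max_y = int(yi.max())
            logc = np.array(
                [math.log(table.conditional(first_year + k)) for k in range(max_y + 1)]
            )
            cum = np.concatenate([[0.0], np.cumsum(logc)])
            out[m] = s_switch * np.exp(cum[yi] + frac * logc[yi])
        return out

    return SurvivalCurve(evaluate, "spliced")


def background_mortality_curve(
    lt: LifeTable,
    start_age: float,
    fatal_ae_prob: float = 0.0,
    horizon: int = 240,
) -> SurvivalCurve:
    """Survival under age-matched background mortality plus fatal AEs.

    Each month's death probability converts the age-matched annual
    probability at constant hazard, ``1 - (1-q)**(1/12)``.  The fatal
    treatment-related AE probability is applied once as an extra factor
    ``(1 - p)`` in the first cycle.  The curve is defined on a monthly
    grid out to ``horizon + 24`` months (the extra year feeds the
    time-to-death utility lookahead) and interpolated at constant hazard
    in between.
    """
    if not (0.0 <= fatal_ae_prob <= 1.0):
        raise ValueError("fatal_ae_prob must be a probability")
    n = horizon + 24
    if math.floor(start_age + horizon / 12.0) > lt.ages[-1]:
        raise CoverageError(
            f"life table ends at age {lt.ages[-1]}; horizon requires "
            f"{start_age + horizon / 12.0:.1f}"
        )
    q = np.empty(n)
    for i in range(n):
        age = start_age + i / 12.0
        # hold the last tabulated rate for the lookahead past the horizon
        q[i] = lt.mortality(min(age, lt.ages[-1]))
    p_month = 1.0 - np.power(1.0 - q, 1.0 / 12.0)
    S = np.concatenate([[1.0], np.cumprod(1.0 - p_month)])
    S[1:] *= 1.0 - fatal_ae_prob

    logS = np.log(np.maximum(S, 1e-300))

    def evaluate(t: np.ndarray) -> np.ndarray:
        ti = np.clip(t, 0.0, float(n))
        i = np.floor(ti).astype(int)
        i2 = np.minimum(i + 1, n)
        frac = ti - i
        return np.exp(logS[i] + frac * (logS[i2] - logS[i]))

    return SurvivalCurve(evaluate, "background_mortality")


# ---------------------------------------------------------------------------
# Indirect comparison


@dataclass(frozen=True)
class HazardRatioEstimate:
    """A hazard ratio with its 95% confidence interval."""

    hr: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low > 0 and self.hr > 0 and self.ci_high > 0):
            raise ValueError("hazard ratio and CI bounds must be positive")
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError(
                f"CI must bracket the estimate ({self.ci_low} <= {self.hr} "
                f"<= {self.ci_high})"
            )

    @property
    def log_se(self) -> float:
        """Standard error on the log scale implied by the 95% CI."""
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2.0 * Z95)


def bucher_indirect_hr(
    hr_a_vs_c: HazardRatioEstimate, hr_b_vs_c: HazardRatioEstimate
) -> HazardRatioEstimate:
    """Adjusted indirect comparison of A vs B through a common comparator C.

    With one common comparator per endpoint, a fixed-effect network
    meta-analysis collapses to the ratio of the two trial hazard ratios,
    with variances pooled on the log scale:

        HR_AB = HR_AC / HR_BC,  SE(log HR_AB) = sqrt(SE_AC^2 + SE_BC^2).
    """
    log_hr = math.log(hr_a_vs_c.hr) - math.log(hr_b_vs_c.hr)
    se = math.sqrt(hr_a_vs_c.log_se**2 + hr_b_vs_c.log_se**2)
    return HazardRatioEstimate(
        hr=math.exp(log_hr),
        ci_low=math.exp(log_hr - Z95 * se),
        ci_high=math.exp(log_hr + Z95 * se),
    )
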