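"""Synthetic stand-ins for the external inputs the analysis assumes.

The pipeline normally consumes three kinds of external data: digitized
trial Kaplan-Meier curves, a registry conditional-survival extract for the
long-term splice, and a national life table for background mortality.
None are redistributable, so this module generates statistically similar
substitutes: censored individual patient data drawn from a chosen survival
family (with the Kaplan-Meier curve and number-at-risk table computed from
it, mimicking what one would digitize from a publication), an illustrative
distant-stage NSCLC conditional-survival table, and a smooth
Gompertz-shaped adult life table.

The bundled ``*_synthetic.tsv`` files under ``pembrocea/data`` are frozen
outputs of the default generators here; they are illustrative fixtures,
not transcriptions of SEER or national vital statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from .ipd_refit import KMDigitization, PseudoIPD
from .survival import ConditionalSurvivalTable, LifeTable

__all__ = [
    "SimulationSpec",
    "simulate_km",
    "make_registry_table",
    "make_life_table",
    "default_registry_table",
    "default_life_table",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one simulated trial arm.

    ``params`` are the generating distribution's parameters in the same
    conventions as :mod:`pembrocea.ipd_refit` (e.g. ``theta``/``kappa``
    for log-logistic).  Censoring combines an administrative cutoff (study
    end) with independent exponential dropout at ``censor_rate`` per month
    (0 disables dropout).
    """

    family: str = "loglogistic"
    params: Mapping[str, float] = field(default_factory=lambda: {"theta": 0.01422, "kappa": 1.80138})
    n: int = 400
    cutoff_months: float = 24.0
    censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        if self.cutoff_months <= 0:
            raise ValueError("administrative cutoff must be positive")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be >= 0")


def _draw_event_times(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    p = dict(spec.params)
    u = rng.uniform(size=spec.n)
    if spec.family == "exponential":
        return -np.log(u) / p["rate"]
    if spec.family == "weibull":  # S = exp(-theta t^kappa)
        return (-np.log(u) / p["theta"]) ** (1.0 / p["kappa"])
    if spec.family == "loglogistic":  # S = 1/(1+theta t^kappa)
        return ((1.0 / u - 1.0) / p["theta"]) ** (1.0 / p["kappa"])
    if spec.family == "lognormal":
        from scipy import stats

        return np.exp(p["mu"] + p["sigma"] * stats.norm.ppf(1.0 - u))
    if spec.family == "gompertz":  # H = a/b (e^{bt}-1)
        a, b = p["a"], p["b"]
        if abs(b) < 1e-12:
            return -np.log(u) / a
        return np.log1p(-b * np.log(u) / a) / b
    raise ValueError(f"unknown family {spec.family!r}")


def simulate_km(spec: SimulationSpec) -> tuple[PseudoIPD, KMDigitization]:
    """Simulate censored IPD and the figure one would digitize from it.

    Returns the true records plus a :class:`KMDigitization` holding the KM
    step coordinates and a number-at-risk table on a 1-month grid, exactly
    the inputs :func:`pembrocea.ipd_refit.reconstruct_ipd` expects.
    """
    rng = np.random.default_rng(spec.seed)
    event_t = _draw_event_times(spec, rng)
    cens_t = np.full(spec.n, spec.cutoff_months)
    if spec.censor_rate > 0:
        cens_t = np.minimum(cens_t, rng.exponential(1.0 / spec.censor_rate, size=spec.n))
    obs_t = np.minimum(event_t, cens_t)
    obs_t = np.maximum(obs_t, 1e-6)
    event = (event_t <= cens_t).astype(int)
    ipd = PseudoIPD(times=tuple(float(x) for x in obs_t), events=tuple(int(x) for x in event))

    kmf = KaplanMeierFitter()
    kmf.fit(obs_t, event_observed=event)
    # step coordinates: (0,1) plus the KM value at each observed event time
    ev_times = np.unique(obs_t[event == 1])
    surv_at = kmf.survival_function_at_times(ev_times).to_numpy()
    times = [0.0, *[float(x) for x in ev_times]]
    survival = [1.0, *[float(s) for s in surv_at]]
    if times[-1] < spec.cutoff_months:  # curve end, as a digitizer would record
        times.append(float(spec.cutoff_months))
        survival.append(survival[-1])
    times, survival = tuple(times), tuple(survival)

    grid = np.unique(
        np.append(np.arange(0.0, math.floor(spec.cutoff_months) + 1.0), spec.cutoff_months)
    )
    at_risk = np.array([(obs_t >= g).sum() for g in grid], dtype=int)
    keep = at_risk > 0
    dig = KMDigitization(
        times=times,
        survival=survival,
        risk_times=tuple(float(g) for g in grid[keep]),
        risk_counts=tuple(int(c) for c in at_risk[keep]),
        total_events=int(event.sum()),
    )
    return ipd, dig


def make_registry_table(
    annual_survivals: Sequence[float], start_year: int = 5
) -> ConditionalSurvivalTable:
    """Wrap a list of annual conditional survivals for the splice."""
    if len(annual_survivals) == 0:
        raise ValueError("annual survival list is empty")
    return ConditionalSurvivalTable(
        years=tuple(range(start_year, start_year + len(annual_survivals))),
        probabilities=tuple(float(p) for p in annual_survivals),
    )


#: Illustrative annual conditional survival, years 5-19 after diagnosis,
#: shaped like long-term distant-stage NSCLC registry experience (low
#: conditional survival just after year 5, improving toward a plateau).
#: These values are synthetic, not a SEER transcription.
DEFAULT_REGISTRY_CONDITIONALS = (
    0.70, 0.75, 0.80, 0.84, 0.87, 0.90, 0.92, 0.93, 0.94,
    0.95, 0.95, 0.95, 0.95, 0.95, 0.95,
)


def default_registry_table() -> ConditionalSurvivalTable:
    return make_registry_table(DEFAULT_REGISTRY_CONDITIONALS, start_year=5)


def make_life_table(start_age: int, annual_mortality: Sequence[float]) -> LifeTable:
    """Wrap an annual mortality schedule starting at ``start_age``."""
    if len(annual_mortality) < 20:
        raise ValueError("life-table schedule must cover at least 20 years")
    return LifeTable(
        ages=tuple(range(start_age, start_age + len(annual_mortality))),
        annual_mortality=tuple(float(q) for q in annual_mortality),
    )


def default_life_table(
    first_age: int = 40, last_age: int = 110, a: float = 0.01, b: float = 0.085
) -> LifeTable:
    """Synthetic adult life table with Gompertz-shaped mortality.

    ``q(age) = min(1, a * exp(b * (age - 60)))`` -- roughly 1.5% annual
    mortality at 65 rising to ~8% at 85, a smooth stand-in for a national
    all-cause table.
    """
    q = [min(1.0, a * math.exp(b * (age - 60))) for age in range(first_age, last_age + 1)]
    return make_life_table(first_age, q)
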