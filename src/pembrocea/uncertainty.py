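"""Sensitivity analysis: one-way deterministic sweeps and Monte-Carlo PSA.

The one-way analysis re-evaluates the model at each parameter's low and
high bound with everything else at baseline and ranks parameters by the
ICER spread (tornado ordering).  Where a bound produces a dominated or
dominant outcome the ICER is undefined, so the spread for ranking falls
back to the incremental net monetary benefit at the willingness-to-pay
threshold.

The probabilistic analysis samples all parameters jointly from their
assigned families -- lognormal for hazard ratios (median at the point
estimate, log-SE from the CI), beta for probabilities and utilities and
gamma for costs (both moment-matched to the point estimate and the
CI-implied standard deviation), truncated normal for the rest -- and
summarises the cost-effectiveness acceptability curve over a WTP grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markov import icer
from .model import Comparison, CostEffectivenessModel
from .parameters import Parameter, ParameterSet

__all__ = [
    "TornadoEntry",
    "PsaSample",
    "PsaResult",
    "one_way_dsa",
    "draw_parameter",
    "draw_parameters",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

log = logging.getLogger(__name__)

Z95 = 1.959963984540054

#: $0-$300,000/QALY in $10,000 steps.
DEFAULT_WTP_GRID = tuple(range(0, 300_001, 10_000))


def _nmb(comp: Comparison, wtp: float) -> float:
    """Incremental net monetary benefit of the combination at ``wtp``."""
    inc = comp.incremental
    return wtp * inc.delta_qalys - inc.delta_cost


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: Optional[float]
    icer_high: Optional[float]
    flag_low: Optional[str]
    flag_high: Optional[str]
    spread: float
    spread_scale: str  # 'icer' or 'nmb'


def one_way_dsa(
    model: CostEffectivenessModel,
    params: Optional[ParameterSet] = None,
    wtp: float = 100_000.0,
) -> list[TornadoEntry]:
    """One entry per parameter, sorted by descending influence.

    Parameters with a degenerate range (low == high) naturally come out
    with zero spread and sink to the bottom of the ranking.
    """
    params = params or model.params
    entries = []
    for p in params.parameters.values():
        lo = model.run({p.name: p.low})
        hi = model.run({p.name: p.high})
        if lo.incremental.icer is not None and hi.incremental.icer is not None:
            spread = abs(hi.incremental.icer - lo.incremental.icer)
            scale = "icer"
        else:
            spread = abs(_nmb(hi, wtp) - _nmb(lo, wtp))
            scale = "nmb"
        entries.append(
            TornadoEntry(
                parameter=p.name,
                low_value=p.low,
                high_value=p.high,
                icer_low=lo.incremental.icer,
                icer_high=hi.incremental.icer,
                flag_low=lo.incremental.flag,
                flag_high=hi.incremental.flag,
                spread=spread,
                spread_scale=scale,
            )
        )
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


def tornado_plot(entries: Sequence[TornadoEntry], path, top: int = 10, base_icer=None):
    """Horizontal-bar tornado of the ``top`` most influential parameters."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [e for e in entries[:top] if e.icer_low is not None and e.icer_high is not None]
    fig, ax = plt.subplots(figsize=(7, 0.45 * max(len(shown), 4) + 1))
    for i, e in enumerate(reversed(shown)):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in reversed(shown)])
    if base_icer is not None:
        ax.axvline(base_icer, color="k", lw=0.8, ls="--")
    ax.set_xlabel("ICER (USD per QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve: pd.DataFrame, path):
    """Cost-effectiveness acceptability curve over the WTP grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["p_combination_cost_effective"], marker="o", ms=3)
    ax.set_xlabel("Willingness to pay (USD per QALY)")
    ax.set_ylabel("P(combination cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


def draw_parameter(p: Parameter, rng: np.random.Generator) -> float:
    """One draw from the parameter's assigned distribution.

    Falls back to uniform(low, high) with a warning when the CI-implied
    moments are infeasible for the family (e.g. a beta SD too large for
    the mean).
    """
    if p.is_fixed:
        return p.value
    sd = (p.high - p.low) / (2.0 * Z95)
    if p.dist_family == "lognormal":
        sigma = (math.log(p.high) - math.log(p.low)) / (2.0 * Z95)
        return float(math.exp(math.log(p.value) + sigma * rng.standard_normal()))
    if p.dist_family == "beta":
        m = p.value
        if 0.0 < m < 1.0 and sd > 0 and sd * sd < m * (1.0 - m):
            nu = m * (1.0 - m) / (sd * sd) - 1.0
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        log.warning("%s: beta moments infeasible, sampling uniform(low, high)", p.name)
        return float(rng.uniform(p.low, p.high))
    if p.dist_family == "gamma":
        if p.value > 0 and sd > 0:
            shape = (p.value / sd) ** 2
            return float(rng.gamma(shape, sd * sd / p.value))
        log.warning("%s: gamma moments infeasible, sampling uniform(low, high)", p.name)
        return float(rng.uniform(p.low, p.high))
    if p.dist_family == "normal":
        for _ in range(1000):  # truncate to the support by rejection
            x = p.value + sd * rng.standard_normal()
            if p.low <= x <= p.high:
                return float(x)
        return float(np.clip(p.value, p.low, p.high))
    raise ValueError(f"{p.name}: cannot draw from family {p.dist_family!r}")


def draw_parameters(params: ParameterSet, rng: np.random.Generator) -> dict[str, float]:
    """A joint draw of every parameter (fixed ones at baseline)."""
    return {name: draw_parameter(p, rng) for name, p in params.parameters.items()}


@dataclass(frozen=True)
class PsaSample:
    iteration: int
    cost_combination: float
    qalys_combination: float
    cost_monotherapy: float
    qalys_monotherapy: float

    @property
    def delta_cost(self) -> float:
        return self.cost_combination - self.cost_monotherapy

    @property
    def delta_qalys(self) -> float:
        return self.qalys_combination - self.qalys_monotherapy


@dataclass
class PsaResult:
    samples: list[PsaSample]
    seed: int
    n_failed: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": s.iteration,
                    "cost_combination": s.cost_combination,
                    "qalys_combination": s.qalys_combination,
                    "cost_monotherapy": s.cost_monotherapy,
                    "qalys_monotherapy": s.qalys_monotherapy,
                }
                for s in self.samples
            ]
        )


def run_psa(
    model: CostEffectivenessModel,
    n_iter: int = 10_000,
    seed: int = 0,
    params: Optional[ParameterSet] = None,
) -> PsaResult:
    """Monte-Carlo PSA: one full model evaluation per joint draw.

    Iterations whose evaluation fails (e.g. an extreme draw producing a
    degenerate curve) are logged and excluded; the count is reported on
    the result.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    params = params or model.params
    rng = np.random.default_rng(seed)
    result = PsaResult(samples=[], seed=seed)
    for i in range(n_iter):
        values = draw_parameters(params, rng)
        try:
            comp = model.run(values)
        except Exception as exc:  # noqa: BLE001 -- any failure is excluded
            result.n_failed += 1
            result.failures.append((i, str(exc)))
            log.warning("PSA iteration %d failed: %s", i, exc)
            continue
        result.samples.append(
            PsaSample(
                iteration=i,
                cost_combination=comp.combination.cost,
                qalys_combination=comp.combination.qalys,
                cost_monotherapy=comp.monotherapy.cost,
                qalys_monotherapy=comp.monotherapy.qalys,
            )
        )
    return result


def ceac(
    psa: PsaResult | Sequence[PsaSample],
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> pd.DataFrame:
    """P(combination cost-effective) at each willingness-to-pay value.

    A sample favours the combination when its incremental net monetary
    benefit is positive: wtp * dQALY - dCost > 0.
    """
    samples = psa.samples if isinstance(psa, PsaResult) else list(psa)
    if not samples:
        raise ValueError("no PSA samples")
    dq = np.array([s.delta_qalys for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    rows = [
        {"wtp": float(w), "p_combination_cost_effective": float(np.mean(w * dq - dc > 0))}
        for w in wtp_grid
    ]
    return pd.DataFrame(rows)
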