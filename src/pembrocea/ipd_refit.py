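"""Pseudo individual-patient data from published KM curves, and refitting.

Published survival figures can be turned back into analysable data: given
digitized curve coordinates and the number-at-risk table, the
reconstruction allocates events and censorings interval by interval so
that the rebuilt Kaplan-Meier estimate and at-risk counts match the
figure.  Candidate parametric families are then fitted to the
reconstructed records by censored-data maximum likelihood and compared by
AIC/BIC.

The log-logistic family uses the ``S(t) = 1/(1 + theta * t**kappa)``
parameterization so fitted values drop straight into the survival module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KMDigitization",
    "PseudoIPD",
    "FitResult",
    "FitError",
    "reconstruct_ipd",
    "fit_distribution",
    "select_best",
    "FAMILIES",
]

log = logging.getLogger(__name__)

FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gompertz")


@dataclass(frozen=True)
class KMDigitization:
    """Digitized KM curve coordinates plus the number-at-risk table."""

    times: tuple[float, ...]  # months, non-decreasing, starting at 0
    survival: tuple[float, ...]  # non-increasing, survival[0] == 1
    risk_times: tuple[float, ...]
    risk_counts: tuple[int, ...]
    total_events: int | None = None

    def __post_init__(self):
        if len(self.times) != len(self.survival):
            raise ValueError("coordinate times and survival differ in length")
        if len(self.times) < 2:
            raise ValueError("need at least two digitized coordinates")
        if self.times[0] != 0 or abs(self.survival[0] - 1.0) > 1e-9:
            raise ValueError("digitization must start at (0, 1)")
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("coordinate times must be non-decreasing")
        if any(b > a + 1e-9 for a, b in zip(self.survival, self.survival[1:])):
            raise ValueError("survival coordinates must be non-increasing")
        if len(self.risk_times) != len(self.risk_counts):
            raise ValueError("risk table columns differ in length")
        if len(self.risk_times) < 2:
            raise ValueError("risk table needs at least two intervals")
        if any(b > a for a, b in zip(self.risk_counts, self.risk_counts[1:])):
            raise ValueError("number at risk cannot increase over time")

    @classmethod
    def from_tsv(cls, curve_path: str | Path, risk_path: str | Path, **kw) -> "KMDigitization":
        curve = pd.read_csv(curve_path, sep="\t")
        risk = pd.read_csv(risk_path, sep="\t")
        return cls(
            times=tuple(float(x) for x in curve.iloc[:, 0]),
            survival=tuple(float(x) for x in curve.iloc[:, 1]),
            risk_times=tuple(float(x) for x in risk.iloc[:, 0]),
            risk_counts=tuple(int(x) for x in risk.iloc[:, 1]),
            **kw,
        )


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed (time, event) records; event 1 = death/progression."""

    times: tuple[float, ...]
    events: tuple[int, ...]

    def __post_init__(self):
        if len(self.times) != len(self.events):
            raise ValueError("times and events differ in length")
        if any(t <= 0 for t in self.times):
            raise ValueError("record times must be positive")
        if any(e not in (0, 1) for e in self.events):
            raise ValueError("event indicators must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(sum(self.events))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})


def reconstruct_ipd(km: KMDigitization) -> PseudoIPD:
    """Allocate events and censorings consistent with curve and risk table.

    Interval-wise reconstruction: within each risk-table interval the
    number censored is adjusted iteratively until the implied number at
    risk at the next interval matches the published count, censoring times
    spread uniformly across the interval and event counts chosen so the
    running KM product tracks the digitized steps.  After the last
    risk-table time, remaining subjects are assigned using ``total_events``
    when provided, otherwise censored at the last coordinate.
    """
    S = np.asarray(km.survival, dtype=float)
    T = np.asarray(km.times, dtype=float)
    trisk = list(km.risk_times)
    nrisk = list(km.risk_counts)
    J = len(trisk)

    # index of the first coordinate at/after each risk time
    lower = [int(np.searchsorted(T, rt, side="left")) for rt in trisk]
    lower.append(len(T))

    times_out: list[float] = []
    events_out: list[int] = []

    n_hat = float(nrisk[0])
    km_prod = 1.0  # running KM estimate at the last event
    s_last = 1.0  # digitized survival at the last event

    for j in range(J):
        k_lo, k_hi = lower[j], lower[j + 1]
        t_start = trisk[j]
        t_end = trisk[j + 1] if j + 1 < J else (T[-1] if len(T) else t_start)
        target_next = nrisk[j + 1] if j + 1 < J else None

        if target_next is None:
            # beyond-last-interval handling happens after the loop
            last_interval_start = (k_lo, n_hat, km_prod, s_last)
            break

        # initial censoring guess from the survival drop across the interval
        s_start = S[k_lo - 1] if k_lo > 0 else 1.0
        s_end = S[k_hi - 1] if k_hi > 0 else 1.0
        guess = int(round(n_hat * (s_end / s_start if s_start > 0 else 0.0))) - target_next
        n_cen = max(0, guess)

        for _ in range(200):
            d_total, n_after, records = _allocate_interval(
                T[k_lo:k_hi], S[k_lo:k_hi], n_hat, km_prod, s_last,
                n_cen, t_start, t_end,
            )
            diff = int(round(n_after)) - target_next
            if diff == 0:
                break
            n_cen = max(0, n_cen + diff)
            if n_cen > n_hat:
                raise ValueError(
                    "risk table inconsistent with curve: cannot match "
                    f"number at risk {target_next} at t={t_end}"
                )
        else:
            raise ValueError("event/censoring allocation did not converge")

        for t_rec, ev, s_dig, km_new in records:
            times_out.append(t_rec)
            events_out.append(ev)
            if ev == 1 and s_dig is not None:
                s_last, km_prod = s_dig, km_new
        n_hat = n_after
    else:
        last_interval_start = (len(T), n_hat, km_prod, s_last)

    # final open-ended interval
    k_lo, n_hat, km_prod, s_last = last_interval_start
    remaining = int(round(n_hat))
    n_events_so_far = sum(events_out)
    for k in range(k_lo, len(T)):
        if remaining <= 0:
            break
        if km.total_events is not None and n_events_so_far >= km.total_events:
            break
        drop = 1.0 - (S[k] / s_last if s_last > 0 else 0.0)
        d = int(round(remaining * drop))
        d = min(d, remaining)
        for _ in range(d):
            times_out.append(float(T[k]))
            events_out.append(1)
        if d > 0:
            km_prod *= 1.0 - d / remaining
            s_last = S[k]
            remaining -= d
            n_events_so_far += d
    # survivors past the last recorded event are censored no earlier than
    # the final risk-table time, so rebuilt at-risk counts match it
    t_cens = max(float(T[-1]) if len(T) else 0.0, float(trisk[-1]))
    for _ in range(remaining):
        times_out.append(max(t_cens, 1e-9))
        events_out.append(0)

    order = np.argsort(times_out, kind="stable")
    return PseudoIPD(
        times=tuple(float(times_out[i]) for i in order),
        events=tuple(int(events_out[i]) for i in order),
    )


def _allocate_interval(T, S, n_start, km_prod, s_last, n_cen, t_start, t_end):
    """Distribute ``n_cen`` censorings and matching events in one interval.

    Censoring times are spread evenly; at each digitized drop the event
    count is the rounded number that brings the running KM product onto
    the digitized value.  Returns total events, subjects left, and the
    records as (time, event, digitized S, new KM product).
    """
    if n_cen > 0:
        width = max(t_end - t_start, 1e-9)
        cen_times = [t_start + (i + 0.5) * width / n_cen for i in range(int(n_cen))]
    else:
        cen_times = []
    cen_used = 0
    n_hat = n_start
    records = []
    d_total = 0
    for k in range(len(T)):
        # censorings that fall before this coordinate leave the risk set first
        while cen_used < len(cen_times) and cen_times[cen_used] <= T[k]:
            records.append((max(cen_times[cen_used], 1e-9), 0, None, None))
            n_hat -= 1
            cen_used += 1
        if n_hat <= 0:
            break
        if s_last > 0 and S[k] < s_last - 1e-12:
            d = int(round(n_hat * (1.0 - S[k] / s_last)))
            d = max(0, min(d, int(n_hat)))
            if d > 0:
                km_new = km_prod * (1.0 - d / n_hat)
                for _ in range(d):
                    records.append((float(T[k]), 1, S[k], km_new))
                km_prod = km_new
                s_last = S[k]
                n_hat -= d
                d_total += d
    while cen_used < len(cen_times):
        records.append((max(cen_times[cen_used], 1e-9), 0, None, None))
        n_hat -= 1
        cen_used += 1
    return d_total, n_hat, records


# ---------------------------------------------------------------------------
# Parametric fitting


class FitError(RuntimeError):
    """Maximum-likelihood fitting failed; carries optimizer diagnostics."""


@dataclass(frozen=True)
class FitResult:
    distribution: str
    params: dict[str, float]
    se: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n: int
    n_events: int

    @property
    def k(self) -> int:
        return len(self.params)


def _loglik_terms(family: str, p: np.ndarray, t: np.ndarray):
    """(log f(t), log S(t)) for the family at packed parameter vector p.

    Positive parameters are passed on the log scale so the optimizer works
    unconstrained.
    """
    if family == "exponential":
        lam = math.exp(p[0])
        return math.log(lam) - lam * t, -lam * t
    if family == "weibull":
        th, ka = math.exp(p[0]), math.exp(p[1])
        H = th * t**ka
        return math.log(th) + math.log(ka) + (ka - 1) * np.log(t) - H, -H
    if family == "loglogistic":
        th, ka = math.exp(p[0]), math.exp(p[1])
        base = 1.0 + th * t**ka
        logf = math.log(th) + math.log(ka) + (ka - 1) * np.log(t) - 2 * np.log(base)
        return logf, -np.log(base)
    if family == "lognormal":
        mu, sig = p[0], math.exp(p[1])
        z = (np.log(t) - mu) / sig
        logf = stats.norm.logpdf(z) - np.log(t * sig)
        return logf, stats.norm.logsf(z)
    if family == "gompertz":
        a, b = math.exp(p[0]), p[1]
        if abs(b) < 1e-12:
            H = a * t
            logh = math.log(a) + b * t
        else:
            H = a / b * np.expm1(b * t)
            logh = math.log(a) + b * t
        return logh - H, -H
    raise ValueError(f"unknown family {family!r}")


def _neg_loglik(p, family, t, e):
    logf, logS = _loglik_terms(family, p, t)
    ll = np.sum(np.where(e == 1, logf, logS))
    return -ll if np.isfinite(ll) else 1e12


def _initial_guess(family: str, t: np.ndarray, e: np.ndarray) -> np.ndarray:
    rate = max(e.sum(), 1) / t.sum()  # exponential MLE
    if family == "exponential":
        return np.array([math.log(rate)])
    if family in ("weibull", "loglogistic"):
        return np.array([math.log(rate), 0.0])
    if family == "lognormal":
        lt = np.log(t[e == 1]) if e.any() else np.log(t)
        return np.array([float(np.mean(lt)), math.log(max(float(np.std(lt)), 0.1))])
    return np.array([math.log(rate), 0.01])  # gompertz


def _hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


_PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("theta", "kappa"),
    "loglogistic": ("theta", "kappa"),
    "lognormal": ("mu", "sigma"),
    "gompertz": ("a", "b"),
}
_LOG_SCALE = {
    "exponential": (True,),
    "weibull": (True, True),
    "loglogistic": (True, True),
    "lognormal": (False, True),
    "gompertz": (True, False),
}


def fit_distribution(ipd: PseudoIPD, family: str) -> FitResult:
    """Censored-data maximum likelihood for one parametric family.

    Requires at least 10 records and 5 events.  Standard errors come from
    the observed information (finite-difference Hessian at the optimum),
    mapped to the natural scale by the delta method.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    t = np.asarray(ipd.times, dtype=float)
    e = np.asarray(ipd.events, dtype=int)
    if ipd.n < 10:
        raise FitError(f"need >= 10 records, got {ipd.n}")
    if ipd.n_events < 5:
        raise FitError(f"need >= 5 events, got {ipd.n_events}")

    x0 = _initial_guess(family, t, e)
    res = optimize.minimize(
        _neg_loglik, x0, args=(family, t, e), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    res2 = optimize.minimize(_neg_loglik, res.x, args=(family, t, e), method="BFGS")
    if res2.fun < res.fun:
        res = res2
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise FitError(f"{family}: likelihood not finite at optimum ({res.message})")

    loglik = -float(res.fun)
    k = len(res.x)
    aic = 2 * k - 2 * loglik
    bic = k * math.log(ipd.n) - 2 * loglik

    names = _PARAM_NAMES[family]
    logscale = _LOG_SCALE[family]
    natural = [math.exp(v) if ls else v for v, ls in zip(res.x, logscale)]

    se = {}
    try:
        H = _hessian(lambda p: _neg_loglik(p, family, t, e), res.x)
        cov = np.linalg.inv(H)
        diag = np.clip(np.diag(cov), 0, None)
        for i, (nm, ls) in enumerate(zip(names, logscale)):
            s = math.sqrt(diag[i])
            se[nm] = s * natural[i] if ls else s  # delta method for log-scale params
    except np.linalg.LinAlgError:
        se = {nm: float("nan") for nm in names}

    return FitResult(
        distribution=family,
        params=dict(zip(names, natural)),
        se=se,
        loglik=loglik,
        aic=aic,
        bic=bic,
        n=ipd.n,
        n_events=ipd.n_events,
    )


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Lowest AIC; ties by lowest BIC, then fewest parameters.

    Logs a warning when the AIC-best and BIC-best candidates disagree.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    by_aic = min(fits, key=lambda f: (f.aic, f.bic, f.k))
    by_bic = min(fits, key=lambda f: (f.bic, f.aic, f.k))
    if by_aic.distribution != by_bic.distribution:
        log.warning(
            "AIC prefers %s but BIC prefers %s; keeping the AIC choice",
            by_aic.distribution, by_bic.distribution,
        )
    return by_aic


def fits_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    rows = [
        {
            "distribution": f.distribution,
            **{f"param_{k}": v for k, v in f.params.items()},
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
        }
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
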