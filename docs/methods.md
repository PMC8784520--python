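# Methods

## Decision problem and model structure

The model compares two first-line strategies for metastatic NSCLC with
PD-L1 ≥ 50%: pembrolizumab monotherapy and pembrolizumab plus
platinum-doublet chemotherapy (pemetrexed + carboplatin for non-squamous
disease, paclitaxel + carboplatin for squamous).  It is a
partitioned-survival cohort model: rather than estimating a transition
matrix, state occupancy is read directly off the arm's overall-survival
(OS) and progression-free-survival (PFS) curves each monthly cycle —
progression-free occupancy is S_PFS(t), death is 1 − S_OS(t), and
progressive disease is the difference, clipped at zero (with a logged
warning) where fitted curves cross.  This is the only construction
consistent with driving a cohort model from two marginal survival curves,
and it makes the QALY results independent of unidentifiable
progression-vs-death pathway assumptions.

The progression-free state is split into on-treatment and off-treatment
sub-states.  The on-treatment fraction decays geometrically by the
combined per-cycle probability of toxicity-driven discontinuation; each
drug's exposure additionally decays by its own per-cycle probability and
stops at its maximum administration count.  Death increments are
allocated to the progression-free and progressed states in proportion to
their prior-cycle occupancy; the remaining progression-free outflow is
the progression increment that triggers progression-related one-off
costs.

Horizon: 240 cycles (20 years).  Cycle time stamps are cycle starts;
discounting is continuous-per-month at an annual rate (default 3% for
both costs and QALYs).  A half-cycle correction (averaging occupancy
between cycle start and end) is available as a switch and off by
default, since the published analysis this model re-implements does not
describe one.

## Survival inputs

Combination-arm OS and PFS are two-parameter log-logistic curves,
S(t) = 1/(1 + θ t^κ) with t in months.  This parameterization matches
the printed (θ, κ) pairs and yields medians consistent with the source
trials (e.g. non-squamous OS median 42.8 months, PFS median 10.6
months); an alternative form would be a one-line change in
`survival.loglogistic_survival`.

The monotherapy arm applies an indirectly estimated hazard ratio on the
cumulative-hazard scale, S^HR, to OS and PFS independently.  The
log-logistic family is not closed under proportional hazards; S^HR is
nevertheless the dominant convention for transporting an external HR
onto a parametric baseline in published cost-effectiveness models, and
the alternatives (proportional odds, accelerated failure time) produce
*heavier* monotherapy tails and drift further from the published
results.  `survival.bucher_indirect_hr` implements the adjusted indirect
comparison (ratio of trial HRs, log-scale variance pooling) that a
fixed-effect network with one common comparator collapses to.

Three tail extrapolations:

1. **Registry splice (base case).** Parametric to month 60, then annual
   conditional-survival probabilities, interpolated within years at
   constant hazard; exactly continuous at the splice.  Conditional years
   beyond the table's last row reuse its final probability, so a finite
   registry extract defines the whole tail.
2. **Pure parametric (scenario 1).** The log-logistic curves over the
   full horizon.  The heavy log-logistic tail makes this the most
   optimistic extrapolation.
3. **Background mortality (scenario 2).** Death driven entirely by an
   age-matched life table (annual probabilities converted to monthly at
   constant hazard) plus a one-off fatal treatment-related AE
   probability in cycle 1.  Under this construction the arms differ in
   survival only through fatal AEs, so the costlier, more toxic
   combination is dominated — reproducing the published qualitative
   finding.  The published absolute QALY levels for this scenario are
   not reproducible under any self-consistent reading we found (a
   parametric-then-background splice would preserve the combination's
   five-year survival advantage and could not produce a negative QALY
   increment), so only the dominance sign is claimed.

## Costs

Doses: pembrolizumab 200 mg flat; pemetrexed 500 mg/m² and paclitaxel
200 mg/m² at BSA 1.79 m²; carboplatin by Calvert formula
(AUC × (CrCl + 25)) at CrCl 70 mL/min.  Billed milligrams round up to
the cheapest achievable combination of US single-use vials (dynamic
programme minimising overage then vial count), charging wastage to the
payer.  Three-weekly schedules accrue 30.44/21 ≈ 1.45 administrations
per monthly cycle as a continuous rate; pembrolizumab caps at 35
administrations (2 years), induction chemotherapy at 4, pemetrexed
maintenance continues until progression.

Infusion fees bill per administration visit: the first hour at the base
CMS rate, each further started hour at the add-on rate, with
co-administered drugs pooling their infusion times into one visit
(pembrolizumab 0.5 h, pemetrexed 0.5 h, carboplatin 1 h, paclitaxel 3 h).
Routine follow-up (monthly physician visit, quarterly imaging) accrues
for progression-free patients; progressed patients instead receive, at
the moment of progression, a subsequent-anticancer-therapy package (for
a configurable uptake fraction, default 0.5) or a best-supportive-care
package (the rest), and a terminal-care package at death.  Treating
progression-phase care as entry packages rather than monthly accruals
reproduces the published per-arm totals and increments; the uptake knob
is exposed because the trial-reported proportions are not public.

Grade ≥ 3 adverse events with incidence ≥ 1% enter as frequency-weighted
aggregates: a one-off cost and a one-off QALY decrement
(Σ incidence × disutility × duration/12, default mean duration 1 month)
applied at model entry.  `costing.ae_burden` regenerates the aggregates
from an incidence table when one is available.

## Utilities

Quality of life follows a time-to-death weighting: a patient alive at t
carries the expected utility over four windows (≤1, 1–6, 6–12, ≥12
months before death), with window probabilities read off the arm's own
OS curve — (S(t+a) − S(t+b))/S(t) for each window and S(t+12)/S(t) for
the far-from-death weight.  This captures the terminal decline in
quality of life without needing progression-status utilities, and it
makes QALYs a function of OS alone (so, in scenario 2, equal background
mortality implies equal gross QALYs and the AE decrements decide the
sign).

## Parameters and uncertainty

Every input is a `Parameter` with value, deterministic range and PSA
family, loaded from YAML; the two bundled files carry the full published
input table (2021 USD) plus documented configuration knobs.  Ranges
without a reported 95% CI default to ±50% of baseline.

One-way DSA re-evaluates the model at each bound; tornado ordering uses
the ICER spread, falling back to incremental net monetary benefit at the
$100,000/QALY threshold when a bound produces dominance (an ICER spread
is undefined there).  PSA draws: lognormal for HRs (median at the point
estimate, log-SE from the CI width); beta for probabilities and
utilities and gamma for costs, moment-matched to the point estimate and
the CI-implied SD ((high − low)/3.92), with a uniform(low, high)
fallback and warning when moments are infeasible; truncated normal for
the remainder.  The acceptability curve reports the fraction of joint
draws with positive incremental net monetary benefit over
$0–$300,000/QALY in $10,000 steps.

## KM reconstruction and refitting

`ipd_refit.reconstruct_ipd` rebuilds (time, event) records from digitized
KM coordinates plus the number-at-risk table: within each risk-table
interval the censoring count is adjusted iteratively until the implied
at-risk count matches the next published value, censorings spread
uniformly across the interval and event counts chosen so the running KM
product tracks the digitized steps; survivors past the last event are
censored no earlier than the final risk-table time.  Candidate families
(exponential, Weibull, log-logistic, log-normal, Gompertz) are fitted by
censored maximum likelihood — Nelder-Mead followed by BFGS on
log-transformed positive parameters, standard errors from the
finite-difference observed information — and compared by AIC, ties
broken by BIC then parsimony, with a logged warning when AIC and BIC
disagree.  The likelihood code is deliberately uniform across families
(no fitter exists for Gompertz in common Python survival libraries),
which lets an independent library serve as a cross-check in the tests.

## Synthetic data: what it does and does not validate

The generators in `pembrocea.synthetic` stand in for three external
inputs: simulated censored trial arms with their KM curve and monthly
number-at-risk table; an illustrative distant-stage-NSCLC
conditional-survival table (years 5–19, 0.70 rising to a 0.95 plateau);
and a Gompertz-shaped adult life table (q(65) ≈ 1.5%, q(85) ≈ 8.4%).
The bundled `*_synthetic.tsv` files are frozen outputs of these
defaults and are labelled synthetic; they are not SEER or national
vital-statistics transcriptions.

Consequently the registry-spliced base case and the background-mortality
scenario are validated *qualitatively* (decision pattern, dominance
sign), not against the published absolute numbers, which depend on the
real registry extract.  The pure-parametric scenario needs no external
data and is validated quantitatively.  The simulated KM arms share the
real pipeline's censoring structure (administrative cutoff plus
exponential dropout) but not digitization error, so reconstruction tests
bound algorithmic — not measurement — error.

## Numerical choices and limitations

* Curves evaluate vectorized with values clipped to [0, 1]; tabulated
  curves interpolate at constant hazard on a monthly grid extended one
  year past the horizon to feed the time-to-death lookahead.
* The occupancy trace is validated each run to sum to 1 within 1e−10
  with monotone death occupancy.
* Degenerate draws or curve failures inside the PSA are logged,
  excluded, and counted rather than aborting the run.
* Dose reductions, relative dose intensity, treatment-effect waning,
  cure fractions and EVPI are out of scope; the comparison is against
  monotherapy only, not traditional chemotherapy.
* Model results for the squamous histology rest on small incremental
  quantities (≈$4,600 and ≈0.33 QALYs), so reasonable alternative
  costing conventions move the squamous ICER proportionally more than
  the non-squamous one.
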