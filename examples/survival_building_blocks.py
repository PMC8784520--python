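"""The survival toolbox: curves, hazard ratios, splicing, indirect HRs.

Walks through the pieces the cohort model is built from: evaluating a
log-logistic survival curve, deriving the comparator arm through a
hazard ratio, splicing a registry conditional-survival table onto the
parametric tail, and combining two trial hazard ratios into an indirect
comparison through their common comparator.
"""

from pembrocea import (
    HazardRatioEstimate,
    LogLogisticParams,
    apply_hazard_ratio,
    bucher_indirect_hr,
    loglogistic_curve,
    per_cycle_event_probability,
    splice_with_registry,
)
from pembrocea.synthetic import default_registry_table

# combination-arm OS for non-squamous disease
os_params = LogLogisticParams(theta=0.03084, kappa=0.92588)
os_combo = loglogistic_curve(os_params)
print(f"median OS: {os_params.median:.1f} months")
for t in (12, 24, 60, 120, 240):
    print(f"  S({t:>3} mo) = {os_combo(float(t)):.3f}")

# monotherapy arm via the indirect HR (cumulative-hazard scale)
os_mono = apply_hazard_ratio(os_combo, 1.67)
print(f"\nwith HR 1.67: S(60 mo) falls {os_combo(60.0):.3f} -> {os_mono(60.0):.3f}")

p = per_cycle_event_probability(os_combo, 12.0, 1.0)
print(f"per-cycle death probability at month 12: {p:.4f}")

# registry splice: parametric for 5 years, conditional survival after
spliced = splice_with_registry(os_combo, default_registry_table(), 60.0)
print(f"\nspliced vs parametric at 10 y: {spliced(120.0):.3f} vs {os_combo(120.0):.3f}")
print("(the registry tail is heavier-mortality than the parametric one)")

# indirect comparison through a common chemotherapy comparator
mono_vs_chemo = HazardRatioEstimate(0.70, 0.3661, 1.3386)
combo_vs_chemo = HazardRatioEstimate(0.4192, 0.2192, 0.8016)
indirect = bucher_indirect_hr(mono_vs_chemo, combo_vs_chemo)
print(f"\nindirect HR mono vs combo: {indirect.hr:.2f} "
      f"(95% CI {indirect.ci_low:.2f}-{indirect.ci_high:.2f})")
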