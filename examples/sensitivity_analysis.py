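"""One-way tornado and a small probabilistic sensitivity analysis.

Prints the ten parameters whose plausible ranges move the non-squamous
base-case ICER the most (the tornado top), then runs a reduced
Monte-Carlo PSA and reports the probability that the combination is
cost-effective at the $100,000/QALY willingness-to-pay threshold.  A
spread of $0 means the model result does not depend on that parameter.
"""

from pembrocea import CostEffectivenessModel, load_bundled
from pembrocea.uncertainty import ceac, one_way_dsa, run_psa

params = load_bundled("non_squamous")
model = CostEffectivenessModel(params, mode="base")

print("Top 10 one-way sensitivities (non-squamous base case):")
for e in one_way_dsa(model)[:10]:
    lo = "dominated" if e.flag_low else (f"{e.icer_low:,.0f}" if e.icer_low else "n/a")
    hi = "dominated" if e.flag_high else (f"{e.icer_high:,.0f}" if e.icer_high else "n/a")
    print(f"  {e.parameter:<28} ICER at bounds [{lo:>10} .. {hi:>10}]  "
          f"spread {e.spread:,.0f} ({e.spread_scale})")

print("\nPSA (500 iterations, seed 1) ...")
psa = run_psa(model, n_iter=500, seed=1)
curve = ceac(psa, (50_000, 100_000, 150_000, 200_000, 300_000))
for _, row in curve.iterrows():
    print(f"  WTP ${row['wtp']:>9,.0f}/QALY  "
          f"P(combination cost-effective) = {row['p_combination_cost_effective']:.3f}")
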