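"""Base case and both scenario analyses for each histology.

Runs the cohort model three ways -- registry-spliced base case, pure
parametric extrapolation, and background-mortality -- and prints the
per-arm discounted cost and QALYs with the resulting ICER.  The printed
ICER is dollars per quality-adjusted life-year gained by adding
chemotherapy to pembrolizumab; "Dominated" means the combination both
costs more and yields fewer QALYs, so no price per QALY exists.
"""

from pembrocea import CostEffectivenessModel, load_bundled

for histology in ("non_squamous", "squamous"):
    params = load_bundled(histology)
    print(f"\n=== {histology.replace('_', '-')} NSCLC, PD-L1 >= 50% ===")
    for mode, label in (
        ("base", "Base case (registry splice, synthetic fixture)"),
        ("scenario1", "Scenario 1 (pure parametric extrapolation)"),
        ("scenario2", "Scenario 2 (background mortality + fatal AEs)"),
    ):
        comp = CostEffectivenessModel(params, mode=mode).run()
        mono, combo, inc = comp.monotherapy, comp.combination, comp.incremental
        print(f"\n  {label}")
        print(f"    pembrolizumab        cost ${mono.cost:>10,.0f}   QALYs {mono.qalys:5.2f}")
        print(f"    pembro+chemotherapy  cost ${combo.cost:>10,.0f}   QALYs {combo.qalys:5.2f}")
        print(
            f"    increments  dCost ${inc.delta_cost:,.0f}  dQALY {inc.delta_qalys:+.2f}"
            f"  ->  ICER {inc.label}"
            + ("" if inc.flag else " $/QALY")
        )
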