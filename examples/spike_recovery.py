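"""Spike-recovery and fold-change analytics on simulated LC-MS peak areas.

A synthetic spike experiment (13 deuterated standards, 3 pre- and 3
post-extraction replicates, 5% multiplicative noise) is generated with known
true recoveries, then analysed exactly as real peak-area tables would be.
A planted 1.45-fold class enrichment demonstrates the endogenous-lipid
fold-change workflow against a reference extraction method.
"""

from solvselect import (
    RecoverySimSpec,
    compute_all_recoveries,
    fold_change,
    normalize_and_sum,
    simulate_peak_areas,
    summarize_recoveries,
)

spec = RecoverySimSpec(
    true_recovery=95.0,
    class_effect={("LPC", "mmc_cpme"): 1.45},
    cv=0.05,
    n_replicates=3,
    seed=5,
)
sim = simulate_peak_areas(spec)

results = compute_all_recoveries(sim.areas)
for method in spec.methods:
    summary = summarize_recoveries(results, method)
    mean, sd = summary.rounded()
    print(f"{method}: panel-average recovery {mean} +/- {sd} % "
          f"(true value 95 %, {summary.n_lipids} standards)")

norm, _ = normalize_and_sum(sim.species, dict(sim.standards))
changes = {r.lipid_class: r for r in fold_change(norm, "mmc_cpme", "folch_chcl3")}
lpc = changes["LPC"]
print(f"\nLPC fold change vs reference: {lpc.fold_change:.2f} +/- {lpc.sd:.2f} "
      f"(planted 1.45), p = {lpc.p_value:.3g}, tier {lpc.tier}")
print(f"PC fold change (no planted effect): {changes['PC'].fold_change:.2f}, "
      f"tier {changes['PC'].tier}")
print("\nRecovery near 100% means the extraction loses little analyte; the")
print("starred tier marks a class whose extraction efficiency differs")
print("significantly from the reference protocol.")
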