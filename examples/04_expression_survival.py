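"""Intragraft expression vs graft survival: step-fit dichotomization,
Kaplan-Meier/log-rank, multi-gene Cox, rejection-class comparison.

Simulates a biopsy cohort with step-structured FGFBP2 expression whose high
level carries excess graft-loss hazard, then runs the full transcript
analysis on the non-rejecting subset.
"""

import numpy as np

from nkgraft import simulate
from nkgraft.transcript_survival import (cox_multigene, dichotomize,
                                         group_compare, km_logrank,
                                         stepminer_threshold)

config = simulate.SimulationConfig()
table = simulate.simulate_expression_survival(config, seed=3)
nonrej = table[table["rejection_class"] == "non-rejection"]
print(f"biopsies: {len(table)} total, {len(nonrej)} non-rejecting")

values = nonrej["FGFBP2"].to_numpy()
fit = stepminer_threshold(values)
high = dichotomize(values, fit)
print(f"\nstep fit: threshold {fit.threshold:.2f} "
      f"(levels {fit.level_low:.2f} / {fit.level_high:.2f}); "
      f"high n = {int(high.sum())}, low n = {int((~high).sum())}")

curves, stat, p = km_logrank(nonrej["time"], nonrej["event"],
                             np.where(high, "high", "low"))
t = float(np.median(nonrej["time"]))
print(f"log-rank chi2 = {stat:.2f}, p = {p:.2g}")
print(f"survival at median follow-up ({t:.1f} months): "
      f"high {curves['high'].survival_function_at_times(t).item():.2f}, "
      f"low {curves['low'].survival_function_at_times(t).item():.2f}")

print("\nCox model with FGFBP2, IFNG and LAMP1 expression (per unit log2):")
print(cox_multigene(table).round(3).to_string(index=False))
# only FGFBP2 carries hazard in the generator; IFNG/LAMP1 HRs near 1 show
# its effect is independent of the other two genes

print("\nFGFBP2 by rejection class vs non-rejection (rank-sum, Bonferroni):")
for res in group_compare(table, "FGFBP2"):
    print(f"  {res.grouping:<24} n = {res.n_pairs:3d}  "
          f"p_adj = {res.p_bonferroni:.2g}")
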