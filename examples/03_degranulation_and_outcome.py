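"""Donor-induced degranulation and graft-function association, end to end.

Simulates a small cohort (genotypes -> education -> baseline and
donor-stimulated events), measures the Ksp37 degranulation delta among
total NK cells, generates eGFR outcomes driven by that delta and fits the
correlation and the covariate-adjusted linear model.
"""

import logging

from nkgraft import pipeline, simulate

logging.disable(logging.WARNING)

config = simulate.SimulationConfig()
result = pipeline.run_synthetic_study(config, seed=11, n_subjects=40)

print(f"cohort: {result['n_subjects']} recipients; "
      f"Bw4-loss pair rate {result['bw4_loss_rate']:.2f}")
print(f"Ksp37 delta vs 2-year eGFR: Pearson r = {result['pearson_r']:.3f} "
      f"(p = {result['pearson_p']:.2g})")
print(f"screened covariates: {result['screened_covariates']}")
print(f"adjusted slope = {result['adjusted_beta']:.2f} eGFR per "
      f"percentage point (p = {result['adjusted_p']:.2g}); "
      "the generator's slope is -1.5")

print("\nmean donor-induced CD107a delta per subset (percentage points):")
for subset, mean in sorted(result["cd107a_subset_means"].items()):
    print(f"  {subset:<18} {mean:+5.1f}")
# NKG2A+KIR+ subsets carry the most educated receptors and respond most;
# NKG2A-KIR- subsets are uneducated and respond least.  Ksp37 moves the
# other way (release), and its per-subject delta tracks worse graft
# function through the planted negative slope.
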