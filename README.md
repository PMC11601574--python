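# nkgraft

NK-cell immunogenetics and CyTOF repertoire analysis linked to
kidney-allograft outcomes.

Natural killer (NK) cells are tuned ("educated") by inhibitory
receptor–ligand interactions between KIR/NKG2A receptors and class I HLA
epitopes (Bw4, C1, C2, A3/A11, HLA-E). In kidney transplantation, a donor
organ that encodes fewer copies of a recipient's educating ligand —
missing self, here *Bw4 loss* — releases the recipient's educated NK cells
from inhibition, and their stimulation-induced degranulation tracks graft
function even without donor-specific antibody. `nkgraft` implements that
analysis chain for immunologists and transplant researchers:

- **immunogenetics** — HLA allele → KIR-ligand epitope mapping (bundled
  motif table), per-receptor education assignment, donor/recipient Bw4
  missing-self calls.
- **cytometry** — arcsinh transform (cofactor 5), the manual-style NK gate
  chain (viable CD3− CD14− CD19− HLA-DR^dim/− CD56+ CD16+), Boolean
  partition into the 8 CD57/NKG2A/KIR subsets, a 2000-event cap per
  sample × condition, subset × marker frequency tables.
- **diversity** — inverse Simpson index D = 1/Σ pᵢ² over Boolean
  phenotype combinations, per marker-positive population.
- **alloreactivity** — degranulation scores (stimulated − baseline
  percent positive; negative Ksp37 deltas mean release), paired Wilcoxon
  with Bonferroni, receptor-blockade contrasts.
- **outcomes** — eGFR = 10 imputation at graft failure, Pearson
  correlation, univariate covariate screening at P < 0.1 with an
  always-include clinical list, covariate-adjusted OLS.
- **transcript_survival** — StepMiner-style step-fit dichotomization of
  intragraft expression (minimize the SSE of a fitted two-level step over
  all sorted splits; threshold = midpoint of segment means), Kaplan-Meier
  + log-rank, multi-gene Cox, rejection-class rank-sum comparisons, GEO
  series-matrix ingestion with probe→gene collapse.
- **simulate** — a synthetic-cohort generator for every input kind:
  paired genotypes with a configurable Bw4-loss rate, bimodal event
  tables with education-scaled stimulation effects, a linear eGFR model
  driven by the Ksp37 delta, and step-structured expression tied to
  graft-loss hazard.

Clinical transplant cohorts with paired genotypes, stimulation cytometry
and outcomes are not publicly available, so the synthetic generator is a
first-class module: it defines the study conditions under which the whole
pipeline is exercised and verified. See `docs/methods.md` for models, parameters and limitations.

## Worked example

`examples/03_degranulation_and_outcome.py` runs a 40-recipient synthetic
cohort end to end — genotypes → education → baseline and donor-stimulated
events → gating → Ksp37 degranulation among total NK cells → eGFR
association:

```
cohort: 40 recipients; Bw4-loss pair rate 0.23
Ksp37 delta vs 2-year eGFR: Pearson r = -0.254 (p = 0.11)
screened covariates: ['delayed_graft_function', 'thymoglobulin', 'acute_rejection']
adjusted slope = -2.13 eGFR per percentage point (p = 0.058); the generator's slope is -1.5

mean donor-induced CD107a delta per subset (percentage points):
  CD57+NKG2A+KIR+    +13.7
  CD57+NKG2A+KIR-     +7.9
  CD57+NKG2A-KIR+     +9.7
  CD57+NKG2A-KIR-     +5.5
  CD57-NKG2A+KIR+    +14.2
  CD57-NKG2A+KIR-     +9.4
  CD57-NKG2A-KIR+     +9.9
  CD57-NKG2A-KIR-     +5.1
```

Reading it: more Ksp37 release (a more negative delta) goes with lower
2-year eGFR, and the adjusted regression recovers the generator's planted
slope of −1.5 eGFR per percentage point within its confidence interval.
The CD107a panel shows the education gradient — NKG2A+KIR+ subsets carry
the most educated receptors and respond most to donor stimulation,
NKG2A−KIR− least. The other examples cover education/missing-self calls,
gating + diversity, and the expression–survival analysis.

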