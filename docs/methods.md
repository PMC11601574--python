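# Methods

`nkgraft` implements an analysis pipeline linking NK-cell immunogenetics
and donor-stimulated NK functional responses to kidney-allograft outcomes,
together with a synthetic-cohort generator that emulates every input the
pipeline consumes. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
show.

## Immunogenetics

Inhibitory receptor–ligand pairs: KIR3DL1–Bw4, KIR2DL1–C2, KIR2DL2/L3–C1,
KIR3DL2–A3/A11, NKG2A–HLA-E. A receptor is *educated* when its gene is
present and its cognate ligand is encoded in the subject's class I HLA
genotype. NKG2A is treated as always educated because HLA-E is expressed
near-ubiquitously; `assign_education(..., include_nkg2a=False)` turns this
off. KIR2DL2 and KIR2DL3 are merged into one receptor label ("KIR2DL2/L3")
since they share the C1 ligand.

The allele→epitope table ships as a versioned CSV
(`nkgraft/data/kir_ligand_epitopes.csv`) built from the published epitope
motifs: the Bw4/Bw6 dimorphism at residues 77–83 of HLA-B (with the
exceptions B\*27:08→Bw6 and the Bw4-motif B\*15 variants), the residue-80
C1/C2 dimorphism of HLA-C (exception C\*16:02→C2), the Bw4-bearing HLA-A
allotypes A\*23/A\*24/A\*32, and the KIR3DL2 epitope on A\*03/A\*11.
Lookups try the 2-field allele first and fall back to the 1-field group
with a one-time logged warning. The rare C1-bearing HLA-B alleles
(B\*46:01, B\*73:01) are counted in a separate `b_c1_copies` field so that
the HLA-C partition invariant (`c1_copies + c2_copies = 2`) stays exact;
KIR2DL2/L3 education uses the total C1 count (`c1_copies + b_c1_copies`),
because the B-derived epitope is a genuine ligand. Which HLA-A alleles to
count as Bw4 is genuinely open in the field; the A\*23/A\*24/A\*32 default
is configurable by editing/supplying the epitope table.

**Bw4 missing-self.** A donor/recipient pair is `BW4_LOSS` iff the
recipient carries ≥1 Bw4 copy (counted over HLA-B and HLA-A), expresses
KIR3DL1, and the donor carries strictly fewer Bw4 copies. Everything else
— donor with equal or more copies, or recipient lacking KIR3DL1 — is
`NO_LOSS`.

## Cytometry

Raw intensities are variance-stabilized with `asinh(x / 5)`, the standard
mass-cytometry cofactor. The NK gate is the conjunction viable · CD3− ·
CD14− · CD19− · HLA-DR^dim/− · CD56+ · CD16+; HLA-DR^dim/− is a single
upper cut, not a two-sided window, and an optional NKG2C− atom supports
education-focused gating. Gates are expression trees of
(channel, comparator, threshold) atoms with and/or/not composition, so the
default chain is reproducible and editable.

**Positivity thresholds** live on the transformed scale and are normally
supplied by the analyst. The automated default fits a two-component 1-D
Gaussian mixture per channel and places the cut at the posterior crossing
between the component means (the valley). When the two components are
separated by less than 2 pooled SDs the channel is treated as unimodal —
viability when every event is live, a marker nobody expresses — and the
cut is placed 4 SDs beyond the cloud, on the side implied by the cloud's
position relative to `asinh(1)` (i.e. one cofactor of raw intensity). This
guard exists because a 2-component mixture will happily split a single
cloud in half. These defaults keep the pipeline runnable end to end; no
downstream conclusion in the test suite depends on an absolute threshold
value.

**Boolean subsets.** The canonical partition is over (CD57, NKG2A, KIR),
giving 8 subsets; "KIR+" is the disjunction over the KIR3DL1, KIR3DL2,
KIR2DL1, KIR2DL3 channels and is computed before partitioning so the
label space stays small. Labels encode sign per marker in input order
(`CD57-NKG2A+KIR+`). Per-subset percent-positive for functional markers
is tabulated per sample × condition; an empty subset yields a missing
percentage, never 0/0, and missingness propagates through downstream
statistics.

**Subsampling.** Events are capped at 2000 per sample × condition by
uniform sampling without replacement, deterministic given a seed; groups
at or under the cap are kept whole.

## Repertoire diversity

For marker *m* in a panel, the conditioning population is the *m*-positive
events and richness is over the +/− Boolean combinations of the remaining
panel markers; the score is the plug-in inverse Simpson index
D = 1/Σ pᵢ². Conditioning on all events instead is available via
`condition_on_positive=False`. No small-sample bias correction is applied
(plain plug-in estimator, common practice); the subsampling-consistency
test documents the resulting downward bias shrinking with n.

## Alloreactivity and outcomes

The degranulation score is percent positive under stimulation minus
percent positive at baseline, in percentage points; for Ksp37 — lost from
the cell on degranulation — negative deltas indicate release, and the sign
is preserved (no absolute value). Paired subset/timepoint comparisons use
the two-sided Wilcoxon signed-rank test with `zero_method="zsplit"` (so
identical vectors land at the null center with p = 1) and Bonferroni
correction across an explicitly declared family: the family is exactly the
set of comparisons passed in one call, since figure-panel family
boundaries are an analyst choice. Blockade contrasts (blocked − isotype)
reuse the same machinery.

Graft failure at a timepoint is handled by assigning eGFR = 10 mL/min
before any association. Association is Pearson correlation on complete
cases (≥3 pairs; zero-variance inputs are flagged untestable, not forced),
then OLS of eGFR on the score plus screened covariates. The univariate
screen admits covariates at P < 0.1 — Pearson for numeric, Welch t for
binary, constants excluded — and always appends thymoglobulin induction,
acute rejection and delayed graft function when present, reflecting prior
outcome studies. Missing covariates mean complete-case analysis; the only
imputation anywhere is the eGFR = 10 rule. Rank-deficient designs raise an
error naming the collinear columns rather than silently dropping them.

## Transcript survival

**Step fit.** Expression values are sorted; for every split k ∈ 1..n−1 the
two segment means are fitted and the SSE computed (O(n) via prefix sums);
the argmin split wins, ties going to the smallest k, and the threshold is
the midpoint of the two segment means. Values strictly above the
threshold are "high"; a value exactly at the threshold is "low". The
original StepMiner's ±0.5-margin "intermediate" class is deliberately
omitted — the analysis needs only a high/low dichotomy. Constant input is
a degenerate-fit error for the caller to resolve. Numerical note: with
flat segments several splits can tie in exact arithmetic while differing
by float epsilon between algebraically equivalent SSE forms; the oracle
tests therefore identify the split only when the minimizer is unique at
1e-10.

Survival uses lifelines: Kaplan-Meier product-limit curves per expression
group, the log-rank test between them, and a Cox proportional-hazards
model with FGFBP2, IFNG and LAMP1 expression as simultaneous covariates to
test independence of the FGFBP2 effect. Note the Cox coefficients are per
unit of (log-scale) expression, not per high/low group.

**GEO ingestion.** `load_series_matrix` parses the series-matrix text
format (header of `!`-prefixed sample annotations, then a probes × samples
matrix between `table_begin`/`table_end` markers) with line-numbered parse
errors. Probe→gene collapse defaults to keeping the probe with the highest
mean expression; a `mean` rule averages instead. The collapse rule
materially affects any reproduction of published group sizes and is
therefore explicit in the API.

## Synthetic cohort

The generator emulates the study conditions, not CyTOF physics:

- **Genotypes.** Allele pools at 2-field resolution with
  European-weighted frequencies (Bw4-motif alleles ≈40% of HLA-B mass,
  C1/C2 ≈57/43); KIR gene carrier frequencies 0.95/1.0/0.97/0.55/0.90 for
  3DL1/3DL2/2DL1/2DL2/2DL3. Pairs are assigned loss/no-loss at
  `bw4_loss_rate` (default 0.25, matching the typed-cohort prevalence of
  roughly a quarter of pairs) and genotypes are rejection-sampled to
  realize the assignment, so the observed rate is binomially consistent
  with the configured one.
- **Events.** 2000 events per sample × condition (the analysis cap), a
  3% contaminant fraction (T/B/monocyte events that the gate removes),
  subset composition over the 8 CD57/NKG2A/KIR classes, and two-mode
  lognormal intensities per channel (raw medians 0.5 / 150, log-SD 0.6) —
  the simplest model producing cleanly gateable bimodality. Under
  stimulation, activation-marker positivity rises (and Ksp37 positivity
  falls) by 0.05 plus 0.04 per educated receptor the event expresses;
  receptor blockade multiplies the effect by 0.3, K562 targets by 1.2,
  HLA-E–transduced K562 attenuates NKG2A+ cells to 0.4 of that. The
  per-event education count uses NKG2A (when educated) plus each expressed
  educated KIR channel.
- **Outcomes.** eGFR = 60 − 1.5·(Ksp37 delta) + covariate effects +
  N(0, 10²) at the 2-year timepoint; latent values below 15 mL/min are
  flagged as graft failures (the eGFR = 10 imputation happens downstream,
  in the analysis, as it would with real data). Covariates are drawn with
  realistic marginals (e.g. living donor 50%, rejection 15%, DGF 20%,
  mismatch ~ Binomial(6, 0.5)).
- **Expression/survival.** FGFBP2 is a two-level step mixture (levels
  6.0/8.5 on a log2-like scale, SD 0.5, high fraction 0.15); graft-loss
  times are exponential with hazard 0.05/month × exp(1.1) for high
  expressors; exponential censoring is calibrated so the expected censored
  fraction is 0.3; rejection classes (non-rejection 73%, TCMR 12%, ABMR
  8%, mixed 3%, acute 4%) shift all three genes up by 1.0. IFNG and LAMP1
  carry no hazard.

Every generator is a pure function of (config, seed); identical seeds give
byte-identical tables.

**What the synthetic data do not show.** Intensities are independent
two-mode lognormals — no spillover, acquisition drift, doublets, or
correlated marker modules; subset composition is exchangeable across
subjects rather than individually stable; the outcome model is exactly
linear with Gaussian noise. Passing tests therefore demonstrate that the
pipeline recovers planted structure under its own assumptions, not that
the biological effect sizes are as stated; clinical cohorts with paired
genotypes, stimulation cytometry and outcomes are not publicly available,
so no test asserts clinical numbers.

## Problem sizes and design choices

The verification suite runs oracle equivalence for the step fit on 1000
random vectors (n ≤ 50, tolerance 1e-10) and for the diversity index on
panels of ≤ 4 markers and ≤ 100 events (tolerance 1e-12); rule truth
tables exhaustively over ligand × gene-presence grids; planted-slope
recovery with β = −1.5, σ = 10, n = 50 over 200 seeds; null calibration
with 2000 correlation replicates and 500 log-rank replicates; and the
education-ordering check over 200 simulated cohorts of 8 subjects with
2000 events per sample × condition — sizes chosen to give stable rates
while keeping a full run in minutes on one CPU. Cohort-level examples use
40–70 subjects, mirroring the discovery-cohort scale.

The package is a library: the importable API plus `examples/` scripts are
the interface, and `scripts/acceptance.py` reproduces the headline
quantities; no shell CLI is provided because the pipeline is driven from
Python in practice. FCS ingestion is out of scope; event tables arrive as
CSV/Parquet in the documented schema.
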