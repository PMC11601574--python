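"""End-to-end synthetic study: genotypes -> events -> scores -> outcomes.

Convenience driver used by the examples and the reproduction script; each
step is the public API of the corresponding module, so this is also a
worked recipe for assembling the pipeline on real inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import alloreactivity, cytometry, immunogenetics, outcomes, simulate


def derive_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) from one master seed."""
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def cohort_education(config: simulate.SimulationConfig, seed: int,
                     n: int | None = None):
    """Genotypes plus per-recipient education and Bw4-loss calls."""
    rec_hla, rec_kir, don_hla = simulate.simulate_genotypes(config, seed, n)
    table = immunogenetics.load_epitope_table()
    educations, calls = [], []
    for hla, kir, donor in zip(rec_hla, rec_kir, don_hla):
        prof = immunogenetics.ligand_profile(hla, table)
        educations.append(immunogenetics.assign_education(prof, kir))
        calls.append(immunogenetics.call_bw4_loss(
            prof, kir, immunogenetics.ligand_profile(donor, table)))
    return rec_hla, rec_kir, don_hla, educations, calls


def measure_degranulation(subjects, educations,
                          config: simulate.SimulationConfig, seed: int,
                          markers=("CD107a", "Ksp37"),
                          subset_markers=("CD57", "NKG2A", "KIR"),
                          n_max: int = 2000) -> pd.DataFrame:
    """Simulate baseline + donor-stimulation events for a cohort and return
    the per-subject stimulated-minus-baseline deltas.

    Output: one row per (subject, subset, marker) with delta_pct, plus the
    total-NK delta under subset label "all".
    """
    events = simulate.simulate_cohort_events(
        subjects, educations, ("baseline", "donor_stim"), config, seed)
    events = cytometry.transform_events(events)
    thresholds = cytometry.estimate_thresholds(events)
    nk = cytometry.gate_nk(events, cytometry.default_nk_gate(thresholds))
    nk = cytometry.subsample_events(nk, n_max=n_max, seed=seed)

    rows = []
    for label_markers, parent in (((), "NK"), (subset_markers, "NK")):
        labels = cytometry.boolean_partition(nk, label_markers, thresholds)
        freqs = cytometry.subset_frequencies(nk, labels, markers, thresholds,
                                             parent=parent)
        for subset in labels.unique():
            for marker in markers:
                for s in alloreactivity.donor_induced_change(
                        freqs, marker, subset):
                    rows.append(s.__dict__)
    return pd.DataFrame(rows)


def run_synthetic_study(config: simulate.SimulationConfig, seed: int,
                        n_subjects: int | None = None) -> dict:
    """Full pipeline on one synthetic cohort.

    Returns the Ksp37-vs-eGFR correlation (total NK cells), the
    covariate-adjusted slope, the Bw4-loss rate, and the per-subset CD107a
    response ordering.
    """
    seeds = derive_seeds(seed, 3)
    rec_hla, rec_kir, _, educations, calls = cohort_education(
        config, seeds[0], n_subjects)
    subjects = [h.subject_id for h in rec_hla]
    deltas = measure_degranulation(subjects, educations, config, seeds[1])

    ksp37 = deltas[(deltas["marker"] == "Ksp37") & (deltas["subset"] == "all")]
    score_map = dict(zip(ksp37["subject_id"], ksp37["delta_pct"]))
    records = simulate.simulate_outcomes(
        subjects, [score_map.get(s, np.nan) for s in subjects],
        config, seeds[2])
    tp = config.outcome_timepoint
    corr = outcomes.correlate(score_map, records, tp, predictor="Ksp37_delta")
    screened = outcomes.covariate_screen(records, tp)
    adj = outcomes.adjusted_model(score_map, records, tp, screened,
                                  predictor="Ksp37_delta")

    cd107a = deltas[(deltas["marker"] == "CD107a") & (deltas["subset"] != "all")]
    subset_means = cd107a.groupby("subset")["delta_pct"].mean()
    loss_rate = float(np.mean([c.category.value == "BW4_LOSS" for c in calls]))
    return {
        "n_subjects": len(subjects),
        "bw4_loss_rate": loss_rate,
        "pearson_r": corr.pearson_r,
        "pearson_p": corr.p_value,
        "adjusted_beta": adj.adjusted_coef,
        "adjusted_p": adj.adjusted_p,
        "screened_covariates": screened,
        "cd107a_subset_means": subset_means.to_dict(),
        "deltas": deltas,
        "records": records,
    }
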