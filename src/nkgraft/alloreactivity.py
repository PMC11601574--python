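"""Donor-induced NK functional responses per Boolean subset.

The degranulation score for a functional marker in a subset is the percent
positive under stimulation (donor B-cell coculture) minus percent positive
at baseline (PBMC only), in percentage points.  For activation markers
(CD107a, IFN-g, XCL1) positive deltas indicate response; for Ksp37, which
is lost from the cell on degranulation, *negative* deltas indicate release.

Subset and timepoint comparisons use the paired two-sided Wilcoxon
signed-rank test with Bonferroni correction across an explicitly declared
comparison family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegranulationScore:
    """Stimulated-minus-baseline percent positive, one subject/subset/marker."""

    subject_id: str
    subset: str
    marker: str
    timepoint: str
    delta_pct: float

    def __post_init__(self) -> None:
        if not -100.0 <= self.delta_pct <= 100.0:
            raise ValueError(f"delta_pct out of range: {self.delta_pct}")


@dataclass(frozen=True)
class ComparisonResult:
    grouping: str
    statistic: float | None
    p_raw: float | None
    p_bonferroni: float | None
    n_pairs: int
    untestable: bool = False


def donor_induced_change(freqs: pd.DataFrame, marker: str, subset: str,
                         stim_condition: str = "donor_stim",
                         base_condition: str = "baseline"
                         ) -> list[DegranulationScore]:
    """Per-subject delta_pct for one marker in one subset.

    ``freqs`` is a subset-frequency table (see
    :func:`nkgraft.cytometry.subset_frequencies`).  Subjects missing either
    condition, or with an empty subset (missing percent), are omitted with a
    logged count.
    """
    sel = freqs[(freqs["marker"] == marker) & (freqs["subset"] == subset)]
    if sel.empty:
        known_subsets = freqs["subset"].unique()
        known_markers = freqs["marker"].unique()
        if subset not in known_subsets and marker not in known_markers:
            raise KeyError(f"unknown subset {subset!r} and marker {marker!r}")
        if subset not in known_subsets:
            raise KeyError(f"unknown subset: {subset!r}")
        if marker not in known_markers:
            raise KeyError(f"unknown marker: {marker!r}")
    wide = sel.pivot_table(index=["sample_id", "timepoint"],
                           columns="condition", values="pct_positive",
                           aggfunc="first")
    scores: list[DegranulationScore] = []
    n_missing = 0
    for (sid, tp), row in wide.iterrows():
        stim = row.get(stim_condition)
        base = row.get(base_condition)
        if pd.isna(stim) or pd.isna(base):
            n_missing += 1
            continue
        scores.append(DegranulationScore(subject_id=str(sid), subset=subset,
                                         marker=marker, timepoint=str(tp),
                                         delta_pct=float(stim - base)))
    if n_missing:
        logger.info("donor_induced_change(%s, %s): %d subject-timepoints "
                    "missing a condition, omitted", marker, subset, n_missing)
    return scores


def scores_frame(scores: Sequence[DegranulationScore]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in scores])


def paired_subset_comparison(pairs: dict[str, tuple[np.ndarray, np.ndarray]]
                             ) -> list[ComparisonResult]:
    """Two-sided Wilcoxon signed-rank per comparison, Bonferroni across the
    declared family.

    ``pairs`` maps a comparison label to two aligned per-subject vectors
    (the declared family is exactly the dict's keys).  Comparisons with
    fewer than 2 complete pairs, or with all-zero differences, are flagged
    untestable.
    """
    k = len(pairs)
    results: list[ComparisonResult] = []
    for label, (a, b) in pairs.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        n = len(a)
        if n < 2:
            results.append(ComparisonResult(label, None, None, None, n,
                                            untestable=True))
            continue
        # zsplit keeps zero differences, so identical vectors land at the
        # null center with p = 1 instead of erroring out
        stat, p = stats.wilcoxon(a, b, alternative="two-sided",
                                 zero_method="zsplit")
        results.append(ComparisonResult(label, float(stat), float(p),
                                        min(1.0, float(p) * k), n))
    return results


def blockade_contrast(freqs: pd.DataFrame, marker: str = "CD107a",
                      subset: str | None = None,
                      blocked_condition: str = "blocked",
                      isotype_condition: str = "isotype"
                      ) -> list[DegranulationScore]:
    """Per-subject change in percent positive under receptor blockade,
    sign convention blocked - isotype (negative = response abrogated).

    Reuses the donor-induced-change machinery with the blockade condition
    pair.  ``subset=None`` contrasts every subset present.
    """
    subsets = [subset] if subset is not None else sorted(freqs["subset"].unique())
    out: list[DegranulationScore] = []
    for s in subsets:
        out.extend(donor_induced_change(freqs, marker, s,
                                        stim_condition=blocked_condition,
                                        base_condition=isotype_condition))
    return out
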