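"""Boolean-phenotype repertoire diversity (inverse Simpson index).

Boolean gating over a large antibody panel assigns each NK cell one of
2^k +/- phenotype combinations.  The inverse Simpson index
D = 1 / sum_i p_i^2 over the observed combination proportions is the
effective number of equally abundant phenotypes: D = 1 when all cells share
one phenotype and D = k for a uniform spread over k phenotypes.

Per-marker scores condition on the marker-positive population: for marker
m, events positive for m are kept and richness is computed over the +/-
combinations of the remaining panel markers.  Highly prevalent markers
(CD56) therefore score high and rare activation markers (IFN-g) score low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytometry import EventTable, positivity_matrix


@dataclass(frozen=True)
class DiversityScore:
    sample_id: str
    marker: str
    inverse_simpson: float | None
    n_phenotypes_observed: int
    n_events_used: int


def inverse_simpson(counts) -> float:
    """D = 1 / sum p_i^2 for a vector of combination counts."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no observations")
    p = counts / counts.sum()
    return float(1.0 / np.sum(p * p))


def enumerate_phenotypes(events: EventTable, panel: Sequence[str],
                         thresholds: Mapping[str, float],
                         mask: np.ndarray | None = None) -> pd.Series:
    """Counts over the observed +/- combinations of the panel markers.

    Unobserved combinations are omitted.  ``mask`` optionally restricts the
    events (used for per-marker conditioning).
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    pos = positivity_matrix(events, panel, thresholds)
    if mask is not None:
        pos = pos[mask]
    if pos.shape[0] == 0:
        return pd.Series(dtype=int)
    # pack the boolean phenotype into a tuple key per event
    keys = pd.Series([tuple(row) for row in pos])
    counts = keys.value_counts()
    counts.index = ["".join("+" if s else "-" for s in key)
                    for key in counts.index]
    return counts


def inverse_simpson_per_marker(events: EventTable, panel: Sequence[str],
                               thresholds: Mapping[str, float],
                               sample_id: str | None = None,
                               *, condition_on_positive: bool = True
                               ) -> list[DiversityScore]:
    """Per-marker inverse Simpson diversity scores.

    For each marker m in the panel: restrict to events positive for m
    (unless ``condition_on_positive`` is False, in which case all events are
    used), enumerate Boolean combinations of the remaining markers and
    return D = 1 / sum p_i^2.  Markers with zero positive events yield a
    missing score.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    pos = positivity_matrix(events, panel, thresholds)
    if sample_id is None:
        ids = events.data["sample_id"].unique()
        sample_id = str(ids[0]) if len(ids) == 1 else "pooled"
    scores: list[DiversityScore] = []
    for j, marker in enumerate(panel):
        rest = [m for i, m in enumerate(panel) if i != j]
        mask = pos[:, j] if condition_on_positive else None
        n_used = int(pos[:, j].sum()) if condition_on_positive else pos.shape[0]
        if n_used == 0:
            scores.append(DiversityScore(sample_id, marker, None, 0, 0))
            continue
        if rest:
            counts = enumerate_phenotypes(events, rest, thresholds, mask=mask)
            d = inverse_simpson(counts.to_numpy())
            n_pheno = int(len(counts))
        else:
            d, n_pheno = 1.0, 1  # single-marker panel: one conditioned class
        scores.append(DiversityScore(sample_id, marker, d, n_pheno, n_used))
    return scores


def diversity_frame(scores: Sequence[DiversityScore]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in scores])
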