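"""Mass-cytometry event processing: transform, gate, partition, tabulate.

Raw CyTOF intensities are arcsinh-transformed (cofactor 5), NK cells are
selected by a conjunctive manual-style gate chain
(viable CD3- CD14- CD19- HLA-DRdim/- CD56+ CD16+), Boolean gating splits NK
cells into all +/- combinations of a marker set (CD57, NKG2A, KIR gives the
8 canonical subsets), events are capped at 2000 per sample x condition, and
percent-positive frequencies are tabulated per subset and functional marker.

Positivity thresholds live on the transformed scale.  When no threshold is
supplied, a per-channel default is estimated by a two-component Gaussian
mixture on pooled baseline events (the valley between the negative and
positive modes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

#: metadata columns every event table carries alongside channel columns
METADATA_COLUMNS = ("sample_id", "condition", "timepoint")

CONDITIONS = ("baseline", "donor_stim", "k562", "k562_hlaE", "isotype", "blocked")
TIMEPOINTS = ("pre", "m6", "m12", "m18")

#: channels whose disjunction defines the aggregate "KIR+" phenotype
KIR_CHANNELS = ("KIR3DL1", "KIR3DL2", "KIR2DL1", "KIR2DL3")


class SchemaError(KeyError):
    """A referenced channel or marker is missing from the event table."""


@dataclass(frozen=True)
class EventTable:
    """Single-cell events x channels with per-event sample metadata.

    ``data`` holds the metadata columns plus one column per channel; raw
    intensities are non-negative.  ``transformed`` records whether channel
    columns are on the arcsinh scale.
    """

    data: pd.DataFrame
    channels: tuple[str, ...]
    transformed: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        missing = [c for c in self.channels if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing channel columns: {missing}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    def __len__(self) -> int:
        return len(self.data)

    def require_channels(self, channels: Iterable[str]) -> None:
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise SchemaError(f"channels not in panel: {missing}")

    def intensities(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise SchemaError(f"channel not in panel: {channel}")
        return self.data[channel].to_numpy()


def arcsinh_transform(values, cofactor: float = 5.0):
    """Elementwise asinh(x / cofactor); the standard CyTOF variance
    stabilizer.  Strictly monotone and invertible
    (:func:`arcsinh_inverse`)."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def arcsinh_inverse(values, cofactor: float = 5.0):
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.sinh(np.asarray(values, dtype=float)) * cofactor


def transform_events(events: EventTable, cofactor: float = 5.0) -> EventTable:
    """Return a copy of the table with all channel columns arcsinh-transformed."""
    if events.transformed:
        return events
    data = events.data.copy()
    data[list(events.channels)] = arcsinh_transform(
        data[list(events.channels)].to_numpy(), cofactor)
    return EventTable(data=data, channels=events.channels, transformed=True)


# ---------------------------------------------------------------------------
# gate expressions

@dataclass(frozen=True)
class GateAtom:
    """One threshold comparison on a transformed channel."""

    channel: str
    comparator: str  # ">" or "<"
    threshold: float

    def evaluate(self, events: EventTable) -> np.ndarray:
        x = events.intensities(self.channel)
        if self.comparator == ">":
            return x > self.threshold
        if self.comparator == "<":
            return x < self.threshold
        raise ValueError(f"unknown comparator {self.comparator!r}")


@dataclass(frozen=True)
class GateExpr:
    """Boolean composition of gate atoms (and/or/not)."""

    op: str  # "and" | "or" | "not"
    terms: tuple

    def evaluate(self, events: EventTable) -> np.ndarray:
        masks = [t.evaluate(events) for t in self.terms]
        if self.op == "and":
            out = masks[0]
            for m in masks[1:]:
                out = out & m
            return out
        if self.op == "or":
            out = masks[0]
            for m in masks[1:]:
                out = out | m
            return out
        if self.op == "not":
            (m,) = masks
            return ~m
        raise ValueError(f"unknown op {self.op!r}")


def gate_and(*terms) -> GateExpr:
    return GateExpr(op="and", terms=tuple(terms))


def gate_or(*terms) -> GateExpr:
    return GateExpr(op="or", terms=tuple(terms))


def gate_not(term) -> GateExpr:
    return GateExpr(op="not", terms=(term,))


def estimate_thresholds(events: EventTable,
                        channels: Sequence[str] | None = None,
                        *, random_state: int = 0) -> dict[str, float]:
    """Default positivity thresholds on the transformed scale.

    Fits a two-component 1-D Gaussian mixture per channel on pooled events
    and places the cut at the point between the two component means where
    the weighted densities cross (the valley).  Falls back to the midpoint
    of the means if no crossing lies between them.

    Channels without real bimodality (component separation under 2 pooled
    SDs — e.g. viability when every event is live, or a marker nobody
    expresses) get a one-sided cut 4 SDs away from the single cloud, on the
    side implied by the cloud's position relative to asinh(1) (raw
    intensity of one cofactor): a high cloud is all-positive, a low cloud
    all-negative.
    """
    events = transform_events(events)
    if channels is None:
        channels = events.channels
    events.require_channels(channels)
    thresholds: dict[str, float] = {}
    for ch in channels:
        x = events.intensities(ch).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, random_state=random_state,
                             n_init=3).fit(x)
        means = gm.means_.ravel()
        order = np.argsort(means)
        lo, hi = means[order]
        pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
        if hi - lo < 2.0 * pooled_sd:
            m, s = float(x.mean()), float(x.std())
            thresholds[ch] = m - 4.0 * s if m > np.arcsinh(1.0) else m + 4.0 * s
            continue
        grid = np.linspace(lo, hi, 512)
        post = gm.predict_proba(grid.reshape(-1, 1))[:, order[1]]
        crossing = np.nonzero(post >= 0.5)[0]
        thresholds[ch] = float(grid[crossing[0]]) if crossing.size else float((lo + hi) / 2)
    return thresholds


def default_nk_gate(thresholds: Mapping[str, float],
                    *, exclude_nkg2c: bool = False) -> GateExpr:
    """The manual-style NK gate chain:
    viable CD3- CD14- CD19- HLA-DRdim/- CD56+ CD16+.

    ``thresholds`` supplies per-channel cuts on the transformed scale;
    HLA-DRdim/- is a single upper cut.  ``exclude_nkg2c`` adds an NKG2C-
    atom for education-focused analyses.
    """
    atoms = [
        GateAtom("viability", ">", thresholds["viability"]),
        GateAtom("CD3", "<", thresholds["CD3"]),
        GateAtom("CD14", "<", thresholds["CD14"]),
        GateAtom("CD19", "<", thresholds["CD19"]),
        GateAtom("HLA-DR", "<", thresholds["HLA-DR"]),
        GateAtom("CD56", ">", thresholds["CD56"]),
        GateAtom("CD16", ">", thresholds["CD16"]),
    ]
    if exclude_nkg2c:
        atoms.append(GateAtom("NKG2C", "<", thresholds["NKG2C"]))
    return gate_and(*atoms)


def gate_nk(events: EventTable, gates: GateExpr) -> EventTable:
    """Apply a gate expression; returns the passing events with metadata
    preserved.  Idempotent for conjunctive gates."""
    events = transform_events(events)
    mask = gates.evaluate(events)
    return replace(events, data=events.data.loc[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Boolean partition and frequencies

def positivity_matrix(events: EventTable, markers: Sequence[str],
                      thresholds: Mapping[str, float]) -> np.ndarray:
    """Boolean events x markers matrix; the aggregate pseudo-marker "KIR"
    is the disjunction over the four KIR channels."""
    events = transform_events(events)
    cols = []
    for m in markers:
        if m == "KIR":
            events.require_channels(KIR_CHANNELS)
            kir = np.zeros(len(events), dtype=bool)
            for ch in KIR_CHANNELS:
                kir |= events.intensities(ch) > thresholds[ch]
            cols.append(kir)
        else:
            if m not in events.channels:
                raise SchemaError(f"unknown marker: {m}")
            cols.append(events.intensities(m) > thresholds[m])
    if not cols:
        return np.zeros((len(events), 0), dtype=bool)
    return np.column_stack(cols)


def subset_label(marker_signs: Sequence[bool], markers: Sequence[str]) -> str:
    """Label string encoding +/- per marker in input order, e.g.
    ``CD57-NKG2A+KIR+``."""
    return "".join(f"{m}{'+' if s else '-'}" for m, s in zip(markers, marker_signs))


def boolean_partition(events: EventTable, markers: Sequence[str],
                      thresholds: Mapping[str, float]) -> pd.Series:
    """Assign each event to one of the 2^k Boolean subsets of ``markers``.

    With markers (CD57, NKG2A, KIR) this yields the 8 canonical NK subsets.
    An empty marker list puts every event in a single "all" class.
    """
    if len(markers) == 0:
        return pd.Series(["all"] * len(events), index=events.data.index,
                         name="subset")
    pos = positivity_matrix(events, markers, thresholds)
    labels = [subset_label(row, markers) for row in pos]
    return pd.Series(labels, index=events.data.index, name="subset")


def all_subset_labels(markers: Sequence[str]) -> list[str]:
    """The complete 2^k label set, CD57-...- first (binary order, + = 1)."""
    if not markers:
        return ["all"]
    k = len(markers)
    out = []
    for code in range(2 ** k):
        signs = [(code >> (k - 1 - i)) & 1 == 1 for i in range(k)]
        out.append(subset_label(signs, markers))
    return out


def subsample_events(events: EventTable, n_max: int = 2000,
                     seed: int = 0) -> EventTable:
    """Cap events per (sample, condition) group by uniform sampling without
    replacement; groups at or under the cap are kept whole.  Deterministic
    given ``seed``."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.random.default_rng(seed)
    kept = []
    # sort groups for a stable draw order regardless of row order
    groups = events.data.groupby(["sample_id", "condition"], sort=True)
    for _, group in groups:
        if len(group) <= n_max:
            kept.append(group.index.to_numpy())
        else:
            kept.append(rng.choice(group.index.to_numpy(), size=n_max,
                                   replace=False))
    idx = np.concatenate(kept) if kept else np.array([], dtype=int)
    idx.sort()
    return replace(events, data=events.data.loc[idx].reset_index(drop=True))


def subset_frequencies(events: EventTable, labels: pd.Series,
                       functional_markers: Sequence[str],
                       thresholds: Mapping[str, float],
                       *, parent: str = "NK") -> pd.DataFrame:
    """Tabulate percent-positive per (sample, condition, subset, marker).

    Output rows carry: sample_id, condition, timepoint, subset, parent,
    marker, pct_positive (NaN for empty subsets, never 0/0), n_subset,
    n_parent, pct_of_parent.  Percentages of a complete partition sum to
    100 within one (sample, condition).
    """
    if len(labels) != len(events):
        raise ValueError("labels not aligned to events")
    pos = positivity_matrix(events, functional_markers, thresholds)
    meta = events.data[list(METADATA_COLUMNS)].copy()
    meta["subset"] = labels.to_numpy()
    for j, m in enumerate(functional_markers):
        meta[f"_pos_{m}"] = pos[:, j]

    rows = []
    for (sid, cond, tp), sample_group in meta.groupby(
            ["sample_id", "condition", "timepoint"], sort=True):
        n_parent = len(sample_group)
        for subset, sub in sample_group.groupby("subset", sort=True):
            n_subset = len(sub)
            for m in functional_markers:
                n_pos = int(sub[f"_pos_{m}"].sum())
                pct = 100.0 * n_pos / n_subset if n_subset else np.nan
                rows.append({
                    "sample_id": sid, "condition": cond, "timepoint": tp,
                    "subset": subset, "parent": parent, "marker": m,
                    "pct_positive": pct, "n_positive": n_pos,
                    "n_subset": n_subset, "n_parent": n_parent,
                    "pct_of_parent": 100.0 * n_subset / n_parent,
                })
    return pd.DataFrame(rows)


def read_event_csv(path, channels: Sequence[str]) -> EventTable:
    """Load a wide-format event CSV (metadata columns + channel columns)."""
    return EventTable(data=pd.read_csv(path), channels=tuple(channels))


def read_event_parquet(path, channels: Sequence[str]) -> EventTable:
    return EventTable(data=pd.read_parquet(path), channels=tuple(channels))
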