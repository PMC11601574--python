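"""Intragraft expression vs graft survival: step-fit dichotomization,
Kaplan-Meier/log-rank, multi-gene Cox, rejection-class comparisons.

Expression of a gene across biopsies is dichotomized by an adaptive
one-step regression (the StepMiner approach): values are sorted and, for
every split point, a two-level step (low-segment mean / high-segment mean)
is fitted; the split minimizing squared error wins and the threshold is the
midpoint of the two segment means.  High/low groups then enter a
Kaplan-Meier / log-rank comparison of time to graft loss, a multi-gene Cox
proportional-hazards model tests independence between genes, and rank-sum
tests with Bonferroni correction compare expression across histological
rejection classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .alloreactivity import ComparisonResult

logger = logging.getLogger(__name__)

REJECTION_CLASSES = ("non-rejection", "TCMR", "ABMR", "mixed", "acute")


@dataclass(frozen=True)
class StepFit:
    """Best two-level step fit of a sorted expression vector.

    ``step_index`` k means the k smallest values form the low segment.
    ``threshold`` is the midpoint of the segment means; SSE never exceeds
    the SSE of the constant one-level fit.
    """

    threshold: float
    step_index: int
    sse: float
    level_low: float
    level_high: float


class DegenerateFitError(ValueError):
    """All values equal: no step can be fitted."""


def stepminer_threshold(values) -> StepFit:
    """Adaptive one-step regression minimizing squared error.

    Sorts ascending and, for each split k in 1..n-1, fits the two segment
    means and computes the SSE; returns the argmin split (ties -> smallest
    k).  Requires n >= 4 and at least two distinct values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 values, got {n}")
    if np.all(x == x[0]):
        raise DegenerateFitError("all values equal; step fit is degenerate")
    # prefix sums give each split's SSE in O(1):
    # SSE(k) = (S2 - S1^2/n) - n*k/(n-k)/n * (mean_hi - mean_lo)^2 ... use
    # the direct form sum(x^2) - k*m_lo^2 - (n-k)*m_hi^2
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)
    total = csum[-1]
    total2 = csum2[-1]
    ks = np.arange(1, n)
    m_lo = csum[ks - 1] / ks
    m_hi = (total - csum[ks - 1]) / (n - ks)
    sse = total2 - ks * m_lo**2 - (n - ks) * m_hi**2
    best = int(np.argmin(sse))  # argmin returns the first (smallest k) tie
    k = int(ks[best])
    lo, hi = float(m_lo[best]), float(m_hi[best])
    return StepFit(threshold=(lo + hi) / 2.0, step_index=k,
                   sse=max(float(sse[best]), 0.0), level_low=lo, level_high=hi)


def dichotomize(values, fit: StepFit) -> np.ndarray:
    """Label values high (True) iff strictly above the fitted threshold.

    Values exactly at the threshold classify low.  Returns a boolean array
    aligned to ``values``.
    """
    return np.asarray(values, dtype=float) > fit.threshold


# ---------------------------------------------------------------------------
# survival analysis

def km_logrank(times, events, groups):
    """Product-limit curves per group plus the two-group log-rank test.

    Returns ``(curves, statistic, p)`` where ``curves`` maps group label ->
    fitted :class:`~lifelines.KaplanMeierFitter`.  Requires >= 2 nonempty
    groups; the log-rank statistic is the chi-square over all groups (for
    two groups this is the classical two-sample log-rank).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 nonempty groups for log-rank")
    curves = {}
    for lab in labels:
        m = groups == lab
        kmf = KaplanMeierFitter(label=str(lab))
        kmf.fit(times[m], event_observed=events[m])
        curves[lab] = kmf
    res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


def cox_multigene(table: pd.DataFrame,
                  genes: Sequence[str] = ("FGFBP2", "IFNG", "LAMP1"),
                  time_col: str = "time", event_col: str = "event"
                  ) -> pd.DataFrame:
    """Cox proportional-hazards fit with the gene expressions as covariates.

    Tests whether one gene's effect on graft loss is independent of the
    others.  Returns a frame with hazard ratio, 95% CI and p per gene.
    Warns (not fails) when complete cases < 10 x number of genes; raises on
    collinear covariates or non-convergence.
    """
    cols = [time_col, event_col, *genes]
    frame = table[cols].dropna().astype(float)
    n = len(frame)
    if n < 10 * len(genes):
        logger.warning("only %d complete cases for %d covariates "
                       "(guideline >= %d)", n, len(genes), 10 * len(genes))
    X = frame[list(genes)].to_numpy()
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(genes):
        raise np.linalg.LinAlgError(
            f"collinear expression covariates among {list(genes)}")
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col=time_col, event_col=event_col)
    except Exception as err:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    out = pd.DataFrame({
        "gene": list(genes),
        "log_hr": cph.params_[list(genes)].to_numpy(),
        "hr": np.exp(cph.params_[list(genes)].to_numpy()),
        "hr_ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0][list(genes)].to_numpy()),
        "hr_ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1][list(genes)].to_numpy()),
        "p": cph.summary.loc[list(genes), "p"].to_numpy(),
    })
    return out


def group_compare(table: pd.DataFrame, gene: str,
                  classes: Sequence[str] = REJECTION_CLASSES,
                  reference: str = "non-rejection",
                  class_col: str = "rejection_class") -> list[ComparisonResult]:
    """Rank-sum comparison of a gene's expression per rejection class vs the
    reference class, Bonferroni-corrected across the class family.

    Classes absent or with < 2 samples are skipped with a log message.
    """
    ref_vals = table.loc[table[class_col] == reference, gene].dropna().to_numpy()
    comparisons = []
    for cls in classes:
        if cls == reference:
            continue
        vals = table.loc[table[class_col] == cls, gene].dropna().to_numpy()
        if len(vals) < 2:
            logger.info("class %s has %d samples; skipped", cls, len(vals))
            continue
        comparisons.append((cls, vals))
    k = len(comparisons)
    results: list[ComparisonResult] = []
    for cls, vals in comparisons:
        if len(ref_vals) < 2:
            results.append(ComparisonResult(f"{cls} vs {reference}", None,
                                            None, None, 0, untestable=True))
            continue
        stat, p = stats.ranksums(vals, ref_vals)
        results.append(ComparisonResult(
            grouping=f"{cls} vs {reference}", statistic=float(stat),
            p_raw=float(p), p_bonferroni=min(1.0, float(p) * k),
            n_pairs=len(vals)))
    return results


# ---------------------------------------------------------------------------
# GEO series-matrix ingestion

class SeriesMatrixParseError(ValueError):
    """Malformed series-matrix file; message carries the line number."""


def load_series_matrix(path, platform_table: pd.DataFrame | None = None,
                       collapse_rule: str = "highest_mean"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GEO series-matrix text file.

    The format is a block of ``!key<TAB>value...`` sample annotations
    followed by a tab-separated expression matrix delimited by
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` (probes x
    samples, first column ``ID_REF``).

    ``platform_table`` optionally maps probes to gene symbols (columns
    ``probe``, ``gene``); multiple probes per gene collapse by
    ``collapse_rule`` ("highest_mean" keeps the probe with the highest mean
    expression, "mean" averages probes).

    Returns ``(expression, annotations)``: expression as samples x
    genes/probes, annotations as one row per sample with the
    ``!Sample_*`` header fields.
    """
    header: dict[str, list[str]] = {}
    matrix_lines: list[str] = []
    in_matrix = ended = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("!series_matrix_table_begin"):
                in_matrix = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_matrix = False
                ended = True
                continue
            if in_matrix:
                matrix_lines.append(line)
            elif line.startswith("!"):
                parts = line.split("\t")
                key = parts[0].lstrip("!")
                header[key] = [p.strip('"') for p in parts[1:]]
            else:
                raise SeriesMatrixParseError(
                    f"line {lineno}: unexpected content outside header/matrix")
    if not matrix_lines or not ended:
        raise SeriesMatrixParseError("truncated file: no complete "
                                     "series_matrix_table block")
    cols = [c.strip('"') for c in matrix_lines[0].split("\t")]
    if not cols or cols[0] != "ID_REF":
        raise SeriesMatrixParseError("matrix header must start with ID_REF")
    rows = []
    for i, line in enumerate(matrix_lines[1:], start=2):
        parts = [p.strip('"') for p in line.split("\t")]
        if len(parts) != len(cols):
            raise SeriesMatrixParseError(
                f"matrix line {i}: expected {len(cols)} fields, got {len(parts)}")
        rows.append(parts)
    mat = pd.DataFrame(rows, columns=cols).set_index("ID_REF").astype(float)
    expr = mat.T  # samples x probes
    expr.index.name = "sample_id"

    ann_fields = {k: v for k, v in header.items() if k.startswith("Sample_")}
    annotations = pd.DataFrame(ann_fields)
    if not annotations.empty:
        if "Sample_geo_accession" in annotations:
            annotations = annotations.set_index("Sample_geo_accession")
            annotations.index.name = "sample_id"
        annotations = annotations.loc[expr.index.intersection(annotations.index)]

    if platform_table is not None:
        probe2gene = dict(zip(platform_table["probe"], platform_table["gene"]))
        keep = [p for p in expr.columns if p in probe2gene]
        expr = expr[keep]
        genes = pd.Series([probe2gene[p] for p in keep], index=keep)
        if collapse_rule == "highest_mean":
            by_gene = {}
            for gene, probes in genes.groupby(genes).groups.items():
                sub = expr[list(probes)]
                by_gene[gene] = sub[sub.mean().idxmax()]
            expr = pd.DataFrame(by_gene)
        elif collapse_rule == "mean":
            expr = expr.T.groupby(genes).mean().T
        else:
            raise ValueError(f"unknown collapse rule: {collapse_rule!r}")
        expr.index.name = "sample_id"
    return expr, annotations


def expression_survival_table(expr: pd.DataFrame, annotations: pd.DataFrame,
                              time_field: str, event_field: str,
                              rejection_field: str | None = None
                              ) -> pd.DataFrame:
    """Join expression with survival annotations into one analysis table."""
    table = expr.copy()
    table["time"] = pd.to_numeric(annotations[time_field], errors="coerce")
    table["event"] = annotations[event_field].astype(str).isin(
        ("1", "True", "true", "yes", "loss"))
    if rejection_field is not None:
        table["rejection_class"] = annotations[rejection_field]
    return table.reset_index()
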