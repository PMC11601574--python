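"""Graft-function association: eGFR imputation, correlation, covariate
screen, adjusted linear models.

Graft failure is handled by assigning eGFR = 10 mL/min at failed
timepoints before any association, so failures contribute as very poor
function rather than missing data.  Degranulation scores are related to
eGFR by Pearson correlation, then by ordinary least squares adjusted for a
covariate set assembled by univariate screening at P < 0.1 plus an
always-include list (induction thymoglobulin, acute rejection, delayed
graft function) motivated by prior outcome studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

FAILURE_EGFR = 10.0  # mL/min assigned at graft-failure timepoints

ALWAYS_INCLUDE_COVARIATES = ("thymoglobulin", "acute_rejection",
                             "delayed_graft_function")


@dataclass
class OutcomeRecord:
    """Per-subject graft-function outcomes and clinical covariates.

    ``egfr`` and ``graft_failure`` are keyed by timepoint label (e.g.
    "0.5y", "1y", "2y", "5y"); eGFR in mL/min/1.73m2.
    """

    subject_id: str
    egfr: dict[str, float]
    graft_failure: dict[str, bool]
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    outcome_timepoint: str
    n: int
    pearson_r: float | None
    p_value: float | None
    covariates: tuple[str, ...] = ()
    adjusted_coef: float | None = None
    adjusted_se: float | None = None
    adjusted_p: float | None = None
    untestable: bool = False


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient; message names the collinear columns."""


def impute_failure_egfr(records: Sequence[OutcomeRecord]) -> list[OutcomeRecord]:
    """Assign eGFR = 10 at timepoints flagged as graft failure; all other
    values untouched.  Idempotent; returns new records."""
    out = []
    for rec in records:
        egfr = dict(rec.egfr)
        for tp, failed in rec.graft_failure.items():
            if failed:
                egfr[tp] = FAILURE_EGFR
        out.append(OutcomeRecord(subject_id=rec.subject_id, egfr=egfr,
                                 graft_failure=dict(rec.graft_failure),
                                 covariates=dict(rec.covariates)))
    return out


def _aligned_pairs(scores: Mapping[str, float], records: Sequence[OutcomeRecord],
                   timepoint: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    xs, ys, ids = [], [], []
    for rec in records:
        if rec.subject_id in scores and timepoint in rec.egfr:
            x = scores[rec.subject_id]
            y = rec.egfr[timepoint]
            if x is not None and y is not None and np.isfinite(x) and np.isfinite(y):
                xs.append(x)
                ys.append(y)
                ids.append(rec.subject_id)
    return np.asarray(xs, float), np.asarray(ys, float), ids


def correlate(scores: Mapping[str, float], records: Sequence[OutcomeRecord],
              timepoint: str, predictor: str = "score",
              *, impute_failures: bool = True) -> AssociationResult:
    """Pearson correlation of a per-subject score with eGFR at a timepoint.

    Complete cases only, after failure imputation.  Fewer than 3 pairs, or
    zero variance in either variable, flags the result untestable.
    """
    if impute_failures:
        records = impute_failure_egfr(records)
    x, y, _ = _aligned_pairs(scores, records, timepoint)
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return AssociationResult(predictor, timepoint, n, None, None,
                                 untestable=True)
    r, p = stats.pearsonr(x, y)
    return AssociationResult(predictor, timepoint, n, float(r), float(p))


def covariate_screen(records: Sequence[OutcomeRecord], timepoint: str,
                     *, alpha: float = 0.1,
                     always_include: Sequence[str] = ALWAYS_INCLUDE_COVARIATES,
                     impute_failures: bool = True) -> list[str]:
    """Select covariates univariately associated with eGFR at P < alpha.

    Numeric covariates are tested by Pearson correlation; binary ones by a
    two-sample t-test.  Constant (degenerate) covariates are excluded with
    a log message.  The always-include list is appended regardless of its
    univariate P, when present in the records.
    """
    if impute_failures:
        records = impute_failure_egfr(records)
    cov_names: list[str] = []
    for rec in records:
        for name in rec.covariates:
            if name not in cov_names:
                cov_names.append(name)
    included: list[str] = []
    for name in cov_names:
        vals = {rec.subject_id: rec.covariates.get(name) for rec in records
                if rec.covariates.get(name) is not None}
        x, y, _ = _aligned_pairs(vals, records, timepoint)
        if len(x) < 3:
            continue
        uniq = np.unique(x)
        if uniq.size < 2:
            logger.info("covariate %s is constant; excluded from screen", name)
            continue
        if uniq.size == 2:
            g0, g1 = y[x == uniq[0]], y[x == uniq[1]]
            if len(g0) < 2 or len(g1) < 2:
                continue
            _, p = stats.ttest_ind(g0, g1, equal_var=False)
        else:
            _, p = stats.pearsonr(x, y)
        if p < alpha:
            included.append(name)
    for name in always_include:
        if name in cov_names and name not in included:
            included.append(name)
    return included


def adjusted_model(scores: Mapping[str, float], records: Sequence[OutcomeRecord],
                   timepoint: str, covariates: Sequence[str] = (),
                   predictor: str = "score",
                   *, impute_failures: bool = True) -> AssociationResult:
    """OLS of eGFR on the score plus screened covariates (complete cases).

    With zero covariates the score coefficient equals the simple-regression
    slope.  A rank-deficient design raises :class:`RankDeficiencyError`
    naming the collinear columns.
    """
    if impute_failures:
        records = impute_failure_egfr(records)
    rows = []
    for rec in records:
        if rec.subject_id not in scores or timepoint not in rec.egfr:
            continue
        row = {"score": scores[rec.subject_id], "egfr": rec.egfr[timepoint]}
        for c in covariates:
            row[c] = rec.covariates.get(c)
        rows.append(row)
    frame = pd.DataFrame(rows).dropna()
    n = len(frame)
    if n < len(covariates) + 2:
        return AssociationResult(predictor, timepoint, n, None, None,
                                 covariates=tuple(covariates), untestable=True)
    X = sm.add_constant(frame[["score", *covariates]].astype(float),
                        has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns not adding rank, scanning left to right
        collinear = []
        cols = list(X.columns)
        kept: list[str] = []
        for c in cols:
            trial = X[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept):
                collinear.append(c)
            else:
                kept.append(c)
        raise RankDeficiencyError(f"collinear columns: {collinear}")
    fit = sm.OLS(frame["egfr"].astype(float), X).fit()
    r_res = correlate(scores, records, timepoint, predictor,
                      impute_failures=False)
    return AssociationResult(
        predictor=predictor, outcome_timepoint=timepoint, n=n,
        pearson_r=r_res.pearson_r, p_value=r_res.p_value,
        covariates=tuple(covariates),
        adjusted_coef=float(fit.params["score"]),
        adjusted_se=float(fit.bse["score"]),
        adjusted_p=float(fit.pvalues["score"]),
    )


def records_to_frame(records: Sequence[OutcomeRecord]) -> pd.DataFrame:
    """Flatten outcome records to a long table (one row per timepoint)."""
    rows = []
    for rec in records:
        for tp, egfr in rec.egfr.items():
            rows.append({"subject_id": rec.subject_id, "timepoint": tp,
                         "egfr": egfr,
                         "graft_failure": rec.graft_failure.get(tp, False),
                         **rec.covariates})
    return pd.DataFrame(rows)
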