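"""Step-fit dichotomization, survival analysis, rejection-class comparisons,
series-matrix ingestion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nkgraft.transcript_survival import (DegenerateFitError,
                                         SeriesMatrixParseError, StepFit,
                                         cox_multigene, dichotomize,
                                         expression_survival_table,
                                         group_compare, km_logrank,
                                         load_series_matrix,
                                         stepminer_threshold)
from nkgraft import simulate


def brute_force_step_fit(values):
    """Independent oracle: try every split explicitly with plain Python."""
    x = sorted(values)
    n = len(x)
    best = None
    for k in range(1, n):
        lo, hi = x[:k], x[k:]
        m_lo = sum(lo) / len(lo)
        m_hi = sum(hi) / len(hi)
        sse = sum((v - m_lo) ** 2 for v in lo) + sum((v - m_hi) ** 2
                                                     for v in hi)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, k, m_lo, m_hi)
    return best


class TestStepMiner:
    def test_clean_two_level_step(self):
        fit = stepminer_threshold([1, 1, 1, 5, 5, 5])
        assert fit.step_index == 3
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.threshold == pytest.approx(3.0)
        assert (fit.level_low, fit.level_high) == (1.0, 5.0)

    def test_single_outlier_isolated(self):
        fit = stepminer_threshold([0, 0, 0, 0, 10])
        assert fit.step_index == 4
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_step_any_levels_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            lo, gap = rng.normal(0, 5), rng.uniform(0.5, 10)
            k = rng.integers(2, 9)
            n = rng.integers(k + 2, 15)
            vals = [lo] * k + [lo + gap] * (n - k)
            fit = stepminer_threshold(vals)
            assert fit.step_index == k
            assert fit.sse == pytest.approx(0.0, abs=1e-9)

    def test_sse_never_exceeds_constant_fit(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(4, 30))
            fit = stepminer_threshold(x)
            const_sse = float(np.sum((x - x.mean()) ** 2))
            assert fit.sse <= const_sse + 1e-10
            assert fit.level_low <= fit.level_high

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = rng.integers(4, 51)
            x = rng.normal(0, 1, n)
            fit = stepminer_threshold(x)
            sse, k, m_lo, m_hi = brute_force_step_fit(x)
            assert fit.sse == pytest.approx(sse, abs=1e-10)
            assert fit.step_index == k
            assert fit.threshold == pytest.approx((m_lo + m_hi) / 2,
                                                  abs=1e-10)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            stepminer_threshold([1.0, 2.0, 3.0])

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateFitError):
            stepminer_threshold([2.0] * 6)


class TestDichotomize:
    FIT = StepFit(threshold=3.0, step_index=3, sse=0.0, level_low=1.0,
                  level_high=5.0)

    def test_all_below_threshold_all_low(self):
        assert not dichotomize([0.0, 1.0, 2.9], self.FIT).any()

    def test_clean_step_three_three(self):
        labels = dichotomize([1, 1, 1, 5, 5, 5], self.FIT)
        assert labels.sum() == 3

    def test_value_at_threshold_is_low(self):
        assert not dichotomize([3.0], self.FIT)[0]

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=20),
           st.integers(0, 19), st.floats(0.01, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_raising_one_value_never_moves_other_labels(self, vals, idx,
                                                        bump):
        idx = idx % len(vals)
        before = dichotomize(vals, self.FIT)
        raised = list(vals)
        raised[idx] += bump
        after = dichotomize(raised, self.FIT)
        keep = np.arange(len(vals)) != idx
        assert np.array_equal(before[keep], after[keep])


class TestSurvival:
    def test_product_limit_hand_computation(self):
        # events at t = 1, 2, 3, no censoring: S(2) = 1/3
        curves, stat, p = km_logrank([1, 2, 3, 1, 2, 3],
                                     [True] * 6,
                                     ["g1"] * 3 + ["g2"] * 3)
        s2 = curves["g1"].survival_function_at_times(2.0).item()
        assert s2 == pytest.approx(1 / 3)

    def test_identical_groups_null_statistic(self):
        t = [1, 2, 3, 4, 5]
        curves, stat, p = km_logrank(t + t, [True] * 10,
                                     ["a"] * 5 + ["b"] * 5)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 40)
        curves, *_ = km_logrank(np.concatenate([t, t + 1]),
                                [True] * 80,
                                ["x"] * 40 + ["y"] * 40)
        km = curves["x"]
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            emp = np.mean(t > q)
            assert km.survival_function_at_times(q).item() == pytest.approx(
                emp, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3], [True] * 3, ["only"] * 3)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(5, 60)
        e = rng.random(60) < 0.8
        g = np.where(rng.random(60) < 0.5, "a", "b")
        _, stat_ab, _ = km_logrank(t, e, g)
        swapped = np.where(g == "a", "b", "a")
        _, stat_ba, _ = km_logrank(t, e, swapped)
        assert stat_ab == pytest.approx(stat_ba, abs=1e-10)

    def test_logrank_power_under_hazard_ratio_three(self):
        """HR = 3 with 100 per group and ~20% censoring is detected in
        > 90% of replicates at alpha = 0.05."""
        rejections = 0
        n_reps = 100
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            h = np.repeat([0.05, 0.15], 100)
            t_event = rng.exponential(1 / h)
            t_cens = rng.exponential(1 / (h.mean() * 0.25), 200)
            time = np.minimum(t_event, t_cens)
            event = t_event <= t_cens
            groups = np.repeat(["low", "high"], 100)
            _, _, p = km_logrank(time, event, groups)
            rejections += p < 0.05
        assert rejections / n_reps > 0.9


class TestCox:
    @staticmethod
    def _table(n=300, log_hr=(1.0, 0.0, 0.0), seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, 3))
        h = 0.05 * np.exp(X @ np.asarray(log_hr))
        t_event = rng.exponential(1 / h)
        t_cens = rng.exponential(1 / (h.mean() * 0.25), n)
        return pd.DataFrame({
            "geneA": X[:, 0], "geneB": X[:, 1], "geneC": X[:, 2],
            "time": np.minimum(t_event, t_cens),
            "event": t_event <= t_cens})

    def test_planted_log_hr_recovered(self):
        covered = 0
        n_seeds = 200
        for seed in range(n_seeds):
            table = self._table(seed=seed)
            fit = cox_multigene(table, genes=("geneA", "geneB", "geneC"))
            row = fit.set_index("gene").loc["geneA"]
            covered += row["hr_ci_low"] <= np.exp(1.0) <= row["hr_ci_high"]
        assert covered / n_seeds >= 0.9

    def test_null_gene_ci_covers_one(self):
        covered = 0
        n_seeds = 50
        for seed in range(n_seeds):
            table = self._table(log_hr=(0.0, 0.0, 0.0), seed=seed)
            fit = cox_multigene(table, genes=("geneA", "geneB", "geneC"))
            row = fit.set_index("gene").loc["geneA"]
            covered += row["hr_ci_low"] <= 1.0 <= row["hr_ci_high"]
        assert covered / n_seeds >= 0.9

    def test_duplicated_covariate_collinearity_error(self):
        table = self._table()
        table["geneB"] = table["geneA"]
        with pytest.raises(np.linalg.LinAlgError):
            cox_multigene(table, genes=("geneA", "geneB", "geneC"))


class TestGroupCompare:
    @staticmethod
    def _table(shift=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "FGFBP2": np.concatenate([rng.normal(0, 1, n),
                                      rng.normal(shift, 1, n)]),
            "rejection_class": ["non-rejection"] * n + ["TCMR"] * n})

    def test_identical_distributions_near_null(self):
        table = self._table()
        table["FGFBP2"] = np.tile(table["FGFBP2"][:40], 2)
        (res,) = group_compare(table, "FGFBP2", ("non-rejection", "TCMR"))
        assert res.p_raw > 0.9

    def test_single_comparison_adjusted_equals_raw(self):
        (res,) = group_compare(self._table(shift=1.0), "FGFBP2",
                               ("non-rejection", "TCMR"))
        assert res.p_bonferroni == res.p_raw

    def test_power_under_one_sd_shift(self):
        rejections = sum(
            group_compare(self._table(shift=1.0, seed=s), "FGFBP2",
                          ("non-rejection", "TCMR"))[0].p_raw < 0.05
            for s in range(100))
        assert rejections / 100 > 0.8

    def test_small_class_skipped(self):
        table = self._table()
        table.loc[len(table)] = [0.5, "ABMR"]
        results = group_compare(table, "FGFBP2",
                                ("non-rejection", "TCMR", "ABMR"))
        assert [r.grouping for r in results] == ["TCMR vs non-rejection"]


SERIES_MATRIX = """!Series_title\t"synthetic fixture"
!Sample_geo_accession\t"GSM1"\t"GSM2"
!Sample_title\t"biopsy 1"\t"biopsy 2"
!Sample_characteristics_ch1\t"time: 10"\t"time: 22"
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"
"p1"\t1.5\t2.5
"p2"\t3.0\t4.0
"p3"\t5.0\t6.0
!series_matrix_table_end
"""


class TestSeriesMatrix:
    def test_minimal_fixture_parses(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text(SERIES_MATRIX)
        expr, ann = load_series_matrix(path)
        assert expr.shape == (2, 3)
        assert expr.loc["GSM2", "p2"] == 4.0
        assert list(ann.index) == ["GSM1", "GSM2"]

    def test_duplicate_probe_highest_mean_collapse(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text(SERIES_MATRIX)
        platform = pd.DataFrame({"probe": ["p1", "p2", "p3"],
                                 "gene": ["FGFBP2", "FGFBP2", "IFNG"]})
        expr, _ = load_series_matrix(path, platform)
        assert list(sorted(expr.columns)) == ["FGFBP2", "IFNG"]
        # p2 has the higher mean of the two FGFBP2 probes
        assert expr.loc["GSM1", "FGFBP2"] == 3.0

    def test_mean_collapse_rule(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text(SERIES_MATRIX)
        platform = pd.DataFrame({"probe": ["p1", "p2"],
                                 "gene": ["FGFBP2", "FGFBP2"]})
        expr, _ = load_series_matrix(path, platform, collapse_rule="mean")
        assert expr.loc["GSM1", "FGFBP2"] == pytest.approx(2.25)

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text(SERIES_MATRIX.replace("!series_matrix_table_end\n",
                                              ""))
        with pytest.raises(SeriesMatrixParseError):
            load_series_matrix(path)

    def test_ragged_matrix_line_raises_with_line_number(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text(SERIES_MATRIX.replace('"p2"\t3.0\t4.0', '"p2"\t3.0'))
        with pytest.raises(SeriesMatrixParseError, match="line"):
            load_series_matrix(path)


def test_synthetic_geo_style_pipeline():
    """Step fit + KM/log-rank on the non-rejecting subset recovers the
    planted high-expression group and its excess graft-loss hazard."""
    cfg = simulate.SimulationConfig()
    table = simulate.simulate_expression_survival(cfg, seed=5)
    nonrej = table[table["rejection_class"] == "non-rejection"]
    values = nonrej["FGFBP2"].to_numpy()
    fit = stepminer_threshold(values)
    high = dichotomize(values, fit)
    # the two step levels are 5 SD apart within non-rejection, so the
    # dichotomization should match the generating labels almost exactly
    assert (high == nonrej["true_high"].to_numpy()).mean() > 0.95
    curves, stat, p = km_logrank(nonrej["time"], nonrej["event"],
                                 np.where(high, "high", "low"))
    t_med = float(np.median(nonrej["time"]))
    s_high = curves["high"].survival_function_at_times(t_med).item()
    s_low = curves["low"].survival_function_at_times(t_med).item()
    assert s_high < s_low  # high expressors lose grafts faster
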