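"""ROC/AUC, Youden cutoffs, correlation and paired differences."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import scarshape as ss
from scarshape.outcome_stats import (
    empirical_roc,
    paired_difference,
    pearson_r,
    roc_summary_report,
    youden_j,
    youden_optimal,
)


def brute_force_auc(values, labels):
    """Exhaustive pairwise P(value+ > value-) + 0.5 P(tie)."""
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    pos = v[y == 1]
    neg = v[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        assert empirical_roc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_partial_overlap_matches_brute_force(self):
        assert empirical_roc([1, 3, 2, 4], [0, 0, 1, 1]).auc == 0.75

    def test_rank_auc_equals_pairwise_probability_exhaustively(self):
        """AUC equals the exhaustive Mann-Whitney pairwise probability
        on every small instance, ties included."""
        rng = np.random.default_rng(12)
        for _ in range(60):
            n = int(rng.integers(4, 21))
            v = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            r = empirical_roc(v, y)
            assert r.auc == pytest.approx(brute_force_auc(v, y), abs=1e-12)
            # independent library cross-check
            assert r.auc == pytest.approx(roc_auc_score(y, v), abs=1e-12)

    def test_null_metric_gives_chance_auc(self):
        rng = np.random.default_rng(99)
        v = rng.normal(size=5000)
        y = rng.integers(0, 2, size=5000)
        assert abs(empirical_roc(v, y).auc - 0.5) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(size=40)
        y = rng.integers(0, 2, size=40)
        a = youden_optimal(empirical_roc(v, y))
        b = youden_optimal(empirical_roc(np.log(v), y))
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.j_statistic == pytest.approx(b.j_statistic, abs=1e-12)

    def test_direction_flip(self):
        r = empirical_roc([4, 3, 2, 1], [1, 1, 0, 0], direction="lower_predicts_positive")
        assert r.auc == 0.0  # under the flipped direction the metric anti-discriminates
        r2 = empirical_roc([1, 2, 3, 4], [1, 1, 0, 0], direction="lower_predicts_positive")
        assert r2.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2, 3], [1, 1, 1])


class TestYoudenOptimal:
    @pytest.mark.parametrize(
        "sens,spec,expected_j",
        [(0.929, 0.60, 0.529), (0.50, 1.00, 0.500), (0.571, 1.00, 0.571)],
    )
    def test_j_arithmetic_from_operating_points(self, sens, spec, expected_j):
        assert youden_j(sens, spec) == pytest.approx(expected_j, abs=1e-12)

    def test_selected_cutoff_attains_max_j(self):
        rng = np.random.default_rng(4)
        v = np.round(rng.normal(size=60), 1)
        y = (rng.uniform(size=60) < 0.4).astype(int)
        r = youden_optimal(empirical_roc(v, y))
        j_all = r.sensitivities + r.specificities - 1.0
        assert r.j_statistic == pytest.approx(j_all.max(), abs=1e-12)
        assert r.j_statistic == pytest.approx(r.sensitivity + r.specificity - 1.0)

    def test_ties_break_toward_higher_sensitivity(self):
        # two cutoffs share J = 0.5: (sens 1, spec 0.5) and (sens 0.5, spec 1)
        v = [1.0, 3.0, 2.0, 4.0]
        y = [0, 0, 1, 1]
        r = youden_optimal(empirical_roc(v, y))
        j_all = r.sensitivities + r.specificities - 1.0
        ties = np.isclose(j_all, j_all.max())
        assert ties.sum() > 1
        assert r.sensitivity == r.sensitivities[ties].max()

    def test_constant_metric_best_j_is_zero(self):
        r = youden_optimal(empirical_roc([5.0] * 6, [0, 1, 0, 1, 0, 1]))
        assert r.j_statistic == pytest.approx(0.0, abs=1e-12)


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        # independent evaluation straight from the covariance definition
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_r(x, y).r == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPairedDifference:
    def test_identical_columns(self):
        d = paired_difference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d.mean_diff == 0.0
        assert d.ci95[0] <= 0.0 <= d.ci95[1]

    def test_closed_form_t_interval(self):
        d = paired_difference([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])  # diffs 1, 2, 3
        assert d.mean_diff == pytest.approx(2.0)
        t_975_df2 = 4.302652729911275  # printed t-table value
        half = t_975_df2 * 1.0 / np.sqrt(3.0)
        assert d.ci95[0] == pytest.approx(2.0 - half, abs=1e-9)
        assert d.ci95[1] == pytest.approx(2.0 + half, abs=1e-9)

    def test_mean_diff_equals_difference_of_group_means(self):
        rng = np.random.default_rng(8)
        a = rng.normal(71.7, 5.0, size=24)
        b = rng.normal(82.4, 5.0, size=24)
        d = paired_difference(a, b)
        assert d.mean_diff == pytest.approx(a.mean() - b.mean(), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_difference([1.0, 2.0], [1.0])


class TestRocSummaryReport:
    def test_auc_gate_blanks_weak_metrics(self):
        cohort = ss.generate_cohort(300, effect=ss.LogisticEffect(beta1=0.0), seed=2)
        report = roc_summary_report(cohort)
        weak = report[report["auc"] <= 0.7]
        assert weak["cutoff"].isna().all()
        assert weak["j_statistic"].isna().all()

    def test_strong_effect_rows_get_operating_points(self):
        effect = ss.LogisticEffect(beta1=3.0)
        cohort = ss.generate_cohort(400, effect=effect, seed=6)
        report = roc_summary_report(cohort)
        row = report[
            (report["metric"] == effect.metric) & (report["config"] == effect.config)
        ].iloc[0]
        assert row["auc"] > 0.7
        assert np.isfinite(row["cutoff"])
        assert row["j_statistic"] == pytest.approx(
            row["sensitivity"] + row["specificity"] - 1.0
        )

    def test_gate_is_strict_at_exactly_0_7(self):
        # engineered metric with AUC exactly 0.7: 14 of 20 pos-neg pairs won
        values = np.array([1.0, 2.0, 3.0, 4.0, 4.2, 4.5, 0.5, 2.5, 5.0])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1])
        r = empirical_roc(values, labels)
        assert r.auc == pytest.approx(0.7, abs=1e-12)
        cohort = ss.generate_cohort(9, seed=0)
        table = cohort.table.copy()
        table["surface_healthy_he_cm2_45-55"] = values
        table["recurrence"] = labels
        gated = roc_summary_report(ss.CohortTable(table=table, metadata={}))
        row = gated[
            (gated["metric"] == "surface_healthy_he_cm2") & (gated["config"] == "45-55")
        ].iloc[0]
        assert row["auc"] == pytest.approx(0.7, abs=1e-12)
        assert np.isnan(row["cutoff"])

    def test_cumulative_j_ranks_configs(self):
        cohort = ss.generate_cohort(400, effect=ss.LogisticEffect(beta1=3.0), seed=11)
        report = roc_summary_report(cohort)
        cj = ss.cumulative_j(report, ["total_enhancement_g", "bz_mass_g", "core_mass_g"])
        assert set(cj.index) == set(ss.phantom.THRESHOLD_CONFIG_NAMES)
        assert (cj >= 0).all()
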