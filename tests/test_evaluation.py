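"""Evaluation: ROC/PR areas, QA agreement, coverage curves, significance,
resampling, predictor comparison, QA stratification."""

import numpy as np
import pytest
from scipy import stats

from disqa.calibration import ConfusionCounts, mcc
from disqa.evaluation import (
    EvaluationReport,
    compare_predictors,
    coverage_curve,
    expected_vs_actual,
    pr_auc,
    resample_metric,
    roc_auc,
    significance_test,
    stratify_qa,
)
from disqa.io_formats import ValidationError


def pair_counting_auc(scores, labels):
    """Independent oracle: normalized Mann-Whitney U by exhaustive pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def threshold_sweep_ap(scores, labels):
    """Independent oracle: average precision by explicit threshold sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tp = np.cumsum(labels)
    precision = tp / np.arange(1, len(labels) + 1)
    recall = tp / labels.sum()
    ap, prev_r = 0.0, 0.0
    for p, r in zip(precision, recall):
        ap += (r - prev_r) * p
        prev_r = r
    return ap


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_four_point_case_vs_pair_counting(self):
        scores, labels = [0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0]
        assert roc_auc(scores, labels) == pytest.approx(0.75)
        assert pair_counting_auc(scores, labels) == pytest.approx(0.75)

    def test_constant_scores_are_uninformative(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.integers(0, 10, n) / 10.0  # discretized: forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_prevalence(self):
        labels = [1, 0, 0, 0, 1, 0, 0, 0]
        assert pr_auc([0.5] * 8, labels) == pytest.approx(np.mean(labels))

    def test_four_point_case_vs_threshold_sweep(self):
        scores, labels = [0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0]
        expected = threshold_sweep_ap(scores, labels)
        assert expected == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))
        assert pr_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert pr_auc(scores, labels) == pytest.approx(
            threshold_sweep_ap(scores, labels), abs=1e-12
        )


def blockwise_self_consistent_qa(n_blocks=8, window=50, seed=0):
    """mapped QA constructed so each sorted window's mean equals its MCC."""
    rng = np.random.default_rng(seed)
    n = n_blocks * window
    labels = (rng.random(n) < 0.3).astype(np.int8)
    correct = rng.random(n) < np.linspace(0.55, 0.98, n)
    binary = np.where(correct, labels, 1 - labels).astype(np.int8)
    qa = np.empty(n)
    for b in range(n_blocks):
        sl = slice(b * window, (b + 1) * window)
        qa[sl] = mcc(ConfusionCounts.from_arrays(binary[sl], labels[sl]))
    return qa, binary, labels


class TestExpectedVsActual:
    def test_self_consistency(self):
        qa, binary, labels = blockwise_self_consistent_qa()
        agr = expected_vs_actual(qa, binary, labels, window_size=50, stride=50)
        assert agr.pcc == pytest.approx(1.0, abs=1e-9)
        assert agr.mae == pytest.approx(0.0, abs=1e-12)
        assert agr.mse == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_qa(self):
        qa, binary, labels = blockwise_self_consistent_qa(seed=1)
        agr = expected_vs_actual(-qa, binary, labels, window_size=50, stride=50)
        assert agr.pcc == pytest.approx(-1.0, abs=1e-9)

    def test_insufficient_residues_rejected(self):
        with pytest.raises(ValidationError):
            expected_vs_actual(np.zeros(10), np.zeros(10), np.ones(10),
                               window_size=50)


class TestCoverageCurve:
    def test_full_coverage_equals_dataset_mcc(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 300)
        binary = rng.integers(0, 2, 300)
        qa = rng.uniform(-1, 1, 300)
        curve = coverage_curve(qa, binary, labels, step=0.25,
                               test_significance=False)
        cov, m = curve.points[-1]
        assert cov == 1.0
        assert m == pytest.approx(
            mcc(ConfusionCounts.from_arrays(binary, labels))
        )

    def test_correctness_indicator_qa_selects_perfect_subset(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 400)
        correct = rng.random(400) < 0.7
        binary = np.where(correct, labels, 1 - labels)
        qa = correct.astype(float)
        curve = coverage_curve(qa, binary, labels, step=0.1,
                               test_significance=False)
        for cov, m in curve.points:
            if cov <= 0.5 and np.isfinite(m):  # inside the all-correct subset
                assert m == pytest.approx(1.0)

    def test_single_class_subset_marked_undefined(self):
        labels = np.array([0] * 95 + [1] * 5)
        binary = labels.copy()
        qa = np.linspace(0, 1, 100)  # top residues all ordered
        curve = coverage_curve(qa, binary, labels[::-1], step=0.05,
                               test_significance=False)
        assert any(np.isnan(m) for _, m in curve.points)

    def test_bad_step_rejected(self):
        with pytest.raises(ValidationError):
            coverage_curve(np.zeros(10), np.zeros(10),
                           np.array([0, 1] * 5), step=0.0)


class TestSignificanceTest:
    def test_identical_samples_not_significant(self):
        x = np.random.default_rng(0).normal(size=50)
        p, name = significance_test(x, x.copy())
        assert p == pytest.approx(1.0)

    def test_separated_gaussians_t_test(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.1, 100)
        b = rng.normal(1.0, 0.1, 100)
        p, name = significance_test(a, b)
        assert name == "t-test"
        assert p < 0.001

    def test_heavy_tails_select_rank_sum(self):
        rng = np.random.default_rng(3)
        a = rng.standard_cauchy(100)
        b = rng.standard_cauchy(100) + 5
        p, name = significance_test(a, b)
        assert name == "wilcoxon-rank-sum"
        assert p < 0.001

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            significance_test(np.zeros(5), np.ones(5))


class TestResampleMetric:
    @staticmethod
    def metric(sub):
        return float(np.mean(sub["x"]))

    def test_cardinality(self):
        values = {"x": np.arange(100.0)}
        out = resample_metric(values, self.metric, reps=100, frac=0.5, seed=0)
        assert len(out) == 100

    def test_full_fraction_has_zero_variance(self):
        values = {"x": np.arange(50.0)}
        out = resample_metric(values, self.metric, reps=20, frac=1.0, seed=0)
        assert np.ptp(out) == 0.0

    def test_seeded_reproducibility(self):
        values = {"x": np.random.default_rng(1).random(200)}
        a = resample_metric(values, self.metric, reps=30, frac=0.5, seed=7)
        b = resample_metric(values, self.metric, reps=30, frac=0.5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_protein_unit_subsamples_whole_proteins(self):
        pid = np.repeat(["A", "B", "C", "D"], 10)
        values = {"x": np.arange(40.0)}

        def metric(sub):
            assert len(sub["x"]) % 10 == 0
            return float(np.mean(sub["x"]))

        out = resample_metric(values, metric, unit="proteins",
                              protein_ids=pid, reps=10, frac=0.5, seed=0)
        assert len(out) == 10

    def test_degenerate_subsamples_redrawn_then_error(self):
        values = {"lab": np.array([0] * 99 + [1])}

        def metric(sub):
            if sub["lab"].sum() == 0:
                raise ValidationError("single class")
            return 1.0

        with pytest.raises(ValidationError, match="redraws"):
            resample_metric(values, metric, reps=5, frac=0.1, seed=0)


from conftest import BENCHMARK_TABLE


def benchmark_reports():
    return [
        EvaluationReport(predictor_name=n, roc_auc=a, pr_auc=p, mcc=m)
        for n, a, p, m in BENCHMARK_TABLE
    ]


class TestComparePredictors:
    def test_identical_reports_give_zero_differences(self):
        reports = [
            EvaluationReport("a", 0.9, 0.6, 0.5),
            EvaluationReport("b", 0.9, 0.6, 0.5),
        ]
        table = compare_predictors(reports, reference="a")
        assert table["median_difference"] == {
            "roc_auc": 0.0, "pr_auc": 0.0, "mcc": 0.0
        }

    def test_duplicate_names_rejected(self):
        reports = [EvaluationReport("a", 0.9, 0.6, 0.5)] * 2
        with pytest.raises(ValidationError, match="duplicate"):
            compare_predictors(reports)

    def test_ranking_sorted_by_roc_auc(self):
        table = compare_predictors(benchmark_reports())
        aucs = [row["roc_auc"] for row in table["ranking"]]
        assert aucs == sorted(aucs, reverse=True)

    def test_reference_defaults_to_top_ranked(self):
        table = compare_predictors(benchmark_reports())
        assert table["reference"] == "QUARTERplus"


class TestStratifyQA:
    def test_run_length_class_boundaries(self):
        # runs of 9 (short), 30 (medium), 31 (long)
        labels = np.concatenate([
            np.ones(9), np.zeros(5), np.ones(30), np.zeros(5), np.ones(31),
            np.zeros(5),
        ]).astype(np.int8)
        qa = np.where(labels == 1, 0.5, 0.1)
        qa[:9] = 0.2
        qa[14:44] = 0.4
        qa[49:80] = 0.6
        out = stratify_qa(qa, labels)
        assert out["short"] == pytest.approx(0.2)
        assert out["medium"] == pytest.approx(0.4)
        assert out["long"] == pytest.approx(0.6)
        assert out["ordered"] == pytest.approx(0.1)

    def test_all_ordered_reports_only_ordered_stratum(self):
        labels = np.zeros(50, dtype=np.int8)
        out = stratify_qa(np.full(50, 0.3), labels)
        assert out["short"] is None and out["long"] is None
        assert out["ordered"] == pytest.approx(0.3)
        assert out["terminus_profile"] is None

    def test_uniform_qa_gives_equal_strata(self):
        labels = np.concatenate([
            np.ones(5), np.zeros(10), np.ones(20), np.zeros(10), np.ones(40),
        ]).astype(np.int8)
        out = stratify_qa(np.full(85, 0.42), labels)
        for key in ("short", "medium", "long", "ordered"):
            assert out[key] == pytest.approx(0.42)

    def test_terminus_profile_detects_boundary_dip(self):
        labels = np.concatenate([np.zeros(40), np.ones(20), np.zeros(40)])
        dist_qa = np.full(100, 0.8)
        for i in (39, 40, 59, 60):
            dist_qa[i] = -0.5  # boundary residues flagged poor
        out = stratify_qa(dist_qa, labels.astype(np.int8))
        profile = out["terminus_profile"]
        assert profile[0] < profile[5]
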