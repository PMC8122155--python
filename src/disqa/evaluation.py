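"""Residue-level evaluation of disorder predictions and their QA scores.

Covers the threshold-swept ROC/PR areas and MCC for the predictions
themselves, the expected-vs-actual MCC agreement of calibrated QA scores,
coverage-vs-MCC curves for selective prediction with a resampling-based
significance marker, predictor-comparison summary statistics, and
stratification of QA scores by disordered-region length and distance from
region termini.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .calibration import ConfusionCounts, mcc
from .io_formats import ValidationError


@dataclasses.dataclass
class EvaluationReport:
    """Headline metrics for one predictor on one labeled dataset."""

    predictor_name: str
    roc_auc: float
    pr_auc: float
    mcc: float
    qa_agreement: Optional["QAAgreement"] = None
    coverage: Optional["CoverageCurve"] = None


@dataclasses.dataclass
class QAAgreement:
    """Agreement between mapped QA (expected MCC) and windowed actual MCC."""

    pcc: float
    mae: float
    mse: float
    points: List[Tuple[float, float]]  # (expected, actual) per window


@dataclasses.dataclass
class CoverageCurve:
    """Actual MCC over the top-QA fraction of residues, per coverage level.

    ``points`` maps coverage fraction -> MCC (NaN where the selected subset
    contains a single label class). ``significant_coverage`` is the largest
    coverage whose MCC beats the full-dataset MCC by the relative improvement
    margin with resampling significance; ``qualifying_coverages`` lists every
    coverage meeting the improvement margin (significance tested from the
    largest down until one passes).
    """

    points: List[Tuple[float, float]]
    significant_coverage: Optional[float]
    qualifying_coverages: List[float]
    step: float
    dataset_mcc: float


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("metric requires both label classes present")


def roc_auc(propensity: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve swept over all unique propensity thresholds.

    Equals the normalized Mann-Whitney U statistic.
    """
    _check_two_classes(labels)
    return float(roc_auc_score(labels, propensity))


def pr_auc(propensity: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise interpolation)."""
    _check_two_classes(labels)
    return float(average_precision_score(labels, propensity))


def binary_mcc(binary: np.ndarray, labels: np.ndarray) -> float:
    """MCC of binary calls against labels (0 on a zero marginal)."""
    return mcc(ConfusionCounts.from_arrays(binary, labels))


def _sorted_windows(qa: np.ndarray, window_size: int, stride: Optional[int] = None):
    """Start indices of sliding windows over residues sorted ascending by QA."""
    n = len(qa)
    if n < 2 * window_size:
        raise ValidationError(
            f"need at least {2 * window_size} residues, got {n}"
        )
    if stride is None:
        stride = max(1, -(-window_size // 10))
    order = np.argsort(qa, kind="stable")
    starts = list(range(0, n - window_size + 1, stride))
    if starts[-1] != n - window_size:
        starts.append(n - window_size)
    return order, np.asarray(starts), stride


def expected_vs_actual(
    mapped_qa: np.ndarray,
    binary: np.ndarray,
    labels: np.ndarray,
    window_size: int = 2000,
    stride: Optional[int] = None,
) -> QAAgreement:
    """Compare expected MCC (mean mapped QA per window) with actual MCC.

    Residues are sorted by mapped QA and windowed exactly as in calibration;
    each window contributes an (expected, actual) pair and PCC/MAE/MSE are
    computed over the pairs. Windows whose MCC is undefined (a zero
    contingency marginal, e.g. no disordered residues in the window) are
    excluded rather than scored with the 0 convention.
    """
    mapped_qa = np.asarray(mapped_qa, dtype=float)
    binary = np.asarray(binary)
    labels = np.asarray(labels)
    order, starts, _ = _sorted_windows(mapped_qa, window_size, stride)
    qa_s, bin_s, lab_s = mapped_qa[order], binary[order], labels[order]
    expected, actual = [], []
    for s in starts:
        sl = slice(s, s + window_size)
        counts = ConfusionCounts.from_arrays(bin_s[sl], lab_s[sl])
        defined = (
            (counts.tp + counts.fp) > 0 and (counts.tp + counts.fn) > 0
            and (counts.tn + counts.fp) > 0 and (counts.tn + counts.fn) > 0
        )
        if not defined:
            continue
        expected.append(float(np.mean(qa_s[sl])))
        actual.append(mcc(counts))
    if len(expected) < 2:
        raise ValidationError(
            "fewer than two windows with defined MCC; reduce window_size"
        )
    expected = np.asarray(expected)
    actual = np.asarray(actual)
    if np.std(expected) == 0 or np.std(actual) == 0:
        pcc = 1.0 if np.allclose(expected, actual) else 0.0
    else:
        pcc = float(stats.pearsonr(expected, actual)[0])
    diff = expected - actual
    return QAAgreement(
        pcc=pcc,
        mae=float(np.mean(np.abs(diff))),
        mse=float(np.mean(diff**2)),
        points=list(zip(expected.tolist(), actual.tolist())),
    )


def significance_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    alpha_normality: float = 0.05,
) -> Tuple[float, str]:
    """Two-sample comparison with a normality-gated choice of test.

    Both samples are checked for normality with the Anderson-Darling test at
    ``alpha_normality``; if both pass, a paired t-test is used, otherwise the
    Wilcoxon rank-sum test. Returns (p-value, test name).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("samples must have equal length (paired design)")
    if len(a) < 8:
        raise ValueError("need at least 8 observations per sample")
    if np.array_equal(a, b):
        return 1.0, "identical"

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        res = stats.anderson(x, dist="norm", method="interpolate")
        return float(res.pvalue) > alpha_normality

    if _normal(a) and _normal(b):
        if np.ptp(a - b) == 0:  # constant nonzero difference
            return 0.0, "t-test"
        p = float(stats.ttest_rel(a, b).pvalue)
        return p, "t-test"
    p = float(stats.ranksums(a, b).pvalue)
    return p, "wilcoxon-rank-sum"


def resample_metric(
    values: Dict[str, np.ndarray],
    metric,
    unit: str = "residues",
    protein_ids: Optional[np.ndarray] = None,
    reps: int = 100,
    frac: float = 0.5,
    seed: int = 0,
    max_redraws: int = 10,
) -> np.ndarray:
    """Metric values over ``reps`` random subsamples of fraction ``frac``.

    ``values`` holds aligned per-residue arrays (e.g. propensity/binary/
    labels); ``metric`` is called with the subsampled dict. ``unit`` selects
    whether subsampling draws residues directly or whole proteins (via
    ``protein_ids``). A subsample on which the metric raises (e.g.
    single-class) is redrawn up to ``max_redraws`` times.
    """
    if unit not in ("residues", "proteins"):
        raise ValueError("unit must be 'residues' or 'proteins'")
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    n = len(next(iter(values.values())))
    for v in values.values():
        if len(v) != n:
            raise ValidationError("value arrays must be aligned")
    if unit == "proteins":
        if protein_ids is None:
            raise ValueError("protein-unit resampling requires protein_ids")
        protein_ids = np.asarray(protein_ids)
        uniq = np.unique(protein_ids)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        for attempt in range(max_redraws + 1):
            if unit == "residues":
                k = max(1, int(round(frac * n)))
                idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
            else:
                k = max(1, int(round(frac * len(uniq))))
                chosen = rng.choice(uniq, size=k, replace=False) if k < len(uniq) else uniq
                idx = np.flatnonzero(np.isin(protein_ids, chosen))
            sub = {name: np.asarray(v)[idx] for name, v in values.items()}
            try:
                out.append(float(metric(sub)))
                break
            except (ValidationError, ValueError):
                if attempt == max_redraws:
                    raise ValidationError(
                        "subsample degenerate after maximum redraws"
                    )
    return np.asarray(out)


def coverage_curve(
    mapped_qa: np.ndarray,
    binary: np.ndarray,
    labels: np.ndarray,
    step: float = 0.01,
    improvement: float = 0.10,
    alpha: float = 0.001,
    relative: bool = True,
    reps: int = 100,
    frac: float = 0.5,
    seed: int = 0,
    test_significance: bool = True,
) -> CoverageCurve:
    """MCC over progressively smaller top-QA subsets of residues.

    For each coverage on the grid (step, 2*step, ..., 1.0) the MCC is
    computed over that fraction of residues with the highest mapped QA (ties
    broken by input order). ``significant_coverage`` is the largest coverage
    whose MCC beats the full-dataset MCC by the improvement margin
    (relative by default) with p < ``alpha`` under 100x50% residue
    resampling.
    """
    if not (0 < step <= 1):
        raise ValidationError("step must be in (0, 1]")
    mapped_qa = np.asarray(mapped_qa, dtype=float)
    binary = np.asarray(binary)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    n = len(mapped_qa)
    # descending QA, deterministic tie-break by original index
    order = np.lexsort((np.arange(n), -mapped_qa))
    bin_s, lab_s = binary[order], labels[order]
    full_mcc = mcc(ConfusionCounts.from_arrays(binary, labels))
    grid = np.arange(step, 1.0 + step / 2, step)
    grid[-1] = 1.0
    points: List[Tuple[float, float]] = []
    for cov in grid:
        k = max(1, int(round(cov * n)))
        sel_lab = lab_s[:k]
        if sel_lab.min() == sel_lab.max():
            points.append((float(cov), float("nan")))
            continue
        points.append(
            (float(cov), mcc(ConfusionCounts.from_arrays(bin_s[:k], sel_lab)))
        )

    threshold = full_mcc * (1 + improvement) if relative else full_mcc + improvement
    qualifying = [
        cov for cov, m in points
        if np.isfinite(m) and m >= threshold and cov < 1.0
    ]
    significant: Optional[float] = None
    if test_significance and qualifying:
        def metric(sub):
            return mcc(ConfusionCounts.from_arrays(sub["binary"], sub["labels"]))

        full_samples = resample_metric(
            {"binary": binary, "labels": labels}, metric,
            unit="residues", reps=reps, frac=frac, seed=seed,
        )
        for cov in sorted(qualifying, reverse=True):
            k = max(1, int(round(cov * n)))
            sub_samples = resample_metric(
                {"binary": bin_s[:k], "labels": lab_s[:k]}, metric,
                unit="residues", reps=reps, frac=frac, seed=seed + 1,
            )
            p, _ = significance_test(sub_samples, full_samples)
            if p < alpha:
                significant = cov
                break
    return CoverageCurve(
        points=points,
        significant_coverage=significant,
        qualifying_coverages=qualifying,
        step=float(step),
        dataset_mcc=full_mcc,
    )


def compare_predictors(
    reports: Sequence[EvaluationReport],
    reference: Optional[str] = None,
) -> Dict:
    """Summary statistics comparing a reference predictor to all others.

    Emits per-competitor metric differences (reference minus competitor),
    the median difference per metric, and the relative error reduction in
    ROC-AUC over the best competitor,
    (ref_auc - best_other_auc) / (1 - best_other_auc), as a percentage.
    Reports are sorted by ROC-AUC descending.
    """
    if len(reports) < 2:
        raise ValidationError("need at least two predictors to compare")
    names = [r.predictor_name for r in reports]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate predictor names")
    ranked = sorted(reports, key=lambda r: -r.roc_auc)
    if reference is None:
        reference = ranked[0].predictor_name
    ref = next(r for r in reports if r.predictor_name == reference)
    others = [r for r in ranked if r.predictor_name != reference]
    diffs = {
        r.predictor_name: {
            "roc_auc": ref.roc_auc - r.roc_auc,
            "pr_auc": ref.pr_auc - r.pr_auc,
            "mcc": ref.mcc - r.mcc,
        }
        for r in others
    }
    medians = {
        metric: float(np.median([d[metric] for d in diffs.values()]))
        for metric in ("roc_auc", "pr_auc", "mcc")
    }
    best_other = max(r.roc_auc for r in others)
    rel_reduction = 100.0 * (ref.roc_auc - best_other) / (1.0 - best_other)
    second_best_mcc = max(r.mcc for r in others)
    return {
        "reference": reference,
        "ranking": [
            {"predictor": r.predictor_name, "roc_auc": r.roc_auc,
             "pr_auc": r.pr_auc, "mcc": r.mcc}
            for r in ranked
        ],
        "differences": diffs,
        "median_difference": medians,
        "relative_auc_error_reduction_pct": rel_reduction,
        "mcc_gap_to_second_best": ref.mcc - second_best_mcc,
    }


def _disorder_runs(labels: np.ndarray) -> List[Tuple[int, int]]:
    """(start, end-exclusive) spans of consecutive disordered residues."""
    labels = np.asarray(labels).astype(np.int8)
    padded = np.concatenate([[0], labels, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def stratify_qa(
    mapped_qa: np.ndarray,
    labels: np.ndarray,
    max_distance: int = 20,
) -> Dict:
    """Mean mapped QA by disordered-region length class and terminus distance.

    Disordered runs are classified short (<10 residues), medium (10-30) and
    long (>30); the ordered residues form their own stratum. The terminus
    profile reports mean QA for residues at each distance 0..``max_distance``
    from the nearest disordered-region boundary residue.
    """
    mapped_qa = np.asarray(mapped_qa, dtype=float)
    labels = np.asarray(labels).astype(np.int8)
    if len(mapped_qa) != len(labels):
        raise ValidationError("mapped_qa/labels length mismatch")
    runs = _disorder_runs(labels)
    strata: Dict[str, List[float]] = {"short": [], "medium": [], "long": []}
    for start, end in runs:
        length = end - start
        cls = "short" if length < 10 else ("medium" if length <= 30 else "long")
        strata[cls].extend(mapped_qa[start:end].tolist())
    ordered_vals = mapped_qa[labels == 0]
    result: Dict = {
        "short": float(np.mean(strata["short"])) if strata["short"] else None,
        "medium": float(np.mean(strata["medium"])) if strata["medium"] else None,
        "long": float(np.mean(strata["long"])) if strata["long"] else None,
        "ordered": float(np.mean(ordered_vals)) if len(ordered_vals) else None,
    }
    if runs:
        termini = np.array(
            sorted({s for s, _ in runs} | {e - 1 for _, e in runs})
        )
        pos = np.arange(len(labels))
        dist = np.min(np.abs(pos[:, None] - termini[None, :]), axis=1)
        profile = []
        for d in range(max_distance + 1):
            at_d = mapped_qa[dist == d]
            profile.append(float(np.mean(at_d)) if len(at_d) else None)
        result["terminus_profile"] = profile
    else:
        result["terminus_profile"] = None
    return result


def evaluate(
    propensity: np.ndarray,
    binary: np.ndarray,
    labels: np.ndarray,
    predictor_name: str = "predictor",
    mapped_qa: Optional[np.ndarray] = None,
    window_size: int = 2000,
    coverage_step: float = 0.01,
    seed: int = 0,
    test_significance: bool = True,
) -> EvaluationReport:
    """Full report: ROC/PR/MCC plus QA agreement and coverage when QA given."""
    report = EvaluationReport(
        predictor_name=predictor_name,
        roc_auc=roc_auc(propensity, labels),
        pr_auc=pr_auc(propensity, labels),
        mcc=binary_mcc(binary, labels),
    )
    if mapped_qa is not None:
        if len(mapped_qa) >= 2 * window_size:
            report.qa_agreement = expected_vs_actual(
                mapped_qa, binary, labels, window_size=window_size
            )
        report.coverage = coverage_curve(
            mapped_qa, binary, labels, step=coverage_step, seed=seed,
            test_significance=test_significance,
        )
    return report
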