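"""End-to-end orchestration: simulate -> calibrate -> train -> predict ->
re-calibrate the meta output -> evaluate.

The stages enforce the leakage rule that calibration curves are never fitted
on proteins the meta-model trains on, and every stochastic stage receives a
seed derived from the single run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import calibration, evaluation, meta_model
from .io_formats import Dataset, PredictorTrack, ValidationError
from .synthetic import MetaScenario, make_meta_scenario


class LeakageError(ValidationError):
    """Raised when calibration and meta-training proteins overlap."""


def check_disjoint(calibration_ids: Iterable[str], training_ids: Iterable[str]) -> None:
    overlap = set(calibration_ids) & set(training_ids)
    if overlap:
        raise LeakageError(
            "calibration and meta-training proteins overlap: "
            + ", ".join(sorted(overlap)[:5])
        )


def fit_curves(
    dataset: Dataset,
    predictor_names: Sequence[str],
    calibration_ids: Sequence[str],
    window_size: int,
    training_ids: Optional[Sequence[str]] = None,
) -> Dict[str, calibration.CalibrationCurve]:
    """Fit one raw-QA calibration curve per predictor on the calibration
    proteins; refuses to proceed if those overlap ``training_ids``."""
    if training_ids is not None:
        check_disjoint(calibration_ids, training_ids)
    curves = {}
    for name in predictor_names:
        triples = [
            (dataset.tracks[(pid, name)], dataset.record(pid).labels, pid)
            for pid in calibration_ids
        ]
        curves[name] = calibration.build_curve(
            triples, window_size=window_size, predictor_name=name
        )
    return curves


def map_dataset_qa(
    dataset: Dataset, curves: Dict[str, calibration.CalibrationCurve]
) -> None:
    """Fill mapped_qa on every track whose predictor has a fitted curve."""
    for (pid, name), track in dataset.tracks.items():
        if name in curves and track.raw_qa is not None:
            track.mapped_qa = calibration.apply_curve(curves[name], track.raw_qa)


def features_for(
    dataset: Dataset,
    ids: Sequence[str],
    predictor_order: Sequence[str],
) -> List[Tuple[meta_model.MetaFeatures, np.ndarray]]:
    """Per-protein (MetaFeatures, labels) pairs in a fixed predictor order."""
    out = []
    for pid in ids:
        tracks = [dataset.tracks[(pid, name)] for name in predictor_order]
        feats = meta_model.assemble_features(tracks, predictor_order)
        out.append((feats, dataset.record(pid).labels))
    return out


def threshold_margin_qa(propensity: np.ndarray, threshold: float) -> np.ndarray:
    """Default raw-QA provider for the meta output.

    Confidence is the distance of the propensity from the binary threshold,
    rescaled to [0, 1]. This is a synthetic stand-in confidence stream — any
    raw-QA generator can be plugged in instead — and it is calibrated through
    the same raw-QA -> MCC mapping as every other stream.
    """
    propensity = np.asarray(propensity, dtype=float)
    scale = max(threshold, 1.0 - threshold)
    return np.abs(propensity - threshold) / scale


@dataclasses.dataclass
class PipelineResult:
    scenario: MetaScenario
    curves: Dict[str, calibration.CalibrationCurve]
    meta: meta_model.TrainedMeta
    meta_curve: calibration.CalibrationCurve
    reports: List[evaluation.EvaluationReport]
    comparison: Dict


def run_pipeline(
    seed: int = 0,
    out_dir: Optional[Path] = None,
    scenario: Optional[MetaScenario] = None,
    config: Optional[meta_model.MetaModelConfig] = None,
    curve_window: int = 150,
    coverage_step: float = 0.01,
    raw_qa_provider=threshold_margin_qa,
    test_significance: bool = True,
) -> PipelineResult:
    """Run the full synthetic study and optionally write artifacts.

    Stages: generate the meta scenario; fit per-predictor calibration curves
    on the calibration proteins; map all raw QA; train the meta-model on the
    training proteins; predict on the held-out test proteins; derive a raw QA
    stream for the meta output and calibrate it on the calibration proteins;
    evaluate meta and bases on the test proteins.
    """
    rng = np.random.default_rng(seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1))
             for name in ("scenario", "train", "evaluate")}
    if scenario is None:
        scenario = make_meta_scenario(seed=seeds["scenario"])
    dataset = scenario.dataset
    order = scenario.predictor_names

    check_disjoint(scenario.calibration_ids, scenario.train_ids)
    curves = fit_curves(
        dataset, order, scenario.calibration_ids, curve_window,
        training_ids=scenario.train_ids,
    )
    map_dataset_qa(dataset, curves)

    if config is None:
        config = meta_model.MetaModelConfig(seed=seeds["train"])
    else:
        config = dataclasses.replace(config, seed=seeds["train"])
    train_feats = features_for(dataset, scenario.train_ids, order)
    meta = meta_model.train_meta(train_feats, config)

    # meta predictions + stand-in raw QA on calibration proteins -> meta curve
    meta_tracks: Dict[str, PredictorTrack] = {}
    for pid in list(scenario.calibration_ids) + list(scenario.test_ids):
        tracks = [dataset.tracks[(pid, name)] for name in order]
        t = meta_model.predict_meta(meta, tracks)
        t.raw_qa = raw_qa_provider(t.propensity, meta.binary_threshold)
        meta_tracks[pid] = t
    meta_curve = calibration.build_curve(
        [
            (meta_tracks[pid], dataset.record(pid).labels, pid)
            for pid in scenario.calibration_ids
        ],
        window_size=curve_window,
        predictor_name="meta",
    )
    for pid in scenario.test_ids:
        meta_tracks[pid].mapped_qa = calibration.apply_curve(
            meta_curve, meta_tracks[pid].raw_qa
        )

    test_labels = np.concatenate(
        [dataset.record(pid).labels for pid in scenario.test_ids]
    )
    reports = []
    for name in order:
        prop = np.concatenate(
            [dataset.tracks[(pid, name)].propensity for pid in scenario.test_ids]
        )
        binary = np.concatenate(
            [dataset.tracks[(pid, name)].binary for pid in scenario.test_ids]
        )
        qa = np.concatenate(
            [dataset.tracks[(pid, name)].mapped_qa for pid in scenario.test_ids]
        )
        reports.append(evaluation.evaluate(
            prop, binary, test_labels, predictor_name=name, mapped_qa=qa,
            window_size=curve_window, coverage_step=coverage_step,
            seed=seeds["evaluate"], test_significance=test_significance,
        ))
    meta_prop = np.concatenate(
        [meta_tracks[pid].propensity for pid in scenario.test_ids]
    )
    meta_bin = np.concatenate(
        [meta_tracks[pid].binary for pid in scenario.test_ids]
    )
    meta_qa = np.concatenate(
        [meta_tracks[pid].mapped_qa for pid in scenario.test_ids]
    )
    reports.append(evaluation.evaluate(
        meta_prop, meta_bin, test_labels, predictor_name="meta",
        mapped_qa=meta_qa, window_size=curve_window,
        coverage_step=coverage_step, seed=seeds["evaluate"],
        test_significance=test_significance,
    ))
    comparison = evaluation.compare_predictors(reports, reference="meta")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, curve in {**curves, "meta": meta_curve}.items():
            calibration.save_curve(curve, out_dir / f"curve_{name}.json")
        meta_model.save_meta(meta, out_dir / "meta_model")
        report_payload = {
            r.predictor_name: {
                "roc_auc": r.roc_auc,
                "pr_auc": r.pr_auc,
                "mcc": r.mcc,
                "qa_pcc": r.qa_agreement.pcc if r.qa_agreement else None,
                "qa_mae": r.qa_agreement.mae if r.qa_agreement else None,
                "significant_coverage": (
                    r.coverage.significant_coverage if r.coverage else None
                ),
            }
            for r in reports
        }
        with open(out_dir / "report.json", "w") as fh:
            json.dump({"reports": report_payload, "comparison": comparison},
                      fh, indent=1, default=float)
        manifest = {
            "seed": seed,
            "stage_seeds": seeds,
            "curve_window": curve_window,
            "meta_config": dataclasses.asdict(config),
            "meta_raw_qa_provider": "threshold-margin (synthetic stand-in)",
            "splits": {
                "calibration": scenario.calibration_ids,
                "train": scenario.train_ids,
                "test": scenario.test_ids,
            },
            "artifact_hashes": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out_dir.glob("curve_*.json"))
            },
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return PipelineResult(
        scenario=scenario,
        curves=curves,
        meta=meta,
        meta_curve=meta_curve,
        reports=reports,
        comparison=comparison,
    )
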