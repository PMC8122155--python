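"""Shared fixtures: the canonical synthetic meta-scenario, calibrated and
feature-assembled once per session (several tests and the acceptance suite
reuse it to keep the run short)."""

import numpy as np
import pytest

from disqa import meta_model, pipeline, synthetic

SCENARIO_SEED = 1
CURVE_WINDOW = 150

# Printed benchmark columns (predictor, ROC-AUC, PR-AUC, MCC) of the
# 13-predictor comparison used as a worked example throughout.
BENCHMARK_TABLE = [
    ("QUARTERplus", 0.929, 0.647, 0.611),
    ("SPOT-Disorder", 0.918, 0.582, 0.569),
    ("DISOPRED3", 0.915, 0.619, 0.584),
    ("VSL2B", 0.839, 0.389, 0.309),
    ("ESpritz-Xray", 0.812, 0.355, 0.289),
    ("IUPred-short", 0.810, 0.382, 0.377),
    ("ESpritz-NMR", 0.807, 0.364, 0.340),
    ("disEMBL-465", 0.804, 0.357, 0.361),
    ("ESpritz-DisProt", 0.782, 0.167, 0.137),
    ("JRONN", 0.766, 0.306, 0.246),
    ("disEMBL-HL", 0.760, 0.255, 0.194),
    ("IUPred-long", 0.732, 0.265, 0.278),
    ("GlobPlot", 0.630, 0.139, 0.145),
]


@pytest.fixture(scope="session")
def scenario():
    """Canonical meta scenario with fitted curves and mapped QA."""
    sc = synthetic.make_meta_scenario(seed=SCENARIO_SEED)
    curves = pipeline.fit_curves(
        sc.dataset, sc.predictor_names, sc.calibration_ids, CURVE_WINDOW,
        training_ids=sc.train_ids,
    )
    pipeline.map_dataset_qa(sc.dataset, curves)
    return sc, curves


@pytest.fixture(scope="session")
def scenario_features(scenario):
    """(train_features, test_features, test_labels) for the canonical scenario."""
    sc, _ = scenario
    train = pipeline.features_for(sc.dataset, sc.train_ids, sc.predictor_names)
    test = pipeline.features_for(sc.dataset, sc.test_ids, sc.predictor_names)
    test_labels = np.concatenate(
        [sc.dataset.record(p).labels for p in sc.test_ids]
    )
    return train, test, test_labels


@pytest.fixture(scope="session")
def trained_default_meta(scenario_features):
    """Default biLSTM meta trained once on the canonical scenario."""
    train, _, _ = scenario_features
    return meta_model.train_meta(train, meta_model.MetaModelConfig(seed=3))


def zero_qa_features(features):
    """Copy of per-protein features with the three QA columns zeroed."""
    out = []
    for feats, labels in features:
        mat = feats.matrix.copy()
        mat[:, 3:] = 0.0
        out.append((meta_model.MetaFeatures(mat, feats.predictor_order), labels))
    return out
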