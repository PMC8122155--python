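"""Synthetic benchmark generator for disorder-prediction QA experiments.

Emulates the statistical structure the calibration and meta-prediction
machinery assumes: proteins carrying intrinsically disordered regions (IDRs)
of short/medium/long length classes at a controllable prevalence, an
ensemble of imperfect base predictors with class-conditional propensity
distributions and elevated error near IDR termini, and raw QA streams whose
correlation with per-residue correctness is a single dial
(``qa_informativeness``). Amino-acid composition is deliberately not
modelled: sequences are uniform random letters, since nothing downstream
predicts from sequence.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .io_formats import Dataset, PredictorTrack, ProteinRecord

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: run-length bounds per IDR class (short <10, medium 10-30, long >30)
_CLASS_BOUNDS = {"short": (2, 9), "medium": (10, 30), "long": (31, 90)}

@dataclasses.dataclass
class ErrorModel:
    """Stochastic error process of one simulated base predictor.

    Errors are region-shaped, the way real disorder predictors fail:
    ``miss_rate`` is the probability that a whole disordered run is predicted
    ordered, ``overcall_rate`` the per-ordered-residue rate at which false
    disordered segments are laid down, and ``boundary_blur`` bounds the
    random jitter of predicted region boundaries (the terminus effect; its
    probability scales with ``miss_rate`` so an error-free model stays
    error-free). ``flip_noise`` adds independent per-residue flips on top.
    ``failure_proteins`` optionally names proteins on which all error rates
    are multiplied by ``failure_multiplier`` — predictors with disjoint
    failure sets give a meta-model something to repair.
    """

    name: str
    miss_rate: float = 0.15
    overcall_rate: float = 0.05
    boundary_blur: int = 3
    propensity_noise: float = 0.3
    flip_noise: float = 0.0
    failure_proteins: Optional[Set[str]] = None
    failure_multiplier: float = 4.0

    def __post_init__(self) -> None:
        for rate in (self.miss_rate, self.overcall_rate, self.flip_noise):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must be in [0, 1]")
        if not 0.0 <= self.propensity_noise <= 1.0:
            raise ValueError("propensity_noise must be in [0, 1]")


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for a synthetic benchmark.

    Defaults: 6% disordered residues (the prevalence of large curated
    disorder benchmarks), a mix of short/medium/long IDRs, three base
    predictors, and raw QA correlated 0.9 with correctness.
    """

    n_proteins: int = 100
    length_range: Tuple[int, int] = (100, 300)
    disorder_fraction: float = 0.06
    idr_length_mix: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"short": 0.2, "medium": 0.4, "long": 0.4}
    )
    error_models: List[ErrorModel] = dataclasses.field(
        default_factory=lambda: [
            ErrorModel("base1", miss_rate=0.12, overcall_rate=0.04),
            ErrorModel("base2", miss_rate=0.15, overcall_rate=0.05),
            ErrorModel("base3", miss_rate=0.18, overcall_rate=0.06),
        ]
    )
    qa_informativeness: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.idr_length_mix.values()) - 1.0) > 1e-9:
            raise ValueError("idr_length_mix weights must sum to 1")
        if set(self.idr_length_mix) - set(_CLASS_BOUNDS):
            raise ValueError(f"IDR classes must be among {sorted(_CLASS_BOUNDS)}")
        if self.length_range[0] < 30:
            raise ValueError("minimum protein length is 30")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max) with min <= max")
        if not 0.0 < self.disorder_fraction < 1.0:
            raise ValueError("disorder_fraction must be in (0, 1)")
        if not 0.0 <= self.qa_informativeness <= 1.0:
            raise ValueError("qa_informativeness must be in [0, 1]")


def _draw_run_length(rng: np.random.Generator, mix: Dict[str, float]) -> int:
    classes = sorted(mix)
    weights = np.array([mix[c] for c in classes])
    cls = rng.choice(classes, p=weights / weights.sum())
    lo, hi = _CLASS_BOUNDS[cls]
    return int(rng.integers(lo, hi + 1))


def generate_proteins(config: SyntheticConfig) -> List[ProteinRecord]:
    """Generate labeled proteins whose pooled disorder fraction approximates
    ``config.disorder_fraction`` within 10% relative.

    IDR runs are drawn from ``idr_length_mix`` against a dataset-level
    disorder budget and placed at non-overlapping, non-adjacent random
    positions (so distinct runs never merge into a longer one).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    total = int(lengths.sum())
    target = config.disorder_fraction * total

    run_lengths: List[int] = []
    placed = 0
    while placed < target:
        run = _draw_run_length(rng, config.idr_length_mix)
        if abs(placed + run - target) > abs(placed - target):
            break
        run_lengths.append(run)
        placed += run
    run_lengths.sort(reverse=True)  # place long runs first while space is easy

    labels = [np.zeros(L, dtype=np.int8) for L in lengths]
    occupied: List[List[Tuple[int, int]]] = [[] for _ in lengths]
    realized = 0
    for run in run_lengths:
        done = False
        for _ in range(200):
            p = int(rng.integers(0, config.n_proteins))
            L = int(lengths[p])
            if run > L:
                continue
            start = int(rng.integers(0, L - run + 1))
            end = start + run
            # keep >=1 ordered residue between runs
            if all(end + 1 <= s or start >= e + 1 for s, e in occupied[p]):
                occupied[p].append((start, end))
                labels[p][start:end] = 1
                realized += run
                done = True
                break
        if not done:
            continue  # skip unplaceable run; feasibility checked below

    if target > 0 and abs(realized - target) / target > 0.10:
        raise ValueError(
            f"could not realize disorder fraction {config.disorder_fraction} "
            f"(target {target:.0f} residues, placed {realized})"
        )

    width = len(str(config.n_proteins))
    records = []
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(_AA, size=int(L)))
        records.append(
            ProteinRecord(id=f"SYN{i:0{width}d}", sequence=seq, labels=labels[i])
        )
    return records


def _disorder_runs(labels: np.ndarray) -> List[Tuple[int, int]]:
    padded = np.concatenate([[0], labels, [0]])
    d = np.diff(padded)
    return list(zip(np.flatnonzero(d == 1).tolist(),
                    np.flatnonzero(d == -1).tolist()))


def _predict_binary(
    lab: np.ndarray, model: ErrorModel, in_failure: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Region-shaped prediction errors for one protein."""
    L = len(lab)
    mult = model.failure_multiplier if in_failure else 1.0
    miss = min(model.miss_rate * mult, 0.85)
    overcall = min(model.overcall_rate * mult, 0.5)
    predicted = np.zeros(L, dtype=np.int8)
    blur_p = min(0.8, 2.5 * miss)
    for start, end in _disorder_runs(lab):
        if rng.random() < miss:
            continue  # whole run missed
        s, e = start, end
        # boundary jitter: each terminus shifts by up to boundary_blur
        for side in (0, 1):
            if model.boundary_blur > 0 and rng.random() < blur_p:
                shift = int(rng.integers(1, model.boundary_blur + 1))
                if side == 0:
                    s = max(0, s + (shift if rng.random() < 0.5 else -shift))
                else:
                    e = min(L, e + (shift if rng.random() < 0.5 else -shift))
        if s < e:
            predicted[s:e] = 1
    # false disordered segments over ordered stretches
    n_ordered = int((lab == 0).sum())
    n_seg = rng.poisson(overcall * n_ordered / 8.0)
    for _ in range(n_seg):
        seg = int(rng.integers(3, 13))
        if L - seg <= 0:
            continue
        s = int(rng.integers(0, L - seg + 1))
        if lab[s : s + seg].sum() == 0:
            predicted[s : s + seg] = 1
    if model.flip_noise > 0:
        flips = rng.random(L) < model.flip_noise
        predicted = np.where(flips, 1 - predicted, predicted).astype(np.int8)
    return predicted


def generate_tracks(
    records: Sequence[ProteinRecord],
    error_models: Sequence[ErrorModel],
    qa_informativeness: float,
    seed: int = 0,
) -> Dict[Tuple[str, str], PredictorTrack]:
    """Simulate base-predictor tracks for every (protein, error model) pair.

    The error model yields a per-residue correctness indicator (errors are
    region-shaped: missed disordered runs, jittered boundaries, false
    disordered segments); propensities come from class-conditional
    distributions on either side of the 0.5 threshold (so the binary call
    always reflects the realized class), and raw QA is a convex mix of the
    correctness indicator and uniform noise weighted by
    ``qa_informativeness``.
    """
    rng = np.random.default_rng(seed)
    tracks: Dict[Tuple[str, str], PredictorTrack] = {}
    for model in error_models:
        # per-model concentration of the propensity Beta shapes
        km = 0.5 + 8.0 * (1.0 - model.propensity_noise)
        a, b = 1.0 + 0.7 * km, 1.0 + 0.3 * km
        for rec in records:
            if rec.labels is None:
                raise ValueError(f"protein {rec.id!r} has no labels")
            lab = rec.labels.astype(np.int8)
            L = len(lab)
            in_failure = bool(
                model.failure_proteins and rec.id in model.failure_proteins
            )
            predicted = _predict_binary(lab, model, in_failure, rng)
            correct = predicted == lab
            x = rng.beta(a, b, size=L)  # mode ~0.7 on [0, 1]
            prop = np.where(predicted == 1, 0.5 + 0.5 * x, 0.5 - 0.5 * x)
            raw_qa = (
                qa_informativeness * correct.astype(float)
                + (1.0 - qa_informativeness) * rng.random(L)
            )
            tracks[(rec.id, model.name)] = PredictorTrack(
                predictor_name=model.name,
                propensity=prop,
                binary=(prop > 0.5).astype(np.int8),
                raw_qa=raw_qa,
            )
    return tracks


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Convenience: proteins plus tracks under one config."""
    records = generate_proteins(config)
    tracks = generate_tracks(
        records, config.error_models, config.qa_informativeness,
        seed=config.seed + 1,
    )
    return Dataset(records=records, tracks=tracks)


@dataclasses.dataclass
class MetaScenario:
    """Canonical fixture for meta-predictor experiments.

    Three base predictors with pairwise-disjoint failure-protein sets whose
    union covers every protein, informative QA, and a three-way protein
    split: ``calibration_ids`` (QA-curve fitting), ``train_ids``
    (meta training) and ``test_ids`` (held-out evaluation) — kept disjoint
    so calibration never sees meta-training or test proteins.
    """

    dataset: Dataset
    predictor_names: Tuple[str, str, str]
    error_models: List[ErrorModel]
    calibration_ids: List[str]
    train_ids: List[str]
    test_ids: List[str]


def make_meta_scenario(
    seed: int = 0,
    n_proteins: int = 60,
    length_range: Tuple[int, int] = (100, 220),
    disorder_fraction: float = 0.12,
    qa_informativeness: float = 0.9,
) -> MetaScenario:
    """Build the standard meta-dominance scenario.

    Each of the three base predictors is moderately noisy everywhere and
    fails hard on its own third of the proteins, where its error rates are
    multiplied (disordered residues are then predicted ordered more often
    than not, i.e. the prediction is near-inverted). Plain consensus of the
    three propensities cannot repair residues where two predictors err
    together, and cannot tell which predictor is the failing one; the QA
    streams flag exactly that, so a QA-aware meta-model out-predicts both
    every individual base and the QA-blind consensus.
    """
    rng = np.random.default_rng(seed)
    config = SyntheticConfig(
        n_proteins=n_proteins,
        length_range=length_range,
        disorder_fraction=disorder_fraction,
        idr_length_mix={"short": 0.3, "medium": 0.5, "long": 0.2},
        qa_informativeness=qa_informativeness,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    records = generate_proteins(config)
    ids = [r.id for r in records]
    perm = rng.permutation(len(ids))
    thirds = np.array_split(perm, 3)
    names = ("base1", "base2", "base3")
    models = [
        ErrorModel(
            name,
            miss_rate=0.15,
            overcall_rate=0.05,
            propensity_noise=0.45,
            failure_proteins={ids[j] for j in third},
            failure_multiplier=3.0,
        )
        for name, third in zip(names, thirds)
    ]
    tracks = generate_tracks(
        records, models, qa_informativeness, seed=int(rng.integers(0, 2**31 - 1))
    )
    dataset = Dataset(records=records, tracks=tracks)
    # split stratified by failure set so every subset sees each predictor
    # fail on the same share of proteins
    calibration: List[str] = []
    train: List[str] = []
    test: List[str] = []
    for third in thirds:
        sub = rng.permutation(third)
        n_cal = max(1, len(sub) // 4)
        n_test = max(1, len(sub) // 4)
        calibration.extend(ids[j] for j in sub[:n_cal])
        test.extend(ids[j] for j in sub[n_cal : n_cal + n_test])
        train.extend(ids[j] for j in sub[n_cal + n_test :])
    return MetaScenario(
        dataset=dataset,
        predictor_names=names,
        error_models=models,
        calibration_ids=calibration,
        train_ids=train,
        test_ids=test,
    )
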