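"""QA-aware deep meta-predictor of intrinsic disorder.

Per residue, the meta-model consumes six features — the disorder propensities
of three base predictors plus their three MCC-calibrated QA scores — and
outputs a fused disorder propensity. The QA columns let the network recognise
residues where a particular base prediction is unreliable and repair them
from the other two streams.

Three architectures are provided: a position-wise feedforward network, a
stacked-LSTM sequence labeller, and the default bidirectional-LSTM variant.
The networks are small (tens of units) and implemented directly in numpy with
analytic backpropagation; training uses stochastic gradient descent with
binary cross-entropy loss, one protein per update, and a multiplicative
per-epoch learning-rate decay. Shallow logistic-regression and k-NN baselines
share the prediction contract.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .io_formats import PredictorTrack, ValidationError

ARCHITECTURES = ("feedforward", "recurrent", "bidirectional-recurrent")

#: LSTM-layer sizes of the architecture search grid, largest first
GRID_SIZES = (200, 100, 50, 25, 12, 6, 3)

_MAX_GRAD_NORM = 5.0  # global-norm clip; keeps small-batch LSTM SGD stable


@dataclasses.dataclass
class MetaModelConfig:
    """Hyperparameters of one meta-model candidate.

    Defaults reproduce the selected design: a bidirectional-LSTM network with
    25 units per recurrent layer and a 10-unit dense input layer, dropout
    0.5, SGD at learning rate 0.01 decayed 1% per epoch for 50 epochs,
    binary cross-entropy loss.
    """

    architecture: str = "bidirectional-recurrent"
    recurrent_units: int = 25
    dense_units: int = 10
    dropout: float = 0.5
    learning_rate: float = 0.01
    decay_per_epoch: float = 0.01
    epochs: int = 50
    seed: int = 0
    validation_fraction: float = 0.2
    optimizer: str = "rmsprop"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}"
            )
        if self.optimizer not in ("sgd", "momentum", "rmsprop"):
            raise ValueError("optimizer must be sgd, momentum or rmsprop")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate must be > 0 and epochs >= 1")


@dataclasses.dataclass
class MetaFeatures:
    """Per-residue feature matrix: three propensities then three mapped QA."""

    matrix: np.ndarray  # (L, 6)
    predictor_order: Tuple[str, str, str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 6:
            raise ValidationError("feature matrix must be (L, 6)")
        props, qas = self.matrix[:, :3], self.matrix[:, 3:]
        if props.size and (props.min() < 0 or props.max() > 1):
            raise ValidationError("propensity features outside [0, 1]")
        if qas.size and (qas.min() < -1 or qas.max() > 1):
            raise ValidationError("QA features outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.matrix)


def assemble_features(
    tracks: Sequence[PredictorTrack],
    predictor_order: Sequence[str],
) -> MetaFeatures:
    """Build the (L, 6) meta input from exactly three tracks with mapped QA.

    Columns follow ``predictor_order`` regardless of the order in which the
    tracks are supplied.
    """
    if len(tracks) != 3 or len(predictor_order) != 3:
        raise ValidationError("exactly three base-predictor tracks are required")
    by_name = {t.predictor_name: t for t in tracks}
    if set(by_name) != set(predictor_order):
        raise ValidationError(
            f"track names {sorted(by_name)} do not match declared order "
            f"{list(predictor_order)}"
        )
    ordered = [by_name[name] for name in predictor_order]
    lengths = {len(t) for t in ordered}
    if len(lengths) != 1:
        raise ValidationError(f"track lengths differ: {sorted(lengths)}")
    for t in ordered:
        if t.mapped_qa is None:
            raise ValidationError(f"track {t.predictor_name!r} has no mapped_qa")
    mat = np.column_stack(
        [t.propensity for t in ordered] + [t.mapped_qa for t in ordered]
    )
    return MetaFeatures(matrix=mat, predictor_order=tuple(predictor_order))


# ---------------------------------------------------------------------------
# numpy layers (sequence-first: inputs are (T, features), one protein at a
# time, so no padding or masking is ever needed)
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Dense:
    def __init__(self, rng, d_in, d_out, activation="relu"):
        self.W = _glorot(rng, d_in, d_out)
        self.b = np.zeros(d_out)
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        a = x @ self.W + self.b
        if self.activation == "relu":
            self._a = a
            return np.maximum(a, 0.0)
        if self.activation == "linear":
            return a
        raise AssertionError(self.activation)

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * (self._a > 0)
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class _Dropout:
    def __init__(self, rng, rate):
        self.rng = rng
        self.rate = rate

    def params(self):
        return []

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTM:
    """Single-direction LSTM over a (T, D) sequence, gate order i, f, g, o."""

    def __init__(self, rng, d_in, units, reverse=False):
        h = units
        self.Wx = _glorot(rng, d_in, 4 * h)
        self.Wh = _glorot(rng, h, 4 * h)
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias init
        self.units = h
        self.reverse = reverse
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("Wx", self.Wx, self.dWx), ("Wh", self.Wh, self.dWh),
                ("b", self.b, self.db)]

    def forward(self, x, train=False):
        if self.reverse:
            x = x[::-1]
        T = x.shape[0]
        h = self.units
        xw = x @ self.Wx + self.b
        H = np.zeros((T, h))
        cache = []
        h_prev = np.zeros(h)
        c_prev = np.zeros(h)
        for t in range(T):
            a = xw[t] + h_prev @ self.Wh
            i = _sigmoid(a[:h])
            f = _sigmoid(a[h : 2 * h])
            g = np.tanh(a[2 * h : 3 * h])
            o = _sigmoid(a[3 * h :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            H[t] = o * tc
            cache.append((i, f, g, o, c_prev, tc))
            h_prev, c_prev = H[t], c
        self._x, self._H, self._cache = x, H, cache
        out = H[::-1] if self.reverse else H
        return out

    def backward(self, dH):
        if self.reverse:
            dH = dH[::-1]
        x, H, cache = self._x, self._H, self._cache
        T, h = H.shape
        dA = np.zeros((T, 4 * h))
        dh_next = np.zeros(h)
        dc_next = np.zeros(h)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc = cache[t]
            dh = dH[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ])
            dA[t] = da
            dh_next = da @ self.Wh.T
        self.dWx += x.T @ dA
        h_prev_all = np.vstack([np.zeros(h), H[:-1]])
        self.dWh += h_prev_all.T @ dA
        self.db += dA.sum(axis=0)
        dx = dA @ self.Wx.T
        return dx[::-1] if self.reverse else dx


class _BiLSTM:
    def __init__(self, rng, d_in, units):
        self.fwd = _LSTM(rng, d_in, units)
        self.bwd = _LSTM(rng, d_in, units, reverse=True)
        self.units = 2 * units

    def params(self):
        return [("f" + n, p, g) for n, p, g in self.fwd.params()] + \
               [("b" + n, p, g) for n, p, g in self.bwd.params()]

    def forward(self, x, train=False):
        return np.concatenate(
            [self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=1
        )

    def backward(self, dy):
        h = self.units // 2
        return self.fwd.backward(dy[:, :h]) + self.bwd.backward(dy[:, h:])


class _Network:
    """A stack of layers with a sigmoid scalar output per sequence position."""

    def __init__(self, config: MetaModelConfig, d_in: int = 6):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: List = []
        if config.architecture == "feedforward":
            layers.append(_Dense(rng, d_in, config.dense_units))
            layers.append(_Dropout(rng, config.dropout))
            layers.append(_Dense(rng, config.dense_units, config.dense_units))
            layers.append(_Dropout(rng, config.dropout))
            d_last = config.dense_units
        else:
            layers.append(_Dense(rng, d_in, config.dense_units))
            rec = _BiLSTM if config.architecture == "bidirectional-recurrent" \
                else _LSTM
            r1 = rec(rng, config.dense_units, config.recurrent_units)
            width = r1.units
            layers.append(r1)
            layers.append(_Dropout(rng, config.dropout))
            r2 = rec(rng, width, config.recurrent_units)
            layers.append(r2)
            layers.append(_Dropout(rng, config.dropout))
            d_last = r2.units
        layers.append(_Dense(rng, d_last, 1, activation="linear"))
        self.layers = layers

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for _, p, _ in layer.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return _sigmoid(x[:, 0])

    def train_step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One SGD step on one protein; returns the mean BCE loss."""
        p = self.forward(x, train=True)
        eps = 1e-12
        loss = -float(np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        # combined sigmoid + BCE gradient wrt the pre-activation
        d = ((p - y) / len(y))[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)
        self._clip_and_apply(lr)
        return loss

    def _clip_and_apply(self, lr: float) -> None:
        grads = [g for layer in self.layers for _, _, g in layer.params()]
        norm = math.sqrt(sum(float(np.sum(g * g)) for g in grads))
        scale = _MAX_GRAD_NORM / norm if norm > _MAX_GRAD_NORM else 1.0
        opt = self.config.optimizer
        if not hasattr(self, "_opt_state"):
            self._opt_state = [np.zeros_like(g) for g in grads]
        params = [p for layer in self.layers for _, p, _ in layer.params()]
        for p, g, s in zip(params, grads, self._opt_state):
            gc = scale * g
            if opt == "rmsprop":
                s *= 0.9
                s += 0.1 * gc * gc
                p -= lr * gc / (np.sqrt(s) + 1e-7)
            elif opt == "momentum":
                s *= 0.9
                s += gc
                p -= lr * s
            else:
                p -= lr * gc
            g[...] = 0.0

    # -- weight (de)serialization -------------------------------------------
    def get_weights(self) -> Dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for name, p, _ in layer.params():
                out[f"layer{li}_{name}"] = p.copy()
        return out

    def set_weights(self, weights: Dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name, p, _ in layer.params():
                p[...] = weights[f"layer{li}_{name}"]


def build_network(config: MetaModelConfig) -> _Network:
    """Instantiate an untrained network for ``config``."""
    return _Network(config)


@dataclasses.dataclass
class TrainedMeta:
    """A trained meta-predictor plus everything needed to apply it."""

    config: MetaModelConfig
    network: _Network
    predictor_order: Tuple[str, str, str]
    binary_threshold: float
    validation_auc: float

    def predict(self, features: MetaFeatures) -> np.ndarray:
        if features.predictor_order != tuple(self.predictor_order):
            raise ValidationError(
                f"feature predictor order {features.predictor_order} does not "
                f"match the model's {tuple(self.predictor_order)}"
            )
        return self.network.forward(features.matrix, train=False)


def _roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def _best_mcc_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold on [0, 1] propensities that maximizes MCC, scanned over the
    midpoints of sorted unique scores."""
    from .calibration import ConfusionCounts, mcc as _mcc

    uniq = np.unique(scores)
    if len(uniq) == 1:
        return 0.5
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    if len(cands) > 512:  # subsample the sweep for speed; MCC is smooth in t
        cands = cands[np.linspace(0, len(cands) - 1, 512).astype(int)]
    best_t, best_m = 0.5, -2.0
    for t in cands:
        m = _mcc(ConfusionCounts.from_arrays(scores > t, labels))
        if m > best_m:
            best_t, best_m = float(t), m
    return best_t


def _split_proteins(n: int, validation_fraction: float, rng) -> Tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * validation_fraction)))
    if n_val >= n:
        n_val = n - 1
    return idx[n_val:], idx[:n_val]


def train_meta(
    proteins: Sequence[Tuple[MetaFeatures, np.ndarray]],
    config: MetaModelConfig,
) -> TrainedMeta:
    """Train the configured network on per-protein (features, labels) pairs.

    Proteins are split at random (seeded) into design and validation subsets
    by ``validation_fraction``; training runs SGD on the design subset, the
    binary threshold is chosen to maximize MCC on the validation subset, and
    the validation ROC-AUC is recorded for model selection.
    """
    if len(proteins) < 2:
        raise ValidationError("training requires at least two proteins")
    order = proteins[0][0].predictor_order
    for feats, labels in proteins:
        if feats.predictor_order != order:
            raise ValidationError("inconsistent predictor order across proteins")
        if len(feats) != len(labels):
            raise ValidationError("feature/label length mismatch")
    all_labels = np.concatenate([lab for _, lab in proteins])
    if len(np.unique(all_labels)) < 2:
        raise ValidationError(
            "training requires both ordered and disordered residues"
        )
    rng = np.random.default_rng(config.seed)
    design_idx, val_idx = _split_proteins(len(proteins), config.validation_fraction, rng)
    design = [proteins[i] for i in design_idx]
    design_labels = np.concatenate([lab for _, lab in design])
    if len(np.unique(design_labels)) < 2:
        raise ValidationError(
            "training requires both ordered and disordered residues in the "
            "design subset"
        )
    val = [proteins[i] for i in val_idx]

    net = _Network(config)
    lr = config.learning_rate
    for epoch in range(config.epochs):
        for i in rng.permutation(len(design)):
            feats, labels = design[i]
            net.train_step(feats.matrix, np.asarray(labels, dtype=float), lr)
        lr *= 1.0 - config.decay_per_epoch

    val_scores = np.concatenate([net.forward(f.matrix) for f, _ in val])
    val_labels = np.concatenate([np.asarray(lab) for _, lab in val])
    if len(np.unique(val_labels)) < 2:
        # degenerate validation subset: fall back to design subset for
        # threshold/AUC bookkeeping
        val_scores = np.concatenate([net.forward(f.matrix) for f, _ in design])
        val_labels = design_labels
    auc = _roc_auc(val_scores, val_labels)
    threshold = _best_mcc_threshold(val_scores, val_labels)
    return TrainedMeta(
        config=config,
        network=net,
        predictor_order=order,
        binary_threshold=threshold,
        validation_auc=auc,
    )


def default_grid(
    epochs: int = 50, seed: int = 0, validation_fraction: float = 0.2
) -> List[MetaModelConfig]:
    """The 21-candidate search grid: 3 architectures x 7 layer sizes.

    Sizes scale the recurrent layers; the dense layer scales as
    max(3, size // 2) except the published 25-unit winner, whose dense layer
    is pinned at 10.
    """
    grid = []
    for arch in ARCHITECTURES:
        for size in GRID_SIZES:
            dense = 10 if size == 25 else max(3, size // 2)
            grid.append(MetaModelConfig(
                architecture=arch,
                recurrent_units=size,
                dense_units=dense if arch != "feedforward" else max(dense, size),
                epochs=epochs,
                seed=seed,
                validation_fraction=validation_fraction,
            ))
    return grid


def select_architecture(
    proteins: Sequence[Tuple[MetaFeatures, np.ndarray]],
    grid: Sequence[MetaModelConfig],
) -> TrainedMeta:
    """Train every config in ``grid`` and return the one with the highest
    validation ROC-AUC (ties broken by smaller parameter count)."""
    if not grid:
        raise ValueError("empty architecture grid")
    best: Optional[TrainedMeta] = None
    for config in grid:
        model = train_meta(proteins, config)
        if best is None:
            best = model
            continue
        if model.validation_auc > best.validation_auc or (
            model.validation_auc == best.validation_auc
            and model.network.parameter_count() < best.network.parameter_count()
        ):
            best = model
    return best


def predict_meta(model: TrainedMeta, tracks: Sequence[PredictorTrack]) -> PredictorTrack:
    """Apply a trained meta-model to three base tracks.

    Returns a track whose propensity is the network output and whose binary
    call thresholds it at the model's MCC-optimal threshold. QA fields are
    left unset; they are filled by the calibration module downstream.
    """
    feats = assemble_features(tracks, model.predictor_order)
    prop = model.predict(feats)
    return PredictorTrack(
        predictor_name="meta",
        propensity=np.clip(prop, 0.0, 1.0),
        binary=(prop > model.binary_threshold).astype(np.int8),
    )


# ---------------------------------------------------------------------------
# shallow baselines
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TrainedBaseline:
    """Window-free per-residue baseline with the TrainedMeta contract."""

    kind: str
    estimator: object
    predictor_order: Tuple[str, str, str]
    binary_threshold: float
    validation_auc: float

    def predict(self, features: MetaFeatures) -> np.ndarray:
        if features.predictor_order != tuple(self.predictor_order):
            raise ValidationError("predictor order mismatch")
        return self.estimator.predict_proba(features.matrix)[:, 1]


def baseline_meta(
    proteins: Sequence[Tuple[MetaFeatures, np.ndarray]],
    kind: str,
    seed: int = 0,
    validation_fraction: float = 0.2,
    knn_neighbors: int = 10,
) -> TrainedBaseline:
    """Train a shallow baseline (``logistic`` or ``knn``) on the 6 features."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier

    if kind not in ("logistic", "knn"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    if len(proteins) < 2:
        raise ValidationError("training requires at least two proteins")
    order = proteins[0][0].predictor_order
    all_labels = np.concatenate([np.asarray(lab) for _, lab in proteins])
    if len(np.unique(all_labels)) < 2:
        raise ValidationError(
            "training requires both ordered and disordered residues"
        )
    rng = np.random.default_rng(seed)
    design_idx, val_idx = _split_proteins(len(proteins), validation_fraction, rng)
    X_design = np.vstack([proteins[i][0].matrix for i in design_idx])
    y_design = np.concatenate([np.asarray(proteins[i][1]) for i in design_idx])
    X_val = np.vstack([proteins[i][0].matrix for i in val_idx])
    y_val = np.concatenate([np.asarray(proteins[i][1]) for i in val_idx])
    if kind == "logistic":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    else:
        est = KNeighborsClassifier(n_neighbors=knn_neighbors)
    est.fit(X_design, y_design)
    if len(np.unique(y_val)) < 2:
        X_val, y_val = X_design, y_design
    scores = est.predict_proba(X_val)[:, 1]
    return TrainedBaseline(
        kind=kind,
        estimator=est,
        predictor_order=order,
        binary_threshold=_best_mcc_threshold(scores, y_val),
        validation_auc=_roc_auc(scores, y_val),
    )


# ---------------------------------------------------------------------------
# model bundle I/O
# ---------------------------------------------------------------------------


def save_meta(model: TrainedMeta, directory) -> None:
    """Write a model bundle: config.yaml + weights.npz + predictor_order.txt."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(model.config)
    cfg["binary_threshold"] = model.binary_threshold
    cfg["validation_auc"] = model.validation_auc
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    np.savez(directory / "weights.npz", **model.network.get_weights())
    (directory / "predictor_order.txt").write_text(
        "\n".join(model.predictor_order) + "\n"
    )


def load_meta(directory) -> TrainedMeta:
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    threshold = cfg.pop("binary_threshold")
    auc = cfg.pop("validation_auc")
    config = MetaModelConfig(**cfg)
    net = _Network(config)
    with np.load(directory / "weights.npz") as npz:
        net.set_weights(dict(npz))
    order = tuple(
        (directory / "predictor_order.txt").read_text().split()
    )
    return TrainedMeta(
        config=config,
        network=net,
        predictor_order=order,
        binary_threshold=float(threshold),
        validation_auc=float(auc),
    )
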