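"""Raw-QA -> interpretable-MCC calibration.

A predictor's raw per-residue quality-assessment (QA) scores are mapped onto
the MCC scale by pooling a labeled calibration set, sorting residues by raw
QA, sliding a fixed-size window over the sorted list, and measuring the MCC
of the binary disorder calls inside each window. The window MCCs, smoothed as
running percentiles, define a piecewise-linear mapping from raw QA to an
expected MCC; the resulting "mapped QA" score for a residue reads directly as
the MCC a practitioner should expect for predictions with that confidence.
The fitted curve is deliberately not forced monotone.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import PredictorTrack, ValidationError

#: number of consecutive window positions over which the percentile bands
#: (25th/50th/75th) of window MCCs are taken
PERCENTILE_NEIGHBORHOOD = 21

DEFAULT_WINDOW = 2000


@dataclasses.dataclass
class ConfusionCounts:
    """2x2 contingency counts; disordered residues are the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_arrays(cls, binary: np.ndarray, labels: np.ndarray) -> "ConfusionCounts":
        binary = np.asarray(binary).astype(bool)
        labels = np.asarray(labels).astype(bool)
        return cls(
            tp=int(np.sum(binary & labels)),
            tn=int(np.sum(~binary & ~labels)),
            fp=int(np.sum(binary & ~labels)),
            fn=int(np.sum(~binary & labels)),
        )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Returns 0.0 when any contingency marginal is zero (the standard
    convention for an undefined denominator). Raises on an empty table.
    """
    if counts.total == 0:
        raise ValueError("MCC undefined for empty confusion table")
    tp, tn, fp, fn = (float(counts.tp), float(counts.tn),
                      float(counts.fp), float(counts.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclasses.dataclass
class CalibrationCurve:
    """Fitted raw-QA -> MCC mapping with descriptive percentile bands.

    ``knots`` are (raw_qa_value, mcc_median, mcc_p25, mcc_p75) tuples in
    ascending raw-QA order. ``dataset_mcc`` is the MCC over the whole
    calibration pool (the reference line for coverage analyses).
    """

    predictor_name: str
    knots: List[Tuple[float, float, float, float]]
    dataset_mcc: float
    window_size: int
    built_on: int

    def __post_init__(self) -> None:
        if not self.knots:
            raise ValidationError("calibration curve needs at least one knot")
        xs = [k[0] for k in self.knots]
        if any(b < a for a, b in zip(xs, xs[1:])):
            raise ValidationError("knots must be sorted ascending by raw QA")
        for raw, med, p25, p75 in self.knots:
            if not (-1.0 - 1e-9 <= p25 <= med + 1e-9 and med <= p75 + 1e-9 <= 1.0 + 2e-9):
                raise ValidationError(
                    f"knot at raw={raw}: requires p25 <= median <= p75 in [-1, 1]"
                )
        if not -1.0 <= self.dataset_mcc <= 1.0:
            raise ValidationError("dataset_mcc outside [-1, 1]")


def _pool(tracks: Sequence[Tuple[PredictorTrack, np.ndarray, str]]):
    """Pool residues across proteins, sorted by (raw_qa, protein id, position)."""
    raws, bins, labs, keys = [], [], [], []
    for track, labels, pid in tracks:
        if track.raw_qa is None:
            raise ValidationError(f"track {pid!r} has no raw_qa")
        labels = np.asarray(labels)
        if len(labels) != len(track):
            raise ValidationError(f"track {pid!r}: labels/track length mismatch")
        raws.append(np.asarray(track.raw_qa, dtype=float))
        bins.append(np.asarray(track.binary, dtype=np.int8))
        labs.append(labels.astype(np.int8))
        keys.extend((pid, i) for i in range(len(track)))
    raw = np.concatenate(raws)
    order = sorted(range(len(raw)), key=lambda i: (raw[i], keys[i][0], keys[i][1]))
    order = np.asarray(order)
    return raw[order], np.concatenate(bins)[order], np.concatenate(labs)[order]


def _window_starts(n: int, window: int, stride: int) -> np.ndarray:
    starts = list(range(0, n - window + 1, stride))
    if starts[-1] != n - window:
        starts.append(n - window)
    return np.asarray(starts)


def build_curve(
    tracks: Sequence[Tuple[PredictorTrack, np.ndarray, str]],
    window_size: int = DEFAULT_WINDOW,
    stride: Optional[int] = None,
    predictor_name: Optional[str] = None,
) -> CalibrationCurve:
    """Fit the raw-QA -> MCC mapping from labeled tracks.

    ``tracks`` is a sequence of (track-with-raw_qa, labels, protein-id). The
    pooled residues are sorted ascending by raw QA (ties broken by protein id
    then position), a window of ``window_size`` residues slides with
    ``stride`` (default ceil(window/10)), and each window position yields a
    knot whose x is the window's median raw QA and whose median/p25/p75 MCC
    values are percentiles of window MCCs over a 21-window neighborhood.
    """
    if window_size < 1:
        raise ValueError("window_size must be positive")
    raw, binary, labels = _pool(tracks)
    n = len(raw)
    if n < 2 * window_size:
        raise ValidationError(
            f"need at least {2 * window_size} pooled residues, got {n}"
        )
    if labels.sum() == 0:
        raise ValidationError("no disordered residues in calibration pool")
    name = predictor_name or tracks[0][0].predictor_name
    total = ConfusionCounts.from_arrays(binary, labels)
    dataset_mcc = mcc(total)
    built_on = n

    if raw.max() == raw.min():
        # no ordering information: degenerate single-knot curve
        knot = (float(raw[0]), dataset_mcc, dataset_mcc, dataset_mcc)
        return CalibrationCurve(name, [knot], dataset_mcc, window_size, built_on)

    if stride is None:
        stride = max(1, math.ceil(window_size / 10))
    starts = _window_starts(n, window_size, stride)

    # cumulative sums give each window's contingency in O(1)
    cum_b = np.concatenate([[0], np.cumsum(binary)])
    cum_l = np.concatenate([[0], np.cumsum(labels)])
    cum_bl = np.concatenate([[0], np.cumsum((binary == 1) & (labels == 1))])
    ends = starts + window_size
    tp = cum_bl[ends] - cum_bl[starts]
    pb = cum_b[ends] - cum_b[starts]
    pl = cum_l[ends] - cum_l[starts]
    fp = pb - tp
    fn = pl - tp
    tn = window_size - tp - fp - fn
    num = tp * tn - fp * fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    window_mcc = np.where(denom > 0, num / np.sqrt(np.maximum(denom, 1.0)), 0.0)

    half = window_size // 2
    knot_x = np.array([
        float(np.median(raw[s : s + window_size])) for s in starts
    ])
    # (knot x could also be raw[s + half]; the median is robust to ties)
    _ = half

    k = PERCENTILE_NEIGHBORHOOD // 2
    m = len(starts)
    knots: List[Tuple[float, float, float, float]] = []
    for j in range(m):
        lo, hi = max(0, j - k), min(m, j + k + 1)
        nb = window_mcc[lo:hi]
        p25, med, p75 = np.percentile(nb, [25, 50, 75])
        knots.append((knot_x[j], float(med), float(p25), float(p75)))

    knots.sort(key=lambda t: t[0])
    # merge duplicate x (ties in raw QA) by the median of each band, so a few
    # windows straddling a regime boundary cannot drag the merged knot
    merged: List[Tuple[float, float, float, float]] = []
    i = 0
    while i < len(knots):
        j = i
        while j < len(knots) and knots[j][0] == knots[i][0]:
            j += 1
        group = knots[i:j]
        merged.append((
            group[0][0],
            float(np.median([g[1] for g in group])),
            float(np.median([g[2] for g in group])),
            float(np.median([g[3] for g in group])),
        ))
        i = j
    return CalibrationCurve(name, merged, dataset_mcc, window_size, built_on)


def apply_curve(curve: CalibrationCurve, raw_qa: np.ndarray) -> np.ndarray:
    """Map raw QA values to MCC-valued scores via the median line.

    Piecewise-linear interpolation on the (raw, median) knots; values outside
    the knot range clamp to the nearest end knot.
    """
    raw_qa = np.asarray(raw_qa, dtype=float)
    xs = np.array([k[0] for k in curve.knots])
    ys = np.array([k[1] for k in curve.knots])
    return np.clip(np.interp(raw_qa, xs, ys), -1.0, 1.0)


def save_curve(curve: CalibrationCurve, path) -> None:
    payload = {
        "predictor_name": curve.predictor_name,
        "window_size": curve.window_size,
        "built_on": curve.built_on,
        "dataset_mcc": round(curve.dataset_mcc, 6),
        "knots": [
            {"raw": round(r, 6), "median": round(m, 6),
             "p25": round(p25, 6), "p75": round(p75, 6)}
            for r, m, p25, p75 in curve.knots
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_curve(path) -> CalibrationCurve:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        knots = [
            (float(k["raw"]), float(k["median"]), float(k["p25"]), float(k["p75"]))
            for k in payload["knots"]
        ]
        return CalibrationCurve(
            predictor_name=payload["predictor_name"],
            knots=knots,
            dataset_mcc=float(payload["dataset_mcc"]),
            window_size=int(payload["window_size"]),
            built_on=int(payload["built_on"]),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed calibration curve file: {exc}") from exc
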