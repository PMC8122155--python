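"""Readers and writers for sequences, per-residue prediction tracks and labels.

All in-memory vectors are 0-based numpy arrays; per-residue files use 1-based
contiguous positions. Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclasses.dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue disorder labels.

    Labels use 1 for disordered, 0 for ordered; when present they must match
    the sequence length. Sequences are restricted to the 20 standard residues.
    """

    id: str
    sequence: str
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        bad = [i for i, c in enumerate(self.sequence) if c not in STANDARD_AA]
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: non-standard residue "
                f"{self.sequence[bad[0]]!r} at position {bad[0] + 1}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sequence),):
                raise ValidationError(
                    f"protein {self.id!r}: labels length {len(self.labels)} "
                    f"!= sequence length {len(self.sequence)}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ValidationError(f"protein {self.id!r}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class PredictorTrack:
    """One predictor's per-residue outputs for one protein.

    ``propensity`` is the real-valued disorder likelihood in [0, 1] and
    ``binary`` the predictor's own thresholded call. ``raw_qa`` is an
    uncalibrated confidence stream; ``mapped_qa`` is the calibrated,
    MCC-valued confidence in [-1, 1].
    """

    predictor_name: str
    propensity: np.ndarray
    binary: np.ndarray
    raw_qa: Optional[np.ndarray] = None
    mapped_qa: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.propensity = np.asarray(self.propensity, dtype=float)
        self.binary = np.asarray(self.binary, dtype=np.int8)
        n = len(self.propensity)
        if self.propensity.min(initial=0.0) < 0 or self.propensity.max(initial=0.0) > 1:
            raise ValidationError(
                f"track {self.predictor_name!r}: propensity outside [0, 1]"
            )
        for name in ("binary", "raw_qa", "mapped_qa"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=np.int8 if name == "binary" else float)
            setattr(self, name, v)
            if len(v) != n:
                raise ValidationError(
                    f"track {self.predictor_name!r}: {name} length {len(v)} "
                    f"!= propensity length {n}"
                )
        if self.mapped_qa is not None and (
            self.mapped_qa.min() < -1 or self.mapped_qa.max() > 1
        ):
            raise ValidationError(
                f"track {self.predictor_name!r}: mapped_qa outside [-1, 1]"
            )

    def __len__(self) -> int:
        return len(self.propensity)


@dataclasses.dataclass
class Dataset:
    """Protein records plus per-(protein, predictor) tracks."""

    records: List[ProteinRecord]
    tracks: Dict[Tuple[str, str], PredictorTrack]

    def __post_init__(self) -> None:
        by_id = {r.id: r for r in self.records}
        for (pid, pname), track in self.tracks.items():
            if pid not in by_id:
                raise ValidationError(f"track for unknown protein {pid!r}")
            if len(track) != len(by_id[pid]):
                raise ValidationError(
                    f"track ({pid!r}, {pname!r}) length {len(track)} != "
                    f"sequence length {len(by_id[pid])}"
                )

    def record(self, pid: str) -> ProteinRecord:
        for r in self.records:
            if r.id == pid:
                return r
        raise KeyError(pid)

    def predictor_names(self) -> List[str]:
        return sorted({name for _, name in self.tracks})


def read_fasta(path) -> List[ProteinRecord]:
    """Read FASTA into ProteinRecords; ids are headers up to first whitespace.

    Raises FormatError on malformed FASTA or duplicate ids, ValidationError on
    non-standard residues.
    """
    path = Path(path)
    records: List[ProteinRecord] = []
    seen = set()
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1 does not start with '>'")
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq).upper()))
    return records


def write_fasta(records: List[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def _split_line(line: str) -> List[str]:
    # TAB-separated canonical form; comma accepted on read.
    return line.split("\t") if "\t" in line else line.split(",")


def read_track(path, expected_length: Optional[int] = None,
               predictor_name: Optional[str] = None) -> PredictorTrack:
    """Read a per-residue prediction table.

    Columns: position (1-based, contiguous), residue, propensity, binary,
    then optionally raw_qa and mapped_qa. Lines starting with ``#`` are
    header/comment lines; a ``# predictor: NAME`` header sets the name.
    """
    path = Path(path)
    rows: List[List[str]] = []
    name = predictor_name or path.stem
    header_cols: Optional[List[str]] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.lower().startswith("predictor:"):
                    name = stripped.split(":", 1)[1].strip()
                elif stripped.lower().startswith("position"):
                    header_cols = [c.strip() for c in _split_line(stripped)]
                continue
            fields = [f.strip() for f in _split_line(line)]
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 columns")
            rows.append(fields)
    ncol = len(rows[0]) if rows else 4
    if header_cols is None:
        # positional fallback: 5th column raw_qa, 6th mapped_qa
        header_cols = ["position", "residue", "propensity", "binary",
                       "raw_qa", "mapped_qa"][:ncol]
    if len(header_cols) != ncol:
        raise FormatError(f"{path}: header names {len(header_cols)} columns "
                          f"but rows have {ncol}")
    col_index = {c: i for i, c in enumerate(header_cols)}
    prop, binary, raw_qa, mapped_qa = [], [], [], []
    for i, fields in enumerate(rows):
        if len(fields) != ncol:
            raise FormatError(f"{path}: inconsistent column count at row {i + 1}")
        if int(fields[0]) != i + 1:
            raise FormatError(
                f"{path}: non-contiguous positions (expected {i + 1}, "
                f"got {fields[0]})"
            )
        p = float(fields[col_index["propensity"]])
        if not 0.0 <= p <= 1.0:
            raise ValidationError(
                f"{path}: propensity {p} outside [0, 1] at position {i + 1}"
            )
        prop.append(p)
        binary.append(int(fields[col_index["binary"]]))
        if "raw_qa" in col_index:
            raw_qa.append(float(fields[col_index["raw_qa"]]))
        if "mapped_qa" in col_index:
            mapped_qa.append(float(fields[col_index["mapped_qa"]]))
    if expected_length is not None and len(prop) != expected_length:
        raise ValidationError(
            f"{path}: {len(prop)} rows but expected {expected_length}"
        )
    return PredictorTrack(
        predictor_name=name,
        propensity=np.array(prop),
        binary=np.array(binary),
        raw_qa=np.array(raw_qa) if raw_qa else None,
        mapped_qa=np.array(mapped_qa) if mapped_qa else None,
    )


def write_track(track: PredictorTrack, record: ProteinRecord, path) -> None:
    """Write a track as a TAB-separated per-residue table (6-decimal floats)."""
    if len(track) != len(record):
        raise ValidationError(
            f"track length {len(track)} != sequence length {len(record)}"
        )
    cols = ["position", "residue", "propensity", "binary"]
    if track.raw_qa is not None:
        cols.append("raw_qa")
    if track.mapped_qa is not None:
        cols.append("mapped_qa")
    with open(path, "w") as fh:
        fh.write(f"# predictor: {track.predictor_name}\n")
        fh.write("# " + "\t".join(cols) + "\n")
        for i in range(len(track)):
            fields = [
                str(i + 1),
                record.sequence[i],
                f"{track.propensity[i]:.6f}",
                str(int(track.binary[i])),
            ]
            if track.raw_qa is not None:
                fields.append(f"{track.raw_qa[i]:.6f}")
            if track.mapped_qa is not None:
                fields.append(f"{track.mapped_qa[i]:.6f}")
            fh.write("\t".join(fields) + "\n")


def read_labels(path, expected_length: Optional[int] = None) -> np.ndarray:
    """Read a two-column (position, label) per-residue ground-truth file."""
    path = Path(path)
    labels: List[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in _split_line(line)]
            if int(fields[0]) != len(labels) + 1:
                raise FormatError(f"{path}:{lineno}: non-contiguous positions")
            lab = int(fields[-1])
            if lab not in (0, 1):
                raise ValidationError(f"{path}:{lineno}: label must be 0/1")
            labels.append(lab)
    if expected_length is not None and len(labels) != expected_length:
        raise ValidationError(
            f"{path}: {len(labels)} labels but expected {expected_length}"
        )
    return np.array(labels, dtype=np.int8)


def write_labels(labels: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("# position\tlabel\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i + 1}\t{int(lab)}\n")
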