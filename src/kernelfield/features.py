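"""Sequence features: amino-acid composition and [0, 1] range scaling.

A protein is represented by its amino-acid composition — the 20-vector of
residue frequencies in fixed alphabetical one-letter order. Composition is
order-free, so the representation only carries which residues occur and how
often, not where. Ambiguity and non-standard codes (B, J, O, U, X, Z) are
excluded from both numerator and denominator and tallied in ``n_skipped``.

All learning inputs are range-scaled to [0, 1] per feature with min/max
learned from training data only; test values falling outside the training
range are clipped back into [0, 1] so kernel arguments stay bounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, fixed alphabetical one-letter order
AMINO_ACIDS = ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L",
               "M", "N", "P", "Q", "R", "S", "T", "V", "W", "Y")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: ambiguity / non-standard one-letter codes excluded from composition
NONSTANDARD = frozenset("BJOUXZ")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = "".join(self.sequence.split()).upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass
class CompositionVector:
    """Amino-acid fractions plus the counted/skipped residue tallies."""

    fractions: np.ndarray
    n_counted: int
    n_skipped: int

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (20,):
            raise ValueError(f"composition must have 20 entries, got {self.fractions.shape}")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, whitespace-free)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq.strip():
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records, width: int = 60) -> None:
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def aa_composition(rec: SequenceRecord) -> CompositionVector:
    """Amino-acid composition of a sequence.

    fraction_i = count of standard residue i / total standard residues.
    """
    counts = np.zeros(20, dtype=float)
    n_skipped = 0
    for ch in rec.sequence:
        idx = _AA_INDEX.get(ch)
        if idx is None:
            if ch in NONSTANDARD:
                n_skipped += 1
            else:
                raise ValueError(f"record {rec.id!r}: unexpected character {ch!r} in sequence")
        else:
            counts[idx] += 1
    n_counted = int(counts.sum())
    if n_counted == 0:
        raise ValueError(f"record {rec.id!r} has no standard amino acids")
    if n_skipped:
        logger.warning("record %r: skipped %d non-standard residue(s)", rec.id, n_skipped)
    return CompositionVector(fractions=counts / n_counted, n_counted=n_counted, n_skipped=n_skipped)


def composition_matrix(records) -> np.ndarray:
    """Stack per-record compositions into an (n, 20) matrix."""
    return np.vstack([aa_composition(r).fractions for r in records])


@dataclass
class RangeScaler:
    """Per-feature min/max map onto [0, 1], learned from training data.

    Constant training columns (max == min) are flagged and mapped to 0;
    transformed values are clipped into [0, 1].
    """

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maxs == self.mins

    @property
    def n_features(self) -> int:
        return self.mins.shape[0]


def fit_scaler(X) -> RangeScaler:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("fit_scaler expects a 2-D matrix")
    if X.shape[0] < 2:
        raise ValueError(f"fit_scaler needs at least 2 rows, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("fit_scaler requires finite inputs")
    return RangeScaler(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_scaler(scaler: RangeScaler, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    one_row = X.ndim == 1
    if one_row:
        X = X[None, :]
    if X.shape[1] != scaler.n_features:
        raise ValueError(
            f"feature count mismatch: scaler fitted on {scaler.n_features}, got {X.shape[1]}"
        )
    span = scaler.maxs - scaler.mins
    const = scaler.constant_mask
    safe_span = np.where(const, 1.0, span)
    out = (X - scaler.mins) / safe_span
    out[:, const] = 0.0
    np.clip(out, 0.0, 1.0, out=out)
    return out[0] if one_row else out
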