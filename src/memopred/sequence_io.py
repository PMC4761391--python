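"""Reading, validation, curation and numeric encoding of protein sequences.

A protein sequence of length ``k`` is encoded residue-by-residue into integer
codes and embedded row-major into an ``n x n`` square matrix with
``n = ceil(sqrt(k))``; trailing cells are zero padding.  The square embedding
is what makes 2-D moment descriptors (raw, central, Hahn) applicable to a 1-D
primary structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

#: The 20 canonical amino acids in alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL = frozenset(AMINO_ACIDS)

#: Annotation keywords whose presence in a record description disqualifies it
#: from a curated training set (case-insensitive substring match).
DEFAULT_EXCLUDED_KEYWORDS: tuple[str, ...] = (
    "fragment",
    "potential",
    "probable",
    "probably",
    "may be",
    "by similarity",
)

ValidationPolicy = Literal["strict", "drop_nonstandard", "map_x_to_zero"]


class SequenceError(ValueError):
    """Malformed or invalid sequence input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein record: identifier, free-text description, residue string."""

    id: str
    residues: str
    description: str = ""

    @property
    def k(self) -> int:
        """Length of the polypeptide chain."""
        return len(self.residues)


@dataclass(frozen=True)
class EncodingMap:
    """Bijection from the 20 canonical residues to integer codes 1..20."""

    mapping: dict[str, int] = field(
        default_factory=lambda: {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
    )

    def __post_init__(self) -> None:
        if set(self.mapping) != _CANONICAL:
            raise ValueError("encoding map must cover exactly the 20 canonical residues")
        if sorted(self.mapping.values()) != list(range(1, 21)):
            raise ValueError("encoding map codes must be a bijection onto 1..20")

    @classmethod
    def alphabetical(cls) -> "EncodingMap":
        """A=1, C=2, ..., Y=20 (default)."""
        return cls()


@dataclass(frozen=True)
class SequenceMatrix:
    """Square row-major embedding of an encoded sequence, zero padded."""

    values: np.ndarray
    source_length: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records, order preserved.

    Residues are case-folded to uppercase and a trailing ``*`` terminator is
    stripped.  Raises :class:`SequenceError` on an empty file or a record with
    no sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().rstrip("*")
        if not residues:
            raise SequenceError(f"record {rec.id!r} has an empty sequence")
        records.append(ProteinSequence(id=rec.id, residues=residues, description=rec.description))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def validate_sequence(
    seq: ProteinSequence, policy: ValidationPolicy = "drop_nonstandard"
) -> ProteinSequence:
    """Apply a non-canonical-residue policy to a sequence.

    strict
        Error on any letter outside the 20-letter alphabet, listing positions.
    drop_nonstandard
        Remove non-canonical letters (X, B, Z, ...) and shorten the sequence.
    map_x_to_zero
        Keep non-canonical letters; they encode to 0 (padding value) later.
    """
    if not seq.residues:
        raise SequenceError(f"sequence {seq.id!r} is empty")
    residues = seq.residues.upper()
    bad = [i for i, aa in enumerate(residues) if aa not in _CANONICAL]
    if policy == "strict":
        if bad:
            raise SequenceError(
                f"sequence {seq.id!r} has non-canonical residues at positions "
                + ", ".join(f"{i}:{residues[i]}" for i in bad)
            )
        return replace(seq, residues=residues)
    if policy == "drop_nonstandard":
        if bad:
            keep = "".join(aa for aa in residues if aa in _CANONICAL)
            if not keep:
                raise SequenceError(f"sequence {seq.id!r} has no canonical residues")
            return replace(seq, residues=keep)
        return replace(seq, residues=residues)
    if policy == "map_x_to_zero":
        return replace(seq, residues=residues)
    raise ValueError(f"unknown validation policy {policy!r}")


def curate_dataset(
    seqs: Iterable[ProteinSequence],
    min_length: int = 50,
    excluded_keywords: Sequence[str] = DEFAULT_EXCLUDED_KEYWORDS,
) -> tuple[list[ProteinSequence], list[tuple[ProteinSequence, str]]]:
    """Filter sequences by minimum length and ambiguous-annotation keywords.

    A sequence is kept iff its length is at least ``min_length`` and its
    description contains none of ``excluded_keywords`` (case-insensitive
    substring match).  Rejected records carry the first matching reason:
    ``"min_length"`` or the offending keyword.
    """
    kept: list[ProteinSequence] = []
    rejected: list[tuple[ProteinSequence, str]] = []
    lowered = [kw.lower() for kw in excluded_keywords]
    for seq in seqs:
        if seq.k < min_length:
            rejected.append((seq, "min_length"))
            continue
        desc = seq.description.lower()
        reason = next((kw for kw in lowered if kw in desc), None)
        if reason is not None:
            rejected.append((seq, reason))
        else:
            kept.append(seq)
    return kept, rejected


def encode_sequence(
    seq: ProteinSequence,
    encoding: EncodingMap | None = None,
    unknown: Literal["error", "zero"] = "error",
) -> np.ndarray:
    """Encode residues to integer codes under the encoding map.

    ``unknown="zero"`` maps residues absent from the map (non-canonical
    letters retained by the ``map_x_to_zero`` policy) to code 0.
    """
    encoding = encoding or EncodingMap.alphabetical()
    codes = np.empty(seq.k, dtype=np.int64)
    for i, aa in enumerate(seq.residues):
        code = encoding.mapping.get(aa)
        if code is None:
            if unknown == "zero":
                code = 0
            else:
                raise SequenceError(
                    f"residue {aa!r} at position {i} of {seq.id!r} is not in the encoding map"
                )
        codes[i] = code
    return codes


def embed_square(values: np.ndarray) -> np.ndarray:
    """Embed a 1-D array row-major into the smallest square grid, zero padded."""
    values = np.asarray(values, dtype=float).ravel()
    k = values.size
    if k == 0:
        raise SequenceError("cannot embed an empty array")
    n = math.isqrt(k - 1) + 1  # ceil(sqrt(k)) without float error
    grid = np.zeros(n * n, dtype=float)
    grid[:k] = values
    return grid.reshape(n, n)


def reshape_to_matrix(codes: np.ndarray) -> SequenceMatrix:
    """Row-major square embedding of a code list: n = ceil(sqrt(k))."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise SequenceError("cannot reshape an empty code list")
    return SequenceMatrix(values=embed_square(codes), source_length=int(codes.size))


def write_curation_report(
    path: str | Path,
    kept: Sequence[ProteinSequence],
    rejected: Sequence[tuple[ProteinSequence, str]],
) -> None:
    """Write a TSV curation report: id, decision, reason."""
    with open(path, "w") as fh:
        fh.write("id\tdecision\treason\n")
        for seq in kept:
            fh.write(f"{seq.id}\tkept\t.\n")
        for seq, reason in rejected:
            fh.write(f"{seq.id}\trejected\t{reason}\n")
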