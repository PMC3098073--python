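"""Sequence, label, substitution-matrix and prediction-table I/O.

This module owns the domain containers (:class:`Sequence`,
:class:`LabeledDataset`, :class:`SubstitutionMatrix`) and every file format
the tool touches: FASTA for sequences, two-column TSV for class memberships,
NCBI-style text for substitution matrices, and the ranked prediction table.

Conventions
-----------
* Residue strings are uppercase letters over the 20 canonical amino acids
  plus the ambiguity letters B, Z, X, U, O, J (i.e. all of A-Z).  A ``*``
  (stop) is accepted only at the very end of a FASTA record and is stripped.
* Positions are 1-based in all user-facing output.
* Class labels may intersect and nest: one sequence may carry many labels,
  and a sequence with no label still belongs to every class complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence as SeqOf

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Align import substitution_matrices as _bio_matrices

from .errors import FormatError, PaasError

logger = logging.getLogger(__name__)

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_RESIDUES = "BZXUOJ"
#: Every residue letter a validated sequence may contain (all of A-Z).
RESIDUE_ALPHABET = "".join(sorted(CANONICAL_RESIDUES + AMBIGUITY_RESIDUES))

_RESIDUE_SET = frozenset(RESIDUE_ALPHABET)


@dataclass(frozen=True)
class Sequence:
    """A named amino-acid sequence, the atomic unit of all scoring.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a dataset.
    residues : str
        Uppercase residue string over :data:`RESIDUE_ALPHABET`, length >= 1.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise PaasError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise PaasError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _RESIDUE_SET:
                raise PaasError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def _normalize_record(seq_id: str, raw: str) -> Sequence:
    """Uppercase, strip one terminal ``*`` and validate a raw residue string."""
    residues = raw.upper()
    if residues.endswith("*"):
        residues = residues[:-1]
    if not residues:
        raise FormatError(f"record {seq_id!r} has an empty sequence")
    star = residues.find("*")
    if star != -1:
        raise FormatError(
            f"sequence {seq_id!r}: '*' allowed only at the sequence end "
            f"(found at position {star + 1})"
        )
    for pos, ch in enumerate(residues, start=1):
        if ch not in _RESIDUE_SET:
            raise FormatError(
                f"sequence {seq_id!r}: invalid residue {ch!r} at position {pos}"
            )
    return Sequence(seq_id, residues)


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into a list of validated :class:`Sequence`.

    Record ids are the first whitespace-delimited token of the header line.
    Residues are uppercased; a single terminal ``*`` is stripped.  Duplicate
    ids, empty records and non-letter residues raise :class:`FormatError`.
    """
    path = Path(path)
    sequences: list[Sequence] = []
    seen: set[str] = set()
    for record in _BioSeqIO.parse(str(path), "fasta"):
        seq_id = record.id
        if not seq_id:
            raise FormatError(f"{path}: record with empty identifier")
        if seq_id in seen:
            raise FormatError(f"{path}: duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        sequences.append(_normalize_record(seq_id, str(record.seq)))
    return sequences


def write_fasta(sequences: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line wrapping (deterministic bytes)."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


@dataclass(frozen=True)
class LabeledDataset:
    """Sequences plus intersecting class memberships.

    ``memberships`` is a set of ``(sequence id, class name)`` pairs; classes
    may intersect and nest.  Sequences with no label are retained — they
    enrich every class complement.
    """

    sequences: tuple[Sequence, ...]
    memberships: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        object.__setattr__(self, "memberships", frozenset(self.memberships))
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PaasError(f"duplicate sequence ids in dataset: {dup}")
        known = set(ids)
        for seq_id, cls in sorted(self.memberships):
            if not cls:
                raise PaasError(f"empty class name for sequence {seq_id!r}")
            if seq_id not in known:
                raise PaasError(f"label references unknown sequence id {seq_id!r}")

    @cached_property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)

    @cached_property
    def by_id(self) -> dict[str, Sequence]:
        return {s.id: s for s in self.sequences}

    @cached_property
    def class_index(self) -> dict[str, frozenset[str]]:
        """Mapping class name -> frozenset of member sequence ids."""
        index: dict[str, set[str]] = {}
        for seq_id, cls in self.memberships:
            index.setdefault(cls, set()).add(seq_id)
        return {c: frozenset(m) for c, m in index.items()}

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_index)

    def members(self, class_name: str) -> frozenset[str]:
        try:
            return self.class_index[class_name]
        except KeyError:
            raise PaasError(f"unknown class {class_name!r}") from None

    def complement(self, class_name: str) -> frozenset[str]:
        """Ids of every sequence not labeled with ``class_name``."""
        return frozenset(self.ids) - self.members(class_name)

    def filter_classes(self, min_class_size: int) -> "LabeledDataset":
        """Drop classes with fewer than ``min_class_size`` members (idempotent)."""
        if min_class_size < 1:
            raise PaasError("min_class_size must be >= 1")
        keep = {c for c, m in self.class_index.items() if len(m) >= min_class_size}
        dropped = sorted(set(self.class_index) - keep)
        if dropped:
            logger.warning(
                "dropping %d class(es) smaller than %d members: %s",
                len(dropped), min_class_size, ", ".join(dropped),
            )
        kept = frozenset(p for p in self.memberships if p[1] in keep)
        return LabeledDataset(self.sequences, kept)


def read_labels(
    path: str | Path,
    sequences: SeqOf[Sequence],
    min_class_size: int = 10,
) -> LabeledDataset:
    """Read a two-column (sequence id, class name) TSV into a dataset.

    Rows are deduplicated; classes smaller than ``min_class_size`` are dropped
    with a logged warning.  Sequences left without any label are retained.
    """
    path = Path(path)
    memberships: set[tuple[str, str]] = set()
    known = {s.id for s in sequences}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            seq_id, cls = parts[0].strip(), parts[1].strip()
            if not cls:
                raise FormatError(f"{path}:{lineno}: empty class name")
            if seq_id not in known:
                raise FormatError(
                    f"{path}:{lineno}: label references unknown sequence id {seq_id!r}"
                )
            memberships.add((seq_id, cls))
    dataset = LabeledDataset(tuple(sequences), frozenset(memberships))
    return dataset.filter_classes(min_class_size)


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    """Write memberships as a sorted two-column TSV (deterministic bytes)."""
    with Path(path).open("w") as fh:
        for seq_id, cls in sorted(dataset.memberships):
            fh.write(f"{seq_id}\t{cls}\n")


class SubstitutionMatrix:
    """Symmetric residue substitution score table.

    Parameters
    ----------
    alphabet : str
        Ordered residue letters, one per row/column.
    scores : array-like of shape (K, K)
        Integer-valued symmetric score table.
    name : str
        Free-form label ("BLOSUM62", "identity", file stem, ...).
    """

    def __init__(self, alphabet: str, scores, name: str = "custom") -> None:
        self.alphabet = str(alphabet)
        self.scores = np.asarray(scores, dtype=np.float64)
        self.name = name
        k = len(self.alphabet)
        if self.scores.shape != (k, k):
            raise FormatError(
                f"matrix shape {self.scores.shape} does not match alphabet size {k}"
            )
        if len(set(self.alphabet)) != k:
            raise FormatError("matrix alphabet has repeated letters")
        bad = np.argwhere(self.scores != self.scores.T)
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"asymmetric matrix entry for pair "
                f"({self.alphabet[i]}, {self.alphabet[j]})"
            )
        self._index = {ch: i for i, ch in enumerate(self.alphabet)}

    def score(self, a: str, b: str) -> float:
        """Raw score(a, b); raises ``KeyError`` for letters not in the alphabet."""
        return float(self.scores[self._index[a], self._index[b]])

    def __contains__(self, letter: str) -> bool:
        return letter in self._index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubstitutionMatrix)
            and self.alphabet == other.alphabet
            and np.array_equal(self.scores, other.scores)
        )

    def __repr__(self) -> str:
        return f"SubstitutionMatrix({self.name!r}, alphabet={self.alphabet!r})"

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """The standard BLOSUM62 table (Biopython's copy)."""
        mat = _bio_matrices.load("BLOSUM62")
        alphabet = "".join(mat.alphabet)
        return cls(alphabet, np.asarray(mat), name="BLOSUM62")

    @classmethod
    def identity(cls, alphabet: str = RESIDUE_ALPHABET) -> "SubstitutionMatrix":
        """Identity table: score(a, a) = 1, score(a, b) = 0."""
        return cls(alphabet, np.eye(len(alphabet)), name="identity")


def read_matrix(path: str | Path) -> SubstitutionMatrix:
    """Read an NCBI-style substitution matrix text file.

    Lines starting with ``#`` are comments; the first data line is the column
    header of letters; each following row is a letter label plus one integer
    per column.  Ragged rows and asymmetric entries raise :class:`FormatError`.
    """
    path = Path(path)
    header: list[str] | None = None
    row_labels: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if header is None:
                header = parts
                continue
            label, values = parts[0], parts[1:]
            if len(values) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: ragged row {label!r} "
                    f"({len(values)} values for {len(header)} columns)"
                )
            row_labels.append(label)
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
    if header is None or not rows:
        raise FormatError(f"{path}: no matrix data found")
    if row_labels != header:
        raise FormatError(
            f"{path}: row labels {row_labels} do not match header {header}"
        )
    alphabet = "".join(header)
    scores = np.asarray(rows)
    bad = np.argwhere(scores != scores.T)
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: asymmetric entry for pair ({alphabet[i]}, {alphabet[j]}): "
            f"{scores[i, j]} vs {scores[j, i]}"
        )
    return SubstitutionMatrix(alphabet, scores, name=path.stem)


def write_matrix(matrix: SubstitutionMatrix, path: str | Path) -> None:
    """Write a matrix in NCBI-style text (integer formatting when exact)."""
    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(v)

    with Path(path).open("w") as fh:
        fh.write("   " + "  ".join(matrix.alphabet) + "\n")
        for i, letter in enumerate(matrix.alphabet):
            fh.write(letter + "  " + "  ".join(fmt(v) for v in matrix.scores[i]) + "\n")


PREDICTION_COLUMNS = ("query_id", "class", "B", "P1", "P0", "delta")


def write_predictions(records, path: str | Path) -> None:
    """Write prediction records as a ranked TSV.

    Rows are sorted by ``P1 - P0`` descending within each query (queries keep
    their first-appearance order); ties break by class name ascending.  An
    empty record list yields a header-only file.
    """
    records = list(records)
    query_order: dict[str, int] = {}
    for rec in records:
        query_order.setdefault(rec.query_id, len(query_order))
    records.sort(key=lambda r: (query_order[r.query_id], -r.delta, r.class_name))
    with Path(path).open("w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.class_name}\t{r.b:.6f}\t{r.p1:.6f}"
                f"\t{r.p0:.6f}\t{r.delta:.6f}\n"
            )
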