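"""Seeded synthetic benchmark datasets with implanted class motifs.

The generator emulates the statistical structure the projection classifier
assumes: each class is defined by one short local motif shared by its
members, embedded at a random position in otherwise unrelated background
sequence of highly variable length.  Labels may intersect (a sequence can
carry the motifs of two classes), nest (subclass members inherit a
superclass label), and include null classes whose labels are assigned at
random and carry no motif — the negative control whose leave-one-out IAP
should sit near chance.

Generation is a pure function of the :class:`SyntheticSpec` (seed included):
the same spec always yields byte-identical FASTA and label files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import PaasError
from .seqio import (
    CANONICAL_RESIDUES,
    LabeledDataset,
    Sequence,
    write_fasta,
    write_labels,
)


def planted_class_name(j: int) -> str:
    """Name of the j-th (1-based) motif-bearing class."""
    return f"C{j:02d}"


def null_class_name(j: int) -> str:
    """Name of the j-th (1-based) randomly-labeled null class."""
    return f"R{j:02d}"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Defaults describe the package's standard benchmark: 5 motif classes of
    20 sequences each, motif length 12 mutated at rate 0.1 per position,
    sequence lengths uniform in 80-300, one randomly-labeled null class.

    Parameters
    ----------
    n_classes : int
        Number of motif-bearing (planted) classes.
    sequences_per_class : int
        Members generated per planted class (and labels per null class).
    motif_length : (int, int)
        Inclusive range of motif lengths, drawn per class.
    sequence_length : (int, int)
        Inclusive range of member sequence lengths, drawn per sequence.
    mutation_rate : float in [0, 1)
        Per-position probability that an implanted motif residue is replaced
        by a uniformly chosen different residue.
    background_frequencies : mapping letter -> float, optional
        Background residue distribution; uniform over the 20 canonical
        residues when omitted.
    overlap_plan : tuple of (class_a, class_b, prob)
        Each member of ``class_a`` additionally carries ``class_b``'s motif
        and label with probability ``prob``.
    nesting_plan : tuple of (subclass, superclass)
        Members of ``subclass`` also receive the ``superclass`` label.
    null_classes : int
        Number of randomly-labeled classes (no motif implanted).
    seed : int
        Seed for the generator; part of the spec.
    """

    n_classes: int = 5
    sequences_per_class: int = 20
    motif_length: tuple[int, int] = (12, 12)
    sequence_length: tuple[int, int] = (80, 300)
    mutation_rate: float = 0.1
    background_frequencies: Mapping[str, float] | None = None
    overlap_plan: tuple[tuple[str, str, float], ...] = ()
    nesting_plan: tuple[tuple[str, str], ...] = ()
    null_classes: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 1 or self.sequences_per_class < 1:
            raise PaasError("class and per-class counts must be positive")
        if self.null_classes < 0:
            raise PaasError("null_classes must be >= 0")
        lo, hi = self.motif_length
        slo, shi = self.sequence_length
        if not (1 <= lo <= hi):
            raise PaasError(f"bad motif length range {self.motif_length}")
        if not (1 <= slo <= shi):
            raise PaasError(f"bad sequence length range {self.sequence_length}")
        if hi > slo:
            raise PaasError(
                f"motif may be longer ({hi}) than the minimum sequence length ({slo})"
            )
        if not (0.0 <= self.mutation_rate < 1.0):
            raise PaasError(f"mutation_rate must be in [0, 1), got {self.mutation_rate}")
        planted = {planted_class_name(j + 1) for j in range(self.n_classes)}
        for a, b, p in self.overlap_plan:
            if a not in planted or b not in planted or a == b:
                raise PaasError(f"overlap plan references invalid class pair ({a}, {b})")
            if not (0.0 <= p <= 1.0):
                raise PaasError(f"overlap probability must be in [0, 1], got {p}")
            if 2 * hi > slo:
                raise PaasError(
                    "impossible overlap plan: two motifs cannot fit the shortest sequence"
                )
        for sub, sup in self.nesting_plan:
            if sub not in planted or sup not in planted or sub == sup:
                raise PaasError(f"nesting plan references invalid pair ({sub}, {sup})")
        if self.background_frequencies is not None:
            freqs = dict(self.background_frequencies)
            if set(freqs) - set(CANONICAL_RESIDUES):
                raise PaasError("background frequencies must cover canonical residues only")
            total = sum(freqs.values())
            if total <= 0:
                raise PaasError("background frequencies must sum to a positive value")

    def to_json(self) -> str:
        payload = asdict(self)
        if payload["background_frequencies"] is not None:
            payload["background_frequencies"] = dict(payload["background_frequencies"])
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"


def _background_probs(spec: SyntheticSpec) -> np.ndarray:
    if spec.background_frequencies is None:
        return np.full(len(CANONICAL_RESIDUES), 1.0 / len(CANONICAL_RESIDUES))
    p = np.array([spec.background_frequencies.get(ch, 0.0) for ch in CANONICAL_RESIDUES])
    return p / p.sum()


def _random_string(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    letters = rng.choice(len(CANONICAL_RESIDUES), size=length, p=probs)
    return "".join(CANONICAL_RESIDUES[i] for i in letters)


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    if rate == 0.0:
        return motif
    out = []
    for ch in motif:
        if rng.random() < rate:
            pool = CANONICAL_RESIDUES.replace(ch, "")
            out.append(pool[rng.integers(len(pool))])
        else:
            out.append(ch)
    return "".join(out)


def _implant(
    rng: np.random.Generator,
    residues: str,
    motif: str,
    occupied: list[tuple[int, int]],
    max_tries: int = 1000,
) -> tuple[str, int]:
    """Place ``motif`` at a random position not overlapping ``occupied``.

    Returns the new residue string and the 1-based implant position.
    """
    L, w = len(residues), len(motif)
    for _ in range(max_tries):
        start = int(rng.integers(0, L - w + 1))  # 0-based
        if all(start + w <= s or start >= s + e for s, e in occupied):
            occupied.append((start, start + w))
            return residues[:start] + motif + residues[start + w:], start + 1
    raise PaasError("impossible overlap plan: could not place motifs without overlap")


GROUND_TRUTH_COLUMNS = ("id", "class", "motif", "position")


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate a labeled dataset and its ground-truth implant table.

    The ground truth has one row per motif implant — columns ``id``,
    ``class``, ``motif`` (the mutated string actually implanted) and
    ``position`` (1-based first residue).  Null-class and nesting-only labels
    appear in the dataset's memberships but not in the implant table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    probs = _background_probs(spec)
    mlo, mhi = spec.motif_length
    slo, shi = spec.sequence_length
    planted = [planted_class_name(j + 1) for j in range(spec.n_classes)]
    motifs = {
        c: _random_string(rng, int(rng.integers(mlo, mhi + 1)), probs) for c in planted
    }
    overlap_by_class: dict[str, list[tuple[str, float]]] = {c: [] for c in planted}
    for a, b, p in spec.overlap_plan:
        overlap_by_class[a].append((b, p))
    supers_of: dict[str, list[str]] = {c: [] for c in planted}
    for sub, sup in spec.nesting_plan:
        supers_of[sub].append(sup)

    sequences: list[Sequence] = []
    memberships: set[tuple[str, str]] = set()
    truth_rows: list[tuple[str, str, str, int]] = []
    counter = 0
    for c in planted:
        for _ in range(spec.sequences_per_class):
            counter += 1
            seq_id = f"seq{counter:04d}"
            length = int(rng.integers(slo, shi + 1))
            residues = _random_string(rng, length, probs)
            occupied: list[tuple[int, int]] = []
            mutated = _mutate(rng, motifs[c], spec.mutation_rate)
            residues, pos = _implant(rng, residues, mutated, occupied)
            memberships.add((seq_id, c))
            truth_rows.append((seq_id, c, mutated, pos))
            for sup in supers_of[c]:
                memberships.add((seq_id, sup))
            for other, p in overlap_by_class[c]:
                if rng.random() < p:
                    mutated_o = _mutate(rng, motifs[other], spec.mutation_rate)
                    residues, pos_o = _implant(rng, residues, mutated_o, occupied)
                    memberships.add((seq_id, other))
                    truth_rows.append((seq_id, other, mutated_o, pos_o))
                    for sup in supers_of[other]:
                        memberships.add((seq_id, sup))
            sequences.append(Sequence(seq_id, residues))
    if spec.null_classes:
        all_ids = [s.id for s in sequences]
        if spec.sequences_per_class > len(all_ids):
            raise PaasError("null class larger than the generated dataset")
        for j in range(spec.null_classes):
            chosen = rng.choice(len(all_ids), size=spec.sequences_per_class, replace=False)
            for k in sorted(chosen):
                memberships.add((all_ids[k], null_class_name(j + 1)))
    dataset = LabeledDataset(tuple(sequences), frozenset(memberships))
    truth = pd.DataFrame(sorted(truth_rows), columns=list(GROUND_TRUTH_COLUMNS))
    return dataset, truth


def write_fixture(
    dataset: LabeledDataset,
    ground_truth: pd.DataFrame,
    directory: str | Path,
    spec: SyntheticSpec | None = None,
) -> dict[str, Path]:
    """Write FASTA + labels TSV + ground-truth TSV (and optionally the spec).

    Returns the paths written, keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "seqs.fasta",
        "labels": directory / "labels.tsv",
        "ground_truth": directory / "ground_truth.tsv",
    }
    write_fasta(dataset.sequences, paths["fasta"])
    write_labels(dataset, paths["labels"])
    ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    if spec is not None:
        paths["spec"] = directory / "spec.json"
        paths["spec"].write_text(spec.to_json())
    return paths
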