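"""Prediction-accuracy evaluation: IAP and the two validation protocols.

IAP (invariant accuracy of prediction) is the fraction of correctly ordered
(member, non-member) score pairs, with tied pairs credited 0.5 — identical
to the area under the ROC curve.  It is invariant under any strictly
increasing transform of the scores, which is why the B statistic can be used
directly wherever a ranking is evaluated.

Two drivers are provided:

* :func:`loo_cross_validate` — leave-one-out B values per class across a
  grid of frame values, tabulated with an unweighted average row.
* :func:`multi_split_validate` — repeated stratified 2/3-1/3 splits; the
  classifier is trained on the training part and each class's test-set B
  values are scored by IAP, reported as mean and SD over repetitions next to
  the full-data LOO reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as SeqOf

import numpy as np
import pandas as pd

from .classifier import _b_from_sums, loo_b_values
from .errors import PaasError
from .projection import SimilarityMeasure, default_measure, pairwise_profile_sums
from .seqio import LabeledDataset

logger = logging.getLogger(__name__)

DEFAULT_FRAMES = (10, 15, 20, 25, 30, 35, 40, 45)
AVERAGE_ROW = "Average"


def iap(scores, is_member) -> float:
    """Pairwise-ordering accuracy (equals AUC under the 0.5-tie convention).

    Over all (member m, non-member u) pairs: 1 if score(m) > score(u), 0.5 if
    equal, 0 otherwise; returns the mean.  Raises if either side is empty.
    """
    s = np.asarray(scores, dtype=np.float64)
    mem = np.asarray(is_member, dtype=bool)
    if s.shape != mem.shape or s.ndim != 1:
        raise PaasError("scores and is_member must be 1-d vectors of equal length")
    pos = s[mem]
    neg = s[~mem]
    if pos.size == 0 or neg.size == 0:
        raise PaasError("IAP needs at least one member and one non-member")
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return float(wins / (pos.size * neg.size))


@dataclass(frozen=True)
class IapReport:
    """Per-class IAP across a frame grid, plus the unweighted average row."""

    frames: tuple[int, ...]
    class_names: tuple[str, ...]
    member_counts: dict[str, int]
    values: dict[str, np.ndarray]  # class -> IAP per frame

    @property
    def average(self) -> np.ndarray:
        """Unweighted mean IAP over classes, one entry per frame."""
        return np.mean([self.values[c] for c in self.class_names], axis=0)

    def iap_at(self, class_name: str, frame: int) -> float:
        return float(self.values[class_name][self.frames.index(frame)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.class_names:
            rows.append([c, self.member_counts[c], *np.round(self.values[c], 6)])
        rows.append([AVERAGE_ROW, "", *np.round(self.average, 6)])
        return pd.DataFrame(rows, columns=["class", "n_members", *map(str, self.frames)])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def loo_cross_validate(
    dataset: LabeledDataset,
    frames: SeqOf[int] = DEFAULT_FRAMES,
    measure: SimilarityMeasure | None = None,
) -> IapReport:
    """Leave-one-out IAP per class across a frame grid (deterministic)."""
    measure = measure if measure is not None else default_measure()
    frames = tuple(int(f) for f in frames)
    if not frames:
        raise PaasError("need at least one frame value")
    classes = dataset.classes
    if not classes:
        raise PaasError("dataset has no classes")
    values = {c: np.empty(len(frames)) for c in classes}
    for fi, F in enumerate(frames):
        pair_sums = pairwise_profile_sums(dataset.sequences, F, measure)
        for c in classes:
            loo = loo_b_values(dataset, c, F, measure, pair_sums=pair_sums)
            values[c][fi] = iap([v.b for v in loo], [v.is_member for v in loo])
    counts = {c: len(dataset.members(c)) for c in classes}
    return IapReport(frames, tuple(classes), counts, values)


@dataclass(frozen=True)
class SplitReport:
    """Per-class test-set IAP over repeated stratified splits."""

    frame: int
    repeats: int
    train_fraction: float
    seed: int
    class_names: tuple[str, ...]
    member_counts: dict[str, int]
    loo_iap: dict[str, float]
    mean: dict[str, float]
    sd: dict[str, float]
    n_used: dict[str, int]  # repetitions actually contributing per class

    def to_frame(self) -> pd.DataFrame:
        rows = [
            [
                c,
                self.member_counts[c],
                round(self.loo_iap[c], 6),
                round(self.mean[c], 6),
                round(self.sd[c], 6),
                self.n_used[c],
            ]
            for c in self.class_names
        ]
        rows.append(
            [
                AVERAGE_ROW,
                "",
                round(float(np.mean([self.loo_iap[c] for c in self.class_names])), 6),
                round(float(np.mean([self.mean[c] for c in self.class_names])), 6),
                round(float(np.mean([self.sd[c] for c in self.class_names])), 6),
                "",
            ]
        )
        return pd.DataFrame(
            rows, columns=["class", "n_members", "loo_iap", "mean", "sd", "n_repetitions"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _stratified_split(
    dataset: LabeledDataset, train_fraction: float, rng: np.random.Generator
) -> tuple[set[str], set[str]]:
    """One random train/test partition approximately preserving each class's
    member proportion.

    Classes are processed from rarest to most populous; each class tops up
    its training-side member count toward ``round(train_fraction * size)``
    using its not-yet-assigned members.  Unlabeled leftovers are split at the
    same fraction.
    """
    train: set[str] = set()
    test: set[str] = set()
    assigned: set[str] = set()
    by_size = sorted(dataset.classes, key=lambda c: (len(dataset.members(c)), c))
    for c in by_size:
        members = sorted(dataset.members(c))
        target = int(round(train_fraction * len(members)))
        free = [m for m in members if m not in assigned]
        rng.shuffle(free)
        have = sum(1 for m in members if m in train)
        need = min(max(target - have, 0), len(free))
        for m in free[:need]:
            train.add(m)
        for m in free[need:]:
            test.add(m)
        assigned.update(free)
    leftovers = [i for i in dataset.ids if i not in assigned]
    rng.shuffle(leftovers)
    cut = int(round(train_fraction * len(leftovers)))
    train.update(leftovers[:cut])
    test.update(leftovers[cut:])
    return train, test


def multi_split_validate(
    dataset: LabeledDataset,
    F: int = 25,
    repeats: int = 20,
    train_fraction: float = 2 / 3,
    seed: int | None = None,
    measure: SimilarityMeasure | None = None,
) -> SplitReport:
    """Repeated stratified train/test splitting, evaluated per class.

    Each repetition draws one stratified split of the whole dataset; test
    sequences are scored per class by their B statistic against the training
    part (IAP is transform-invariant, so no calibration is needed) and the
    test-set IAP is recorded.  A class is skipped for a repetition (with a
    warning) when its training side keeps fewer than 2 members, its test side
    no member or no non-member, or its training complement is empty; skipped
    repetitions are excluded from that class's mean/SD denominator.
    """
    if repeats < 2:
        raise PaasError(f"repeats must be >= 2, got {repeats}")
    if not (0.0 < train_fraction < 1.0):
        raise PaasError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if seed is None:
        raise PaasError("multi_split_validate requires an explicit seed")
    measure = measure if measure is not None else default_measure()
    classes = dataset.classes
    if not classes:
        raise PaasError("dataset has no classes")
    rng = np.random.default_rng(seed)
    pair_sums = pairwise_profile_sums(dataset.sequences, F, measure)
    loo_ref: dict[str, float] = {}
    for c in classes:
        loo = loo_b_values(dataset, c, F, measure, pair_sums=pair_sums)
        loo_ref[c] = iap([v.b for v in loo], [v.is_member for v in loo])
    idx = {i: k for k, i in enumerate(dataset.ids)}
    lengths = np.array([len(s) for s in dataset.sequences])
    per_class: dict[str, list[float]] = {c: [] for c in classes}
    for rep in range(repeats):
        train_ids, test_ids = _stratified_split(dataset, train_fraction, rng)
        train_idx = np.array(sorted(idx[i] for i in train_ids), dtype=np.intp)
        test_idx = np.array(sorted(idx[i] for i in test_ids), dtype=np.intp)
        for c in classes:
            members = dataset.members(c)
            in_class = np.array(
                [dataset.ids[k] in members for k in train_idx], dtype=bool
            )
            test_is_member = np.array(
                [dataset.ids[k] in members for k in test_idx], dtype=bool
            )
            if (
                in_class.sum() < 2
                or (~in_class).sum() < 1
                or test_is_member.sum() < 1
                or (~test_is_member).sum() < 1
            ):
                logger.warning(
                    "repetition %d: class %s skipped (degenerate split)", rep, c
                )
                continue
            w1 = in_class.astype(np.float64)
            w0 = 1.0 - w1
            b_values = [
                _b_from_sums(
                    pair_sums[q, train_idx], int(lengths[q]), w1, w0, F
                )
                for q in test_idx
            ]
            per_class[c].append(iap(b_values, test_is_member))
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n_used: dict[str, int] = {}
    for c in classes:
        vals = np.asarray(per_class[c])
        n_used[c] = vals.size
        if vals.size == 0:
            mean[c] = float("nan")
            sd[c] = float("nan")
        else:
            mean[c] = float(vals.mean())
            sd[c] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    counts = {c: len(dataset.members(c)) for c in classes}
    return SplitReport(
        frame=F,
        repeats=repeats,
        train_fraction=train_fraction,
        seed=seed,
        class_names=tuple(classes),
        member_counts=counts,
        loo_iap=loo_ref,
        mean=mean,
        sd=sd,
        n_used=n_used,
    )


def class_quality_filter(report: IapReport, threshold: float = 0.6) -> list[str]:
    """Classes whose IAP strictly exceeds ``threshold``, name-sorted.

    The report must have been computed at a single frame value.
    """
    if len(report.frames) != 1:
        raise PaasError(
            f"quality filter needs a single-frame report, got frames {report.frames}"
        )
    return sorted(c for c in report.class_names if report.values[c][0] > threshold)
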