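"""Multi-label projection classifier.

For a query ``Q`` the projection profiles against every training sequence are
condensed, per class ``C``, into the scalar evidence

    B_Q(C) = (1/n) * sum_i (m1_i - m0_i)

where ``s_ik = S_ik / F`` is the normalized per-position evidence,
``m1_i = sum_k W_k(C) s_ik / sum_k W_k(C)`` the weighted mean similarity to
class members at query position ``i``, and ``m0_i`` the same over the class
complement.  With a normalized similarity measure ``B`` is bounded in
[-1, 1]; it is positive when the query resembles class members more than the
rest of the training set.

Because membership probabilities are calibrated through empirical
distribution functions of leave-one-out B values, every downstream quantity
(P1, P0, rankings, IAP) is invariant to any strictly increasing
re-expression of B; only its monotone-evidence behaviour matters.  The exact
contrast form above is isolated behind :func:`b_statistic`.

Calibration: for each class, each training sequence is in turn held out and
scored against the remaining ``N - 1`` sequences (excluded from both the
similarity pool and the weight sums).  The held-out B values of members and
of the complement give two empirical samples; ``P1(B)`` is the smoothed
member CDF and ``P0(B)`` the smoothed complement survival function, both via
midpoint-CDF piecewise-linear interpolation, constant beyond the sample
extremes (so single-sample tails sit at ``1/(2N_c)`` rather than 0/1).  A
new query's B is computed against the full training set while calibration
used ``N - 1``; the small distributional mismatch is inherent to the
protocol and documented.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence as SeqOf

import numpy as np

from .errors import ModelVersionError, PaasError
from .projection import (
    SimilarityMeasure,
    default_measure,
    pairwise_profile_sums,
    profile_matrix,
    query_profile_sums,
)
from .seqio import LabeledDataset, Sequence, SubstitutionMatrix

logger = logging.getLogger(__name__)

MODEL_FORMAT = "paas-model"
MODEL_VERSION = 1

DEFAULT_FRAME = 25
DEFAULT_MIN_CLASS_SIZE = 10

CUTOFFS = ("p1>p0", "all")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class training-sequence weights ``W_k(C)`` and ``W_k(not C)``.

    ``weights[class] = (w_member, w_complement)``, each a non-negative vector
    over the training sequences (in dataset order) with a positive sum.  The
    default is binary: ``w_member = 1`` for members, ``w_complement = 1 -
    w_member``.
    """

    order: tuple[str, ...]
    weights: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for cls, (w1, w0) in self.weights.items():
            if len(w1) != len(self.order) or len(w0) != len(self.order):
                raise PaasError(f"class {cls!r}: weight length mismatch")
            if np.any(w1 < 0) or np.any(w0 < 0):
                raise PaasError(f"class {cls!r}: negative weights")
            if w1.sum() <= 0:
                raise PaasError(f"class {cls!r}: empty class (zero member weight)")
            if w0.sum() <= 0:
                raise PaasError(f"class {cls!r}: cannot form complement")

    @classmethod
    def binary(cls, dataset: LabeledDataset) -> "ClassWeights":
        """0/1 weights derived from the dataset's memberships."""
        order = dataset.ids
        weights = {}
        for name in dataset.classes:
            members = dataset.members(name)
            w1 = np.array([1.0 if i in members else 0.0 for i in order])
            weights[name] = (w1, 1.0 - w1)
        return cls(order, weights)

    def for_class(self, class_name: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.weights[class_name]
        except KeyError:
            raise PaasError(f"no weights for class {class_name!r}") from None


def b_statistic(S: np.ndarray, weights: ClassWeights, class_name: str, F: int) -> float:
    """B statistic of one query from its profile matrix ``S`` (n x N)."""
    if F < 1:
        raise PaasError(f"frame must be >= 1, got {F}")
    S = np.asarray(S, dtype=np.float64)
    w1, w0 = weights.for_class(class_name)
    if S.shape[1] != len(w1):
        raise PaasError(
            f"profile matrix has {S.shape[1]} columns for {len(w1)} training sequences"
        )
    s = S / F
    m1 = s @ w1 / w1.sum()
    m0 = s @ w0 / w0.sum()
    return float(np.mean(m1 - m0))


def _b_from_sums(t_row: np.ndarray, n_query: int, w1: np.ndarray,
                 w0: np.ndarray, F: int) -> float:
    """B from per-training-sequence profile totals (algebraically identical
    to :func:`b_statistic` because the weights are position-independent)."""
    s1 = w1.sum()
    s0 = w0.sum()
    if s1 <= 0:
        raise PaasError("empty class (zero member weight)")
    if s0 <= 0:
        raise PaasError("cannot form complement")
    return float((t_row @ w1 / s1 - t_row @ w0 / s0) / (n_query * F))


class LooValue(NamedTuple):
    """Leave-one-out B value of one training sequence for one class."""

    sequence_id: str
    b: float
    is_member: bool


def loo_b_values(
    dataset: LabeledDataset,
    class_name: str,
    F: int,
    measure: SimilarityMeasure | None = None,
    *,
    pair_sums: np.ndarray | None = None,
) -> list[LooValue]:
    """Leave-one-out B values for one class.

    Each training sequence is held out in turn and scored against the
    remaining ``N - 1`` sequences; the held-out sequence is excluded from
    both the similarity pool and the weight sums.  ``pair_sums`` may carry a
    precomputed :func:`paas.projection.pairwise_profile_sums` matrix for the
    dataset at the same frame/measure, which every class then shares.
    """
    measure = measure if measure is not None else default_measure()
    members = dataset.members(class_name)
    n_total = len(dataset.sequences)
    if len(members) < 2 or n_total - len(members) < 2:
        raise PaasError(
            f"class {class_name!r}: leave-one-out needs >= 2 members and >= 2 "
            f"complement sequences (cannot form complement after a removal)"
        )
    if pair_sums is None:
        pair_sums = pairwise_profile_sums(dataset.sequences, F, measure)
    w1_full = np.array([1.0 if s.id in members else 0.0 for s in dataset.sequences])
    w0_full = 1.0 - w1_full
    out: list[LooValue] = []
    for k, seq in enumerate(dataset.sequences):
        w1 = w1_full.copy()
        w0 = w0_full.copy()
        w1[k] = 0.0
        w0[k] = 0.0
        t_row = pair_sums[k].copy()
        t_row[k] = 0.0  # held-out sequence leaves the similarity pool
        b = _b_from_sums(t_row, len(seq), w1, w0, F)
        out.append(LooValue(seq.id, b, seq.id in members))
    return out


def _midpoint_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct sample points and the midpoint empirical CDF at each."""
    u, counts = np.unique(values, return_counts=True)
    below = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return u, (below + 0.5 * counts) / values.size


@dataclass(frozen=True)
class CalibrationCurve:
    """Smoothed membership-probability functions of one class.

    ``p1(B)`` is the midpoint empirical CDF of member leave-one-out B values,
    ``p0(B)`` the midpoint survival function of the complement values, both
    piecewise-linear between distinct sample points and constant beyond the
    extremes.  ``p1`` is non-decreasing and ``p0`` non-increasing, so
    ``delta = p1 - p0`` is non-decreasing in B.
    """

    member_b: np.ndarray
    complement_b: np.ndarray

    def p1(self, b):
        u, f = _midpoint_cdf(self.member_b)
        return np.interp(b, u, f)

    def p0(self, b):
        u, f = _midpoint_cdf(self.complement_b)
        return 1.0 - np.interp(b, u, f)


def calibrate(loo_values: Iterable[LooValue]) -> CalibrationCurve:
    """Build a class's calibration curve from its leave-one-out B values."""
    values = list(loo_values)
    member = np.sort([v.b for v in values if v.is_member])
    complement = np.sort([v.b for v in values if not v.is_member])
    if member.size < 2 or complement.size < 2:
        raise PaasError(
            f"calibration needs >= 2 member and >= 2 complement values "
            f"(got {member.size} and {complement.size})"
        )
    return CalibrationCurve(member, complement)


@dataclass(frozen=True)
class ClassModel:
    """Trained state of one class: calibration samples and LOO accuracy."""

    curve: CalibrationCurve
    iap: float

    @property
    def member_b(self) -> np.ndarray:
        return self.curve.member_b

    @property
    def complement_b(self) -> np.ndarray:
        return self.curve.complement_b


@dataclass(frozen=True)
class TrainedModel:
    """Serializable classifier state.

    Holds the training sequences and memberships, the frame and similarity
    measure, and per class the sorted leave-one-out B samples (the
    calibration curves) plus the class's LOO IAP.
    """

    frame: int
    measure_name: str
    matrix: SubstitutionMatrix | None
    sequences: tuple[Sequence, ...]
    memberships: frozenset[tuple[str, str]]
    classes: dict[str, ClassModel]

    @property
    def dataset(self) -> LabeledDataset:
        return LabeledDataset(self.sequences, self.memberships)

    @property
    def measure(self) -> SimilarityMeasure:
        return SimilarityMeasure.from_name(self.measure_name, self.matrix)

    def to_json(self) -> str:
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "frame": self.frame,
            "measure": self.measure_name,
            "matrix": None
            if self.matrix is None
            else {
                "name": self.matrix.name,
                "alphabet": self.matrix.alphabet,
                "scores": self.matrix.scores.tolist(),
            },
            "sequences": [[s.id, s.residues] for s in self.sequences],
            "memberships": sorted(self.memberships),
            "classes": {
                name: {
                    "member_b": cm.member_b.tolist(),
                    "complement_b": cm.complement_b.tolist(),
                    "iap": cm.iap,
                }
                for name, cm in sorted(self.classes.items())
            },
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise PaasError(f"truncated or corrupt model file: {exc}") from exc
        if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
            raise ModelVersionError("not a projection-classifier model file")
        if payload.get("version") != MODEL_VERSION:
            raise ModelVersionError(
                f"unsupported model version {payload.get('version')!r} "
                f"(expected {MODEL_VERSION})"
            )
        matrix = None
        if payload["matrix"] is not None:
            matrix = SubstitutionMatrix(
                payload["matrix"]["alphabet"],
                np.asarray(payload["matrix"]["scores"]),
                name=payload["matrix"]["name"],
            )
        classes = {
            name: ClassModel(
                CalibrationCurve(
                    np.asarray(entry["member_b"], dtype=np.float64),
                    np.asarray(entry["complement_b"], dtype=np.float64),
                ),
                float(entry["iap"]),
            )
            for name, entry in payload["classes"].items()
        }
        return cls(
            frame=int(payload["frame"]),
            measure_name=payload["measure"],
            matrix=matrix,
            sequences=tuple(Sequence(i, r) for i, r in payload["sequences"]),
            memberships=frozenset((i, c) for i, c in payload["memberships"]),
            classes=classes,
        )


def train(
    dataset: LabeledDataset,
    F: int = DEFAULT_FRAME,
    measure: SimilarityMeasure | str | None = None,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> TrainedModel:
    """Train the classifier: LOO B values, calibration and LOO IAP per class.

    Classes smaller than ``min_class_size`` (or too small for leave-one-out)
    are dropped with a warning; if none survive a :class:`PaasError` is
    raised.  Training is deterministic.
    """
    from .validation import iap  # deferred: validation imports this module

    if isinstance(measure, str):
        measure = SimilarityMeasure.from_name(measure)
    measure = measure if measure is not None else default_measure()
    filtered = dataset.filter_classes(min_class_size)
    n_total = len(filtered.sequences)
    eligible = []
    for name in filtered.classes:
        n_mem = len(filtered.members(name))
        if n_mem < 2 or n_total - n_mem < 2:
            logger.warning(
                "class %s skipped: %d members of %d sequences leave no room for "
                "leave-one-out calibration", name, n_mem, n_total,
            )
            continue
        eligible.append(name)
    if not eligible:
        raise PaasError("no class survives filtering")
    pair_sums = pairwise_profile_sums(filtered.sequences, F, measure)
    classes: dict[str, ClassModel] = {}
    for name in eligible:
        loo = loo_b_values(filtered, name, F, measure, pair_sums=pair_sums)
        curve = calibrate(loo)
        class_iap = iap([v.b for v in loo], [v.is_member for v in loo])
        classes[name] = ClassModel(curve, class_iap)
    return TrainedModel(
        frame=F,
        measure_name=measure.name,
        matrix=measure.matrix,
        sequences=filtered.sequences,
        memberships=frozenset(
            p for p in filtered.memberships if p[1] in classes
        ),
        classes=classes,
    )


@dataclass(frozen=True)
class PredictionRecord:
    """One (query, class) prediction: evidence B and calibrated P1/P0."""

    query_id: str
    class_name: str
    b: float
    p1: float
    p0: float

    @property
    def delta(self) -> float:
        return self.p1 - self.p0


def predict(
    model: TrainedModel,
    queries: SeqOf[Sequence],
    cutoff: str = "p1>p0",
    min_iap: float | None = None,
) -> list[PredictionRecord]:
    """Rank class predictions for new queries.

    For each query the B statistic is computed per class against the full
    training set and mapped through the class calibration curves.  Records
    are filtered by the cutoff (``"p1>p0"`` keeps P1 > P0; ``"all"`` keeps
    everything), optionally restricted to classes whose stored LOO IAP
    exceeds ``min_iap``, and sorted by ``P1 - P0`` descending within each
    query (ties broken by class name).
    """
    if cutoff not in CUTOFFS:
        raise PaasError(f"unknown cutoff {cutoff!r}; expected one of {CUTOFFS}")
    measure = model.measure
    dataset = model.dataset
    class_names = sorted(model.classes)
    if min_iap is not None:
        class_names = [c for c in class_names if model.classes[c].iap > min_iap]
    weights = {}
    for name in class_names:
        members = dataset.members(name)
        w1 = np.array([1.0 if s.id in members else 0.0 for s in model.sequences])
        weights[name] = (w1, 1.0 - w1)
    records: list[PredictionRecord] = []
    for query in queries:
        if len(query) < 1:
            raise PaasError(f"query {query.id!r} is empty")
        t_row = query_profile_sums(query, model.sequences, model.frame, measure)
        per_query: list[PredictionRecord] = []
        for name in class_names:
            w1, w0 = weights[name]
            b = _b_from_sums(t_row, len(query), w1, w0, model.frame)
            curve = model.classes[name].curve
            p1 = float(curve.p1(b))
            p0 = float(curve.p0(b))
            rec = PredictionRecord(query.id, name, b, p1, p0)
            if cutoff == "all" or rec.p1 > rec.p0:
                per_query.append(rec)
        per_query.sort(key=lambda r: (-r.delta, r.class_name))
        records.extend(per_query)
    return records


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write the model as canonical versioned JSON (lossless round-trip)."""
    Path(path).write_text(model.to_json())


def load_model(path: str | Path) -> TrainedModel:
    """Load a model written by :func:`save_model`; checks the version tag."""
    return TrainedModel.from_json(Path(path).read_text())
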