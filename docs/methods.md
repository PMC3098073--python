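# Methods

## Model and assumptions

The classifier assumes that membership in a functional protein class (e.g.
the substrates of one kinase) is carried by *local* sequence similarity to
class members: short shared regions — phosphosite contexts, docking motifs,
recruitment surfaces — embedded at arbitrary positions in otherwise
unrelated sequences of very different lengths.  It does not assume global
homology, does not align, and never needs to know where the informative
region is.

Three layers build on each other:

1. **Projection scores** `S_i`: for each query position, the best
   frame-bounded ungapped similarity to a training sequence over all shifts.
   Padding outside the overlap contributes exactly zero; frames are
   truncated at the query boundaries; shifts are enumerated down to a single
   residue of overlap (no minimum-overlap cutoff — none is warranted by the
   model).
2. **B statistic**: the per-position contrast between weighted mean
   similarity to class members and to the complement, averaged over the
   query and normalised by the frame, `B = (1/n) Σ_i (m1_i − m0_i)`.  With
   a similarity measure in [0, 1] this is bounded in [−1, 1].  Because the
   probability calibration below uses only the empirical distribution of B,
   every downstream quantity (P1, P0, rankings, IAP, the P1 > P0 decision)
   is invariant to any strictly increasing re-expression of B; the contrast
   form is the simplest statistic with the required monotone-evidence
   behaviour, and it is isolated behind `classifier.b_statistic` should a
   different form ever be preferred.
3. **Calibration**: leave-one-out B samples per class, member side and
   complement side, turned into `P1(B)` (member CDF) and `P0(B)`
   (complement survival function).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| frame `F` | 25 residues | window length bounding each scored region; the main tuning knob.  Frames shorter than the informative motif dilute it into background; frames much longer than it dilute the contrast.  25 sits at the optimum of the built-in leave-one-out frame scan on motif-implant benchmarks and is the recommended operating point. |
| measure | blosum62-normalized | `clamp(score(a,b)/√(score(a,a)·score(b,b)), 0, 1)`.  Normalising keeps `S_i ∈ [0, F]` and hence `B ∈ [−1, 1]`, comparable across measures; clamping at 0 treats dissimilarity as absence of evidence rather than negative evidence.  `identity` and `raw-matrix` are available (the latter unbounded, for diagnostics). |
| min_class_size | 10 | classes with fewer members give too few calibration samples for a stable empirical CDF; smaller classes are dropped with a warning. |
| cutoff | P1 > P0 | report a class when membership is more probable than non-membership; `all` disables filtering. |
| min_iap (predict) | 0.6 | only classes whose leave-one-out IAP exceeds 0.6 are trusted for prediction; below that the class ranking is too close to chance to act on. |
| repeats / train_fraction | 20 / 2⁄3 | the stratified splitting protocol: twenty random 2/3–1/3 divisions, mean and SD of test-set IAP per class. |

Ambiguity letters (B, Z, X, U, O, J) score via the matrix when present in
it (BLOSUM62 carries B, Z, X entries; X/X is non-positive so X contributes
nothing under normalisation), otherwise 0 — deterministic and conservative.

## Numerical and protocol choices

* **Smoothing.**  "Smooth" estimates of P1/P0 are midpoint empirical CDFs
  with piecewise-linear interpolation between distinct sample values,
  constant beyond the extremes.  The midpoint convention clamps the tails to
  `[1/(2N_c), 1 − 1/(2N_c)]` (N_c = sample count), so no query is ever
  assigned probability exactly 0 or 1 from a finite sample.  Chosen over
  kernel smoothing for determinism and exact testability; it preserves the
  only property the decision rule needs (monotonicity, hence a single
  P1−P0 zero crossing for separated classes).
* **Ties in IAP.**  Tied (member, non-member) pairs count 0.5, which makes
  the pair-counting definition coincide exactly with the midrank
  Mann-Whitney AUC; verified against an independent rank-based
  implementation in the tests.
* **Leave-one-out.**  The held-out sequence is excluded from both the
  similarity pool and the weight sums (index-level exclusion only;
  duplicate sequences are not additionally removed).  New queries are
  scored against the *full* training set while calibration used N−1; the
  resulting distributional mismatch is O(1/N) and accepted as inherent to
  the protocol.
* **Splitting.**  Each repetition draws one stratified partition of the
  whole dataset (classes processed rarest-first, each topping its training
  side up toward 2/3 of its members; leftovers split at the same fraction),
  then every class is evaluated on the same partition.  Test sequences are
  scored by B directly — IAP is transform-invariant, so recalibrating on
  the reduced training part would change nothing.  Degenerate
  (class, repetition) pairs — fewer than 2 training members, or a test side
  missing members or non-members — are skipped with a warning and excluded
  from that class's mean/SD denominator (SD uses ddof = 1).
* **Efficiency.**  With position-independent weights B depends on a
  profile only through its total `Σ_i S_i`, so the leave-one-out and
  splitting drivers compute one all-pairs total matrix per frame and reuse
  it across classes, held-out queries and repetitions.  The per-pair kernel
  (numba) is O(n·m) time, O(n+m) memory; a pure-Python brute-force oracle
  with no cumulative sums verifies it element-wise in the tests.
* **Model files** are canonical versioned JSON (sorted keys, fixed
  separators): save → load → save is byte-identical, and training is fully
  deterministic, so reruns can be diffed.

## Synthetic benchmark

The generator emulates the data shape the classifier targets: classes
defined by one implanted motif per class in uniform-background sequence,
lengths drawn uniformly from a wide range, per-position motif mutation,
intersecting labels via a co-assignment plan, nested labels via a
subclass → superclass plan, and *null* classes whose labels are assigned to
random existing sequences with no motif — a negative control whose
leave-one-out IAP should sit near 0.5.  Generation is a pure function of
the spec (seed included).

Standard conditions: 5 classes × 20 sequences, motif length 12, mutation
rate 0.1, lengths 80–300, one null class.  Under these conditions every
planted class is recovered at leave-one-out IAP ≥ 0.9 at frame 25 and the
20-fold splitting protocol agrees with leave-one-out to within 0.1 per
class; these sizes keep the full protocol (all-pairs scoring of ~100
sequences plus 20 splits) to a few seconds on one CPU.  The frame-sensitivity
property (sub-frame motifs separate worse than frame-length motifs) is
demonstrated at mutation rate 0.6, where recovery is far from saturation
and the comparison is informative.

What the benchmark does *not* emulate — and hence what passing it cannot
show about real data: biological residue composition (background is uniform
over the 20 canonical residues by default, configurable), multiple
cooperating motifs per class, homology structure within classes (on real
substrate sets much of the recoverable signal is family-level similarity),
orthologous near-duplicates, and realistic Ser/Thr/Tyr phosphosite context.
Null-class IAP also has a larger spread than the textbook AUC null
(≈ ±0.07 at 20 vs 80): random labels clump unevenly across the motif
classes, correlating the leave-one-out B values, and a null member's own
class-mates are slightly depleted from its member pool, biasing the null
IAP a little below 0.5.  The accepted band [0.35, 0.65] reflects that.

## Known limitations

* Ungapped frames only: an indel inside a motif splits its contribution
  across shifts; the method relies on frames being short enough that this
  is rare.
* Binary weights are the default and the only weighting exercised by the
  protocols; real-valued weights are accepted but uncalibrated.
* Calibration quality is bounded by class size: with 10 members P1 moves in
  steps of 0.1 and its tails are clamped at 0.05/0.95.
* Classes whose complement is empty (a label covering the whole dataset)
  cannot be trained or evaluated — there is nothing to contrast against.
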