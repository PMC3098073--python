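"""classifier: B statistic, leave-one-out calibration, model persistence,
prediction semantics."""

import numpy as np
import pytest

from paas import (
    CalibrationCurve,
    ClassWeights,
    LabeledDataset,
    ModelVersionError,
    PaasError,
    Sequence,
    b_statistic,
    brute_force_projection_scores,
    calibrate,
    load_model,
    loo_b_values,
    predict,
    profile_matrix,
    save_model,
    train,
)
from paas.classifier import LooValue, _b_from_sums
from paas.projection import query_profile_sums


def _binary_dataset(member_seqs, other_seqs, cls="K"):
    seqs = tuple(member_seqs) + tuple(other_seqs)
    memberships = frozenset((s.id, cls) for s in member_seqs)
    return LabeledDataset(seqs, memberships)


class TestBStatistic:
    def test_identical_training_sequences_give_zero(self, identity_measure):
        seq = Sequence("t", "MKTAYMKTAY")
        train_seqs = [Sequence(f"t{i}", seq.residues) for i in range(4)]
        ds = _binary_dataset(train_seqs[:2], train_seqs[2:])
        Q = Sequence("q", "MKTAYWWWCC")
        S = profile_matrix(Q, list(ds.sequences), 3, identity_measure)
        weights = ClassWeights.binary(ds)
        assert b_statistic(S, weights, "K", 3) == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_negates_b(self, identity_measure):
        rng = np.random.default_rng(2)
        AA = "ACDEFGHIKLMNPQRSTVWY"
        seqs = [
            Sequence(f"t{i}", "".join(AA[j] for j in rng.integers(0, 20, 15)))
            for i in range(5)
        ]
        ds_fwd = LabeledDataset(tuple(seqs), frozenset((s.id, "K") for s in seqs[:2]))
        ds_rev = LabeledDataset(tuple(seqs), frozenset((s.id, "K") for s in seqs[2:]))
        Q = Sequence("q", "".join(AA[j] for j in rng.integers(0, 20, 12)))
        S = profile_matrix(Q, seqs, 4, identity_measure)
        b_fwd = b_statistic(S, ClassWeights.binary(ds_fwd), "K", 4)
        b_rev = b_statistic(S, ClassWeights.binary(ds_rev), "K", 4)
        assert b_fwd == pytest.approx(-b_rev, abs=1e-12)

    def test_motif_class_matches_hand_formula_on_oracle_scores(self, identity_measure):
        """B on a tiny motif set equals the direct weighted-contrast formula
        evaluated on the brute-force score matrix."""
        members = [Sequence("m1", "WWMKTAYWW"), Sequence("m2", "CCMKTAYCC")]
        others = [Sequence("u1", "DDDDDDDDD"), Sequence("u2", "EEEEEEEEE")]
        ds = _binary_dataset(members, others)
        Q = Sequence("q", "GGMKTAYGG")
        F = 3
        S = np.column_stack(
            [
                brute_force_projection_scores(Q, D, F, identity_measure).scores
                for D in ds.sequences
            ]
        )
        s = S / F
        w1 = np.array([1.0, 1.0, 0.0, 0.0])
        expected = float(np.mean(s @ w1 / 2 - s @ (1 - w1) / 2))
        assert expected > 0
        b = b_statistic(S, ClassWeights.binary(ds), "K", F)
        assert b == pytest.approx(expected, abs=1e-12)

    def test_sum_shortcut_equals_per_position_formula(self, blosum_measure):
        rng = np.random.default_rng(8)
        AA = "ACDEFGHIKLMNPQRSTVWY"
        seqs = [
            Sequence(f"t{i}", "".join(AA[j] for j in rng.integers(0, 20, 20)))
            for i in range(6)
        ]
        ds = _binary_dataset(seqs[:3], seqs[3:])
        Q = Sequence("q", "".join(AA[j] for j in rng.integers(0, 20, 17)))
        F = 5
        S = profile_matrix(Q, seqs, F, blosum_measure)
        full = b_statistic(S, ClassWeights.binary(ds), "K", F)
        t_row = query_profile_sums(Q, seqs, F, blosum_measure)
        w1 = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        shortcut = _b_from_sums(t_row, len(Q), w1, 1 - w1, F)
        assert shortcut == pytest.approx(full, rel=1e-12)

    def test_empty_complement_error(self, identity_measure):
        seqs = [Sequence("a", "MKT"), Sequence("b", "MKT")]
        ds = LabeledDataset(tuple(seqs), frozenset({("a", "K"), ("b", "K")}))
        S = np.ones((3, 2))
        with pytest.raises(PaasError, match="complement"):
            b_statistic(S, ClassWeights.binary(ds), "K", 1)


class TestLooBValues:
    def test_separated_families_rank_members_first(self, two_family_dataset):
        for cls in two_family_dataset.classes:
            loo = loo_b_values(two_family_dataset, cls, 10)
            member_b = [v.b for v in loo if v.is_member]
            other_b = [v.b for v in loo if not v.is_member]
            assert min(member_b) > max(other_b)

    def test_matches_full_recompute_oracle(self, two_family_dataset, blosum_measure):
        """Each held-out value equals a from-scratch B computed on a reduced
        dataset that simply drops the held-out sequence."""
        ds = two_family_dataset
        cls = ds.classes[0]
        F = 8
        loo = loo_b_values(ds, cls, F, blosum_measure)
        for v in loo:
            rest = [s for s in ds.sequences if s.id != v.sequence_id]
            reduced = LabeledDataset(
                tuple(rest),
                frozenset(p for p in ds.memberships if p[0] != v.sequence_id),
            )
            Q = ds.by_id[v.sequence_id]
            S = profile_matrix(Q, rest, F, blosum_measure)
            expected = b_statistic(S, ClassWeights.binary(reduced), cls, F)
            assert v.b == pytest.approx(expected, rel=1e-10, abs=1e-12)
            assert v.is_member == (v.sequence_id in ds.members(cls))

    def test_two_sequence_dataset_is_degenerate(self):
        seqs = [Sequence("a", "MKTAY"), Sequence("b", "WWCCD")]
        ds = LabeledDataset(tuple(seqs), frozenset({("a", "K")}))
        with pytest.raises(PaasError):
            loo_b_values(ds, "K", 3)

    def test_singleton_class_error(self):
        seqs = [Sequence(c, "MKTAY") for c in "abcd"]
        ds = LabeledDataset(tuple(seqs), frozenset({("a", "K")}))
        with pytest.raises(PaasError):
            loo_b_values(ds, "K", 3)


def _loo(member_vals, complement_vals):
    vals = [LooValue(f"m{i}", b, True) for i, b in enumerate(member_vals)]
    vals += [LooValue(f"u{i}", b, False) for i, b in enumerate(complement_vals)]
    return vals


class TestCalibration:
    def test_midpoint_interpolation_worked_example(self):
        curve = calibrate(_loo([0.2, 0.4], [-0.3, -0.1]))
        assert curve.p1(0.3) == pytest.approx(0.5)
        assert curve.p0(0.3) == pytest.approx(0.25)  # lower clamp 1/(2*2)

    def test_upper_tail(self):
        curve = calibrate(_loo([0.2, 0.4], [-0.3, -0.1]))
        b = 5.0  # above every sample
        assert curve.p1(b) == pytest.approx(0.75)  # upper clamp 1 - 1/(2*2)
        assert curve.p0(b) == pytest.approx(0.25)
        assert curve.p1(b) - curve.p0(b) > 0

    def test_lower_tail_mirrored(self):
        curve = calibrate(_loo([0.2, 0.4], [-0.3, -0.1]))
        b = -5.0
        assert curve.p1(b) == pytest.approx(0.25)
        assert curve.p0(b) == pytest.approx(0.75)
        assert curve.p1(b) - curve.p0(b) < 0

    def test_monotone_on_dense_grid(self):
        rng = np.random.default_rng(17)
        curve = calibrate(_loo(rng.normal(1, 1, 30), rng.normal(0, 1, 50)))
        grid = np.linspace(-5, 5, 1001)
        p1 = curve.p1(grid)
        p0 = curve.p0(grid)
        assert np.all(np.diff(p1) >= -1e-12)
        assert np.all(np.diff(p0) <= 1e-12)
        assert np.all((p1 >= 0) & (p1 <= 1) & (p0 >= 0) & (p0 <= 1))

    def test_too_few_values_error(self):
        with pytest.raises(PaasError):
            calibrate(_loo([0.2], [-0.3, -0.1]))

    def test_rank_sufficiency_under_monotone_transform(self):
        """Strictly increasing re-expression of all B values (samples and
        queries alike) leaves P1>P0 decisions and delta ordering unchanged."""
        rng = np.random.default_rng(23)
        member = rng.normal(0.5, 0.4, 20)
        complement = rng.normal(-0.2, 0.4, 30)
        queries = rng.normal(0.1, 0.6, 15)
        f = lambda b: np.exp(2.0 * b) - 1.0  # strictly increasing
        base = calibrate(_loo(member, complement))
        trans = calibrate(_loo(f(member), f(complement)))
        d_base = base.p1(queries) - base.p0(queries)
        d_trans = trans.p1(f(queries)) - trans.p0(f(queries))
        assert np.array_equal(d_base > 0, d_trans > 0)
        assert np.array_equal(np.argsort(-d_base, kind="stable"),
                              np.argsort(-d_trans, kind="stable"))


class TestTrainPredict:
    def test_structural_contract(self, benchmark_model):
        assert set(benchmark_model.classes) == {
            "C01", "C02", "C03", "C04", "C05", "R01",
        }
        for cm in benchmark_model.classes.values():
            assert 0.0 <= cm.iap <= 1.0
            assert cm.member_b.size == 20

    def test_training_is_deterministic(self, two_family_dataset):
        m1 = train(two_family_dataset, F=10, min_class_size=2)
        m2 = train(two_family_dataset, F=10, min_class_size=2)
        assert m1.to_json() == m2.to_json()

    def test_no_surviving_class_error(self, two_family_dataset):
        with pytest.raises(PaasError, match="no class survives"):
            train(two_family_dataset, F=10, min_class_size=1000)

    def test_member_query_ranks_its_class_first(self, two_family_dataset):
        model = train(two_family_dataset, F=10, min_class_size=2)
        query = two_family_dataset.sequences[0]
        (true_class,) = [c for c in model.classes
                         if query.id in model.dataset.members(c)]
        records = predict(model, [query], cutoff="all")
        assert records[0].class_name == true_class
        assert records[0].delta > 0

    def test_min_iap_above_one_empties_output(self, two_family_dataset):
        model = train(two_family_dataset, F=10, min_class_size=2)
        assert predict(model, [two_family_dataset.sequences[0]],
                       cutoff="all", min_iap=1.1) == []

    def test_cutoff_all_is_superset_of_default(self, two_family_dataset):
        model = train(two_family_dataset, F=10, min_class_size=2)
        queries = list(two_family_dataset.sequences[:3])
        everything = predict(model, queries, cutoff="all")
        default = predict(model, queries)
        assert len(everything) == len(queries) * len(model.classes)
        keyed = {(r.query_id, r.class_name) for r in everything}
        assert {(r.query_id, r.class_name) for r in default} <= keyed
        for r in default:
            assert r.p1 > r.p0

    def test_unknown_cutoff_error(self, two_family_dataset):
        model = train(two_family_dataset, F=10, min_class_size=2)
        with pytest.raises(PaasError, match="cutoff"):
            predict(model, [], cutoff="maybe")

    def test_delta_nondecreasing_in_b(self, benchmark_model):
        grid = np.linspace(-1, 1, 2001)
        for cm in benchmark_model.classes.values():
            delta = cm.curve.p1(grid) - cm.curve.p0(grid)
            assert np.all(np.diff(delta) >= -1e-12)


class TestModelPersistence:
    def test_save_load_save_identical_bytes(self, tmp_path, two_family_dataset):
        model = train(two_family_dataset, F=10, min_class_size=2)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(model, p1)
        save_model(load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_version_tamper_rejected(self, tmp_path, two_family_dataset):
        model = train(two_family_dataset, F=10, min_class_size=2)
        p = tmp_path / "m.json"
        save_model(model, p)
        p.write_text(p.read_text().replace('"version":1', '"version":99'))
        with pytest.raises(ModelVersionError):
            load_model(p)

    def test_truncated_file_rejected(self, tmp_path, two_family_dataset):
        model = train(two_family_dataset, F=10, min_class_size=2)
        p = tmp_path / "m.json"
        save_model(model, p)
        p.write_text(p.read_text()[: len(p.read_text()) // 2])
        with pytest.raises(PaasError):
            load_model(p)

    def test_loaded_model_predicts_identically(self, tmp_path, two_family_dataset):
        model = train(two_family_dataset, F=10, min_class_size=2)
        p = tmp_path / "m.json"
        save_model(model, p)
        queries = list(two_family_dataset.sequences[:2])
        assert predict(load_model(p), queries, cutoff="all") == predict(
            model, queries, cutoff="all"
        )


class TestMultiLabel:
    def test_query_with_two_motifs_scores_both_classes(self):
        """A query carrying the motifs of two well-separated classes gets
        positive delta for both."""
        from paas import SyntheticSpec, generate_dataset

        spec = SyntheticSpec(
            n_classes=2, sequences_per_class=8, motif_length=(10, 10),
            sequence_length=(60, 100), mutation_rate=0.0,
            overlap_plan=(("C01", "C02", 0.5),), null_classes=0, seed=29,
        )
        dataset, truth = generate_dataset(spec)
        both = truth.groupby("id")["class"].nunique()
        carrier = both[both == 2].index[0]
        model = train(dataset, F=10, min_class_size=2)
        records = predict(model, [dataset.by_id[carrier]], cutoff="all")
        deltas = {r.class_name: r.delta for r in records}
        assert deltas["C01"] > 0 and deltas["C02"] > 0
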