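import itertools

import numpy as np
import pytest

from sugarscope.ingredient_tagger import parse_ingredient_list, tag_ingredients
from sugarscope.sugar_model import (
    FEATURE_NAMES,
    N_FEATURES,
    build_features,
    build_feature_matrix,
    evaluate,
    knn_baseline,
    predict_added_sugars,
    predict_records,
    split_dataset,
    train_bundle,
)
from sugarscope.synthetic_data import GenConfig, generate_products

from conftest import make_record


def _features(record, lexicon):
    return build_features(
        record, tag_ingredients(parse_ingredient_list(record.ingredient_text), lexicon)
    )


class TestFeatures:
    def test_contract_size(self):
        assert N_FEATURES == 26 and len(FEATURE_NAMES) == 26

    def test_hand_assembled_vector(self, lexicon):
        rec = make_record(ingredient_text="milk, sugar, strawberry")
        vec = _features(rec, lexicon)
        expected_tags = [0] * 18
        expected_tags[1] = 1   # position 1 dairy
        expected_tags[3] = 1   # position 2 added sugar
        expected_tags[8] = 1   # position 3 fruit/veg
        assert vec[:18].tolist() == expected_tags
        assert vec[18:].tolist() == list(rec.panel.as_tuple())

    def test_no_sugar_ingredients_zero_tag_block(self, lexicon):
        rec = make_record(ingredient_text="water, salt")
        vec = _features(rec, lexicon)
        assert vec[:18].sum() == 0

    def test_positions_beyond_six_ignored(self, lexicon):
        head = "water, salt, citric acid, flavouring, wheat flour, rice flour"
        a = make_record(ingredient_text=head + ", sugar, honey")
        b = make_record(ingredient_text=head + ", honey, sugar")
        assert np.array_equal(_features(a, lexicon), _features(b, lexicon))

    def test_declared_label_never_a_feature(self, lexicon):
        base = make_record(declared_added_sugars=None)
        labelled = make_record(declared_added_sugars=12.0)
        assert np.array_equal(_features(base, lexicon), _features(labelled, lexicon))


class TestSplit:
    def _records(self, n, seed=0):
        records, _ = generate_products(GenConfig(n_products=n, seed=seed))
        return [r for r in records if r.declared_added_sugars is not None][:n]

    def test_sizes_and_partition(self):
        records = self._records(100)
        train, val, test = split_dataset(records, (0.8, 0.1, 0.1), seed=7)
        assert (len(train), len(val), len(test)) == (80, 10, 10)
        ids = [r.product_id for r in train + val + test]
        assert sorted(ids) == sorted(r.product_id for r in records)
        assert len(set(ids)) == len(ids)

    def test_deterministic_under_seed(self):
        records = self._records(200)
        first = split_dataset(records, seed=3)
        second = split_dataset(records, seed=3)
        assert first == second
        other = split_dataset(records, seed=4)
        assert other != first

    def test_stratification_preserves_prevalence(self):
        records, _ = generate_products(GenConfig(n_products=5000, seed=21))
        records = [r for r in records if r.declared_added_sugars is not None]
        prevalence = np.mean([r.declared_added_sugars > 0 for r in records])
        for part in split_dataset(records, seed=1):
            part_prev = np.mean([r.declared_added_sugars > 0 for r in part])
            assert abs(part_prev - prevalence) <= 0.02

    def test_unlabelled_records_refused(self):
        with pytest.raises(ValueError, match="declared_added_sugars"):
            split_dataset([make_record(declared_added_sugars=None)] * 10)


class TestTrainPredict:
    def test_bundle_roundtrip_identical_predictions(
        self, small_benchmark, small_bundle, lexicon, tmp_path
    ):
        path = tmp_path / "bundle.joblib"
        small_bundle.save(path)
        from sugarscope.sugar_model import TrainedBundle

        reloaded = TrainedBundle.load(path)
        X = build_feature_matrix(small_benchmark.test[:50], lexicon)
        totals = np.array([r.panel.total_sugars for r in small_benchmark.test[:50]])
        a = predict_added_sugars(small_bundle, X, totals)
        b = predict_added_sugars(reloaded, X, totals)
        assert [r.added_sugars_pred for r in a] == [r.added_sugars_pred for r in b]
        assert [r.has_added_sugar for r in a] == [r.has_added_sugar for r in b]

    def test_training_deterministic_under_seed(self, small_benchmark, small_bundle, lexicon):
        again = train_bundle(
            small_benchmark.train, small_benchmark.validation, lexicon, seed=7
        )
        X = build_feature_matrix(small_benchmark.test[:100], lexicon)
        totals = np.array([r.panel.total_sugars for r in small_benchmark.test[:100]])
        a = predict_added_sugars(small_bundle, X, totals)
        b = predict_added_sugars(again, X, totals)
        assert [r.added_sugars_pred for r in a] == [r.added_sugars_pred for r in b]

    def test_gating_negative_is_exact_zero(self, small_benchmark, small_bundle, lexicon):
        preds = predict_records(small_bundle, small_benchmark.test, lexicon)
        negatives = [p for p in preds if not p.has_added_sugar]
        assert negatives, "benchmark should contain presence-negative products"
        assert all(p.added_sugars_pred == 0.0 for p in negatives)

    def test_predictions_bounded_by_total_sugars(self, small_benchmark, small_bundle, lexicon):
        preds = predict_records(small_bundle, small_benchmark.test, lexicon)
        for rec, pred in zip(small_benchmark.test, preds):
            assert 0.0 <= pred.added_sugars_pred <= rec.panel.total_sugars + 1e-9

    def test_clipping_flagged(self, small_benchmark, small_bundle, lexicon):
        """Force clipping by giving a sugary product a tiny total-sugars cap."""
        rec = next(
            r
            for r in small_benchmark.test
            if "sugar" in r.ingredient_text and r.panel.total_sugars > 10
        )
        X = _features(rec, lexicon)
        pred = predict_added_sugars(small_bundle, X, 1.0)
        if pred.has_added_sugar:
            assert pred.added_sugars_pred <= 1.0
            assert pred.clipped

    def test_feature_length_mismatch(self, small_bundle):
        with pytest.raises(ValueError, match="26"):
            predict_added_sugars(small_bundle, np.zeros(10), 5.0)

    def test_label_shuffle_does_not_change_predictions(
        self, small_benchmark, small_bundle, lexicon
    ):
        """Target non-leakage: declared labels are invisible at predict time."""
        import dataclasses

        records = small_benchmark.test[:50]
        shuffled = [
            dataclasses.replace(r, declared_added_sugars=99.0) for r in records
        ]
        a = predict_records(small_bundle, records, lexicon)
        b = predict_records(small_bundle, shuffled, lexicon)
        assert [p.added_sugars_pred for p in a] == [p.added_sugars_pred for p in b]

    def test_insufficient_positive_records(self, lexicon, small_benchmark):
        negatives = [
            r
            for r in small_benchmark.train
            if r.declared_added_sugars is not None and r.declared_added_sugars == 0
        ][:250]
        with pytest.raises(ValueError, match="positive"):
            train_bundle(negatives, small_benchmark.validation, lexicon, seed=0)


class TestKnnBaseline:
    def test_query_on_training_point_k1(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        y = np.array([1.0, 5.0, 9.0])
        assert knn_baseline(X, y, X[1], k=1)[0] == 5.0

    def test_k_equals_n_gives_global_mean(self):
        X = np.array([[0.0], [1.0], [4.0]])
        y = np.array([3.0, 6.0, 9.0])
        assert knn_baseline(X, y, np.array([[2.0]]), k=3)[0] == pytest.approx(6.0)

    def test_matches_bruteforce_neighbours(self):
        """3-point toy set, k=2: verified by exhaustive distance enumeration."""
        X = np.array([[0.0, 1.0], [2.0, 3.0], [10.0, -1.0]])
        y = np.array([2.0, 4.0, 20.0])
        query = np.array([[1.0, 2.0]])
        mu, sd = X.mean(axis=0), X.std(axis=0)
        dists = [np.linalg.norm((X[i] - mu) / sd - (query[0] - mu) / sd) for i in range(3)]
        best2 = np.argsort(dists)[:2]
        expected = y[best2].mean()
        assert knn_baseline(X, y, query, k=2)[0] == pytest.approx(expected)

    def test_k_larger_than_training_refused(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_baseline(np.zeros((3, 2)), np.zeros(3), np.zeros(2), k=4)


class TestEvaluate:
    def test_simple_mae(self):
        assert evaluate([1.0, 0.0], [3.0, 0.0]).mae == pytest.approx(1.0)

    def test_identity_predictions(self):
        rep = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.mae == 0.0 and rep.r2 == pytest.approx(1.0)

    def test_mape_over_positive_truths_only(self):
        rep = evaluate([10.0, 20.0, 0.0], [12.0, 18.0, 1.0])
        assert rep.mae == pytest.approx(5.0 / 3.0)
        assert rep.mape == pytest.approx(15.0)

    def test_constant_truths_leave_r2_missing(self):
        rep = evaluate([2.0, 2.0], [1.0, 3.0])
        assert rep.r2 is None

    def test_per_group_breakdown(self):
        rep = evaluate([1.0, 2.0, 10.0], [1.0, 3.0, 12.0], groups=["a", "a", "b"])
        assert rep.per_group["a"].mae == pytest.approx(0.5)
        assert rep.per_group["b"].mae == pytest.approx(2.0)
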