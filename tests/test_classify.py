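import numpy as np
import pytest

from fatiguehrv import classify
from fatiguehrv.pipeline import REFERENCE_CONFUSION


class TestTrainLVQ:
    def test_determinism(self, blobs_3class):
        x, y = blobs_3class
        cfg = classify.LVQConfig(seed=3)
        a = classify.train_lvq(x, y, cfg)
        b = classify.train_lvq(x, y, cfg)
        np.testing.assert_array_equal(a.codebook, b.codebook)
        np.testing.assert_array_equal(a.proto_class, b.proto_class)

    def test_separable_blobs_training_accuracy(self, blobs_3class):
        x, y = blobs_3class
        model = classify.train_lvq(x, y, classify.LVQConfig(seed=0))
        pred = classify.predict_lvq(model, x)
        assert (pred == y).mean() >= 0.95

    def test_prototype_allocation_balanced(self, blobs_3class):
        x, y = blobs_3class
        model = classify.train_lvq(x, y, classify.LVQConfig(n_prototypes=13, seed=0))
        counts = np.bincount(model.proto_class, minlength=3)
        assert sorted(counts.tolist()) == [4, 4, 5]

    def test_prototypes_converge_to_class_means(self):
        """One prototype per class on distant point clusters ends up
        within 0.1 of each cluster mean (LVQ1 fixed point)."""
        rng = np.random.default_rng(1)
        a = rng.normal([0.0, 0.0], 0.02, size=(80, 2))
        b = rng.normal([5.0, 5.0], 0.02, size=(80, 2))
        c = rng.normal([-5.0, 5.0], 0.02, size=(80, 2))
        x = np.vstack([a, b, c])
        y = np.repeat([0, 1, 2], 80)
        model = classify.train_lvq(x, y, classify.LVQConfig(n_prototypes=3, seed=2))
        for cls, pts in zip((0, 1, 2), (a, b, c)):
            proto = model.codebook[model.proto_class == cls][0]
            assert np.linalg.norm(proto - pts.mean(axis=0)) < 0.1

    def test_missing_class_rejected(self, blobs_3class):
        x, y = blobs_3class
        mask = y != 2
        with pytest.raises(ValueError, match="absent"):
            classify.train_lvq(x[mask], y[mask])

    def test_early_stop_records_mse_trace(self, blobs_3class):
        x, y = blobs_3class
        model = classify.train_lvq(x, y, classify.LVQConfig(seed=0))
        assert len(model.mse_trace) >= 1
        assert model.mse_trace[-1] <= 0.1  # separable data reaches target error


class TestPredictLVQ:
    def test_codebook_vector_maps_to_own_class(self, blobs_3class):
        x, y = blobs_3class
        model = classify.train_lvq(x, y, classify.LVQConfig(seed=0))
        pred = classify.predict_lvq(model, model.codebook)
        np.testing.assert_array_equal(pred, model.proto_class)

    def test_tie_broken_by_lowest_neuron_index(self):
        codebook = np.array([[0.0, 0.0], [2.0, 0.0]])
        proto_class = np.array([2, 0])
        # the midpoint is exactly equidistant: neuron 0 (class 2) wins
        pred = classify.predict_from_codebook(codebook, proto_class,
                                              np.array([[1.0, 0.0]]))
        assert pred[0] == 2

    def test_rotation_invariance(self, blobs_3class):
        x, y = blobs_3class
        model = classify.train_lvq(x, y, classify.LVQConfig(seed=0))
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        base = classify.predict_lvq(model, x)
        rotated_model = classify.LVQModel(codebook=model.codebook @ rot.T,
                                          proto_class=model.proto_class,
                                          config=model.config)
        rotated = classify.predict_lvq(rotated_model, x @ rot.T)
        np.testing.assert_array_equal(base, rotated)

    def test_dimension_mismatch_rejected(self, blobs_3class):
        x, y = blobs_3class
        model = classify.train_lvq(x, y)
        with pytest.raises(ValueError, match="dimension"):
            classify.predict_lvq(model, np.ones((4, 5)))


class TestSizeSelection:
    def test_singleton_candidate(self, blobs_3class):
        x, y = blobs_3class
        res = classify.select_competitive_size(x, y, [13], k=5, seed=0)
        assert res.chosen == 13
        assert len(res.mean_accuracy) == 1

    def test_curve_length_and_capacity(self, blobs_3class):
        x, y = blobs_3class
        res = classify.select_competitive_size(x, y, [3, 7, 13], k=5, seed=0)
        assert len(res.mean_accuracy) == 3 and len(res.mean_mse) == 3
        # chosen accuracy is at least that of the minimal 3-neuron model
        chosen_acc = res.mean_accuracy[res.candidates.index(res.chosen)]
        assert chosen_acc >= res.mean_accuracy[0] - 0.05

    def test_k_larger_than_class_rejected(self, blobs_3class):
        x, y = blobs_3class
        with pytest.raises(ValueError):
            classify.select_competitive_size(x, y, [13], k=200, seed=0)


class TestEvaluate:
    def test_reference_confusion_metric_chain(self):
        """The published 3x96 test confusion yields per-class accuracy
        82.29 / 78.13 / 85.42% and overall 81.94%."""
        rep = classify.evaluate_confusion(np.array(REFERENCE_CONFUSION))
        assert rep.accuracy == pytest.approx(81.94, abs=0.005)
        assert rep.per_class_accuracy[0] == pytest.approx(82.29, abs=0.005)
        assert rep.per_class_accuracy[1] == pytest.approx(78.13, abs=0.006)
        assert rep.per_class_accuracy[2] == pytest.approx(85.42, abs=0.005)
        # overall equals the equal-n mean of per-class accuracies
        assert rep.accuracy == pytest.approx(rep.per_class_accuracy.mean())

    def test_perfect_predictions(self):
        y = np.repeat([0, 1, 2], 10)
        rep = classify.evaluate(y, y)
        assert rep.accuracy == 100.0
        assert np.all(rep.precision == 100.0) and np.all(rep.recall == 100.0)
        assert np.all(rep.confusion - np.diag(np.diag(rep.confusion)) == 0)

    def test_accuracy_variant_f1_worked_example(self):
        """Precision 69.60 with accuracy 69.10 gives 69.35 under the
        accuracy-substituted F1 form."""
        assert classify.f1_accuracy_variant(69.60, 69.10) == pytest.approx(69.35, abs=0.005)

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(4)
        t = rng.integers(0, 3, 200)
        p = rng.integers(0, 3, 200)
        rep = classify.evaluate(t, p)
        for i in range(3):
            for j in range(3):
                assert rep.confusion[i, j] == int(np.sum((t == i) & (p == j)))
        assert rep.confusion.sum() == 200

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            classify.evaluate([0, 1, 3], [0, 1, 2])
        with pytest.raises(ValueError):
            classify.evaluate([0, 1], [0, 1, 2])


class TestROC:
    def test_perfect_separation_auc_one(self):
        y = np.repeat([0, 1, 2], 20)
        scores = np.eye(3)[y] + 0.0
        out = classify.roc_one_vs_rest(scores, y)
        for c in range(3):
            assert out[c]["auc"] == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 3, 1000)
        scores = rng.normal(size=(1000, 3))
        out = classify.roc_one_vs_rest(scores, y)
        for c in range(3):
            assert abs(out[c]["auc"] - 0.5) < 0.05

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 3, 300)
        scores = rng.normal(size=(300, 3)) + np.eye(3)[y]
        a = classify.roc_one_vs_rest(scores, y)
        b = classify.roc_one_vs_rest(np.exp(scores), y)
        for c in range(3):
            assert a[c]["auc"] == pytest.approx(b[c]["auc"])

    def test_single_class_truth_flagged(self):
        y = np.zeros(10, dtype=int)
        scores = np.random.default_rng(7).normal(size=(10, 3))
        out = classify.roc_one_vs_rest(scores, y)
        assert out[1]["auc"] is None and out[2]["auc"] is None


class TestBaselines:
    def test_separable_blobs_and_schema(self, blobs_3class):
        x, y = blobs_3class
        rng = np.random.default_rng(8)
        idx = rng.permutation(len(y))
        tr, te = idx[:240], idx[240:]
        out = classify.train_baselines(x[tr], y[tr], x[te], y[te], seed=0)
        for name in ("bpnn", "svm"):
            rep = out[name]["report"]
            assert rep.accuracy >= 95.0
            # same metric schema as the LVQ evaluation
            assert set(rep.to_dict()) == set(
                classify.evaluate(y[te], y[te]).to_dict())
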