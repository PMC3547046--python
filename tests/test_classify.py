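"""Signature extraction, SVM training, majority voting and the
leave-one-image-per-class cross-validation protocol."""

import dataclasses

import numpy as np
import pytest

import cellcov as cc


# --------------------------------------------------------------------------
# small in-memory dataset shared by the protocol tests
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_dataset():
    spec = cc.default_spec(n_images=3, image_size=384, seed=5)
    imgs, entries = {}, []
    for ci, label in enumerate(["lineA-epi30", "lineC-epi150"]):
        for i in range(3):
            img, _ = cc.generate_image(spec, label, seed=900 + 13 * ci + i)
            pid = f"{label}_{i}"
            imgs[pid] = img
            entries.append(cc.ManifestEntry(pid, label, "20x"))
    return cc.DatasetManifest(tuple(entries)), imgs


@pytest.fixture(scope="module")
def one_image():
    spec = cc.default_spec(n_images=2, image_size=384, seed=5)
    img, _ = cc.generate_image(spec, "lineA-epi30", seed=77)
    return img


class TestSignatureExtraction:
    def test_f1_signature_is_n_vectors_of_120(self, one_image):
        cfg = cc.RunConfig(seed=1, mapping="F1", n_subwindows=20)
        sig = cc.extract_image_signature(one_image, cfg, image_id="a")
        assert len(sig) == 20
        assert all(v.values.shape == (120,) for v in sig)
        assert all(v.mapping_id == "F1" for v in sig)

    def test_f4_signature_has_length_15_vectors(self, one_image):
        cfg = cc.RunConfig(seed=1, mapping="F4", n_subwindows=5)
        sig = cc.extract_image_signature(one_image, cfg, image_id="a")
        assert len(sig) == 5
        assert all(v.values.shape == (15,) for v in sig)   # 5*6/2

    def test_diagonal_only_signature_has_d_values(self, one_image):
        cfg = cc.RunConfig(seed=1, diagonal_only=True, n_subwindows=5)
        sig = cc.extract_image_signature(one_image, cfg, image_id="a")
        assert all(v.values.shape == (15,) for v in sig)

    def test_deterministic_for_fixed_seed_and_id(self, one_image):
        cfg = cc.RunConfig(seed=9, n_subwindows=5)
        s1 = cc.extract_image_signature(one_image, cfg, image_id="a")
        s2 = cc.extract_image_signature(one_image, cfg, image_id="a")
        for v1, v2 in zip(s1, s2):
            np.testing.assert_array_equal(v1.values, v2.values)


class TestTrainSVM:
    def _clusters(self, rng, n=100, d=8, gap=6.0):
        X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(gap, 1, (n, d))])
        y = np.array(["a"] * n + ["b"] * n)
        return X, y

    def test_separable_clusters_fit_perfectly(self, rng):
        X, y = self._clusters(rng)
        model = cc.train_svm(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_training_is_deterministic(self, rng):
        X, y = self._clusters(rng)
        probe = rng.normal(3, 2, (50, 8))
        m1, m2 = cc.train_svm(X, y), cc.train_svm(X, y)
        np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))

    def test_shuffled_labels_give_chance_level(self, rng):
        """Permutation null: held-out accuracy near 50% over 20 repeats."""
        accs = []
        for _ in range(20):
            X = rng.normal(0, 1, (100, 6))
            y = np.array(["a", "b"] * 50)
            rng.shuffle(y)
            model = cc.train_svm(X[:60], y[:60])
            accs.append((model.predict(X[60:]) == y[60:]).mean())
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_standardisation_uses_training_data_only(self, rng):
        X, y = self._clusters(rng, n=40)
        model = cc.train_svm(X, y)
        np.testing.assert_allclose(model.scaler.mean_, X.mean(axis=0))
        np.testing.assert_allclose(model.scaler.scale_, X.std(axis=0))

    def test_single_class_and_nan_rejected(self, rng):
        X = rng.random((10, 4))
        with pytest.raises(cc.ValidationError):
            cc.train_svm(X, np.array(["a"] * 10))
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(cc.ValidationError):
            cc.train_svm(Xn, np.array(["a"] * 5 + ["b"] * 5))


class _StubModel:
    """Fixed per-vector labels and class scores, for vote arithmetic."""

    def __init__(self, labels, scores, classes):
        self._labels, self._scores, self._classes = labels, scores, classes

    @property
    def classes(self):
        return self._classes

    def predict(self, X):
        return np.array(self._labels[: len(X)])

    def class_scores(self, X):
        return np.array(self._scores[: len(X)])


def _vecs(k, d=3):
    return [cc.DescriptorVector(np.zeros(d), "F1", True) for _ in range(k)]


class TestPredictImage:
    def test_unanimous_vote(self):
        model = _StubModel(["A"] * 4, [[1.0, 0.0]] * 4, ("A", "B"))
        res = cc.predict_image(model, _vecs(4))
        assert res.voted_label == "A"
        assert res.vote_histogram == {"A": 4}

    def test_tie_broken_by_summed_margin(self):
        # 2-2 tie; summed decision scores favour A
        model = _StubModel(["A", "A", "B", "B"],
                           [[2.0, 0.1], [2.0, 0.1], [0.0, 1.0], [0.0, 1.0]],
                           ("A", "B"))
        res = cc.predict_image(model, _vecs(4))
        assert res.voted_label == "A"

    def test_tie_with_equal_margins_is_lexicographic(self):
        model = _StubModel(["B", "A"], [[1.0, 1.0], [1.0, 1.0]], ("A", "B"))
        assert cc.predict_image(model, _vecs(2)).voted_label == "A"

    def test_histogram_counts_sum_to_n(self):
        model = _StubModel(["A", "B", "A", "B", "A"], [[1, 0]] * 5, ("A", "B"))
        res = cc.predict_image(model, _vecs(5))
        assert sum(res.vote_histogram.values()) == 5

    def test_empty_signature_rejected(self):
        model = _StubModel([], [], ("A", "B"))
        with pytest.raises(cc.ContractError):
            cc.predict_image(model, [])


def _manifest(rows):
    return cc.DatasetManifest(tuple(cc.ManifestEntry(*r) for r in rows))


class TestFoldPlan:
    def test_fourteen_by_twenty_gives_twenty_folds_of_fourteen(self):
        rows = [(f"i{c}_{k}.png", f"c{c:02d}", "20x")
                for c in range(14) for k in range(20)]
        plan = cc.make_fold_plan(_manifest(rows))
        assert plan.n_folds == 20
        assert all(len(test) == 14 for test, _ in plan.folds)

    def test_smallest_balanced_case(self):
        rows = [("a1", "a", "20x"), ("a2", "a", "20x"),
                ("b1", "b", "20x"), ("b2", "b", "20x")]
        plan = cc.make_fold_plan(_manifest(rows))
        assert plan.n_folds == 2
        assert set(plan.folds[0][0]) == {"a1", "b1"}
        assert set(plan.folds[0][1]) == {"a2", "b2"}

    def test_folds_partition_the_manifest(self):
        rows = [(f"p{c}{k}", f"c{c}", "10x") for c in range(3) for k in range(4)]
        m = _manifest(rows)
        plan = cc.make_fold_plan(m)
        seen = [p for test, _ in plan.folds for p in test]
        assert sorted(seen) == sorted(e.path for e in m.entries)
        for test, train in plan.folds:
            assert not set(test) & set(train)
            assert len(test) + len(train) == len(m.entries)

    def test_unbalanced_classes_rejected_with_counts(self):
        rows = [("a1", "a", "20x"), ("a2", "a", "20x"), ("a3", "a", "20x"),
                ("b1", "b", "20x"), ("b2", "b", "20x")]
        with pytest.raises(cc.ValidationError, match="3"):
            cc.make_fold_plan(_manifest(rows))


class TestCrossValidate:
    def test_report_internally_consistent(self, small_dataset):
        manifest, imgs = small_dataset
        cfg = cc.RunConfig(seed=2, n_subwindows=10)
        rep = cc.cross_validate(manifest, cfg, image_loader=imgs.get)
        assert rep.mean_accuracy == pytest.approx(np.mean(rep.fold_accuracies),
                                                  abs=1e-12)
        assert rep.confusion.sum() == len(manifest.entries)
        assert len(rep.fold_accuracies) == 3

    def test_end_to_end_seeded_determinism(self, small_dataset):
        manifest, imgs = small_dataset
        cfg = cc.RunConfig(seed=2, n_subwindows=10)
        r1 = cc.cross_validate(manifest, cfg, image_loader=imgs.get)
        r2 = cc.cross_validate(manifest, cfg, image_loader=imgs.get)
        assert r1.fold_accuracies == r2.fold_accuracies
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_accuracy_invariant_under_class_renaming(self, small_dataset):
        manifest, imgs = small_dataset
        cfg = cc.RunConfig(seed=2, n_subwindows=10)
        base = cc.cross_validate(manifest, cfg, image_loader=imgs.get)
        renamed = cc.DatasetManifest(tuple(
            dataclasses.replace(e, label="zz-" + e.label)
            for e in manifest.entries))
        rep = cc.cross_validate(renamed, cfg, image_loader=imgs.get)
        assert rep.mean_accuracy == base.mean_accuracy
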