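"""SVM kernel, training, prediction and LOOCV grid-search contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvseizure import (
    TrainingSet,
    gaussian_kernel,
    grid_search_loocv,
    load_model,
    predict,
    save_model,
    train,
)
from hrvseizure.classifier import decision_value, kernel_matrix, predict_many
from hrvseizure.errors import ParameterError


def _blobs(n_per_class=20, separation=6.0, seed=0, dim=3):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_class, dim))
    b = rng.standard_normal((n_per_class, dim))
    b[:, 0] += separation
    features = np.vstack([a, b])
    labels = np.array(["interictal"] * n_per_class + ["preictal"] * n_per_class, dtype=object)
    return TrainingSet(features, labels)


class TestGaussianKernel:
    def test_zero_distance_gives_one(self):
        u = np.array([1.0, 2.0, 3.0])
        assert gaussian_kernel(u, u, gamma=0.7) == 1.0

    def test_unit_argument_gives_inverse_e(self):
        # squared distance equal to gamma -> exp(-1), the divide-by-gamma form
        u = np.zeros(4)
        v = np.array([2.0, 0.0, 0.0, 0.0])
        assert gaussian_kernel(u, v, gamma=4.0) == pytest.approx(math.exp(-1))

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_range(self, u, v, gamma):
        u, v = np.array(u), np.array(v)
        k = gaussian_kernel(u, v, gamma)
        assert k == gaussian_kernel(v, u, gamma)
        assert 0.0 <= k <= 1.0  # mathematically > 0; may underflow to 0.0

    def test_kernel_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 7))
        k = kernel_matrix(x, x, gamma=2.0)
        w = np.linalg.eigvalsh((k + k.T) / 2)
        assert w[0] >= -1e-9

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_kernel(np.zeros(2), np.ones(2), gamma=0.0)


class TestTrain:
    def test_separable_clouds_reach_perfect_training_accuracy(self):
        ts = _blobs(separation=8.0)
        model = train(ts, c=10.0, gamma=4.0)
        labels, _ = predict_many(model, ts.features)
        assert np.all(labels == ts.labels)

    def test_training_is_deterministic(self):
        ts = _blobs(seed=3)
        m1 = train(ts, c=2.0, gamma=1.5)
        m2 = train(ts, c=2.0, gamma=1.5)
        assert np.array_equal(m1.support_vectors, m2.support_vectors)
        assert np.array_equal(m1.dual_coef, m2.dual_coef)
        assert m1.bias == m2.bias

    def test_xor_arrangement_separated_by_kernel(self):
        features = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        labels = np.array(["interictal", "interictal", "preictal", "preictal"], dtype=object)
        ts = TrainingSet(features, labels)
        model = train(ts, c=1e4, gamma=1.0)
        out, _ = predict_many(model, features)
        assert np.all(out == labels)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            TrainingSet(np.zeros((4, 2)), np.array(["preictal"] * 4, dtype=object))

    def test_dual_coefficients_bounded_by_c(self):
        ts = _blobs(separation=1.0, seed=9)  # overlapping -> bound active
        c = 0.7
        model = train(ts, c=c, gamma=2.0)
        assert np.max(np.abs(model.dual_coef)) <= c + 1e-9

    def test_decision_matches_sklearn(self):
        from sklearn.svm import SVC

        ts = _blobs(seed=4)
        c, gamma = 3.0, 2.5
        model = train(ts, c, gamma)
        svc = SVC(kernel="rbf", C=c, gamma=1.0 / gamma).fit(
            ts.features, ts.labels.astype(str)
        )
        probe = np.array([0.5, -0.2, 1.0])
        assert decision_value(model, probe) == pytest.approx(
            float(svc.decision_function(probe[None, :])[0]), abs=1e-9
        )


class TestPredict:
    def test_support_vector_keeps_own_label_when_separable(self):
        ts = _blobs(separation=10.0)
        model = train(ts, c=100.0, gamma=8.0)
        sv = model.support_vectors[0]
        # find its label in the training set
        idx = np.argmin(np.sum((ts.features - sv) ** 2, axis=1))
        label, _ = predict(model, sv)
        assert label == ts.labels[idx]

    def test_midpoint_of_symmetric_singletons_is_zero(self):
        features = np.array([[-1.0, 0.0], [1.0, 0.0]])
        labels = np.array(["interictal", "preictal"], dtype=object)
        model = train(TrainingSet(features, labels), c=10.0, gamma=1.0)
        _, dec = predict(model, np.array([0.0, 0.0]))
        assert dec == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_training_order_permutation(self):
        ts = _blobs(seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ts.labels))
        ts_perm = TrainingSet(ts.features[perm], ts.labels[perm], ts.provenance[perm])
        m1 = train(ts, c=4.0, gamma=2.0)
        m2 = train(ts_perm, c=4.0, gamma=2.0)
        probes = rng.standard_normal((50, 3))
        l1, d1 = predict_many(m1, probes)
        l2, d2 = predict_many(m2, probes)
        assert np.array_equal(l1, l2)
        # decision values agree to the dual-solver tolerance
        assert np.allclose(d1, d2, atol=1e-2)

    def test_length_mismatch_rejected(self):
        ts = _blobs()
        model = train(ts, c=1.0, gamma=1.0)
        with pytest.raises(ParameterError):
            predict(model, np.zeros(5))


class TestGridSearch:
    def test_separable_set_reaches_perfect_cv(self):
        ts = _blobs(separation=8.0, seed=1)
        c, gamma, acc = grid_search_loocv(ts)
        assert acc == 1.0

    def test_single_point_grid_returned(self):
        ts = _blobs(seed=2)
        c, gamma, acc = grid_search_loocv(ts, c_grid=(2.0,), gamma_grid=(3.0,))
        assert (c, gamma) == (2.0, 3.0)
        assert 0.0 <= acc <= 1.0

    def test_permuted_labels_give_chance_level_accuracy(self):
        rng = np.random.default_rng(12)
        features = rng.standard_normal((80, 7))
        labels = np.array(["preictal"] * 40 + ["interictal"] * 40, dtype=object)
        labels = labels[rng.permutation(80)]
        ts = TrainingSet(features, labels)
        _, _, acc = grid_search_loocv(ts)
        assert 0.3 <= acc <= 0.7

    def test_provenance_grouping_blocks_leakage(self):
        # two identical samples share provenance: both must leave together,
        # so a memorizing kernel cannot score them from each other
        rng = np.random.default_rng(8)
        features = np.vstack([rng.standard_normal((10, 3))] * 2)
        labels = np.array(
            ["preictal"] * 5 + ["interictal"] * 5 + ["preictal"] * 5 + ["interictal"] * 5,
            dtype=object,
        )
        prov = np.array([f"s{i}" for i in range(10)] * 2, dtype=object)
        ts_grouped = TrainingSet(features, labels, prov)
        ts_ungrouped = TrainingSet(features, labels)
        # needle kernel: only exact duplicates look similar
        from hrvseizure.classifier import _loocv_accuracy

        acc_grouped = _loocv_accuracy(ts_grouped, 10.0, 1e-3)
        acc_ungrouped = _loocv_accuracy(ts_ungrouped, 10.0, 1e-3)
        assert acc_ungrouped == 1.0
        assert acc_grouped < 1.0

    def test_too_few_samples_per_class_rejected(self):
        features = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        labels = np.array(["preictal", "interictal", "interictal"], dtype=object)
        with pytest.raises(ParameterError):
            grid_search_loocv(TrainingSet(features, labels))


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        ts = _blobs(seed=11)
        model = train(ts, c=5.0, gamma=3.0)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        rng = np.random.default_rng(1)
        probes = rng.standard_normal((1000, 3)) * 3
        l1, d1 = predict_many(model, probes)
        l2, d2 = predict_many(loaded, probes)
        assert np.array_equal(l1, l2)
        assert np.array_equal(d1, d2)
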