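"""Kernels, the sparse Bayesian classifier, baselines and serialization."""

import numpy as np
import pytest

import somnoscore as ss
from somnoscore.classifiers import (
    BinarySparseModel,
    FeatureStandardizer,
    lda_fit,
    lda_predict,
)
from somnoscore.io import STAGE_ORDER, SleepStage


def blobs(rng, n_per=20, sep=2.0, sd=0.5):
    X = np.vstack(
        [
            rng.normal([-sep, -sep], sd, (n_per, 2)),
            rng.normal([sep, sep], sd, (n_per, 2)),
        ]
    )
    y = np.r_[np.zeros(n_per), np.ones(n_per)]
    return X, y


class TestKernelMatrix:
    def test_rbf_self_diagonal_is_one(self, rng):
        X = rng.standard_normal((6, 3))
        K = ss.kernel_matrix(X, X, ss.KernelSpec("rbf", 0.5))
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T)

    def test_linear_orthogonal_vectors(self):
        X = np.eye(3)
        K = ss.kernel_matrix(X, X, ss.KernelSpec("linear"))
        np.testing.assert_allclose(K, np.eye(3))

    def test_matches_elementwise_loop_oracle(self, rng):
        X, Z = rng.standard_normal((5, 3)), rng.standard_normal((4, 3))
        for spec in (ss.KernelSpec("linear"), ss.KernelSpec("rbf", 0.7)):
            K = ss.kernel_matrix(X, Z, spec)
            for i in range(5):
                for j in range(4):
                    if spec.kind == "linear":
                        want = X[i] @ Z[j]
                    else:
                        want = np.exp(-0.7 * np.sum((X[i] - Z[j]) ** 2))
                    assert K[i, j] == pytest.approx(want, abs=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            ss.kernel_matrix(
                rng.standard_normal((3, 2)),
                rng.standard_normal((3, 4)),
                ss.KernelSpec("linear"),
            )


class TestRvmBinary:
    def test_separable_blobs_perfect_and_sparse(self):
        rng = np.random.default_rng(1)
        X, y = blobs(rng)
        m = ss.rvm_fit_binary(X, y, ss.KernelSpec("linear"))
        p = ss.predict_binary(m, X)
        assert np.mean((p > 0.5) == y) == 1.0
        assert m.n_relevance_vectors < len(y) / 2
        assert np.all((p > 0.5) == (y == 1))

    def test_xor_with_rbf_kernel(self):
        rng = np.random.default_rng(2)
        centers = np.array([[2, 2], [-2, -2], [2, -2], [-2, 2]])
        X = np.vstack([rng.normal(centers[i % 4], 0.5, (20, 2)) for i in range(4)])
        y = np.r_[np.ones(40), np.zeros(40)]
        m = ss.rvm_fit_binary(X, y, ss.KernelSpec("rbf", 0.5))
        p = ss.predict_binary(m, X)
        assert np.mean((p > 0.5) == y) >= 0.9
        assert m.n_relevance_vectors < len(y)

    def test_probabilities_open_unit_interval(self, rng):
        X, y = blobs(rng)
        m = ss.rvm_fit_binary(X, y, ss.KernelSpec("rbf", 0.5))
        p = ss.predict_binary(m, rng.standard_normal((50, 2)) * 3)
        assert np.all((p > 0.0) & (p < 1.0))

    def test_zero_score_gives_half(self):
        m = BinarySparseModel(
            relevance_vectors=np.zeros((1, 2)),
            weights=np.array([0.0]),
            bias=0.0,
            kernel=ss.KernelSpec("linear"),
            alpha=np.array([1.0]),
            iterations_run=0,
            converged=True,
        )
        assert ss.predict_binary(m, np.array([[3.0, -1.0]]))[0] == pytest.approx(0.5)

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="both classes"):
            ss.rvm_fit_binary(X, np.zeros(10), ss.KernelSpec("linear"))

    def test_non_finite_features_raise(self, rng):
        X, y = blobs(rng, n_per=5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ss.rvm_fit_binary(X, y, ss.KernelSpec("linear"))


def five_blob_dataset(rng, n_per=30, sd=0.4):
    centers = np.array(
        [[0, 4], [4, 0], [-4, 0], [0, -4], [4, 4]], dtype=float
    )
    X, y = [], []
    for stage, c in zip(STAGE_ORDER, centers):
        X.append(rng.normal(c, sd, (n_per, 2)))
        y += [stage] * n_per
    return np.vstack(X), y


class TestOneVsAll:
    def test_five_separated_blobs_high_accuracy(self):
        rng = np.random.default_rng(3)
        X, y = five_blob_dataset(rng)
        Xt, yt = five_blob_dataset(rng)  # fresh draw, same centers
        model = ss.ova_fit(X, y, base="rvm", kernel=ss.KernelSpec("rbf", 0.5))
        pred = ss.ova_predict(model, Xt)
        acc = np.mean([p == t for p, t in zip(pred, yt)])
        assert acc >= 0.95

    def test_tie_breaks_to_first_stage_in_order(self):
        rng = np.random.default_rng(4)
        X, y = five_blob_dataset(rng, n_per=10)
        model = ss.ova_fit(X, y, base="rvm", kernel=ss.KernelSpec("rbf", 0.5))
        # force identical member outputs: all-zero weights -> p = 0.5 each
        for m in model.members.values():
            m.weights = np.zeros_like(m.weights)
            m.bias = 0.0
        assert ss.ova_predict(model, np.zeros((1, 2)))[0] is SleepStage.W

    def test_absent_stage_raises_with_name(self, rng):
        X = rng.standard_normal((20, 2))
        y = [SleepStage.W, SleepStage.N1] * 10  # N2, N3, REM missing
        with pytest.raises(ValueError, match="N3"):
            ss.ova_fit(X, y, base="rvm")

    def test_prediction_invariant_to_test_row_order(self):
        rng = np.random.default_rng(5)
        X, y = five_blob_dataset(rng, n_per=10)
        model = ss.ova_fit(X, y, base="rvm", kernel=ss.KernelSpec("rbf", 0.5))
        Xt = rng.standard_normal((15, 2)) * 3
        perm = rng.permutation(15)
        direct = ss.ova_predict(model, Xt[perm])
        reordered = [ss.ova_predict(model, Xt)[i] for i in perm]
        assert direct == reordered


class TestLda:
    def test_symmetric_two_class_boundary_near_zero(self):
        rng = np.random.default_rng(6)
        X = np.r_[rng.normal(-2, 1, 100), rng.normal(2, 1, 100)][:, None]
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = lda_fit(X, y)
        grid = np.linspace(-3, 3, 1201)[:, None]
        pred = np.array(lda_predict(model, grid))
        boundary = grid[np.argmax(pred == "b"), 0]
        assert abs(boundary) < 0.3

    def test_training_point_gets_own_class_when_separable(self, rng):
        X, y01 = blobs(rng, sep=4.0)
        y = np.where(y01 == 0, "lo", "hi")
        model = lda_fit(X, y)
        assert lda_predict(model, X[:1])[0] == "lo"

    def test_singular_covariance_without_ridge_raises(self, rng):
        X = np.repeat(rng.standard_normal((10, 1)), 3, axis=1)  # rank-1 features
        y = np.array(["a", "b"] * 5)
        with pytest.raises(np.linalg.LinAlgError):
            lda_fit(X, y, ridge=False)
        lda_fit(X, y, ridge=True)  # ridge fallback succeeds

    def test_class_with_one_sample_raises(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            lda_fit(X, y)


class TestKnn:
    def test_k1_returns_nearest_label(self, rng):
        X, y01 = blobs(rng)
        labels = [str(v) for v in y01]
        assert ss.knn_predict(X, labels, X[3:4], k=1)[0] == labels[3]

    def test_k_equals_n_gives_global_majority(self, rng):
        X = rng.standard_normal((20, 2))
        labels = ["a"] * 12 + ["b"] * 8
        pred = ss.knn_predict(X, labels, rng.standard_normal((7, 2)), k=20)
        assert pred == ["a"] * 7

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(7)
        Xtr = rng.standard_normal((60, 4))
        ytr = ["a" if i % 2 else "b" for i in range(60)]
        Xte = rng.standard_normal((25, 4))
        got = ss.knn_predict(Xtr, ytr, Xte, k=13)
        for i, row in enumerate(Xte):
            d = np.array([np.sqrt(np.sum((row - x) ** 2)) for x in Xtr])
            nearest = np.argsort(d, kind="stable")[:13]
            votes = {}
            for j in nearest:
                votes[ytr[j]] = votes.get(ytr[j], 0) + 1
            best = max(votes.values())
            tied = {c for c, v in votes.items() if v == best}
            want = next(ytr[j] for j in nearest if ytr[j] in tied)
            assert got[i] == want

    def test_invalid_k_raises(self, rng):
        X, y01 = blobs(rng, n_per=5)
        with pytest.raises(ValueError):
            ss.knn_predict(X, list(y01), X, k=11)
        with pytest.raises(ValueError):
            ss.knn_predict(X, list(y01), X, k=0)


class TestStandardizerInvariance:
    def test_feature_rescaling_leaves_predictions_unchanged(self):
        """Consistent rescaling of a feature column is absorbed by z-scoring."""
        rng = np.random.default_rng(8)
        X, y = five_blob_dataset(rng, n_per=15)
        Xt = rng.standard_normal((10, 2)) * 3
        scale = np.array([100.0, 0.01])
        for kind in ("knn", "lda"):
            a = ss.SleepStageClassifier(kind).fit(X, y).predict(Xt)
            b = ss.SleepStageClassifier(kind).fit(X * scale, y).predict(Xt * scale)
            assert a == b

    def test_constant_feature_passes_through(self, rng):
        X = np.c_[rng.standard_normal(10), np.full(10, 3.0)]
        std = FeatureStandardizer.fit(X)
        assert np.all(np.isfinite(std.transform(X)))


class TestSerialization:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(9)
        X, y = five_blob_dataset(rng, n_per=12)
        model = ss.ova_fit(X, y, base="rvm", kernel=ss.KernelSpec("rbf", 0.5))
        path = tmp_path / "model.json"
        ss.save_model(model, path)
        back = ss.load_model(path)
        Xt = rng.standard_normal((20, 2)) * 3
        assert ss.ova_predict(model, Xt) == ss.ova_predict(back, Xt)
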