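"""Fisher criteria, agreement metrics, PCA and LOSO mechanics."""

import math

import numpy as np
import pytest

import somnoscore as ss
from somnoscore.evaluation import ConfusionMatrix, scatter_matrices
from somnoscore.io import STAGE_ORDER, SleepStage


def brute_force_scatter(X, y):
    """Double-loop scatter matrices, independent of the vectorized path."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    m = X.mean(axis=0)
    d = X.shape[1]
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for c in set(y.tolist()):
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        Sb += len(Xc) * np.outer(mc - m, mc - m)
        for x in Xc:
            Sw += np.outer(x - mc, x - mc)
    return Sb, Sw


class TestFisherCriteria:
    def test_identical_class_means_give_zero(self, rng):
        base = rng.standard_normal((40, 3))
        X = np.vstack([base, base])  # both classes share every point
        y = np.array([0] * 40 + [1] * 40)
        scores = ss.fisher_criteria(X, y)
        assert scores.J1 == pytest.approx(0.0, abs=1e-12)
        assert scores.J2 == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_1d_example(self):
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array(["A", "A", "B", "B"])
        scores = ss.fisher_criteria(X, y)
        assert scores.J1 == pytest.approx(4.0)  # Sb=16, Sw=4
        assert scores.J2 == pytest.approx(4.0)

    def test_j2_invariant_under_invertible_linear_map(self):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(c, 1.0, (20, 4)) for c in (0.0, 2.0, -1.5)])
        y = np.repeat([0, 1, 2], 20)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        a = ss.fisher_criteria(X, y)
        b = ss.fisher_criteria(X @ A, y)
        assert b.J2 == pytest.approx(a.J2, abs=1e-8 * max(1, a.J2))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(22)
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 3, 30)
        while len(set(y.tolist())) < 3 or min(np.bincount(y)) < 2:
            y = rng.integers(0, 3, 30)
        Sb, Sw = scatter_matrices(X, y)
        Sb2, Sw2 = brute_force_scatter(X, y)
        np.testing.assert_allclose(Sb, Sb2, atol=1e-9)
        np.testing.assert_allclose(Sw, Sw2, atol=1e-9)
        scores = ss.fisher_criteria(X, y)
        assert scores.J1 == pytest.approx(np.trace(Sb2) / np.trace(Sw2), abs=1e-9)
        assert scores.J2 == pytest.approx(
            np.trace(np.linalg.inv(Sw2) @ Sb2), abs=1e-9
        )

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            ss.fisher_criteria(rng.standard_normal((10, 2)), np.zeros(10))


def cm_from_2x2(a, b, c, d):
    """Embed a 2-class count table into the 5-stage matrix (W vs N1)."""
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1] = a, b, c, d
    return ConfusionMatrix(counts)


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        stages = [s for s in STAGE_ORDER for _ in range(3)]
        cm = ss.confusion_matrix(stages, stages)
        assert np.all(cm.counts == 3 * np.eye(5))
        assert ss.overall_accuracy(cm) == 1.0
        assert ss.cohen_kappa(cm) == pytest.approx(1.0)

    def test_single_epoch_placement(self):
        cm = ss.confusion_matrix([SleepStage.W], [SleepStage.N2])
        assert cm.counts[0, 2] == 1
        assert cm.total == 1

    def test_additivity_over_concatenation(self, rng):
        t1 = [list(STAGE_ORDER)[i] for i in rng.integers(0, 5, 30)]
        p1 = [list(STAGE_ORDER)[i] for i in rng.integers(0, 5, 30)]
        t2 = [list(STAGE_ORDER)[i] for i in rng.integers(0, 5, 20)]
        p2 = [list(STAGE_ORDER)[i] for i in rng.integers(0, 5, 20)]
        lhs = ss.confusion_matrix(t1 + t2, p1 + p2)
        rhs = ss.confusion_matrix(t1, p1) + ss.confusion_matrix(t2, p2)
        assert np.array_equal(lhs.counts, rhs.counts)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ss.confusion_matrix([SleepStage.W], [])


class TestAgreementMetrics:
    def test_two_class_fixture_accuracy_and_sensitivity(self):
        cm = cm_from_2x2(45, 5, 15, 35)
        assert ss.overall_accuracy(cm) == pytest.approx(0.80)
        sens = ss.per_class_sensitivity(cm)
        assert sens[SleepStage.W] == pytest.approx(0.90)
        assert sens[SleepStage.N1] == pytest.approx(0.70)

    def test_two_class_fixture_kappa(self):
        cm = cm_from_2x2(45, 5, 15, 35)  # p_o = 0.8, p_e = 0.5
        assert ss.cohen_kappa(cm) == pytest.approx(0.6)

    def test_constant_predictor_gets_zero_kappa(self):
        cm = cm_from_2x2(50, 0, 50, 0)  # everything predicted W
        assert ss.cohen_kappa(cm) == pytest.approx(0.0)

    def test_empty_truth_row_sensitivity_is_missing(self):
        cm = cm_from_2x2(45, 5, 15, 35)
        sens = ss.per_class_sensitivity(cm)
        assert math.isnan(sens[SleepStage.REM])
        assert sens[SleepStage.W] == pytest.approx(0.9)

    def test_kappa_never_exceeds_accuracy(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            cm = ConfusionMatrix(rng.integers(0, 30, (5, 5)))
            if cm.total == 0:
                continue
            kappa = ss.cohen_kappa(cm)
            if not math.isnan(kappa):
                assert kappa <= ss.overall_accuracy(cm) + 1e-12

    def test_degenerate_single_cell_kappa_missing(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[2, 2] = 17
        assert math.isnan(ss.cohen_kappa(ConfusionMatrix(counts)))

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            ss.overall_accuracy(ConfusionMatrix(np.zeros((5, 5), dtype=int)))

    def test_kappa_matches_sklearn_on_random_labelings(self, rng):
        from sklearn.metrics import cohen_kappa_score

        t = [list(STAGE_ORDER)[i] for i in rng.integers(0, 5, 200)]
        p = [list(STAGE_ORDER)[i] for i in rng.integers(0, 5, 200)]
        ours = ss.cohen_kappa(ss.confusion_matrix(t, p))
        theirs = cohen_kappa_score([s.value for s in t], [s.value for s in p])
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestPca:
    def test_line_in_3d_explained_by_first_component(self, rng):
        t = rng.standard_normal(50)
        X = np.outer(t, [1.0, 2.0, -1.0]) + 1e-6 * rng.standard_normal((50, 3))
        _, evr = ss.pca_project(X)
        assert evr[0] >= 0.999

    def test_rank2_pairwise_distances_preserved(self, rng):
        scores_true = rng.standard_normal((40, 2))
        basis = np.linalg.qr(rng.standard_normal((5, 2)))[0]
        X = scores_true @ basis.T
        proj, _ = ss.pca_project(X)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(proj), pdist(scores_true), atol=1e-8)

    def test_score_columns_uncorrelated(self, rng):
        X = rng.standard_normal((60, 6))
        proj, _ = ss.pca_project(X)
        r = np.corrcoef(proj[:, 0], proj[:, 1])[0, 1]
        assert abs(r) < 1e-8

    def test_constant_data_raises(self):
        with pytest.raises(ValueError):
            ss.pca_project(np.ones((10, 3)))


def make_feature_dataset(rng, n_subjects=3, n_epochs=60):
    """Cheap stand-in dataset: Gaussian stage clusters, no signal synthesis."""
    centers = {s: rng.normal(0, 3, 4) for s in STAGE_ORDER}
    ds = {}
    for i in range(n_subjects):
        stages = [list(STAGE_ORDER)[j % 5] for j in range(n_epochs)]
        X = np.vstack([centers[s] + rng.normal(0, 0.8, 4) for s in stages])
        ds[f"S{i:02d}"] = (X, stages)
    return ds


class TestLoso:
    def test_each_subject_tested_exactly_once(self, rng):
        ds = make_feature_dataset(rng)
        report = ss.loso_evaluate(ds, lambda: ss.SleepStageClassifier("lda"))
        assert sorted(report.per_subject) == sorted(ds)
        assert report.pooled_confusion.total == 3 * 60

    def test_own_labels_do_not_influence_predictions(self, rng):
        ds = make_feature_dataset(rng)
        rep1 = ss.loso_evaluate(
            ds, lambda: ss.SleepStageClassifier("lda"), keep_predictions=True
        )
        X0, y0 = ds["S00"]
        shuffled = list(y0)
        shuffled = shuffled[1:] + shuffled[:1]
        ds2 = dict(ds)
        ds2["S00"] = (X0, shuffled)
        rep2 = ss.loso_evaluate(
            ds2, lambda: ss.SleepStageClassifier("lda"), keep_predictions=True
        )
        assert rep1.per_subject["S00"].predictions == rep2.per_subject["S00"].predictions

    def test_missing_stage_in_training_fold_names_both(self, rng):
        ds = make_feature_dataset(rng, n_subjects=2)
        X1, y1 = ds["S01"]
        ds["S01"] = (X1, [SleepStage.W] * len(y1))  # S00's fold lacks 4 stages
        with pytest.raises(ValueError, match="S00") as exc:
            ss.loso_evaluate(ds, lambda: ss.SleepStageClassifier("lda"))
        assert "N1" in str(exc.value)

    def test_unknown_epochs_excluded(self, rng):
        ds = make_feature_dataset(rng)
        X0, y0 = ds["S00"]
        y0 = list(y0)
        y0[0] = SleepStage.UNKNOWN
        ds["S00"] = (X0, y0)
        report = ss.loso_evaluate(ds, lambda: ss.SleepStageClassifier("lda"))
        assert report.per_subject["S00"].confusion.total == 59

    def test_report_serializes_to_json(self, rng, tmp_path):
        ds = make_feature_dataset(rng)
        report = ss.loso_evaluate(ds, lambda: ss.SleepStageClassifier("lda"))
        path = tmp_path / "report.json"
        report.save_json(path)
        import json

        data = json.loads(path.read_text())
        assert set(data["per_subject"]) == set(ds)
        assert data["mean_accuracy"] == pytest.approx(report.mean_accuracy)
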