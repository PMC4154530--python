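"""Separability, agreement and leave-one-subject-out evaluation.

Feature-set separability is measured with the two Fisher criteria
J1 = tr(S_b)/tr(S_w) and J2 = tr(S_w^-1 S_b), where S_b and S_w are the
between- and within-class scatter matrices; larger values mean better
class separation. Classifier-vs-expert agreement uses the overall
accuracy, per-stage sensitivity and Cohen's kappa computed from a 5x5
confusion matrix (rows = expert stage, columns = predicted stage).
Generalization across people is estimated by leave-one-subject-out (LOSO)
cross-validation: each subject is scored by a model trained only on the
other subjects, and results are reported both per subject (mean +/- SD)
and pooled over epochs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .classifiers import SleepStageClassifier
from .io import STAGE_ORDER, SleepStage


@dataclass(frozen=True)
class FisherScores:
    J1: float
    J2: float


def scatter_matrices(X: np.ndarray, y) -> tuple[np.ndarray, np.ndarray]:
    """Between-class (S_b) and within-class (S_w) scatter matrices.

    S_b = sum_c n_c (m_c - m)(m_c - m)^T;
    S_w = sum_c sum_{i in c} (x_i - m_c)(x_i - m_c)^T.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = [c for c in dict.fromkeys(y.tolist())]
    if len(classes) < 2:
        raise ValueError("fisher criteria need at least 2 classes")
    m = X.mean(axis=0)
    d = X.shape[1]
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mc = Xc.mean(axis=0)
        diff = (mc - m)[:, None]
        Sb += Xc.shape[0] * (diff @ diff.T)
        Sw += (Xc - mc).T @ (Xc - mc)
    return Sb, Sw


def fisher_criteria(X: np.ndarray, y, ridge: bool = True) -> FisherScores:
    """J1 = tr(S_b)/tr(S_w), J2 = tr(S_w^-1 S_b).

    When S_w is near-singular, J2 falls back to a ridge-stabilized inverse
    (1e-9 * trace on the diagonal) unless ``ridge`` is disabled.
    """
    Sb, Sw = scatter_matrices(X, y)
    tr_w = float(np.trace(Sw))
    if tr_w <= 0:
        raise ValueError("within-class scatter has non-positive trace")
    j1 = float(np.trace(Sb)) / tr_w
    d = Sw.shape[0]
    if np.linalg.cond(Sw) > 1e12:
        if not ridge:
            raise np.linalg.LinAlgError("within-class scatter is singular")
        Sw = Sw + (1e-9 * tr_w / d) * np.eye(d)
    j2 = float(np.trace(np.linalg.solve(Sw, Sb)))
    return FisherScores(J1=j1, J2=j2)


def feature_set_separability(
    dataset: dict[str, tuple[np.ndarray, list[SleepStage]]]
) -> FisherScores:
    """Fisher criteria of a pooled per-subject feature dataset.

    Features are z-scored first, because the classifier consumes
    standardized features and J1 (a trace ratio) is otherwise dominated by
    whichever features happen to have the largest absolute variance; J2 is
    affine-invariant and unaffected by the standardization.
    """
    X = np.vstack([dataset[s][0] for s in dataset])
    y = np.array(
        [stage.value for s in dataset for stage in dataset[s][1]]
    )
    keep = y != SleepStage.UNKNOWN.value
    X, y = X[keep], y[keep]
    sd = X.std(axis=0)
    Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return fisher_criteria(Xz, y)


# ---------------------------------------------------------------------------
# Confusion matrix and agreement metrics


@dataclass
class ConfusionMatrix:
    """5x5 counts; rows = expert (truth) stage, columns = predicted stage."""

    counts: np.ndarray
    class_order: tuple[SleepStage, ...] = STAGE_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_order != other.class_order:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.class_order)


def confusion_matrix(truth, predicted) -> ConfusionMatrix:
    truth = [SleepStage(t) for t in truth]
    predicted = [SleepStage(p) for p in predicted]
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted lengths differ")
    index = {s: i for i, s in enumerate(STAGE_ORDER)}
    counts = np.zeros((len(STAGE_ORDER), len(STAGE_ORDER)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"label outside the 5-stage set: {t}, {p}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def per_class_sensitivity(cm: ConfusionMatrix) -> dict[SleepStage, float]:
    """Recall per stage; a stage never seen in truth is reported as NaN."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    out: dict[SleepStage, float] = {}
    row_totals = cm.counts.sum(axis=1)
    for i, stage in enumerate(cm.class_order):
        out[stage] = (
            float(cm.counts[i, i]) / row_totals[i] if row_totals[i] > 0 else math.nan
        )
    return out


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace/total), p_e the agreement expected
    by chance from the marginals. Degenerate p_e = 1 returns NaN.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / n
    rows = cm.counts.sum(axis=1) / n
    cols = cm.counts.sum(axis=0) / n
    p_e = float(rows @ cols)
    if abs(1.0 - p_e) < 1e-15:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# PCA projection (for 2-D feature scatter plots)


def pca_project(X: np.ndarray, n_components: int = 2):
    """Mean-centered projection onto the top-variance directions.

    Returns (scores, explained_variance_ratio). Component signs are fixed by
    making each loading vector's largest-magnitude entry positive, so plots
    are reproducible across runs and platforms.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 2 or d < n_components:
        raise ValueError("need n >= 2 rows and d >= n_components features")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant data has no principal components")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xc)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores, pca.explained_variance_ratio_.copy()


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation


@dataclass
class SubjectResult:
    subject_id: str
    accuracy: float
    kappa: float
    sensitivity: dict[SleepStage, float]
    confusion: ConfusionMatrix
    predictions: list[SleepStage] = field(default_factory=list)


@dataclass
class EvaluationReport:
    per_subject: dict[str, SubjectResult]
    mean_accuracy: float
    sd_accuracy: float
    mean_kappa: float
    sd_kappa: float
    pooled_confusion: ConfusionMatrix

    @property
    def pooled_accuracy(self) -> float:
        return overall_accuracy(self.pooled_confusion)

    @property
    def pooled_kappa(self) -> float:
        return cohen_kappa(self.pooled_confusion)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_kappa": self.mean_kappa,
            "sd_kappa": self.sd_kappa,
            "pooled_accuracy": self.pooled_accuracy,
            "pooled_kappa": self.pooled_kappa,
            "pooled_confusion": self.pooled_confusion.counts.tolist(),
            "class_order": [s.value for s in STAGE_ORDER],
            "per_subject": {
                sid: {
                    "accuracy": r.accuracy,
                    "kappa": r.kappa,
                    "sensitivity": {
                        s.value: (None if math.isnan(v) else v)
                        for s, v in r.sensitivity.items()
                    },
                    "confusion": r.confusion.counts.tolist(),
                }
                for sid, r in self.per_subject.items()
            },
        }

    def save_json(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def loso_evaluate(
    dataset: dict[str, tuple[np.ndarray, list[SleepStage]]],
    classifier_factory,
    keep_predictions: bool = False,
) -> EvaluationReport:
    """Leave-one-subject-out cross-validation over a per-subject dataset.

    ``dataset`` maps subject_id -> (feature matrix, stage labels);
    ``classifier_factory`` builds a fresh :class:`SleepStageClassifier`
    (or anything with fit/predict) per fold, so no training state leaks
    between folds. Standardization and fitting see only the n-1 training
    subjects. Epochs labeled UNKNOWN are excluded everywhere. A training
    fold missing a stage raises, naming the stage and the held-out subject.
    """
    subjects = list(dataset.keys())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")

    clean: dict[str, tuple[np.ndarray, list[SleepStage]]] = {}
    for sid, (X, y) in dataset.items():
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = [SleepStage(s) for s in y]
        keep = [i for i, s in enumerate(y) if s != SleepStage.UNKNOWN]
        clean[sid] = (X[keep], [y[i] for i in keep])

    results: dict[str, SubjectResult] = {}
    pooled = ConfusionMatrix(np.zeros((5, 5), dtype=int))
    for test_sid in subjects:
        X_tr = np.vstack([clean[s][0] for s in subjects if s != test_sid])
        y_tr = [lbl for s in subjects if s != test_sid for lbl in clean[s][1]]
        missing = [s.value for s in STAGE_ORDER if s not in set(y_tr)]
        if missing:
            raise ValueError(
                f"training fold for held-out subject {test_sid!r} lacks "
                f"stage(s) {missing}"
            )
        X_te, y_te = clean[test_sid]
        clf = classifier_factory()
        clf.fit(X_tr, y_tr)
        pred = clf.predict(X_te)
        cm = confusion_matrix(y_te, pred)
        results[test_sid] = SubjectResult(
            subject_id=test_sid,
            accuracy=overall_accuracy(cm),
            kappa=cohen_kappa(cm),
            sensitivity=per_class_sensitivity(cm),
            confusion=cm,
            predictions=list(pred) if keep_predictions else [],
        )
        pooled = pooled + cm

    accs = np.array([r.accuracy for r in results.values()])
    kaps = np.array([r.kappa for r in results.values()])
    return EvaluationReport(
        per_subject=results,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        mean_kappa=float(np.nanmean(kaps)),
        sd_kappa=float(np.nanstd(kaps, ddof=1)) if kaps.size > 1 else 0.0,
        pooled_confusion=pooled,
    )
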