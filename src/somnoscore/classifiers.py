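"""Sparse Bayesian (relevance vector machine) classification and baselines.

The RVM here is the classification variant of sparse Bayesian learning: a
kernel expansion y(x) = sigma(sum_i w_i K(x, x_i) + b) with an independent
zero-mean Gaussian prior of precision alpha_i on each weight. Training
alternates (a) finding the posterior mode of the weights under a Bernoulli
likelihood by iteratively reweighted least squares (Laplace approximation)
with (b) type-II maximum-likelihood re-estimation of the precisions,
alpha_i <- gamma_i / mu_i^2 where gamma_i = 1 - alpha_i * Sigma_ii. Most
alpha_i diverge, their basis functions are pruned, and the few surviving
training points are the relevance vectors. Unlike an SVM there is no
penalty parameter to cross-validate — the per-weight regularization is
estimated from the data — and the output is a genuine class probability.

Multiclass staging uses a one-against-all ensemble over the fixed stage
order (W, N1, N2, N3, REM). LDA and k-NN baselines sit behind the same
fit/predict interface; an SVM (scikit-learn's SVC, C = 50) is admitted for
comparison, since the contribution under study is the RVM side.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .io import STAGE_ORDER, SleepStage


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family: 'linear' (X @ Z.T) or 'rbf' (exp(-gamma * ||x-z||^2))."""

    kind: str = "linear"
    rbf_gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError("kernel kind must be 'linear' or 'rbf'")
        if self.kind == "rbf" and not self.rbf_gamma > 0:
            raise ValueError("rbf_gamma must be positive")


def kernel_matrix(X: np.ndarray, Z: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = k(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} features, Z has {Z.shape[1]}"
        )
    if kernel.kind == "linear":
        return X @ Z.T
    sq = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(Z * Z, axis=1)[None, :]
        - 2.0 * (X @ Z.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-kernel.rbf_gamma * sq)


@dataclass
class BinarySparseModel:
    """A trained binary RVM: the retained relevance vectors and weights."""

    relevance_vectors: np.ndarray  # (r, d)
    weights: np.ndarray            # (r,)
    bias: float
    kernel: KernelSpec
    alpha: np.ndarray              # (r,) retained precisions
    iterations_run: int
    converged: bool

    @property
    def n_relevance_vectors(self) -> int:
        return int(self.relevance_vectors.shape[0])


def _laplace_posterior(
    Phi: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    w0: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-6,
):
    """Posterior mode and covariance of the weights (IRLS / Newton).

    Maximizes the Bernoulli log-likelihood minus the Gaussian prior penalty
    0.5 * sum(alpha_i w_i^2); steps are halved when the penalized likelihood
    decreases. Returns (w_mode, Sigma, cholesky-ok flag).
    """
    w = w0.copy()

    def objective(wv: np.ndarray) -> float:
        s = np.clip(Phi @ wv, -500, 500)
        # log-likelihood written to avoid log(0): log sigma(s)=-log1p(exp(-s))
        ll = -np.sum(np.logaddexp(0.0, -s[y == 1])) - np.sum(
            np.logaddexp(0.0, s[y == 0])
        )
        return ll - 0.5 * np.sum(alpha * wv * wv)

    obj = objective(w)
    H_chol = None
    for _ in range(max_iter):
        s = np.clip(Phi @ w, -500, 500)
        p = expit(s)
        g = Phi.T @ (y - p) - alpha * w
        b = np.maximum(p * (1.0 - p), 1e-12)
        H = (Phi * b[:, None]).T @ Phi
        H[np.diag_indices_from(H)] += alpha
        try:
            H_chol = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-8 * np.trace(H) / H.shape[0]
            H_chol = cho_factor(H, lower=True)
        step = cho_solve(H_chol, g)
        # backtracking line search on the penalized likelihood
        lam, new_obj = 1.0, objective(w + step)
        while new_obj < obj and lam > 1e-4:
            lam *= 0.5
            new_obj = objective(w + lam * step)
        if new_obj < obj:
            break
        w = w + lam * step
        if new_obj - obj < tol * (1.0 + abs(obj)):
            obj = new_obj
            break
        obj = new_obj
    # covariance at the final mode
    s = np.clip(Phi @ w, -500, 500)
    p = expit(s)
    b = np.maximum(p * (1.0 - p), 1e-12)
    H = (Phi * b[:, None]).T @ Phi
    H[np.diag_indices_from(H)] += alpha
    try:
        H_chol = cho_factor(H, lower=True)
    except np.linalg.LinAlgError:
        H[np.diag_indices_from(H)] += 1e-8 * np.trace(H) / H.shape[0]
        H_chol = cho_factor(H, lower=True)
    Sigma = cho_solve(H_chol, np.eye(H.shape[0]))
    return w, Sigma


def rvm_fit_binary(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    max_iter: int = 20000,
    tol: float = 1e-3,
    prune_threshold: float = 1e9,
    alpha_init: float = 1e-2,
    irls_max_iter: int = 25,
) -> BinarySparseModel:
    """Train a binary RVM on labels in {0, 1}.

    Basis functions whose precision alpha exceeds ``prune_threshold`` are
    removed permanently; iteration stops at ``max_iter`` or when
    max |delta log alpha| < ``tol``. Non-convergence is recorded in the
    returned model's metadata rather than raised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be in {0, 1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training data")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features in training data")
    n = X.shape[0]

    # design matrix: column 0 is the bias, column j+1 the kernel at x_j
    Phi_full = np.empty((n, n + 1))
    Phi_full[:, 0] = 1.0
    Phi_full[:, 1:] = kernel_matrix(X, X, kernel)

    active = np.arange(n + 1)
    alpha_active = np.full(n + 1, float(alpha_init))
    w = np.zeros(n + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Phi = Phi_full[:, active]
        w, Sigma = _laplace_posterior(Phi, y, alpha_active, w, max_iter=irls_max_iter)
        gamma = 1.0 - alpha_active * np.diag(Sigma)
        gamma = np.clip(gamma, 1e-12, None)
        new_alpha = gamma / np.maximum(w * w, 1e-300)
        delta = np.abs(np.log(new_alpha) - np.log(alpha_active))
        alpha_active = new_alpha
        keep = alpha_active < prune_threshold
        if not np.any(keep):  # degenerate: retain the most relevant basis
            keep[int(np.argmin(alpha_active))] = True
        # convergence is judged on the surviving basis only; pruned alphas
        # have diverged by design and never re-enter
        if np.max(delta[keep]) < tol and np.all(keep):
            converged = True
            break
        active = active[keep]
        alpha_active = alpha_active[keep]
        w = w[keep]

    # final posterior mode on the surviving basis
    Phi = Phi_full[:, active]
    w, _ = _laplace_posterior(Phi, y, alpha_active, w, max_iter=irls_max_iter)

    has_bias = active[0] == 0
    rv_idx = active[1:] - 1 if has_bias else active - 1
    weights = w[1:] if has_bias else w
    bias = float(w[0]) if has_bias else 0.0
    alphas = alpha_active[1:] if has_bias else alpha_active
    if rv_idx.size == 0:
        # keep at least one relevance vector so the model is well-formed
        rv_idx = np.array([int(np.argmax(np.abs(Phi_full[:, 1:].T @ (y - 0.5))))])
        weights = np.array([0.0])
        alphas = np.array([np.inf])
    return BinarySparseModel(
        relevance_vectors=X[rv_idx].copy(),
        weights=np.asarray(weights, dtype=float),
        bias=bias,
        kernel=kernel,
        alpha=np.asarray(alphas, dtype=float),
        iterations_run=it,
        converged=converged,
    )


def predict_binary(model: BinarySparseModel, X: np.ndarray) -> np.ndarray:
    """Class-1 probability sigma(K(X, RVs) @ w + b) for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = kernel_matrix(X, model.relevance_vectors, model.kernel)
    return expit(K @ model.weights + model.bias)


# ---------------------------------------------------------------------------
# Feature standardization (the "Normalization" stage before the classifier)


@dataclass
class FeatureStandardizer:
    """Per-feature z-scoring with training-set mean/SD only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureStandardizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant features pass through
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.mean) / self.sd


# ---------------------------------------------------------------------------
# One-against-all multiclass wrapper


@dataclass
class MulticlassModel:
    """One binary scorer per sleep stage; prediction is the argmax score.

    Ties are broken by the fixed class order (first wins). The feature
    standardizer is fit on training data only and applied to test data.
    """

    class_order: tuple[SleepStage, ...]
    members: dict[SleepStage, object]
    feature_standardizer: FeatureStandardizer
    base: str = "rvm"


def _binary_fit(base: str, X: np.ndarray, y01: np.ndarray, kernel: KernelSpec, **kw):
    if base == "rvm":
        return rvm_fit_binary(X, y01, kernel=kernel, **kw)
    if base == "svm":
        from sklearn.svm import SVC

        params = dict(C=kw.get("C", 50.0))
        if kernel.kind == "rbf":
            clf = SVC(kernel="rbf", gamma=kernel.rbf_gamma, **params)
        else:
            clf = SVC(kernel="linear", **params)
        clf.fit(X, y01)
        return clf
    raise ValueError(f"unknown one-vs-all base classifier {base!r}")


def _binary_score(base: str, model, X: np.ndarray) -> np.ndarray:
    if base == "rvm":
        return predict_binary(model, X)
    return model.decision_function(X)  # SVC margin, monotone ranking score


def ova_fit(
    X: np.ndarray,
    y: list[SleepStage],
    base: str = "rvm",
    kernel: KernelSpec = KernelSpec(),
    standardize: bool = True,
    **kwargs,
) -> MulticlassModel:
    """Fit one stage-vs-rest binary model per stage in the fixed order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = [SleepStage(s) for s in y]
    present = set(y)
    absent = [s.value for s in STAGE_ORDER if s not in present]
    if absent:
        raise ValueError(f"stage(s) absent from training data: {absent}")
    std = (
        FeatureStandardizer.fit(X)
        if standardize
        else FeatureStandardizer(np.zeros(X.shape[1]), np.ones(X.shape[1]))
    )
    Xs = std.transform(X)
    members: dict[SleepStage, object] = {}
    for stage in STAGE_ORDER:
        y01 = np.array([1.0 if s == stage else 0.0 for s in y])
        members[stage] = _binary_fit(base, Xs, y01, kernel, **kwargs)
    return MulticlassModel(
        class_order=STAGE_ORDER, members=members, feature_standardizer=std, base=base
    )


def ova_decision_scores(model: MulticlassModel, X: np.ndarray) -> np.ndarray:
    """Per-stage scores, columns in class order (probabilities for RVM)."""
    Xs = model.feature_standardizer.transform(X)
    return np.column_stack(
        [_binary_score(model.base, model.members[s], Xs) for s in model.class_order]
    )


def ova_predict(model: MulticlassModel, X: np.ndarray) -> list[SleepStage]:
    scores = ova_decision_scores(model, X)
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum: tie rule
    return [model.class_order[i] for i in idx]


# ---------------------------------------------------------------------------
# Baselines: LDA and k-NN


@dataclass
class LDAModel:
    classes: list
    means: np.ndarray        # (c, d)
    cov_inv: np.ndarray      # (d, d) pooled within-class inverse
    log_priors: np.ndarray   # (c,)


def lda_fit(X: np.ndarray, y, ridge: bool = True) -> LDAModel:
    """Linear discriminant analysis: Gaussian classes, shared covariance.

    The pooled within-class covariance is ridge-stabilized with
    1e-6 * trace(S)/d on the diagonal when near-singular (or always refused
    with ``ridge=False``, in which case singularity raises).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = sorted(set(y.tolist()), key=lambda s: str(s))
    n, d = X.shape
    means, priors, S = [], [], np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        m = Xc.mean(axis=0)
        means.append(m)
        priors.append(Xc.shape[0] / n)
        S += (Xc - m).T @ (Xc - m)
    S /= n - len(classes)
    singular = np.linalg.cond(S) > 1e12 if np.all(np.isfinite(S)) else True
    if singular:
        if not ridge:
            raise np.linalg.LinAlgError(
                "pooled within-class covariance is singular (ridge disabled)"
            )
        S = S + (1e-6 * np.trace(S) / d) * np.eye(d)
    cov_inv = np.linalg.inv(S)
    return LDAModel(
        classes=classes,
        means=np.array(means),
        cov_inv=cov_inv,
        log_priors=np.log(np.array(priors)),
    )


def lda_predict(model: LDAModel, X: np.ndarray) -> list:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = model.cov_inv @ model.means.T                      # (d, c)
    lin = X @ A                                            # (n, c)
    const = -0.5 * np.sum(model.means * A.T, axis=1) + model.log_priors
    idx = np.argmax(lin + const, axis=1)
    return [model.classes[i] for i in idx]


def knn_predict(
    X_train: np.ndarray, y_train, X_test: np.ndarray, k: int = 13
) -> list:
    """k-nearest-neighbor vote with Euclidean distance.

    Vote ties are broken by the nearest neighbor among the tied classes
    (not by class order), so k need not be odd.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = list(y_train)
    n = X_train.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n_train ({n}), got {k}")
    from scipy.spatial.distance import cdist

    D = cdist(X_test, X_train)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    out = []
    for row in order:
        votes: dict = {}
        for j in row:
            votes[y_train[j]] = votes.get(y_train[j], 0) + 1
        best = max(votes.values())
        tied = {c for c, v in votes.items() if v == best}
        if len(tied) == 1:
            out.append(tied.pop())
        else:
            out.append(next(y_train[j] for j in row if y_train[j] in tied))
    return out


# ---------------------------------------------------------------------------
# Unified classifier front-end used by LOSO evaluation and the CLI


class SleepStageClassifier:
    """fit/predict facade over the one-vs-all kernel models and baselines.

    ``kind``: 'rvm' | 'svm' (one-against-all kernel classifiers),
    'lda' | 'knn' (direct multiclass baselines). All kinds standardize
    features with training-set statistics.
    """

    def __init__(
        self,
        kind: str = "rvm",
        kernel: KernelSpec = KernelSpec(),
        k: int = 13,
        C: float = 50.0,
        **rvm_kwargs,
    ) -> None:
        if kind not in ("rvm", "svm", "lda", "knn"):
            raise ValueError(f"unknown classifier kind {kind!r}")
        self.kind = kind
        self.kernel = kernel
        self.k = k
        self.C = C
        self.rvm_kwargs = rvm_kwargs
        self._model = None
        self._std: FeatureStandardizer | None = None
        self._train: tuple[np.ndarray, list] | None = None

    def fit(self, X: np.ndarray, y) -> "SleepStageClassifier":
        y = [SleepStage(s) for s in y]
        if self.kind in ("rvm", "svm"):
            kw = dict(self.rvm_kwargs)
            if self.kind == "svm":
                kw = {"C": self.C}
            self._model = ova_fit(X, y, base=self.kind, kernel=self.kernel, **kw)
        else:
            self._std = FeatureStandardizer.fit(np.atleast_2d(np.asarray(X, float)))
            Xs = self._std.transform(X)
            if self.kind == "lda":
                self._model = lda_fit(Xs, np.array([s.value for s in y]))
            else:
                self._train = (Xs, [s.value for s in y])
        return self

    def predict(self, X: np.ndarray) -> list[SleepStage]:
        if self.kind in ("rvm", "svm"):
            return ova_predict(self._model, X)
        Xs = self._std.transform(X)
        if self.kind == "lda":
            labels = lda_predict(self._model, Xs)
        else:
            Xtr, ytr = self._train
            labels = knn_predict(Xtr, ytr, Xs, k=self.k)
        return [SleepStage(lbl) for lbl in labels]

    @property
    def n_relevance_vectors(self) -> dict[SleepStage, int] | None:
        """Per-stage relevance-vector counts (RVM only)."""
        if self.kind != "rvm" or self._model is None:
            return None
        return {
            s: m.n_relevance_vectors for s, m in self._model.members.items()
        }


# ---------------------------------------------------------------------------
# Serialization (RVM one-vs-all models)


def save_model(model: MulticlassModel, path: str | os.PathLike) -> None:
    """Write a one-vs-all RVM model as a single JSON file."""
    if model.base != "rvm":
        raise ValueError("only RVM one-vs-all models serialize to JSON")
    payload = {
        "base": model.base,
        "class_order": [s.value for s in model.class_order],
        "standardizer": {
            "mean": model.feature_standardizer.mean.tolist(),
            "sd": model.feature_standardizer.sd.tolist(),
        },
        "members": {
            stage.value: {
                "relevance_vectors": m.relevance_vectors.tolist(),
                "weights": m.weights.tolist(),
                "bias": m.bias,
                "alpha": m.alpha.tolist(),
                "kernel": {"kind": m.kernel.kind, "rbf_gamma": m.kernel.rbf_gamma},
                "iterations_run": m.iterations_run,
                "converged": m.converged,
            }
            for stage, m in model.members.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str | os.PathLike) -> MulticlassModel:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    members = {}
    for stage_s, m in payload["members"].items():
        members[SleepStage(stage_s)] = BinarySparseModel(
            relevance_vectors=np.array(m["relevance_vectors"], dtype=float),
            weights=np.array(m["weights"], dtype=float),
            bias=float(m["bias"]),
            kernel=KernelSpec(**m["kernel"]),
            alpha=np.array(m["alpha"], dtype=float),
            iterations_run=int(m["iterations_run"]),
            converged=bool(m["converged"]),
        )
    std = FeatureStandardizer(
        mean=np.array(payload["standardizer"]["mean"], dtype=float),
        sd=np.array(payload["standardizer"]["sd"], dtype=float),
    )
    return MulticlassModel(
        class_order=tuple(SleepStage(s) for s in payload["class_order"]),
        members=members,
        feature_standardizer=std,
        base=payload["base"],
    )
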