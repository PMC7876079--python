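"""SVM and kernel PCA on precomputed kernel matrices, with an evaluation harness.

One kernel matrix feeds both branches of the framework: support vector
machines for phenotype prediction (classification or regression) and
kernel PCA for ordination.  The harness reproduces the replicated
hold-out protocol typical of microbiome prediction studies: repeated
random 80/20 train/test partitions (optionally grouped so related
individuals never straddle the split), hyperparameters tuned by repeated
k-fold cross-validation inside the training portion only, the final
model refit on the whole training set, and the test metric collected
into an error distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import (
    GroupShuffleSplit,
    KFold,
    ShuffleSplit,
    StratifiedKFold,
    StratifiedShuffleSplit,
)
from sklearn.svm import SVC, SVR

from .kernels import KernelMatrix

__all__ = [
    "CVConfig",
    "TrainedModel",
    "EvalReport",
    "svm_train",
    "svm_predict",
    "kpca",
    "accuracy",
    "nmse",
    "replicate_evaluation",
    "permuted_labels",
    "median_heuristic_gamma",
]

_TIE_TOL = 1e-12


def _derive_seed(*entropy: int) -> int:
    """Deterministic 31-bit seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31 - 1))


@dataclass
class CVConfig:
    """Replicated hold-out evaluation settings.

    ``outer_test_fraction`` of the samples form the test set of each of
    ``n_replicates`` random partitions; hyperparameters are tuned by
    ``inner_folds``-fold cross-validation repeated ``inner_repeats``
    times on the training portion.  If ``group_ids`` are given (e.g.
    litters of full sibs), a group is never split across train and test.
    """

    outer_test_fraction: float = 0.2
    n_replicates: int = 40
    inner_folds: int = 5
    inner_repeats: int = 5
    group_ids: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.outer_test_fraction < 1.0):
            raise ValueError("outer_test_fraction must lie in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be at least 2")
        if self.n_replicates < 1 or self.inner_repeats < 1:
            raise ValueError("n_replicates and inner_repeats must be positive")


@dataclass
class TrainedModel:
    """Fitted SVM on a precomputed kernel.

    Stores the dual expansion (support indices relative to the training
    set, signed dual coefficients, intercept) plus provenance so that
    signatures and rectangular-block predictions can be derived later.
    """

    task: str
    estimator: object
    sample_ids: list[str]
    kernel_meta: dict
    cost: float

    @property
    def support_(self) -> np.ndarray:
        return self.estimator.support_

    @property
    def dual_coef_(self) -> np.ndarray:
        return self.estimator.dual_coef_

    @property
    def intercept_(self) -> np.ndarray:
        return self.estimator.intercept_


def svm_train(K_train: KernelMatrix, y, task: str = "classification",
              cost: float = 1.0) -> TrainedModel:
    """Train an SVM (C-SVC or epsilon-SVR) on a precomputed kernel matrix."""
    if task not in ("classification", "regression"):
        raise ValueError(f"task must be 'classification' or 'regression', got {task!r}")
    if not np.isfinite(cost) or cost <= 0:
        raise ValueError(f"cost must be a positive real, got {cost}")
    y = np.asarray(y)
    if y.shape[0] != K_train.n_samples:
        raise ValueError("labels are not aligned with the kernel matrix")
    if task == "classification" and np.unique(y).size < 2:
        raise ValueError("classification needs at least two classes in y")
    est = (SVC(C=cost, kernel="precomputed") if task == "classification"
           else SVR(C=cost, kernel="precomputed"))
    est.fit(K_train.values, y)
    return TrainedModel(task=task, estimator=est,
                        sample_ids=list(K_train.sample_ids),
                        kernel_meta=dict(K_train.meta), cost=float(cost))


def svm_predict(model: TrainedModel, K_test_train: np.ndarray,
                column_ids: Sequence[str] | None = None) -> np.ndarray:
    """Predict from a rectangular (test x train) kernel block.

    Columns must follow the model's training-sample order; pass
    ``column_ids`` to have the alignment verified.
    """
    K_test_train = np.atleast_2d(np.asarray(K_test_train, dtype=float))
    if K_test_train.shape[1] != len(model.sample_ids):
        raise ValueError(
            f"kernel block has {K_test_train.shape[1]} columns but the model was "
            f"trained on {len(model.sample_ids)} samples"
        )
    if column_ids is not None and list(column_ids) != model.sample_ids:
        raise ValueError("kernel block columns are not aligned with training samples")
    return model.estimator.predict(K_test_train)


@dataclass
class KPCAResult:
    projections: np.ndarray  # N x n_components
    eigenvalues: np.ndarray  # decreasing
    sample_ids: list[str]


def kpca(K: KernelMatrix, n_components: int = 2) -> KPCAResult:
    """Kernel principal components analysis of a precomputed kernel matrix.

    Double-centers the matrix, eigendecomposes it and returns the sample
    projections ``u_c * sqrt(lambda_c)`` sorted by decreasing eigenvalue.
    For a linear kernel this reproduces the ordinary PCA scores of the
    underlying features.  Sign convention: the largest-magnitude loading
    of each component is positive.
    """
    n = K.n_samples
    if not (1 <= n_components <= n - 1):
        raise ValueError(f"n_components must lie in [1, N-1] = [1, {n - 1}]")
    values = K.values
    row = values.mean(axis=1, keepdims=True)
    kc = values - row - row.T + values.mean()
    eigvals, eigvecs = np.linalg.eigh(kc)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = int(np.sum(eigvals > max(eigvals[0], 0.0) * 1e-12))
    if n_components > positive:
        warnings.warn(
            f"only {positive} positive eigenvalues; truncating from "
            f"{n_components} requested components",
            UserWarning,
            stacklevel=2,
        )
        n_components = max(positive, 1)
    eigvals = eigvals[:n_components].clip(min=0.0)
    eigvecs = eigvecs[:, :n_components]
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    proj = eigvecs * np.sqrt(eigvals)
    return KPCAResult(projections=proj, eigenvalues=eigvals,
                      sample_ids=list(K.sample_ids))


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return float(np.mean(y_true == y_pred))


def nmse(y_true, y_pred) -> float:
    """Mean squared error normalized by the (population) variance of y_true.

    The trivial mean predictor scores approximately 1; smaller is better.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    var = float(np.var(y_true))
    if var == 0.0:
        raise ValueError("NMSE is undefined for a constant target")
    return float(np.mean((y_true - y_pred) ** 2) / var)


def median_heuristic_gamma(sq_distances: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise squared distance: 1 / median."""
    off = sq_distances[np.triu_indices_from(sq_distances, k=1)]
    med = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
    return 1.0 / med


def _score(task: str, y_true, y_pred) -> float:
    """Higher-is-better internal score (accuracy, or negative NMSE)."""
    return accuracy(y_true, y_pred) if task == "classification" else -nmse(y_true, y_pred)


def _fit_predict(K: np.ndarray, y, tr, va, task: str, cost: float) -> np.ndarray:
    est = SVC(C=cost, kernel="precomputed") if task == "classification" else \
        SVR(C=cost, kernel="precomputed")
    est.fit(K[np.ix_(tr, tr)], y[tr])
    return est.predict(K[np.ix_(va, tr)])


def inner_cv_score(K_train: np.ndarray, y_train: np.ndarray, task: str, cost: float,
                   folds: int, repeats: int, seed: int) -> float:
    """Mean repeated k-fold CV score of an SVM on a (train-only) kernel block."""
    scores = []
    idx = np.arange(len(y_train))
    for r in range(repeats):
        rs = _derive_seed(seed, r)
        if task == "classification":
            splitter = StratifiedKFold(folds, shuffle=True, random_state=rs)
            splits = splitter.split(idx, y_train)
        else:
            splitter = KFold(folds, shuffle=True, random_state=rs)
            splits = splitter.split(idx)
        for tr, va in splits:
            pred = _fit_predict(K_train, y_train, tr, va, task, cost)
            scores.append(_score(task, y_train[va], pred))
    return float(np.mean(scores))


@dataclass
class EvalReport:
    """Replicated hold-out evaluation results.

    ``records`` holds one dict per replicate (test ids, chosen
    hyperparameters, test metric).  ``metric`` is "accuracy" or "nmse".
    """

    task: str
    metric: str
    records: list[dict] = field(default_factory=list)

    @property
    def scores(self) -> np.ndarray:
        return np.array([r["score"] for r in self.records])

    @property
    def median(self) -> float:
        return float(np.median(self.scores))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.scores, [25, 75])
        return float(q3 - q1)

    def as_dict(self) -> dict:
        return {
            "task": self.task,
            "metric": self.metric,
            "median": self.median,
            "iqr": self.iqr,
            "records": self.records,
        }


def permuted_labels(y, seed: int = 0) -> np.ndarray:
    """Random permutation of the labels — the null ("random model") baseline."""
    rng = np.random.default_rng(seed)
    return rng.permutation(np.asarray(y))


def _outer_split(y, groups, test_fraction: float, task: str, seed: int):
    n = len(y)
    if groups is not None:
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction,
                                     random_state=seed)
        return next(splitter.split(np.zeros(n), y, groups=np.asarray(groups)))
    if task == "classification":
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                          random_state=seed)
        return next(splitter.split(np.zeros(n), y))
    splitter = ShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    return next(splitter.split(np.zeros(n)))


def _normalize_kernels(kernels) -> dict:
    if isinstance(kernels, KernelMatrix):
        return {None: kernels}
    if isinstance(kernels, Mapping):
        if not kernels:
            raise ValueError("empty kernel mapping")
        return dict(kernels)
    raise TypeError("kernels must be a KernelMatrix or a {gamma: KernelMatrix} mapping")


def replicate_evaluation(kernels, y, cv: CVConfig,
                         cost_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
                         task: str = "classification",
                         test_one_per_group: bool = False) -> EvalReport:
    """Replicated 80/20 evaluation with inner-CV hyperparameter tuning.

    ``kernels`` is either a single :class:`KernelMatrix` or a mapping
    ``{gamma: KernelMatrix}`` of candidate-bandwidth matrices (gamma is
    then tuned jointly with the SVM cost; matrices are computed once and
    sub-indexed per replicate).  Within each replicate the test block of
    the kernel matrix is touched only at final scoring time.

    ``test_one_per_group`` implements the mixed-time protocol used when a
    per-time-point model is compared against a longitudinal one: the model
    is trained on all training rows but scored on a single randomly chosen
    row per test group (e.g., one time point per individual).
    """
    kernels = _normalize_kernels(kernels)
    first = next(iter(kernels.values()))
    n = first.n_samples
    for Km in kernels.values():
        if Km.sample_ids != first.sample_ids:
            raise ValueError("candidate kernel matrices have mismatched sample_ids")
    y = np.asarray(y)
    if y.shape[0] != n:
        raise ValueError("labels are not aligned with the kernel matrices")
    if task == "classification" and np.unique(y).size < 2:
        raise ValueError("classification needs at least two classes in y")
    if len(cost_grid) == 0:
        raise ValueError("cost_grid must be non-empty")
    groups = None if cv.group_ids is None else np.asarray([str(g) for g in cv.group_ids])
    if groups is not None and groups.shape[0] != n:
        raise ValueError("group_ids are not aligned with the kernel matrices")
    if test_one_per_group and groups is None:
        raise ValueError("test_one_per_group requires group_ids")
    if groups is not None:
        n_groups = np.unique(groups).size
        n_test_groups = int(round(cv.outer_test_fraction * n_groups))
        if n_test_groups < 1 or n_test_groups >= n_groups:
            raise ValueError(
                f"test fraction {cv.outer_test_fraction} is incompatible with "
                f"{n_groups} groups"
            )
    costs = sorted(float(c) for c in cost_grid)
    gammas = sorted(kernels.keys(), key=lambda g: (-np.inf if g is None else float(g)))
    metric = "accuracy" if task == "classification" else "nmse"
    report = EvalReport(task=task, metric=metric)
    for rep in range(cv.n_replicates):
        rep_seed = _derive_seed(cv.seed, rep)
        tr, te = _outer_split(y, groups, cv.outer_test_fraction, task, rep_seed)
        if groups is not None:
            assert not set(groups[tr]) & set(groups[te]), "group leaked across the split"
        if test_one_per_group:
            rng = np.random.default_rng(_derive_seed(cv.seed, rep, 1))
            kept = []
            for g in np.unique(groups[te]):
                members = te[groups[te] == g]
                kept.append(rng.choice(members))
            te = np.sort(np.array(kept))
        # --- tuning: only the train x train block is ever indexed ---
        best = (-np.inf, None, None)
        for gamma in gammas:
            K_tr = kernels[gamma].values[np.ix_(tr, tr)]
            for cost in costs:
                s = inner_cv_score(K_tr, y[tr], task, cost,
                                   cv.inner_folds, cv.inner_repeats, rep_seed)
                if s > best[0] + _TIE_TOL:
                    best = (s, gamma, cost)
        _, gamma, cost = best
        K = kernels[gamma].values
        pred = _fit_predict(K, y, tr, te, task, cost)
        score = accuracy(y[te], pred) if task == "classification" else nmse(y[te], pred)
        report.records.append({
            "replicate": rep,
            "test_ids": [first.sample_ids[i] for i in te],
            "gamma": None if gamma is None else float(gamma),
            "cost": float(cost),
            "inner_score": float(best[0]),
            "score": float(score),
        })
    return report
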