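"""Multi-algorithm calibration, validation schemes and performance metrics.

Regression and classification learners (PLS, k-NN, random forest, SVM) are
evaluated under Venetian-blind k-fold cross-validation or bootstrap
resampling, with pre-processing and PCA compression refitted inside every
fold/iteration so no validation information leaks into the fit.

Classification metrics are computed from the confusion matrix:

* accuracy = trace / total,
* balanced accuracy = mean of per-class recall,
* macro F1 = mean of per-class F1 (harmonic precision/recall mean; a class
  whose denominator vanishes contributes 0, logged),
* MCC: the binary definition

      (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

  generalised for C > 2 to the correlation-coefficient form over the CxC
  matrix, which reduces exactly to the binary formula at C = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR

from .pls import fit_pls
from .preprocess import PreprocessSpec, fit_apply

__all__ = [
    "ModelSpec",
    "FoldAssignment",
    "ConfusionMatrix",
    "EvaluationResult",
    "venetian_blind_folds",
    "pca_compress",
    "fit_predict",
    "regression_metrics",
    "classification_metrics",
    "confusion_from_labels",
    "cross_validate",
    "bootstrap_eval",
    "grid_search",
]

log = logging.getLogger(__name__)

FAMILIES = ("PLS", "kNN", "RF", "SVM")
TASKS = ("regression", "classification")


@dataclass(frozen=True)
class ModelSpec:
    """A learner family with hyperparameters and optional PCA compression.

    PLS uses ``n_lv`` latent variables directly on the (pre-processed)
    spectra. k-NN, RF and SVM operate on PCA scores, so ``pca_components``
    is required for those families — the component count plays the role of
    the reported "PC" column.
    """

    family: str
    task: str = "regression"
    hyperparameters: tuple[tuple[str, object], ...] = ()
    pca_components: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.family == "PLS" and self.task == "classification":
            raise ValueError("PLS classification is not supported; "
                             "use kNN, RF or SVM")
        if self.family != "PLS" and self.pca_components is None:
            raise ValueError(f"{self.family} requires pca_components")
        hp = dict(self.hyperparameters)
        if self.family == "RF":
            n_trees = hp.get("n_trees", 300)
            depth = hp.get("max_depth", 15)
            if not 200 <= n_trees <= 500:
                raise ValueError("RF n_trees must be within 200..500")
            if not 10 <= depth <= 20:
                raise ValueError("RF max_depth must be within 10..20")
        if self.family == "kNN" and hp.get("metric", "euclidean") not in (
            "euclidean", "manhattan",
        ):
            raise ValueError("kNN metric must be euclidean or manhattan")
        if self.family == "SVM" and hp.get("kernel", "linear") not in (
            "linear", "poly", "polynomial", "rbf", "sigmoid",
        ):
            raise ValueError("unknown SVM kernel")

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)

    @property
    def label(self) -> str:
        hp = self.hp
        if self.family == "PLS":
            return f"PLS (LV={hp.get('n_lv', '?')})"
        if self.family == "kNN":
            return f"k-NN (k={hp.get('k', 5)}, {hp.get('metric', 'euclidean')})"
        if self.family == "RF":
            return f"RF ({hp.get('n_trees', 300)} trees, depth {hp.get('max_depth', 15)})"
        return f"SVM ({hp.get('kernel', 'linear')})"

    @property
    def complexity(self) -> int:
        """Latent variables / PCs, used for tie-breaking in grid search."""
        if self.family == "PLS":
            return int(self.hp.get("n_lv", 0))
        return int(self.pca_components or 0)


@dataclass(frozen=True)
class FoldAssignment:
    """Exhaustive, disjoint assignment of rows to k folds."""

    fold_of_row: np.ndarray
    k: int

    def __post_init__(self) -> None:
        fold = np.asarray(self.fold_of_row, dtype=int)
        object.__setattr__(self, "fold_of_row", fold)
        if fold.min() < 0 or fold.max() >= self.k:
            raise ValueError("fold labels must lie in [0, k)")
        if np.unique(fold).size != self.k:
            raise ValueError("every fold must be non-empty")


def venetian_blind_folds(n: int, k: int = 5) -> FoldAssignment:
    """Venetian-blind assignment: row j (in stable sample order) -> j mod k."""
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    return FoldAssignment(fold_of_row=np.arange(n) % k, k=k)


def pca_compress(
    X_cal: np.ndarray, X_val: Optional[np.ndarray], n_components: int
) -> tuple[np.ndarray, Optional[np.ndarray], np.ndarray]:
    """PCA scores with components estimated on calibration rows only."""
    X_cal = np.asarray(X_cal, dtype=float)
    max_c = min(X_cal.shape[0] - 1, X_cal.shape[1])
    if not 1 <= n_components <= max_c:
        raise ValueError(f"n_components must be within 1..{max_c}")
    pca = PCA(n_components=n_components, svd_solver="full")
    T_cal = pca.fit_transform(X_cal)
    T_val = pca.transform(np.asarray(X_val, dtype=float)) if X_val is not None else None
    return T_cal, T_val, pca.components_


def _make_learner(spec: ModelSpec, seed: int):
    hp = spec.hp
    if spec.family == "kNN":
        cls = KNeighborsRegressor if spec.task == "regression" else KNeighborsClassifier
        return cls(n_neighbors=hp.get("k", 5), metric=hp.get("metric", "euclidean"))
    if spec.family == "RF":
        cls = RandomForestRegressor if spec.task == "regression" else RandomForestClassifier
        return cls(
            n_estimators=hp.get("n_trees", 300),
            max_depth=hp.get("max_depth", 15),
            random_state=seed,
        )
    if spec.family == "SVM":
        kernel = hp.get("kernel", "linear")
        if kernel == "polynomial":
            kernel = "poly"
        kwargs = dict(
            kernel=kernel, C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"),
            degree=hp.get("degree", 3),
        )
        return SVR(**kwargs) if spec.task == "regression" else SVC(**kwargs)
    raise AssertionError(spec.family)


def fit_predict(
    spec: ModelSpec,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Train one learner on calibration data and predict the validation set.

    PCA compression (for non-PLS families) is fitted on the calibration
    rows only. Deterministic given ``seed`` (the only stochastic learner is
    the random forest).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    try:
        if spec.family == "PLS":
            n_lv = int(spec.hp.get("n_lv", 2))
            model = fit_pls(X_cal, np.asarray(y_cal, dtype=float), n_lv)
            return model.predict(X_val)
        T_cal, T_val, _ = pca_compress(X_cal, X_val, int(spec.pca_components))
        learner = _make_learner(spec, seed)
        learner.fit(T_cal, y_cal)
        return learner.predict(T_val)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise RuntimeError(f"{spec.family} fit failed: {exc}") from exc


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """R^2 (about the mean of y_true), RMSE and MAE."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("y_true has zero variance; R^2 undefined")
    sse = float(((y_true - y_pred) ** 2).sum())
    return {
        "r2": 1.0 - sse / sst,
        "rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
        "mae": float(np.mean(np.abs(y_true - y_pred))),
    }


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        c = len(self.class_names)
        if counts.shape != (c, c):
            raise ValueError("counts must be CxC with C = len(class_names)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_labels(
    y_true, y_pred, class_names: Sequence[str]
) -> ConfusionMatrix:
    names = list(class_names)
    index = {c: i for i, c in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=tuple(names))


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, balanced accuracy, macro F1 and MCC from a confusion matrix."""
    counts = cm.counts
    total = cm.total
    if total < 1:
        raise ValueError("empty confusion matrix")
    c = counts.shape[0]
    tp = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)  # true-class support (TP + FN)
    col = counts.sum(axis=0).astype(float)  # predicted counts (TP + FP)
    accuracy = float(tp.sum() / total)

    recalls = np.zeros(c)
    nonzero_rows = row > 0
    recalls[nonzero_rows] = tp[nonzero_rows] / row[nonzero_rows]
    if not nonzero_rows.all():
        log.info("classification_metrics: %d class(es) without true samples "
                 "contribute recall 0", int((~nonzero_rows).sum()))
    balanced_accuracy = float(recalls.mean())

    f1 = np.zeros(c)
    denom = 2 * tp + (row - tp) + (col - tp)  # 2TP + FN + FP
    ok = denom > 0
    f1[ok] = 2 * tp[ok] / denom[ok]
    if not ok.all():
        log.info("classification_metrics: %d class(es) with undefined F1 set to 0",
                 int((~ok).sum()))
    f1_macro = float(f1.mean())

    # Correlation-coefficient MCC over the CxC matrix; reduces to the
    # binary TP/TN/FP/FN formula at C = 2.
    s = float(total)
    trace = tp.sum()
    dot_tp = float(row @ col)
    denom_mcc = np.sqrt((s**2 - float(col @ col)) * (s**2 - float(row @ row)))
    mcc = 0.0 if denom_mcc == 0 else float((trace * s - dot_tp) / denom_mcc)
    return {
        "accuracy": accuracy,
        "balanced_accuracy": balanced_accuracy,
        "f1_macro": f1_macro,
        "mcc": mcc,
    }


@dataclass
class EvaluationResult:
    """One leaderboard row: model x pre-processing x CV scheme -> metrics."""

    model: ModelSpec
    preproc: PreprocessSpec
    cv_scheme: str
    metrics: dict[str, float]
    band_selected: bool = False
    n_variables: Optional[int] = None
    extras: dict = field(default_factory=dict)


def _score(task: str, y_true, y_pred, class_names) -> dict[str, float]:
    if task == "regression":
        return regression_metrics(y_true, y_pred)
    return classification_metrics(confusion_from_labels(y_true, y_pred, class_names))


def cross_validate(
    model: ModelSpec,
    preproc: PreprocessSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    seed: int = 0,
    grid_step: float = 1.0,
    class_names: Optional[Sequence[str]] = None,
) -> EvaluationResult:
    """Venetian-blind (or any fold-based) CV with refit-per-fold contract.

    Pre-processing statistics, PCA loadings and the learner are all
    re-estimated on each fold's calibration part; held-out predictions are
    pooled before computing metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if class_names is None and model.task == "classification":
        class_names = sorted(set(map(str, y)))
    preds = np.empty(y.shape[0], dtype=object if model.task == "classification" else float)
    for fold in range(folds.k):
        test = folds.fold_of_row == fold
        train = ~test
        Xc, Xv, _ = fit_apply(preproc, X[train], X[test], grid_step=grid_step)
        preds[test] = fit_predict(model, Xc, y[train], Xv, seed=seed)
    metrics = _score(model.task, y, preds, class_names)
    return EvaluationResult(
        model=model, preproc=preproc, cv_scheme=f"VB{folds.k}",
        metrics=metrics, n_variables=X.shape[1],
    )


def bootstrap_eval(
    model: ModelSpec,
    preproc: PreprocessSpec,
    X: np.ndarray,
    y: np.ndarray,
    B: int = 100,
    seed: int = 0,
    grid_step: float = 1.0,
    class_names: Optional[Sequence[str]] = None,
) -> EvaluationResult:
    """Bootstrap resampling: calibrate on each draw, score out-of-bag rows.

    Iterations whose out-of-bag set is empty, or (classification) whose
    calibration draw misses a class, are skipped; reported metrics are the
    arithmetic mean over scored iterations, with the dispersion retained
    under ``extras['metric_sd']``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if class_names is None and model.task == "classification":
        class_names = sorted(set(map(str, y)))
    rng = np.random.default_rng(seed)
    per_iter: list[dict[str, float]] = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            skipped += 1
            continue
        if model.task == "classification" and set(map(str, y[idx])) != set(class_names):
            skipped += 1
            continue
        try:
            Xc, Xv, _ = fit_apply(preproc, X[idx], X[oob], grid_step=grid_step)
            pred = fit_predict(model, Xc, y[idx], Xv, seed=seed)
            per_iter.append(_score(model.task, y[oob], pred, class_names))
        except (ValueError, RuntimeError):
            skipped += 1
    if not per_iter:
        raise RuntimeError(
            "no bootstrap iteration could be scored "
            "(a class may be absent from every calibration draw)"
        )
    if skipped:
        log.info("bootstrap_eval: skipped %d/%d iterations", skipped, B)
    keys = per_iter[0].keys()
    mean = {k: float(np.mean([m[k] for m in per_iter])) for k in keys}
    sd = {k: float(np.std([m[k] for m in per_iter], ddof=1)) if len(per_iter) > 1
          else 0.0 for k in keys}
    return EvaluationResult(
        model=model, preproc=preproc, cv_scheme=f"B{B}",
        metrics=mean, n_variables=X.shape[1],
        extras={"metric_sd": sd, "n_scored": len(per_iter)},
    )


def grid_search(
    task: str,
    preprocs: Sequence[PreprocessSpec],
    models: Sequence[ModelSpec],
    X: np.ndarray,
    y: np.ndarray,
    cv_scheme: str = "VB5",
    seed: int = 0,
    grid_step: float = 1.0,
    class_names: Optional[Sequence[str]] = None,
    criterion: Optional[str] = None,
) -> tuple[EvaluationResult, list[EvaluationResult]]:
    """Exhaustive evaluation of pre-processing x model candidates.

    The winner minimises RMSE (regression) or maximises macro F1
    (classification) unless another metric is named via ``criterion``.
    Ties break towards fewer latent variables / PCs, then the
    lexicographically smaller pre-processing id. Returns the winner and
    the full leaderboard.
    """
    if not preprocs or not models:
        raise ValueError("candidate preprocs and models must be non-empty")
    if criterion is None:
        criterion = "rmse" if task == "regression" else "f1_macro"
    minimise = criterion in ("rmse", "mae")
    leaderboard: list[EvaluationResult] = []
    failures: list[str] = []
    for preproc in preprocs:
        for model in models:
            if model.task != task:
                raise ValueError(f"model {model.label} has task {model.task!r}, "
                                 f"expected {task!r}")
            try:
                if cv_scheme.startswith("VB"):
                    folds = venetian_blind_folds(X.shape[0], int(cv_scheme[2:] or 5))
                    res = cross_validate(model, preproc, X, y, folds, seed=seed,
                                         grid_step=grid_step, class_names=class_names)
                elif cv_scheme.startswith("B"):
                    res = bootstrap_eval(model, preproc, X, y, B=int(cv_scheme[1:]),
                                         seed=seed, grid_step=grid_step,
                                         class_names=class_names)
                else:
                    raise ValueError(f"unknown cv_scheme {cv_scheme!r}")
            except (ValueError, RuntimeError) as exc:
                failures.append(f"{model.label} / {preproc.label}: {exc}")
                continue
            leaderboard.append(res)
    if not leaderboard:
        raise RuntimeError("all grid-search candidates failed:\n" +
                           "\n".join(failures))
    if failures:
        log.info("grid_search: %d candidate(s) failed", len(failures))

    def sort_key(res: EvaluationResult):
        value = res.metrics[criterion]
        return (value if minimise else -value, res.model.complexity,
                res.preproc.label)

    best = min(leaderboard, key=sort_key)
    return best, leaderboard
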