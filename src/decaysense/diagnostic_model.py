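"""Cross-validated diagnostic modelling on the corrected half-life features.

The pipeline inside each cross-validation fold is: standardize every
compound feature to zero mean and unit sample SD, project onto the top
principal components (nPC of them), fit one of seven classifier families
(logistic regression, LDA, QDA, SVM, KNN, decision tree, random forest),
and score the held-out fold with accuracy, precision, recall, F1 and AUC.
Folds are stratified 3-fold with seeded shuffling; the reported value of a
metric is the arithmetic mean over folds.

The positive class for precision/recall/F1 is the disease group (AD by
default).  Classifiers without native probabilities contribute their
decision-function values to AUC; thresholded metrics always use the model's
own predicted labels, so no calibration step is introduced.

By default standardization and PCA are fitted on the training folds only
and applied to the test fold; ``transform_within_folds=False`` reproduces
the simpler whole-matrix preprocessing order (standardize, PCA, then CV),
which leaks fold information and is provided to make that difference
explicit.

Multi-group settings (AD versus other diseases, AD versus AD-MCI) are
served by :func:`project_2d` (LDA discriminant axes or QDA log-posterior
contrasts) and :func:`group_difference_test` (classical unpaired two-tailed
t test) rather than by the binary classifier stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

METRICS = ("accuracy", "precision", "recall", "f1", "auc")

#: The seven supported classifier families.
FAMILIES = ("logistic", "lda", "qda", "svm", "knn", "tree", "rf")

_DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "logistic": {"max_iter": 2000, "C": 1.0},
    "lda": {},
    "qda": {},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "knn": {"n_neighbors": 5},
    "tree": {},
    "rf": {"n_estimators": 100},
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration: family, retained PCs, hyperparameters, seed."""

    family: str
    n_pc: int
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n_pc < 1:
            raise ValueError("n_pc must be >= 1")
        merged = {**_DEFAULT_HYPERPARAMS[self.family], **self.hyperparams}
        object.__setattr__(self, "hyperparams", merged)

    def build(self, n_train: int | None = None):
        """Instantiate the sklearn estimator with recorded hyperparameters.

        ``n_train`` caps KNN's neighbor count at the training-set size so
        tiny folds remain fittable.
        """
        hp = dict(self.hyperparams)
        if self.family == "knn" and n_train is not None:
            hp["n_neighbors"] = min(hp["n_neighbors"], n_train)
        if self.family == "logistic":
            return LogisticRegression(**hp)
        if self.family == "lda":
            return LinearDiscriminantAnalysis(**hp)
        if self.family == "qda":
            return QuadraticDiscriminantAnalysis(**hp)
        if self.family == "svm":
            return SVC(**hp)
        if self.family == "knn":
            return KNeighborsClassifier(**hp)
        if self.family == "tree":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        return RandomForestClassifier(random_state=self.seed, **hp)


@dataclass(frozen=True)
class ClassifierReport:
    """Per-fold and averaged metrics for one cross-validated model."""

    spec: ModelSpec
    fold_metrics: pd.DataFrame  # one row per fold, columns METRICS
    fold_assignments: np.ndarray  # fold index per sample
    seed: int

    @property
    def averages(self) -> dict[str, float]:
        """Arithmetic mean of each metric over the folds."""
        return {m: float(self.fold_metrics[m].mean()) for m in METRICS}


def standardize_features(
    Z: pd.DataFrame, params: tuple[pd.Series, pd.Series] | None = None
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Scale each feature to mean 0 and sample (n-1) SD 1.

    Zero-variance features are dropped with a warning rather than aborting.
    Pass the returned ``(mean, sd)`` back in as ``params`` to apply a
    training-set scaling to held-out samples.
    """
    if params is None:
        if len(Z) < 2:
            raise ValueError("standardization needs >= 2 samples")
        mean = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=1)
        constant = sd[sd == 0].index
        if len(constant):
            warnings.warn(f"dropping zero-variance features: {list(constant)}")
            Z = Z.drop(columns=constant)
            mean = mean.drop(constant)
            sd = sd.drop(constant)
        params = (mean, sd)
    mean, sd = params
    return (Z[mean.index] - mean) / sd, params


def pca_reduce(
    S: pd.DataFrame | np.ndarray, n_pc: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project standardized features onto the top-``n_pc`` principal axes.

    Returns ``(scores, loadings, explained_variance_fractions)`` where
    ``loadings`` has one row per component.  Fractions are non-increasing
    and sum to at most 1.
    """
    S = np.asarray(S, dtype=float)
    max_pc = min(S.shape[0] - 1, S.shape[1]) if S.shape[0] > 1 else S.shape[1]
    if not 1 <= n_pc <= max_pc:
        raise ValueError(f"n_pc must be in [1, {max_pc}], got {n_pc}")
    pca = PCA(n_components=n_pc)
    scores = pca.fit_transform(S)
    return scores, pca.components_, pca.explained_variance_ratio_


def compute_metrics(
    truth: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and AUC from binary truth and real scores.

    Threshold metrics come from the confusion matrix of ``scores >
    threshold`` (positive class = 1); AUC is the rank statistic (probability
    a positive outscores a negative, ties counted half), equal to the
    trapezoidal area under the ROC curve.  With one-class truth AUC is
    undefined and returned as NaN with a warning; the other metrics are
    still computed.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    pred = (scores > threshold).astype(int)
    return {**_threshold_metrics(truth, pred), "auc": _auc(truth, scores)}


def _threshold_metrics(truth: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / len(truth),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def _auc(truth: np.ndarray, scores: np.ndarray) -> float:
    if len(np.unique(truth)) < 2:
        warnings.warn("one-class truth: AUC undefined, returning NaN")
        return float("nan")
    return float(roc_auc_score(truth, scores))


def _scores_for_auc(model, X: np.ndarray, positive_index: int) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, positive_index]
    return np.asarray(model.decision_function(X), dtype=float)


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence[str],
    spec: ModelSpec,
    k: int = 3,
    positive_label: str = "AD",
    transform_within_folds: bool = True,
) -> ClassifierReport:
    """Stratified k-fold evaluation of one model configuration.

    The dataset is shuffled with the spec's seed and split into ``k``
    stratified folds; each fold in turn is the test set for a model fitted
    on the rest.  Standardization and PCA are fitted inside the training
    folds by default.

    Raises
    ------
    ValueError
        Single-class labels, or ``k`` larger than the smaller class.
    """
    features = pd.DataFrame(features)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present")
    if len(classes) > 2:
        raise ValueError("binary evaluation only; use project_2d for multi-group data")
    smallest = min(int((labels == c).sum()) for c in classes)
    if k > smallest:
        raise ValueError(f"k={k} exceeds the smaller class size {smallest}")
    y = (labels == positive_label).astype(int)
    if y.sum() == 0:
        raise ValueError(f"positive label {positive_label!r} absent from labels")

    if not transform_within_folds:
        S, _ = standardize_features(features)
        scores_all, _, _ = pca_reduce(S, min(spec.n_pc, min(S.shape) - 1))

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    fold_assignments = np.empty(len(y), dtype=int)
    rows = []
    for fold, (train, test) in enumerate(skf.split(features, y)):
        fold_assignments[test] = fold
        if transform_within_folds:
            S_train, params = standardize_features(features.iloc[train])
            S_test, _ = standardize_features(features.iloc[test], params=params)
            n_pc = min(spec.n_pc, len(train) - 1, S_train.shape[1])
            pca = PCA(n_components=n_pc)
            X_train = pca.fit_transform(S_train)
            X_test = pca.transform(S_test)
        else:
            X_train, X_test = scores_all[train], scores_all[test]
        model = spec.build(n_train=len(train))
        model.fit(X_train, y[train])
        pred = model.predict(X_test)
        pos_index = int(np.where(model.classes_ == 1)[0][0])
        auc_scores = _scores_for_auc(model, X_test, pos_index)
        rows.append({**_threshold_metrics(y[test], pred), "auc": _auc(y[test], auc_scores)})
    return ClassifierReport(
        spec=spec,
        fold_metrics=pd.DataFrame(rows),
        fold_assignments=fold_assignments,
        seed=spec.seed,
    )


def sweep_models(
    features: pd.DataFrame,
    labels: Sequence[str],
    families: Sequence[str] = FAMILIES,
    npc_grid: Sequence[int] = (2, 3, 4, 5, 7, 9, 11),
    seed: int = 0,
    k: int = 3,
    positive_label: str = "AD",
) -> pd.DataFrame:
    """Evaluate every (family, nPC) pair; pick each family's best nPC by mean AUC.

    Returns the full grid as a DataFrame (one row per family x nPC with the
    averaged metrics) with a boolean ``selected`` column marking, for each
    family, the nPC maximizing mean AUC; rows are sorted so selected rows
    come first, ranked by AUC descending.  Deterministic given (data, seed).
    """
    if not families or not npc_grid:
        raise ValueError("families and npc_grid must be non-empty")
    rows = []
    for family in families:
        for n_pc in npc_grid:
            spec = ModelSpec(family=family, n_pc=int(n_pc), seed=seed)
            report = cross_validate(
                features, labels, spec, k=k, positive_label=positive_label
            )
            rows.append({"family": family, "n_pc": int(n_pc), **report.averages})
    grid = pd.DataFrame(rows)
    # deterministic argmax: highest AUC, then smallest nPC
    grid = grid.sort_values(["family", "auc", "n_pc"], ascending=[True, False, True])
    grid["selected"] = ~grid.duplicated("family")
    return grid.sort_values(
        ["selected", "auc", "family", "n_pc"], ascending=[False, False, True, True]
    ).reset_index(drop=True)


def project_2d(
    features: pd.DataFrame,
    labels: Sequence[str],
    method: str = "lda",
) -> np.ndarray:
    """Project samples to 2-D coordinates for multi-group visualization.

    ``method="lda"`` projects onto the top-2 discriminant axes; with only
    two groups a single axis exists and the second coordinate is zero.
    ``method="qda"`` uses the first two class log-posterior contrasts
    (log-posterior of class 2 and class 3 minus class 1, classes in sorted
    label order).
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 groups")
    coords = np.zeros((len(X), 2))
    if method == "lda":
        n_axes = min(2, len(classes) - 1, X.shape[1])
        lda = LinearDiscriminantAnalysis(n_components=n_axes)
        coords[:, :n_axes] = lda.fit_transform(X, labels)
        return coords
    if method == "qda":
        smallest = min(int((labels == c).sum()) for c in classes)
        if smallest <= X.shape[1]:
            raise ValueError(
                "a group has too few samples for a full-rank QDA covariance; "
                "use method='lda' or reduce dimensionality first"
            )
        qda = QuadraticDiscriminantAnalysis()
        qda.fit(X, labels)
        logp = qda.predict_log_proba(X)
        coords[:, 0] = logp[:, 1] - logp[:, 0]
        if logp.shape[1] > 2:
            coords[:, 1] = logp[:, 2] - logp[:, 0]
        return coords
    raise ValueError(f"unknown method {method!r}; use 'lda' or 'qda'")


@dataclass(frozen=True)
class TTestResult:
    """Unpaired two-tailed Student t test between two groups."""

    t: float
    p: float

    @property
    def significant(self) -> bool:
        """Conventional significance annotation at P <= 0.05."""
        return self.p <= 0.05


def group_difference_test(values_a: Sequence[float], values_b: Sequence[float]) -> TTestResult:
    """Classical unpaired two-tailed Student t test (equal variances pooled)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), p=float(p))
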