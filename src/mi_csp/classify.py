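"""Six-classifier comparison under stratified k-fold cross-validation.

The classifiers are the standard binary discriminators used in the
motor-imagery literature — logistic regression, LDA, RBF-kernel SVM,
Mahalanobis-metric k-NN with inverse-distance weights, Gaussian naive
Bayes and an entropy-grown decision tree — each instantiated with fixed
hyperparameters (scikit-learn estimators behind a uniform train/predict
surface).  Cross-validation is stratified and seeded; in the default
leakage-safe mode the CSP filters and log-variance features are re-fitted
on the training folds only, while "paper mode" fits CSP once on all trials
before splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .csp import FeatureMatrix, apply_filters, fit_csp, logvar_features
from .errors import ConfigurationError, EstimationError
from .types import EpochSet

__all__ = [
    "ALGORITHMS",
    "ClassifierSpec",
    "TrainedClassifier",
    "CvReport",
    "default_specs",
    "train",
    "cross_validate",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("logreg", "lda", "svm-rbf", "knn", "gnb", "tree")

#: fixed hyperparameters per algorithm (the optimizer-derived reference
#: values: SVM box constraint 0.057704, k=100 Mahalanobis inverse-distance
#: neighbors, 15-split deviance tree).  The SVM kernel scale is fixed to 1.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "logreg": {},
    "lda": {"discriminant_type": "linear"},
    "svm-rbf": {"box_constraint": 0.057704, "kernel_scale": 1.0},
    "knn": {"n_neighbors": 100, "metric": "mahalanobis", "weights": "distance"},
    "gnb": {},
    "tree": {"max_splits": 15, "criterion": "max-deviance-reduction"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Name + hyperparameters of one classifier in the comparison."""

    algorithm: str
    hyperparams: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )

    def resolved(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMS[self.algorithm])
        hp.update(self.hyperparams)
        return hp


def default_specs(names: Sequence[str] = ALGORITHMS) -> list[ClassifierSpec]:
    """The six reference classifiers with their fixed hyperparameters."""
    return [ClassifierSpec(n) for n in names]


@dataclass
class TrainedClassifier:
    """A fitted classifier; ``predict`` maps features to labels in {1, 2}."""

    spec: ClassifierSpec
    estimator: object
    classes: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ConfigurationError(
                f"expected (n, {self.n_features}) features, got {X.shape}"
            )
        return np.asarray(self.estimator.predict(X), dtype=np.int64)

    def predict_proba(self, X: np.ndarray) -> np.ndarray | None:
        """Class-probability matrix (columns ordered as ``classes``), or
        ``None`` for margin-only classifiers (the SVM)."""
        if not hasattr(self.estimator, "predict_proba"):
            return None
        X = np.asarray(X, dtype=np.float64)
        return self.estimator.predict_proba(X)

    @property
    def n_features(self) -> int:
        return int(self._n_features)

    _n_features: int = 0


def _build_estimator(spec: ClassifierSpec, X: np.ndarray, seed: int):
    hp = spec.resolved()
    alg = spec.algorithm
    if alg == "logreg":
        # plain maximum-likelihood logit (C=inf: unpenalized); the iteration
        # cap handles perfectly separable data
        return LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-8, max_iter=1000)
    if alg == "lda":
        return LinearDiscriminantAnalysis(solver="svd")
    if alg == "svm-rbf":
        ks = float(hp.get("kernel_scale", 1.0))
        return SVC(C=float(hp["box_constraint"]), kernel="rbf", gamma=1.0 / ks**2)
    if alg == "knn":
        n_train = X.shape[0]
        k = int(hp["n_neighbors"])
        if k >= n_train:
            logger.warning("knn: clipping k=%d to n_train-1=%d", k, n_train - 1)
            k = n_train - 1
        cov = np.cov(X.T)
        cov = np.atleast_2d(cov)
        d = cov.shape[0]
        cov = cov + (1e-6 * np.trace(cov) / d) * np.eye(d)  # ridge for invertibility
        try:
            VI = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                "training covariance is singular; Mahalanobis k-NN needs "
                "regularization or fewer features"
            ) from exc
        return KNeighborsClassifier(
            n_neighbors=k,
            weights=hp.get("weights", "distance"),
            metric="mahalanobis",
            metric_params={"VI": VI},
            algorithm="brute",
        )
    if alg == "gnb":
        return GaussianNB()
    if alg == "tree":
        max_splits = int(hp["max_splits"])
        # a binary tree with <= s internal splits has <= s + 1 leaves
        return DecisionTreeClassifier(
            criterion="entropy", max_leaf_nodes=max_splits + 1, random_state=seed
        )
    raise ConfigurationError(f"unknown algorithm {alg!r}")  # pragma: no cover


def train(
    spec: ClassifierSpec,
    X: np.ndarray | FeatureMatrix,
    y: np.ndarray | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit one classifier on a feature matrix.

    ``X`` may be a raw ``(n_trials, n_features)`` array with labels ``y``,
    or a :class:`FeatureMatrix` carrying its own labels.
    """
    if isinstance(X, FeatureMatrix):
        y = X.labels
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ConfigurationError("X must be (n, d) with matching label vector")
    if not np.isfinite(X).all():
        raise ConfigurationError("features contain non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise EstimationError(f"training labels contain a single class ({classes.tolist()})")
    if counts.min() < 2:
        raise EstimationError("each class needs at least 2 training trials")
    est = _build_estimator(spec, X, seed)
    est.fit(X, y)
    model = TrainedClassifier(spec=spec, estimator=est, classes=classes)
    model._n_features = X.shape[1]
    return model


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Per-classifier fold accuracies (percent) plus confusion counts.

    ``fold_accuracies[name]`` has one entry per fold; ``confusion[name]`` is
    the 2x2 count matrix (rows true class, columns predicted, in ascending
    label order) summed over folds.  ``metadata`` records the seed, fold
    scheme and whether CSP was refit inside each fold.
    """

    fold_accuracies: dict[str, np.ndarray]
    confusion: dict[str, np.ndarray]
    metadata: dict

    def mean_accuracy(self, algorithm: str) -> float:
        return float(np.mean(self.fold_accuracies[algorithm]))

    @property
    def means(self) -> dict[str, float]:
        return {a: self.mean_accuracy(a) for a in self.fold_accuracies}

    def to_dataframe(self, subject: str = "sim") -> pd.DataFrame:
        """Long-format report: one row per (classifier, fold) plus the mean,
        mirroring the per-subject accuracy-table layout."""
        rows = []
        for alg, accs in self.fold_accuracies.items():
            for f, a in enumerate(accs):
                rows.append(
                    {"subject": subject, "classifier": alg, "fold": f + 1,
                     "accuracy": float(a), "mean": self.mean_accuracy(alg)}
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """One row per classifier with its mean accuracy, best first."""
        df = pd.DataFrame(
            {"classifier": list(self.fold_accuracies), "mean_accuracy": list(self.means.values())}
        )
        return df.sort_values("mean_accuracy", ascending=False).reset_index(drop=True)


def _fold_splits(labels: np.ndarray, k_folds: int, seed: int):
    n = labels.size
    if k_folds == n:  # leave-one-out
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)], "leave-one-out"
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k_folds:
        raise ConfigurationError(
            f"every class needs >= k_folds={k_folds} trials; class counts are "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(n), labels)), "stratified-shuffled"


def cross_validate(
    epochs: EpochSet,
    specs: Sequence[ClassifierSpec] | None = None,
    k_folds: int = 10,
    seed: int = 0,
    refit_csp_per_fold: bool = True,
    m: int = 3,
) -> CvReport:
    """Stratified k-fold comparison of the configured classifiers.

    Parameters
    ----------
    refit_csp_per_fold : bool
        When True (default) the CSP filters and features are estimated on
        the training folds only — no information from test trials enters
        covariance averaging or classifier fitting.  When False ("paper
        mode") CSP is fitted once on all trials before splitting.
    """
    if specs is None:
        specs = default_specs()
    labels = epochs.labels
    splits, scheme = _fold_splits(labels, k_folds, seed)
    classes = np.unique(labels)

    if not refit_csp_per_fold:
        _, feats_all = _features(epochs, m)

    fold_acc: dict[str, list[float]] = {s.algorithm: [] for s in specs}
    confusion = {s.algorithm: np.zeros((2, 2), dtype=np.int64) for s in specs}
    for train_idx, test_idx in splits:
        if refit_csp_per_fold:
            model = fit_csp(epochs.subset(train_idx), m=m)
            Xtr = logvar_features(
                apply_filters(model, epochs.subset(train_idx)), labels[train_idx]
            ).values
            Xte = logvar_features(
                apply_filters(model, epochs.subset(test_idx)), labels[test_idx]
            ).values
        else:
            Xtr = feats_all.values[train_idx]
            Xte = feats_all.values[test_idx]
        ytr, yte = labels[train_idx], labels[test_idx]
        for spec in specs:
            clf = train(spec, Xtr, ytr, seed=seed)
            pred = clf.predict(Xte)
            fold_acc[spec.algorithm].append(100.0 * float(np.mean(pred == yte)))
            for yt, yp in zip(yte, pred):
                confusion[spec.algorithm][
                    int(np.searchsorted(classes, yt)), int(np.searchsorted(classes, yp))
                ] += 1

    return CvReport(
        fold_accuracies={a: np.asarray(v) for a, v in fold_acc.items()},
        confusion=confusion,
        metadata={
            "seed": seed,
            "k_folds": k_folds,
            "fold_scheme": scheme,
            "refit_csp_per_fold": bool(refit_csp_per_fold),
            "m": m,
            "n_trials": int(labels.size),
        },
    )


def _features(epochs: EpochSet, m: int):
    model = fit_csp(epochs, m=m)
    return model, logvar_features(apply_filters(model, epochs), epochs.labels)
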