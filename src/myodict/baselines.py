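"""Comparison classifiers sharing the wavelet-packet feature pipeline.

Six conventional classifiers — linear and RBF support vector machines,
linear discriminant analysis, Gaussian naive Bayes, random forest and
k-nearest neighbors — wrapped so that they consume exactly the same
FeatureMatrix objects as the dictionary-learning classifier.  All are
scikit-learn estimators; hyperparameters default to common practice
(SVM C=1, RBF width 1/d, KNN k=5, RF 100 trees) and are overridable
per name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

BASELINE_NAMES = ("SVM_lin", "SVM_rbf", "LDA", "NB", "KNN", "RF")


@dataclass
class BaselineSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline {self.name!r}; choose from {BASELINE_NAMES}")


def make_baseline(spec: BaselineSpec):
    """Unfitted scikit-learn estimator for a BaselineSpec."""
    hp = dict(spec.hyperparameters)
    if spec.name == "SVM_lin":
        return SVC(kernel="linear", C=hp.pop("C", 1.0), **hp)
    if spec.name == "SVM_rbf":
        # gamma="auto" is 1/d, the conventional RBF width for normalized features
        return SVC(kernel="rbf", C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "auto"), **hp)
    if spec.name == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if spec.name == "NB":
        return GaussianNB(**hp)
    if spec.name == "KNN":
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    if spec.name == "RF":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=spec.seed, **hp
        )
    raise ValueError(f"unknown baseline {spec.name!r}")  # pragma: no cover


def train_baseline(features, spec: BaselineSpec):
    """Fit the named baseline on a FeatureMatrix (columns = windows)."""
    if np.unique(features.labels).size < 2:
        raise ValueError("baseline training needs at least 2 classes")
    clf = make_baseline(spec)
    return clf.fit(features.values.T, features.labels)


def predict_baseline(handle, features) -> np.ndarray:
    """One predicted label per feature column."""
    if features.n == 0:
        return np.array([], dtype=int)
    if features.d != handle.n_features_in_:
        raise ValueError(
            f"feature dimension {features.d} does not match training dimension "
            f"{handle.n_features_in_}"
        )
    return handle.predict(features.values.T)
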