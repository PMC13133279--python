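"""Random-forest vessel-morphology classification.

The classifier reproduces the labeling protocol used for pathologist
supervision: 100 vessels per class for training and another disjoint 100
per class for validation, a 1000-tree forest with four candidate
features per node split, and interobserver agreement summarized by the
concordance rate and unweighted Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from vesselphen.morphometry import FEATURE_NAMES
from vesselphen.simulate.shapes import CLASSES


@dataclass
class ClassifierConfig:
    n_trees: int = 1000
    candidate_features: int = 4
    train_per_class: int = 100
    validation_per_class: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.candidate_features > len(FEATURE_NAMES):
            raise ValueError("candidate features per split cannot exceed 10")
        if min(self.n_trees, self.train_per_class, self.validation_per_class) < 1:
            raise ValueError("sizes must be >= 1")


class VesselMorphologyClassifier(BaseEstimator, ClassifierMixin):
    """Random forest over the ten morphological features.

    Parameters
    ----------
    n_estimators : number of trees (default 1000).
    max_features : candidate features per node split (default 4).
    random_state : seed for bootstrap/split randomness.

    Trees are grown to purity with bootstrap samples the size of the
    training set; prediction is the majority vote over trees, with ties
    broken toward the earlier class in the fixed order
    (micro, collapsed, patent, irregular).
    """

    def __init__(
        self,
        n_estimators: int = 1000,
        max_features: int = 4,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = self._as_matrix(X)
        y = np.asarray(y)
        present = pd.unique(y)
        if len(present) < 2:
            raise ValueError("training set must contain at least two classes")
        unknown = set(present) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        self.classes_ = np.array([c for c in CLASSES if c in set(present)])
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            bootstrap=True,
            random_state=self.random_state,
        )
        self.forest_.fit(X, y)
        imp = self.forest_.feature_importances_
        self.feature_importances_ = imp / imp.sum() if imp.sum() > 0 else imp
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X = self._as_matrix(X)
        proba = self.forest_.predict_proba(X)
        # reorder sklearn's lexicographic classes into the fixed order
        order = [list(self.forest_.classes_).index(c) for c in self.classes_]
        return proba[:, order]

    def predict(self, X):
        proba = self.predict_proba(X)
        # argmax returns the first (earlier-class) index on ties
        return self.classes_[np.argmax(proba, axis=1)]

    @staticmethod
    def _as_matrix(X):
        if isinstance(X, pd.DataFrame):
            return X[list(FEATURE_NAMES)].to_numpy(float)
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} feature columns")
        return X


@dataclass
class EvalReport:
    accuracy: float
    confusion: pd.DataFrame  # rows true class, columns predicted
    per_class_recall: pd.Series
    importances: pd.Series | None = None

    def __post_init__(self) -> None:
        total = self.confusion.to_numpy().sum()
        assert np.isclose(
            self.accuracy, np.trace(self.confusion.to_numpy()) / total
        ), "accuracy must equal trace(confusion)/N"


def split_train_validation(
    labeled: pd.DataFrame,
    config: ClassifierConfig | None = None,
    label_col: str = "class_label",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint stratified train/validation samples, n-per-class each."""
    config = config or ClassifierConfig()
    rng = rng or np.random.default_rng(config.seed)
    need = config.train_per_class + config.validation_per_class
    train_idx, valid_idx = [], []
    for cls in CLASSES:
        idx = labeled.index[labeled[label_col] == cls].to_numpy()
        if len(idx) < need:
            raise ValueError(
                f"class {cls!r} has {len(idx)} labeled vessels; "
                f"need at least {need}"
            )
        chosen = rng.choice(idx, size=need, replace=False)
        train_idx.extend(chosen[: config.train_per_class])
        valid_idx.extend(chosen[config.train_per_class:])
    return labeled.loc[train_idx], labeled.loc[valid_idx]


def train_rf(
    train: pd.DataFrame,
    config: ClassifierConfig | None = None,
    label_col: str = "class_label",
) -> VesselMorphologyClassifier:
    config = config or ClassifierConfig()
    clf = VesselMorphologyClassifier(
        n_estimators=config.n_trees,
        max_features=config.candidate_features,
        random_state=config.seed,
    )
    return clf.fit(train, train[label_col])


def evaluate(
    model: VesselMorphologyClassifier,
    labeled: pd.DataFrame,
    label_col: str = "class_label",
) -> EvalReport:
    """Accuracy, 4x4 confusion, per-class recall, variable importances."""
    if len(labeled) == 0:
        raise ValueError("cannot evaluate on an empty set")
    y_true = labeled[label_col].to_numpy()
    y_pred = model.predict(labeled)
    conf = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    acc = float(np.trace(conf.to_numpy()) / len(y_true))
    row_sums = conf.sum(axis=1)
    recall = pd.Series(
        np.where(row_sums > 0, np.diag(conf) / row_sums.replace(0, 1), np.nan),
        index=conf.index,
        name="recall",
    )
    imp = pd.Series(model.feature_importances_, index=list(FEATURE_NAMES), name="importance")
    return EvalReport(acc, conf, recall, imp)


def interobserver_agreement(labels_a, labels_b) -> tuple[float, float]:
    """Concordance rate and unweighted Cohen's kappa for paired raters.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    product of the two raters' marginal label frequencies.  Degenerate
    marginals (p_e = 1, both raters constant) are guarded: kappa is 1
    for perfect agreement and 0 otherwise.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("empty label vectors")
    p_o = float(np.mean(a == b))
    levels = np.union1d(a, b)
    pa = np.array([np.mean(a == v) for v in levels])
    pb = np.array([np.mean(b == v) for v in levels])
    p_e = float(pa @ pb)
    if np.isclose(p_e, 1.0):
        return p_o, 1.0 if np.isclose(p_o, 1.0) else 0.0
    return p_o, (p_o - p_e) / (1.0 - p_e)


def classify_all(
    model: VesselMorphologyClassifier, features: pd.DataFrame
) -> tuple[pd.Series, pd.Index]:
    """Predict one class per vessel row.

    Rows with missing features are not classified; their index is
    returned separately as a failure report.
    """
    if len(features) == 0:
        return pd.Series([], dtype=object), pd.Index([])
    cols = list(FEATURE_NAMES)
    ok = features[cols].notna().all(axis=1)
    failed = features.index[~ok]
    preds = pd.Series(index=features.index, dtype=object)
    if ok.any():
        preds.loc[ok] = model.predict(features.loc[ok])
    return preds, failed
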