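"""Tree-ensemble trait classifier with fixed hyperparameters and signed importances.

The model is a random forest with a fixed configuration used identically for
every trait: 200 trees, maximum depth 10, decision threshold 0.5. The
per-strain *confidence* is the forest's positive-class probability — the mean
over trees of the proportion of positive training samples in the leaf the
strain falls into. A strain is called positive iff its confidence is at or
above the threshold (the 0.5 tie goes to positive).

Feature importances are reported as *signed* Gini importances: the magnitude
is the forest's normalized mean impurity decrease, and the sign records
whether the presence (+) or the absence (−) of the family drives positive
calls, operationalized as the comparison of presence fractions between the
training classes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .annotations_io import FeatureMatrix
from .errors import ModelFormatError, ValidationError
from .trait_curation import BinaryTraitDataset

#: Serialized-model format version; the major number gates loading.
MODEL_FORMAT_VERSION = "1.0"


@dataclass(frozen=True)
class ModelConfig:
    """Fixed hyperparameters shared by all trait models."""

    n_trees: int = 200
    max_depth: int = 10
    seed: int = 0
    decision_threshold: float = 0.5
    class_weight: str | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValidationError("n_trees and max_depth must be positive")
        if not 0 <= self.decision_threshold <= 1:
            raise ValidationError("decision_threshold must be in [0, 1]")


@dataclass(frozen=True)
class Prediction:
    """One trait call for one strain.

    ``confidence`` is the positive-class probability; ``call`` is
    ``"positive"`` iff confidence ≥ the decision threshold.
    """

    strain_id: str
    trait: str
    confidence: float
    call: str


@dataclass(frozen=True)
class FeatureImportance:
    """Signed Gini importance plus per-class presence fractions."""

    feature_id: str
    signed_gini: float
    presence_in_pos: float
    presence_in_neg: float


class TraitRandomForest(ClassifierMixin, BaseEstimator):
    """Random-forest binary classifier with a probability decision threshold.

    A scikit-learn compatible estimator. ``predict_proba`` returns the
    forest's class probabilities; ``predict`` applies ``decision_threshold``
    to the positive-class probability (ties → positive) instead of the
    arg-max rule, and ``confidence`` exposes the positive-class probability
    directly.

    Parameters
    ----------
    n_estimators : int
        Number of trees (default 200).
    max_depth : int
        Maximum tree depth (default 10).
    decision_threshold : float
        Positive-call threshold on the positive-class probability.
    random_state : int or None
        Seed for the forest; fixing it makes fit/predict deterministic.
    class_weight : str or None
        Passed to the underlying forest; default None (unweighted trees).

    Attributes
    ----------
    forest_ : RandomForestClassifier
        The fitted ensemble.
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is the positive class.
    prevalence_ : float
        Positive-class fraction in the training data.
    feature_ids_ : list of str
        Column names seen at fit time (when X was a DataFrame).
    presence_in_pos_, presence_in_neg_ : ndarray
        Per-feature presence fractions in the training classes.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_depth: int = 10,
        decision_threshold: float = 0.5,
        random_state: int | None = None,
        class_weight: str | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.decision_threshold = decision_threshold
        self.random_state = random_state
        self.class_weight = class_weight

    def fit(self, X, y) -> "TraitRandomForest":
        if isinstance(X, pd.DataFrame):
            self.feature_ids_ = [str(c) for c in X.columns]
            X_arr = X.to_numpy()
        else:
            X_arr = np.asarray(X)
            self.feature_ids_ = [f"x{j}" for j in range(X_arr.shape[1])]
        y_arr = np.asarray(y)
        classes = np.unique(y_arr)
        if classes.size != 2:
            raise ValidationError(
                f"need exactly two classes in y, found {classes.tolist()}"
            )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
            class_weight=self.class_weight,
        )
        self.forest_.fit(X_arr, y_arr)
        self.classes_ = self.forest_.classes_
        pos_mask = y_arr == self.classes_[1]
        self.prevalence_ = float(pos_mask.mean())
        self.presence_in_pos_ = X_arr[pos_mask].mean(axis=0)
        self.presence_in_neg_ = X_arr[~pos_mask].mean(axis=0)
        self.n_features_in_ = X_arr.shape[1]
        return self

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy()
        return np.asarray(X)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._as_array(X))

    def confidence(self, X) -> np.ndarray:
        """Positive-class probability per sample (the paper's confidence)."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        conf = self.confidence(X)
        return np.where(conf >= self.decision_threshold,
                        self.classes_[1], self.classes_[0])

    def signed_importances(self) -> pd.DataFrame:
        """Signed, normalized Gini importances sorted by magnitude.

        Sign is +1 when the feature is at least as frequent among training
        positives as among negatives, −1 otherwise (absence drives the
        positive call). The magnitudes sum to 1 whenever the forest made at
        least one split.
        """
        check_is_fitted(self, "forest_")
        gini = self.forest_.feature_importances_
        sign = np.where(self.presence_in_pos_ >= self.presence_in_neg_, 1.0, -1.0)
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids_,
                "signed_gini": gini * sign,
                "presence_in_pos": self.presence_in_pos_,
                "presence_in_neg": self.presence_in_neg_,
            }
        )
        return df.reindex(
            df["signed_gini"].abs().sort_values(ascending=False, kind="stable").index
        ).reset_index(drop=True)


class BinaryVarianceFilter(TransformerMixin, BaseEstimator):
    """Drop binary features whose presence fraction lies outside [t, 1 − t].

    The sklearn-transformer counterpart of the per-trait low-variance filter:
    fit on the (curated) training strains, then transform any matrix with the
    same columns.
    """

    def __init__(self, t: float = 0.2):
        self.t = t

    def fit(self, X, y=None) -> "BinaryVarianceFilter":
        if self.t >= 0.5:
            raise ValidationError("variance-filter threshold t must be < 0.5")
        arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        p = arr.mean(axis=0)
        self.presence_fraction_ = p
        self.support_ = (p >= self.t) & (p <= 1 - self.t)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


@dataclass
class TraitModel:
    """A trained trait classifier plus the metadata needed to apply it."""

    trait: str
    config: ModelConfig
    feature_ids: list[str]
    estimator: TraitRandomForest
    prevalence: float


def _design(
    matrix: FeatureMatrix, dataset: BinaryTraitDataset
) -> tuple[pd.DataFrame, np.ndarray]:
    """Training design matrix (dataset strains in matrix row order) and labels."""
    in_matrix = set(matrix.strain_ids)
    missing = (dataset.positives | dataset.negatives) - in_matrix
    if missing:
        raise ValidationError(
            f"dataset strains missing from matrix: {sorted(missing)[:5]}"
        )
    order = [
        s for s in matrix.strain_ids if s in dataset.positives or s in dataset.negatives
    ]
    X = matrix.subset(strains=order).frame
    y = np.array([s in dataset.positives for s in order])
    return X, y


def train(
    matrix: FeatureMatrix,
    dataset: BinaryTraitDataset,
    config: ModelConfig = ModelConfig(),
) -> TraitModel:
    """Train a trait model on the matrix rows belonging to the dataset."""
    if not dataset.positives or not dataset.negatives:
        raise ValidationError(
            f"dataset for {dataset.trait!r} must contain both classes "
            f"(pos={dataset.n_pos}, neg={dataset.n_neg})"
        )
    X, y = _design(matrix, dataset)
    est = TraitRandomForest(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        decision_threshold=config.decision_threshold,
        random_state=config.seed,
        class_weight=config.class_weight,
    ).fit(X, y)
    return TraitModel(
        trait=dataset.trait,
        config=config,
        feature_ids=list(X.columns),
        estimator=est,
        prevalence=est.prevalence_,
    )


def predict(
    model: TraitModel,
    matrix: FeatureMatrix,
    zero_fill_missing: bool = False,
) -> list[Prediction]:
    """Apply a trained model to every strain of a matrix.

    The matrix must contain every feature the model was trained on; with
    ``zero_fill_missing`` absent columns are filled with zeros instead of
    raising. Extra columns are ignored.
    """
    frame = matrix.frame
    missing = [f for f in model.feature_ids if f not in frame.columns]
    if missing:
        if not zero_fill_missing:
            raise ValidationError(
                f"matrix lacks {len(missing)} model features "
                f"(e.g. {missing[:5]}); pass zero_fill_missing=True to fill"
            )
        fill = pd.DataFrame(
            0, index=frame.index, columns=missing, dtype=np.int8
        )
        frame = pd.concat([frame, fill], axis=1)
    X = frame[model.feature_ids]
    conf = model.estimator.confidence(X)
    thr = model.config.decision_threshold
    return [
        Prediction(
            strain_id=str(s),
            trait=model.trait,
            confidence=float(c),
            call="positive" if c >= thr else "negative",
        )
        for s, c in zip(X.index, conf)
    ]


def signed_importances(
    model: TraitModel,
    matrix: FeatureMatrix | None = None,
    dataset: BinaryTraitDataset | None = None,
) -> list[FeatureImportance]:
    """Ranked signed Gini importances of a trained model.

    With ``matrix`` and ``dataset`` given, presence fractions are recomputed
    on those strains; otherwise the fractions recorded at training time are
    used. Output is sorted by decreasing magnitude.
    """
    est = model.estimator
    if matrix is not None and dataset is not None:
        X, y = _design(matrix, dataset)
        X = X[model.feature_ids]
        pos = X.to_numpy()[y].mean(axis=0)
        neg = X.to_numpy()[~y].mean(axis=0)
        gini = est.forest_.feature_importances_
        sign = np.where(pos >= neg, 1.0, -1.0)
        rows = zip(model.feature_ids, gini * sign, pos, neg)
        ranked = sorted(rows, key=lambda r: abs(r[1]), reverse=True)
        return [FeatureImportance(f, float(g), float(p), float(n))
                for f, g, p, n in ranked]
    df = est.signed_importances()
    return [
        FeatureImportance(
            str(r.feature_id), float(r.signed_gini),
            float(r.presence_in_pos), float(r.presence_in_neg),
        )
        for r in df.itertuples(index=False)
    ]


def save_model(model: TraitModel, path: str | Path) -> None:
    """Serialize a trait model (format-versioned joblib archive)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "trait": model.trait,
        "config": asdict(model.config),
        "feature_ids": model.feature_ids,
        "prevalence": model.prevalence,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TraitModel:
    """Load a serialized trait model, refusing incompatible major versions."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted or not a joblib archive
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not a phenoforest model archive")
    version = str(payload["format_version"])
    if version.split(".")[0] != MODEL_FORMAT_VERSION.split(".")[0]:
        raise ModelFormatError(
            f"model format version {version} is incompatible with "
            f"{MODEL_FORMAT_VERSION}"
        )
    return TraitModel(
        trait=payload["trait"],
        config=ModelConfig(**payload["config"]),
        feature_ids=list(payload["feature_ids"]),
        estimator=payload["estimator"],
        prevalence=float(payload["prevalence"]),
    )
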