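"""Cross-validation stacking: out-of-fold meta-features + a final classifier.

The model has two layers.  Each of N base classifiers is trained K times
(K-fold cross validation over the training set, one shared stratified
partition); the out-of-fold (OOF) probability — the prediction for each
sample made by the one fold model that never saw it — becomes that base
classifier's meta-feature.  The second-layer classifier is trained on the
n × N matrix of OOF probabilities against the true labels.

At prediction time a sample's meta-feature for base classifier b is the
arithmetic mean of the K fold models' positive-class probabilities; the
final classifier maps the N meta-features to the 6mA probability.

This differs from classical stacked generalization implementations (e.g.
sklearn's ``StackingClassifier``) in that the K fold models are *kept* and
averaged at prediction time, rather than refitting each base learner on the
full training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .encoders import EncoderSpec, FeatureMatrix, encode_dataset, encode_sequences
from .errors import (
    ConfigurationError,
    ContractError,
    DegenerateFoldError,
    SerializationError,
    StratificationError,
)
from .sequence_io import DnaSequence, LabeledDataset

_MODEL_FORMAT = "sixmastack-stacking"
_MODEL_VERSION = 1

try:
    from lightgbm import LGBMClassifier as _LGBMBase
except ImportError:  # pragma: no cover
    _LGBMBase = object


class _QuietLGBMClassifier(_LGBMBase):
    """LGBMClassifier that accepts plain arrays without feature-name noise.

    LightGBM invents 'Column_i' feature names when fitted on an ndarray and
    sklearn then warns on every ndarray predict; this model only ever sees
    plain arrays, so the warning is meaningless here.
    """

    def predict_proba(self, X, **kwargs):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return super().predict_proba(X, **kwargs)


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One learner from the registry, with hyperparameters and a seed.

    Empty ``hyperparameters`` means the underlying implementation's
    defaults.  Every registered learner must fit on (features, binary
    labels) and emit positive-class probabilities for new rows.
    """

    algorithm: str
    hyperparameters: tuple = ()  # stored as sorted (key, value) pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in LEARNER_REGISTRY:
            raise ConfigurationError(
                f"unknown learner {self.algorithm!r}; registered: "
                f"{sorted(LEARNER_REGISTRY)}"
            )
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(
                self, "hyperparameters", tuple(sorted(self.hyperparameters.items()))
            )

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


LEARNER_REGISTRY: dict[str, Callable[[BaseLearnerSpec], Any]] = {}


def register_learner(name: str, factory: Callable[[BaseLearnerSpec], Any]) -> None:
    """Register a learner factory (spec -> unfitted sklearn-style estimator)."""
    LEARNER_REGISTRY[name] = factory


def _xgb_factory(spec: BaseLearnerSpec):
    from xgboost import XGBClassifier

    return XGBClassifier(random_state=spec.seed, n_jobs=1, **spec.params)


def _lgbm_factory(spec: BaseLearnerSpec):
    return _QuietLGBMClassifier(
        random_state=spec.seed, n_jobs=1, verbose=-1, **spec.params
    )


register_learner("xgboost", _xgb_factory)
register_learner("lightgbm", _lgbm_factory)
register_learner(
    "gradient_boosting",
    lambda s: GradientBoostingClassifier(random_state=s.seed, **s.params),
)
register_learner(
    "random_forest",
    lambda s: RandomForestClassifier(random_state=s.seed, n_jobs=1, **s.params),
)
register_learner(
    "logistic_regression",
    lambda s: LogisticRegression(random_state=s.seed, max_iter=2000, **s.params),
)
register_learner(
    "decision_tree", lambda s: DecisionTreeClassifier(random_state=s.seed, **s.params)
)
def _svm_factory(spec: BaseLearnerSpec):
    # The SVM must emit probabilities because stacking averages base-learner
    # outputs and feeds them to the second layer; a sigmoid-calibrated SVC
    # is the probability-emitting (Platt-scaling) mode.
    from sklearn.calibration import CalibratedClassifierCV

    return CalibratedClassifierCV(
        SVC(random_state=spec.seed, **spec.params), method="sigmoid", ensemble=False
    )


register_learner("svm", _svm_factory)


def make_learner(spec: BaseLearnerSpec):
    return LEARNER_REGISTRY[spec.algorithm](spec)


def paper_default_base_specs(seed: int = 0) -> list[BaseLearnerSpec]:
    """The selected first layer: XGBoost, gradient boosting, LightGBM."""
    return [
        BaseLearnerSpec("xgboost", seed=seed),
        BaseLearnerSpec("gradient_boosting", seed=seed),
        BaseLearnerSpec("lightgbm", seed=seed),
    ]


def paper_default_final_spec(seed: int = 0) -> BaseLearnerSpec:
    """The selected second layer: a probability-emitting SVM."""
    return BaseLearnerSpec("svm", seed=seed)


@dataclass(frozen=True)
class FoldAssignment:
    """A K-fold partition of the training samples (fold ids 1..K)."""

    fold_ids: np.ndarray
    K: int
    seed: int
    stratified: bool

    def train_test_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        mask = self.fold_ids == fold
        return np.nonzero(~mask)[0], np.nonzero(mask)[0]


def assign_folds(
    labels: np.ndarray, K: int = 5, seed: int = 0, stratified: bool = True
) -> FoldAssignment:
    """Partition samples into K folds of equal or near-equal size.

    Deterministic given ``seed``.  With stratification, per-fold class
    counts differ by at most one per class.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if K < 2:
        raise ConfigurationError(f"fold count K={K} must be at least 2")
    if K > n:
        raise ConfigurationError(f"fold count K={K} exceeds sample count {n}")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < K:
            raise StratificationError(
                f"smallest class has {counts.min()} members, fewer than K={K}"
            )
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
    fold_ids = np.empty(n, dtype=np.int64)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), y), start=1):
        fold_ids[test_idx] = f
    return FoldAssignment(fold_ids, K, seed, stratified)


def _as_matrix(X: "FeatureMatrix | np.ndarray") -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def positive_proba(model, X: np.ndarray) -> np.ndarray:
    """Positive-class (label 1) probability column of a fitted estimator."""
    proba = model.predict_proba(X)
    classes = list(getattr(model, "classes_", [0, 1]))
    return proba[:, classes.index(1)]


def fit_base_oof(
    spec: BaseLearnerSpec,
    X: "FeatureMatrix | np.ndarray",
    y: np.ndarray,
    folds: FoldAssignment,
) -> tuple[list, np.ndarray]:
    """K-fold-train one base learner; return fold models and OOF vector.

    Fold model f is fitted on all samples with fold id != f; each sample's
    OOF value is the positive-class probability emitted by the one model
    that excluded it.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y)
    if Xm.shape[0] != y.shape[0] or Xm.shape[0] != folds.fold_ids.shape[0]:
        raise ContractError("feature rows, labels and fold ids must align")
    oof = np.empty(y.shape[0], dtype=float)
    models = []
    prototype = make_learner(spec)
    for f in range(1, folds.K + 1):
        train_idx, test_idx = folds.train_test_indices(f)
        if np.unique(y[train_idx]).size < 2:
            raise DegenerateFoldError(
                f"training complement of fold {f} contains a single class"
            )
        model = clone(prototype)
        model.fit(Xm[train_idx], y[train_idx])
        oof[test_idx] = positive_proba(model, Xm[test_idx])
        models.append(model)
    return models, oof


@dataclass
class StackingModel:
    """A fitted two-layer CV-stacking ensemble.

    ``fold_models[b][f]`` is base learner b's model for fold f+1; the final
    model consumes exactly ``len(base_specs)`` meta-features.
    """

    base_specs: list[BaseLearnerSpec]
    fold_models: list[list]
    final_spec: BaseLearnerSpec
    final_model: Any
    fold_assignment: FoldAssignment
    encoder_specs: list[EncoderSpec] | None = None
    training_length: int | None = None
    n_features: int = 0
    n_pos: int = 0
    n_neg: int = 0
    seed: int = 0

    @property
    def K(self) -> int:
        return self.fold_assignment.K

    @property
    def n_base(self) -> int:
        return len(self.base_specs)


def fit_stacking_matrix(
    X: "FeatureMatrix | np.ndarray",
    y: np.ndarray,
    base_specs: Sequence[BaseLearnerSpec],
    final_spec: BaseLearnerSpec,
    K: int = 5,
    seed: int = 0,
) -> StackingModel:
    """Fit the stacking ensemble on an already-encoded feature matrix."""
    if not base_specs:
        raise ConfigurationError("at least one base learner is required")
    Xm = _as_matrix(X)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ConfigurationError("training labels contain a single class")
    folds = assign_folds(y, K=K, seed=seed, stratified=True)
    fold_models: list[list] = []
    meta_cols = []
    for spec in base_specs:
        models, oof = fit_base_oof(spec, Xm, y, folds)
        fold_models.append(models)
        meta_cols.append(oof)
    meta = np.column_stack(meta_cols)
    final_model = make_learner(final_spec)
    final_model.fit(meta, y)
    return StackingModel(
        base_specs=list(base_specs),
        fold_models=fold_models,
        final_spec=final_spec,
        final_model=final_model,
        fold_assignment=folds,
        n_features=Xm.shape[1],
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        seed=seed,
    )


def fit_stacking(
    dataset: LabeledDataset,
    encoder_specs: Sequence[EncoderSpec],
    base_specs: Sequence[BaseLearnerSpec],
    final_spec: BaseLearnerSpec,
    K: int = 5,
    seed: int = 0,
) -> StackingModel:
    """Encode a labeled dataset and fit the full stacking ensemble."""
    X = encode_dataset(dataset, encoder_specs)
    model = fit_stacking_matrix(X, dataset.labels, base_specs, final_spec, K=K, seed=seed)
    model.encoder_specs = list(encoder_specs)
    model.training_length = dataset.uniform_length
    return model


def meta_features_matrix(model: StackingModel, X: "FeatureMatrix | np.ndarray") -> np.ndarray:
    """n × N meta-features: per base learner, the mean fold-model probability."""
    Xm = _as_matrix(X)
    if model.n_features and Xm.shape[1] != model.n_features:
        raise ContractError(
            f"input has {Xm.shape[1]} features but the model was trained on "
            f"{model.n_features}"
        )
    cols = [
        np.mean([positive_proba(m, Xm) for m in models], axis=0)
        for models in model.fold_models
    ]
    return np.column_stack(cols)


def _encode_for_model(model: StackingModel, sequences) -> np.ndarray:
    if isinstance(sequences, LabeledDataset):
        sequences = sequences.sequences
    if model.encoder_specs is None:
        raise ContractError("model was fitted on raw matrices, not sequences")
    if model.training_length is not None:
        for seq in sequences:
            if len(seq) != model.training_length:
                sid = seq.id if isinstance(seq, DnaSequence) else "<str>"
                raise ContractError(
                    f"sequence {sid!r} has length {len(seq)} but the model "
                    f"was trained on {model.training_length}-nt windows"
                )
    return encode_sequences(list(sequences), model.encoder_specs).values


def meta_features_predict(model: StackingModel, X: "FeatureMatrix | np.ndarray") -> np.ndarray:
    """Public alias of :func:`meta_features_matrix` (prediction-time path)."""
    return meta_features_matrix(model, X)


def predict_proba_matrix(model: StackingModel, X: "FeatureMatrix | np.ndarray") -> np.ndarray:
    meta = meta_features_matrix(model, X)
    return positive_proba(model.final_model, meta)


def predict_proba(model: StackingModel, sequences) -> np.ndarray:
    """6mA probabilities for sequences of the model's training length."""
    return predict_proba_matrix(model, _encode_for_model(model, sequences))


def predict_label(model: StackingModel, sequences, threshold: float = 0.5) -> np.ndarray:
    """Thresholded labels: 1 iff probability >= threshold (threshold in (0,1))."""
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold {threshold} outside (0, 1)")
    return (predict_proba(model, sequences) >= threshold).astype(np.int64)


def save_model(model: StackingModel, path: str | Path) -> None:
    """Serialize a fitted model (format-versioned joblib archive)."""
    joblib.dump(
        {"format": _MODEL_FORMAT, "version": _MODEL_VERSION, "model": model}, path
    )


def load_model(path: str | Path) -> StackingModel:
    """Load a model saved by :func:`save_model`; raises on bad archives."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt pickle, truncated file, wrong format
        raise SerializationError(f"cannot load model from {path}: {exc}") from exc
    if (
        not isinstance(payload, dict)
        or payload.get("format") != _MODEL_FORMAT
        or payload.get("version") != _MODEL_VERSION
        or not isinstance(payload.get("model"), StackingModel)
    ):
        raise SerializationError(
            f"{path} is not a version-{_MODEL_VERSION} {_MODEL_FORMAT} archive"
        )
    return payload["model"]
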