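"""Cascade deep forest: layered heterogeneous ensembles with class-vector
feature augmentation and automatic depth.

Each cascade layer is a bank of four base classifiers — logistic regression,
a gradient-boosted tree ensemble (XGBoost), a random forest, and extremely
randomized trees.  For every sample, each classifier contributes its
(p_positive, p_negative) class-distribution pair; concatenated across the
bank this gives an 8-dimensional class vector, which is appended to the
*original* feature vector (never the previous layer's augmented one) to form
the next layer's input — an 800-dimensional pair feature becomes 808 columns.

During fitting, class vectors for training rows are produced out-of-fold so a
layer cannot memorize its own labels; layer depth grows until the validation
AUC stops improving by at least ``epsilon`` (patience 1) or ``max_layers`` is
reached, and the best-scoring prefix of layers is kept.  After training,
features with zero aggregate importance across the bank are pruned.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from lpidf.io_data import ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: fixed classifier order defining the class-vector layout
DEFAULT_CLASSIFIERS = ("logistic", "xgboost", "random_forest", "extra_trees")
_TREE_BASED = {"xgboost", "random_forest", "extra_trees"}


@dataclass(frozen=True)
class ClassDistribution:
    """A two-class probability pair emitted by one (sub-)classifier."""

    p_positive: float
    p_negative: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_positive <= 1.0 and 0.0 <= self.p_negative <= 1.0):
            raise ValidationError("class probabilities must lie in [0, 1]")
        if abs(self.p_positive + self.p_negative - 1.0) > 1e-9:
            raise ValidationError("class probabilities must sum to 1")


def average_tree_distributions(
    per_tree: Sequence[ClassDistribution | tuple[float, float]],
) -> ClassDistribution:
    """Componentwise mean of per-tree class distributions.

    This is how a forest member turns its trees' votes into one class
    distribution: e.g. trees voting (0.3750, 0.6250), (0.5556, 0.4444) and
    (1.0000, 0.0000) average to (0.6435, 0.3565).
    """
    if len(per_tree) == 0:
        raise ValueError("need at least one tree distribution")
    dists = [
        d if isinstance(d, ClassDistribution) else ClassDistribution(*d)
        for d in per_tree
    ]
    p_pos = float(np.mean([d.p_positive for d in dists]))
    p_neg = float(np.mean([d.p_negative for d in dists]))
    return ClassDistribution(p_pos, p_neg)


@dataclass(frozen=True)
class CascadeConfig:
    """Cascade hyperparameters.

    Tree members default to 70 trees with a minimum of 5 samples to split;
    the gradient-boosted member and the logistic member run at library
    defaults.  ``epsilon`` is the minimum validation-AUC gain for the cascade
    to keep growing; ``oof_folds`` controls out-of-fold class-vector
    generation.  Every base classifier is seeded deterministically from
    ``seed`` via :func:`classifier_seed`.
    """

    max_layers: int = 20
    epsilon: float = 1e-3
    validation_fraction: float = 0.2
    oof_folds: int = 3
    seed: int = 0
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS
    n_trees: int = 70
    min_samples_split: int = 5
    prune: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.oof_folds < 2:
            raise ValueError("oof_folds must be >= 2")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        unknown = set(self.classifiers) - set(DEFAULT_CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifier name(s): {sorted(unknown)}")


def classifier_seed(base_seed: int, layer: int, clf_index: int, fold: int = -1) -> int:
    """Deterministic seed for one base classifier.

    ``fold=-1`` addresses the full-refit classifier of that (layer, member);
    folds 0..oof_folds-1 address the out-of-fold clones.
    """
    return (base_seed + 100003 * layer + 1009 * clf_index + fold + 1) % (2**31)


def make_base_classifier(name: str, seed: int, config: CascadeConfig):
    """Instantiate one member of the classifier bank."""
    if name == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "xgboost":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.n_trees,
            min_samples_split=config.min_samples_split,
            random_state=seed,
            n_jobs=1,
        )
    if name == "extra_trees":
        return ExtraTreesClassifier(
            n_estimators=config.n_trees,
            min_samples_split=config.min_samples_split,
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown classifier name {name!r}")


def _proba_pairs(clf, X: np.ndarray) -> np.ndarray:
    """(p_positive, p_negative) pairs from a fitted binary classifier."""
    proba = clf.predict_proba(X)
    classes = list(clf.classes_)
    pos = classes.index(1)
    neg = classes.index(0)
    return np.column_stack([proba[:, pos], proba[:, neg]])


@dataclass
class CascadeLayer:
    """One fitted cascade layer: the refitted bank plus aggregate importances.

    ``importances`` maps each of this layer's input columns to the average of
    the members' normalized importances (impurity importance for tree members,
    |coefficient| for the linear member, coefficients of constant input
    columns forced to zero since they carry no information).
    """

    classifiers: list
    names: tuple[str, ...]
    importances: np.ndarray
    n_inputs: int


def layer_class_vector(layer: CascadeLayer, X: np.ndarray) -> np.ndarray:
    """Per-sample class vector: the bank's (p_pos, p_neg) pairs concatenated.

    With four classifiers and two classes this is an 8-vector per sample;
    every adjacent (2i, 2i+1) pair sums to 1.
    """
    X = np.asarray(X, dtype=np.float64)
    if not layer.classifiers:
        raise RuntimeError("layer has no fitted classifiers")
    if X.shape[1] != layer.n_inputs:
        raise ValidationError(
            f"layer expects {layer.n_inputs} input columns, got {X.shape[1]}"
        )
    return np.hstack([_proba_pairs(clf, X) for clf in layer.classifiers])


def augment_features(X: np.ndarray, class_vecs: np.ndarray) -> np.ndarray:
    """Append class-vector columns to the original feature block.

    The original features here are always the unaugmented layer-0 input: the
    cascade re-concatenates the original d columns with the fresh class
    vector at every depth, so the width is d + 8 at every layer, never
    accumulating.
    """
    X = np.asarray(X, dtype=np.float64)
    class_vecs = np.asarray(class_vecs, dtype=np.float64)
    if X.shape[0] != class_vecs.shape[0]:
        raise ValidationError(
            f"row-count mismatch: {X.shape[0]} features vs {class_vecs.shape[0]} class vectors"
        )
    return np.hstack([X, class_vecs])


@dataclass
class CascadeModel:
    """A fitted cascade: layers, retained-feature mask and stopping metadata."""

    layers: list[CascadeLayer]
    feature_mask: np.ndarray
    stopping_record: list[dict]
    config: CascadeConfig
    n_features: int
    stop_reason: str = ""
    train_indices: np.ndarray | None = None
    validation_indices: np.ndarray | None = None

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _layer_importance(clf, name: str, X_train: np.ndarray) -> np.ndarray:
    """Normalized per-input importance for one fitted member."""
    if name in _TREE_BASED:
        imp = np.asarray(clf.feature_importances_, dtype=np.float64)
    else:
        imp = np.abs(np.asarray(clf.coef_, dtype=np.float64)).ravel()
        # a column constant in training data is uninformative; any nonzero
        # weight on it is optimizer noise absorbed by the intercept
        constant = X_train.min(axis=0) == X_train.max(axis=0)
        imp[constant] = 0.0
    total = imp.sum()
    return imp / total if total > 0 else imp


def _fit_layer(
    A_train: np.ndarray,
    y_train: np.ndarray,
    A_val: np.ndarray,
    layer_idx: int,
    config: CascadeConfig,
) -> tuple[CascadeLayer, np.ndarray, np.ndarray]:
    """Fit one layer; return it plus OOF train vectors and validation vectors.

    Training-row class vectors are produced out-of-fold (each row scored by
    classifiers that never saw it); validation rows are scored by the mean of
    the fold models, mirroring how unseen data flows through the layer.
    """
    n_train = A_train.shape[0]
    skf = StratifiedKFold(
        n_splits=config.oof_folds,
        shuffle=True,
        random_state=classifier_seed(config.seed, layer_idx, 0, fold=500000),
    )
    folds = list(skf.split(A_train, y_train))

    oof = np.zeros((n_train, 2 * len(config.classifiers)))
    val = np.zeros((A_val.shape[0], 2 * len(config.classifiers)))
    refits = []
    importances = []
    for ci, name in enumerate(config.classifiers):
        val_sum = np.zeros((A_val.shape[0], 2))
        for fi, (tr, te) in enumerate(folds):
            clf = make_base_classifier(
                name, classifier_seed(config.seed, layer_idx, ci, fold=fi), config
            )
            clf.fit(A_train[tr], y_train[tr])
            oof[te, 2 * ci : 2 * ci + 2] = _proba_pairs(clf, A_train[te])
            val_sum += _proba_pairs(clf, A_val)
        val[:, 2 * ci : 2 * ci + 2] = val_sum / len(folds)

        refit = make_base_classifier(
            name, classifier_seed(config.seed, layer_idx, ci), config
        )
        refit.fit(A_train, y_train)
        refits.append(refit)
        importances.append(_layer_importance(refit, name, A_train))

    layer = CascadeLayer(
        classifiers=refits,
        names=config.classifiers,
        importances=np.mean(importances, axis=0),
        n_inputs=A_train.shape[1],
    )
    return layer, oof, val


def fit_cascade(
    X: np.ndarray, y: np.ndarray, config: CascadeConfig | None = None
) -> CascadeModel:
    """Train a cascade deep forest on pair features X and binary labels y.

    A stratified ``validation_fraction`` share of the data is held out for
    the depth-stopping rule; layers are grown with out-of-fold class-vector
    augmentation until the held-out AUC improves by less than ``epsilon``
    over the best previous layer, or ``max_layers`` is reached.  The
    best-scoring prefix of layers is kept, and zero-importance features are
    pruned afterwards.
    """
    config = config or CascadeConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValidationError("y must contain both classes, labeled 0 and 1")
    if min(np.bincount(y)) < config.oof_folds:
        raise ValidationError(
            f"need at least oof_folds={config.oof_folds} samples of each class"
        )

    idx = np.arange(X.shape[0])
    train_idx, val_idx = train_test_split(
        idx,
        test_size=config.validation_fraction,
        stratify=y,
        random_state=config.seed % (2**31),
    )
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    layers: list[CascadeLayer] = []
    scores: list[float] = []
    A_tr, A_val = X_tr, X_val
    best_score = -np.inf
    stop_reason = "max_layers reached"
    for layer_idx in range(config.max_layers):
        layer, oof_tr, cv_val = _fit_layer(A_tr, y_tr, A_val, layer_idx, config)
        val_scores = cv_val[:, 0::2].mean(axis=1)  # mean of the p_positive columns
        score = float(roc_auc_score(y_val, val_scores))
        layers.append(layer)
        scores.append(score)
        logger.info("layer %d: validation AUC %.4f", layer_idx, score)
        if layer_idx > 0 and score < best_score + config.epsilon:
            stop_reason = (
                f"validation AUC gain below epsilon={config.epsilon} at layer {layer_idx}"
            )
            break
        best_score = max(best_score, score)
        A_tr = augment_features(X_tr, oof_tr)
        A_val = augment_features(X_val, cv_val)

    best_layer = int(np.argmax(scores))
    kept = layers[: best_layer + 1]
    record = [
        {"layer": i, "validation_auc": scores[i]} for i in range(len(kept))
    ]

    model = CascadeModel(
        layers=kept,
        feature_mask=np.ones(X.shape[1], dtype=bool),
        stopping_record=record,
        config=config,
        n_features=X.shape[1],
        stop_reason=stop_reason,
        train_indices=train_idx,
        validation_indices=val_idx,
    )
    if config.prune:
        model.feature_mask = prune_zero_importance(model)
    return model


def prune_zero_importance(model: CascadeModel) -> np.ndarray:
    """Retained-feature mask over the original input features.

    A feature's aggregate importance is the mean, over every layer, of that
    layer's bank-averaged normalized importance restricted to the original
    feature columns; features whose aggregate is exactly zero are dropped.
    At least one feature is always retained.
    """
    d = model.n_features
    agg = np.zeros(d)
    for layer in model.layers:
        agg += layer.importances[:d]
    mask = agg > 0
    if not mask.any():
        mask[0] = True
    n_dropped = d - int(mask.sum())
    if n_dropped:
        logger.info("pruned %d zero-importance feature(s) of %d", n_dropped, d)
    return mask


def predict_proba(
    model: CascadeModel, X: np.ndarray, *, return_labels: bool = False
):
    """Interaction probability per sample.

    Samples propagate through every kept layer with class-vector
    augmentation; the final score is the mean of the last layer's positive
    class probabilities across the bank.  Pruned features are zeroed before
    entering the cascade.  Hard labels (if requested) use the 0.5 threshold,
    with exact ties classified positive.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValidationError(
            f"expected {model.n_features} feature columns, got shape {X.shape}"
        )
    X0 = X * model.feature_mask
    A = X0
    cv = None
    for layer in model.layers:
        cv = layer_class_vector(layer, A)
        A = augment_features(X0, cv)
    scores = cv[:, 0::2].mean(axis=1)
    if return_labels:
        return scores, (scores >= 0.5).astype(np.int64)
    return scores


def save_model(model: CascadeModel, path) -> None:
    """Serialize a fitted cascade (layers, mask, config, schema version)."""
    with open(path, "wb") as fh:
        pickle.dump({"schema_version": SCHEMA_VERSION, "model": model}, fh)


def load_model(path) -> CascadeModel:
    """Load a serialized cascade; refuses incompatible schema versions."""
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"incompatible model schema {blob.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    return blob["model"]
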