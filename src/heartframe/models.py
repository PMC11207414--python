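"""Classifier families for frame-level PCG features.

Three lightweight families, matching what fits on an embedded target:
k-nearest neighbours (exemplar memory, distance-weighted votes), a
cubic-kernel SVM, and small fully-connected ReLU networks trained
full-batch with L-BFGS under an L2 penalty. Fourteen named presets pin
the exact hyperparameter rows used for the binary (-B) and multiclass
(-M) tasks.

All presets standardize features with statistics computed on the
training rows only.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FEATURE_NAMES


@dataclass
class ClassifierConfig:
    family: str  # 'knn' | 'svm' | 'nn'
    # knn
    k: int = 1
    distance: str = "euclidean"  # or 'cityblock'
    weight: str = "equal"  # 'equal' | 'inverse' | 'squared_inverse'
    # svm
    kernel_degree: int = 3
    box_constraint: float = 1.0
    kernel_scale: str | float = "auto"
    # nn
    layer_sizes: tuple = (100,)
    activation: str = "relu"
    l2_lambda: float = 0.0
    iteration_limit: int = 1000
    # common
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("knn", "svm", "nn"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.k < 1 or self.box_constraint <= 0 or self.l2_lambda < 0:
            raise ValueError("invalid hyperparameter value")
        if not self.layer_sizes:
            raise ValueError("layer_sizes must be non-empty")


# Named hyperparameter rows. -B presets belong to the binary
# (Normal/Pathologic) task, -M presets to the four-class task.
PRESETS: dict[str, ClassifierConfig] = {
    "k-NN1-B": ClassifierConfig(family="knn", k=1, distance="cityblock", weight="inverse"),
    "k-NN2-B": ClassifierConfig(family="knn", k=1, distance="euclidean", weight="equal"),
    "k-NN3-B": ClassifierConfig(family="knn", k=10, distance="euclidean", weight="squared_inverse"),
    "NN1-B": ClassifierConfig(family="nn", layer_sizes=(200, 100, 50), l2_lambda=4.1279e-7),
    "NN2-B": ClassifierConfig(family="nn", layer_sizes=(100, 50, 25), l2_lambda=4.1279e-7),
    "NN3-B": ClassifierConfig(family="nn", layer_sizes=(100,), l2_lambda=0.0),
    "SVM1-B": ClassifierConfig(family="svm", kernel_degree=3, box_constraint=1.0),
    "k-NN1-M": ClassifierConfig(family="knn", k=1, distance="cityblock", weight="squared_inverse"),
    "k-NN2-M": ClassifierConfig(family="knn", k=1, distance="euclidean", weight="equal"),
    "k-NN3-M": ClassifierConfig(family="knn", k=10, distance="euclidean", weight="squared_inverse"),
    "NN1-M": ClassifierConfig(family="nn", layer_sizes=(200, 100, 50), l2_lambda=1.612e-7),
    "NN2-M": ClassifierConfig(family="nn", layer_sizes=(200, 50, 50), l2_lambda=0.0),
    "NN3-M": ClassifierConfig(family="nn", layer_sizes=(100, 50, 25), l2_lambda=1.612e-7),
    "SVM1-M": ClassifierConfig(family="svm", kernel_degree=3, box_constraint=1.0),
}


@dataclass
class StandardizeStats:
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class TrainedModel:
    config: ClassifierConfig
    estimator: object
    stats: StandardizeStats | None
    classes: list
    feature_names: list = field(default_factory=lambda: list(FEATURE_NAMES))

    @property
    def size_bytes(self) -> int:
        return model_size_bytes(self)


def _feature_matrix(table: pd.DataFrame, feature_names) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing[:5]}")
    return table[list(feature_names)].to_numpy(dtype=float)


def standardize_fit(train_table: pd.DataFrame, feature_names=FEATURE_NAMES) -> StandardizeStats:
    """Per-feature mean/SD from training rows only."""
    x = _feature_matrix(train_table, feature_names)
    if len(x) == 0:
        raise ValueError("empty training table")
    return StandardizeStats(mean=x.mean(axis=0), sd=x.std(axis=0, ddof=1))


def standardize_apply(stats: StandardizeStats, x: np.ndarray) -> np.ndarray:
    """z-score with training statistics; constant features map to 0."""
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    z = (x - stats.mean) / sd
    z[:, stats.sd == 0] = 0.0
    return z


def _inverse_power_weights(distances: np.ndarray, power: int) -> np.ndarray:
    # a zero-distance neighbour takes the whole vote (limit of 1/d^p)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.asarray(distances, dtype=float) ** power
    zero_rows = np.isinf(w).any(axis=-1)
    if np.any(zero_rows):
        w[zero_rows] = np.isinf(w[zero_rows]).astype(float)
    return w


def _inverse_weight(distances):
    return _inverse_power_weights(distances, 1)


def _squared_inverse_weight(distances):
    return _inverse_power_weights(distances, 2)


def _knn_weight_fn(kind: str):
    return {
        "equal": "uniform",
        "inverse": _inverse_weight,
        "squared_inverse": _squared_inverse_weight,
    }[kind]


def _median_pairwise_distance(x: np.ndarray, seed: int, max_rows: int = 500) -> float:
    """Kernel-scale heuristic: median Euclidean pairwise distance on a
    (sub)sample of the standardized training rows."""
    rng = np.random.default_rng(seed)
    if len(x) > max_rows:
        x = x[rng.choice(len(x), size=max_rows, replace=False)]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(len(x), k=1)
    med = float(np.median(np.sqrt(d2[iu])))
    return med if med > 0 else 1.0


def _build_estimator(config: ClassifierConfig, x: np.ndarray):
    if config.family == "knn":
        metric = {"cityblock": "manhattan", "euclidean": "euclidean"}[config.distance]
        return KNeighborsClassifier(
            n_neighbors=config.k, metric=metric, weights=_knn_weight_fn(config.weight)
        )
    if config.family == "svm":
        if config.kernel_scale == "auto":
            scale = _median_pairwise_distance(x, config.seed)
        else:
            scale = float(config.kernel_scale)
        # scaled polynomial kernel ((x/s)·(y/s) + 1)^3
        return SVC(
            kernel="poly",
            degree=config.kernel_degree,
            gamma=1.0 / scale**2,
            coef0=1.0,
            C=config.box_constraint,
            probability=True,
            random_state=config.seed,
        )
    return MLPClassifier(
        hidden_layer_sizes=config.layer_sizes,
        activation=config.activation,
        solver="lbfgs",
        alpha=config.l2_lambda,
        max_iter=config.iteration_limit,
        random_state=config.seed,
    )


def train(config: ClassifierConfig | str, train_table: pd.DataFrame) -> TrainedModel:
    """Fit a classifier (config object or preset name) on a feature table."""
    if isinstance(config, str):
        config = PRESETS[config]
    labels = train_table["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("training table must contain at least 2 classes")
    x = _feature_matrix(train_table, FEATURE_NAMES)
    stats = None
    if config.standardize:
        stats = standardize_fit(train_table)
        x = standardize_apply(stats, x)
    est = _build_estimator(config, x)
    est.fit(x, labels)
    return TrainedModel(
        config=config, estimator=est, stats=stats, classes=list(est.classes_)
    )


def _prepare(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    x = _feature_matrix(table, model.feature_names)
    if model.stats is not None:
        x = standardize_apply(model.stats, x)
    return x


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Predicted class label per row."""
    return model.estimator.predict(_prepare(model, table))


def predict_scores(model: TrainedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-class scores (each row sums to 1), columns = class names."""
    proba = model.estimator.predict_proba(_prepare(model, table))
    return pd.DataFrame(proba, columns=model.classes)


def cross_validate(
    config: ClassifierConfig | str, table: pd.DataFrame, folds: int = 10, seed: int = 0
) -> dict:
    """Stratified k-fold CV accuracy; standardization refit per fold."""
    from .dataset import stratified_fold_indices

    if isinstance(config, str):
        config = PRESETS[config]
    assignment = stratified_fold_indices(table["label"], folds=folds, seed=seed)
    accs = []
    for fold in range(folds):
        train_part = table[assignment != fold].reset_index(drop=True)
        val_part = table[assignment == fold].reset_index(drop=True)
        model = train(config, train_part)
        pred = predict(model, val_part)
        accs.append(float(np.mean(pred == val_part["label"].to_numpy())))
    return {
        "fold_accuracy": accs,
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)),
    }


def model_size_bytes(model: TrainedModel) -> int:
    """Byte length of the canonical pickled form (informational)."""
    return len(pickle.dumps(model, protocol=pickle.HIGHEST_PROTOCOL))


def save_model(model: TrainedModel, path):
    """Serialize a trained model (versioned pickle blob)."""
    blob = {"format": "heartframe-model", "version": 1, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(blob, fh, protocol=pickle.HIGHEST_PROTOCOL)
    return path


def load_model(path) -> TrainedModel:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if not (isinstance(blob, dict) and blob.get("format") == "heartframe-model"):
        raise ValueError(f"{path} is not a heartframe model file")
    return blob["model"]
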