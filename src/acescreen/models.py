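"""The four classifier families behind one fit/predict-probability surface.

Families and their defaults (the configurations used for the screening
task; all of them consume the 26-dimensional PseAAC features):

- ``gradient_boosted_trees`` (XGBoost): learning_rate 0.01, n_estimators
  1000, max_depth 4, min_child_weight 1, gamma 0, subsample 0.8.
- ``rbf_svm``: RBF kernel, C 1.0, gamma 0.001. Probability calibration
  (Platt scaling) is enabled so the uniform 0.5 decision threshold
  applies to this family too.
- ``random_forest``: n_estimators 80, max_depth 13, min_samples_split
  150, min_samples_leaf 15, max_features 7, oob_score True,
  random_state 10.
- ``knn``: K = 5; the predicted probability is the fraction of positive
  neighbors among the K nearest (distance ties broken by training input
  order, scikit-learn's behavior).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

FAMILIES = ("gradient_boosted_trees", "rbf_svm", "random_forest", "knn")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "gradient_boosted_trees": {
        "learning_rate": 0.01,
        "n_estimators": 1000,
        "max_depth": 4,
        "min_child_weight": 1,
        "gamma": 0,
        "subsample": 0.8,
    },
    "rbf_svm": {"C": 1.0, "gamma": 0.001},
    "random_forest": {
        "n_estimators": 80,
        "max_depth": 13,
        "min_samples_split": 150,
        "min_samples_leaf": 15,
        "max_features": 7,
        "oob_score": True,
        "random_state": 10,
    },
    "knn": {"n_neighbors": 5},
}


class ConfigError(ValueError):
    """Unknown family or hyperparameter key."""


class FitError(ValueError):
    """The training inputs cannot produce a valid binary classifier."""


@dataclass(frozen=True)
class ModelConfig:
    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; valid: {FAMILIES}")
        valid = set(_DEFAULTS[self.family])
        bad = set(self.hyperparameters) - valid
        if bad:
            raise ConfigError(
                f"unknown hyperparameter(s) {sorted(bad)} for family {self.family!r}; "
                f"valid keys: {sorted(valid)}"
            )


def make_config(
    family: str,
    overrides: Optional[Mapping[str, Any]] = None,
    seed: Optional[int] = None,
) -> ModelConfig:
    """Build a config with the family's default hyperparameters plus overrides."""
    params = dict(_DEFAULTS.get(family, {}))
    overrides = dict(overrides or {})
    cfg = ModelConfig(family=family, hyperparameters={**params, **overrides}, seed=seed)
    return cfg


@dataclass
class FittedModel:
    config: ModelConfig
    feature_dimension: int
    training_fingerprint: str
    estimator: Any

    def __repr__(self) -> str:  # estimator reprs are huge
        return (
            f"FittedModel(family={self.config.family!r}, "
            f"dim={self.feature_dimension}, fp={self.training_fingerprint[:12]})"
        )


def _build_estimator(config: ModelConfig) -> Any:
    hp = config.hyperparameters
    if config.family == "gradient_boosted_trees":
        return XGBClassifier(
            **hp,
            objective="binary:logistic",
            random_state=config.seed if config.seed is not None else 0,
            n_jobs=1,
            verbosity=0,
        )
    if config.family == "rbf_svm":
        # Platt-style sigmoid calibration over the SVM decision values, so
        # the uniform probability threshold applies to this family too.
        # (libsvm's built-in probability estimates degenerate when decision
        # values are small, as they are on these features.)
        svc = SVC(
            **hp,
            kernel="rbf",
            random_state=config.seed if config.seed is not None else 0,
        )
        return CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    if config.family == "random_forest":
        hp = dict(hp)
        if config.seed is not None:
            hp["random_state"] = config.seed
        return RandomForestClassifier(**hp, n_jobs=1)
    if config.family == "knn":
        return KNeighborsClassifier(**hp)
    raise ConfigError(f"unknown family {config.family!r}")


def _fingerprint(X: np.ndarray, y: np.ndarray, seed: Optional[int]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.int64).tobytes())
    h.update(str(seed).encode())
    return h.hexdigest()


def fit(config: ModelConfig, features: np.ndarray, labels: np.ndarray) -> FittedModel:
    """Fit a binary classifier; deterministic given config.seed and inputs.

    Missing feature values (NaN) are accepted only by the gradient-boosted
    family, whose trees learn a default split direction for them.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise FitError(f"features must be a 2-D matrix, got shape {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise FitError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    if X.shape[0] < 2:
        raise FitError("need at least 2 training instances")
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError(f"training labels contain a single class ({classes.tolist()})")
    if not set(classes.tolist()) <= {0, 1}:
        raise FitError(f"labels must be binary 0/1, got classes {classes.tolist()}")
    if np.isnan(X).any() and config.family != "gradient_boosted_trees":
        raise FitError(f"family {config.family!r} does not accept missing feature values")
    est = _build_estimator(config)
    est.fit(X, y)
    return FittedModel(
        config=config,
        feature_dimension=X.shape[1],
        training_fingerprint=_fingerprint(X, y, config.seed),
        estimator=est,
    )


def predict_proba(model: FittedModel, features: np.ndarray) -> np.ndarray:
    """Positive-class probability for each feature row, in [0, 1]."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.feature_dimension:
        raise ValueError(
            f"feature width {X.shape[1]} != model dimension {model.feature_dimension}"
        )
    proba = model.estimator.predict_proba(X)
    pos_col = list(model.estimator.classes_).index(1)
    out = np.asarray(proba[:, pos_col], dtype=float)
    return np.clip(out, 0.0, 1.0)
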