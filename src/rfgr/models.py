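"""Downstream classifier zoo: LR, SVM, GNB, RF, GRU, LSTM.

Default hyperparameters are pinned to the study configuration: logistic
regression with max_iter=100 and C=1.0, SVM capped at max_iter=500,
Gaussian naive Bayes with var_smoothing=1e-9, a 100-tree forest of depth
<= 100, and 64-unit recurrent nets trained 10 epochs with cross-entropy
and Adam.  The recurrent models treat a d-wide feature row as a length-d
univariate sequence, mirroring the 178-step treatment of raw segments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .recurrent import RecurrentClassifier

MODEL_NAMES = ("lr", "svm", "gnb", "rf", "gru", "lstm")


class SpecError(ValueError):
    """Unknown model name or invalid hyperparameter set."""


class CapabilityError(RuntimeError):
    """The fitted model does not support the requested operation."""


class DegenerateLabelsError(ValueError):
    """Fit called with fewer than two classes."""


_DEFAULTS: dict[str, dict] = {
    "lr": {"max_iter": 100, "C": 1.0},
    "svm": {"max_iter": 500, "kernel": "rbf", "probability": False},
    "gnb": {"var_smoothing": 1e-9},
    "rf": {"max_depth": 100, "n_estimators": 100},
    "gru": {"units": 64, "dropout": 0.2, "epochs": 10, "batch_size": 64,
            "learning_rate": 3e-3},
    "lstm": {"units": 64, "dropout": 0.2, "epochs": 10, "batch_size": 64,
             "learning_rate": 3e-3},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A model family name plus its hyperparameters and seed."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise SpecError(f"unknown model {self.name!r}; known: {MODEL_NAMES}")
        unknown = set(self.hyperparameters) - set(_DEFAULTS[self.name])
        if unknown:
            raise SpecError(f"unknown hyperparameters for {self.name}: {sorted(unknown)}")

    @property
    def resolved(self) -> dict:
        """Defaults overlaid with any explicit overrides."""
        return {**_DEFAULTS[self.name], **self.hyperparameters}


def default_specs(seed: int = 0) -> dict[str, ClassifierSpec]:
    """One default spec per model family."""
    return {name: ClassifierSpec(name, seed=seed) for name in MODEL_NAMES}


def make_classifier(spec: ClassifierSpec, input_width: int | None = None):
    """Instantiate an unfitted model handle from a spec."""
    hp = spec.resolved
    if spec.name == "lr":
        return LogisticRegression(
            max_iter=hp["max_iter"], C=hp["C"], random_state=spec.seed
        )
    if spec.name == "svm":
        return SVC(
            max_iter=hp["max_iter"], kernel=hp["kernel"],
            probability=hp["probability"], random_state=spec.seed,
        )
    if spec.name == "gnb":
        return GaussianNB(var_smoothing=hp["var_smoothing"])
    if spec.name == "rf":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            random_state=spec.seed,
        )
    # gru / lstm over a length-d univariate sequence
    return RecurrentClassifier(
        cell=spec.name, units=hp["units"], dropout=hp["dropout"],
        epochs=hp["epochs"], batch_size=hp["batch_size"],
        learning_rate=hp["learning_rate"], seed=spec.seed,
    )


@dataclass
class FittedClassifier:
    """A fitted model with its spec, class order, and input width."""

    spec: ClassifierSpec
    model: object
    classes_: np.ndarray
    input_width: int

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_width:
            raise ValueError(
                f"feature width {X.shape[-1] if X.ndim == 2 else '?'} does not "
                f"match fit width {self.input_width}"
            )
        return X

    @property
    def supports_proba(self) -> bool:
        if self.spec.name == "svm" and not self.spec.resolved["probability"]:
            return False
        return True


def fit(model, features: np.ndarray, labels, spec: ClassifierSpec | None = None) -> FittedClassifier:
    """Fit an unfitted handle; deterministic for a given spec seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on row count")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("need at least 2 classes to fit")
    model = copy.deepcopy(model)
    model.fit(X, y)
    if spec is None:
        spec = _infer_spec(model)
    return FittedClassifier(spec, model, np.asarray(model.classes_), X.shape[1])


def _infer_spec(model) -> ClassifierSpec:
    for name, cls in (
        ("lr", LogisticRegression), ("svm", SVC), ("gnb", GaussianNB),
        ("rf", RandomForestClassifier),
    ):
        if isinstance(model, cls):
            return ClassifierSpec(name)
    if isinstance(model, RecurrentClassifier):
        return ClassifierSpec(model.cell)
    raise SpecError(f"cannot infer spec for {type(model).__name__}")


def fit_spec(spec: ClassifierSpec, features: np.ndarray, labels) -> FittedClassifier:
    """Convenience: instantiate from spec and fit."""
    X = np.asarray(features, dtype=float)
    return fit(make_classifier(spec, X.shape[1]), X, labels, spec=spec)


def predict(fitted: FittedClassifier, features: np.ndarray) -> np.ndarray:
    """Predicted codes, ties broken toward the lowest code."""
    X = fitted._check(features)
    if X.shape[0] == 0:
        return np.empty(0, dtype=fitted.classes_.dtype)
    if fitted.supports_proba:
        proba = predict_proba(fitted, X)
        return fitted.classes_[np.argmax(proba, axis=1)]
    return np.asarray(fitted.model.predict(X))


def predict_proba(fitted: FittedClassifier, features: np.ndarray) -> np.ndarray:
    """n x K class-probability matrix in ascending class-code order."""
    if not fitted.supports_proba:
        raise CapabilityError(
            "this SVM was configured margin-only (probability=False); "
            "refit with probability=True for probability output"
        )
    X = fitted._check(features)
    if X.shape[0] == 0:
        return np.empty((0, fitted.classes_.size))
    return np.asarray(fitted.model.predict_proba(X))


def save_classifier(fitted: FittedClassifier, path: str | Path) -> Path:
    """Persist a fitted classifier (spec + seed + state) to one file."""
    path = Path(path)
    joblib.dump(fitted, path)
    return path


def load_classifier(path: str | Path) -> FittedClassifier:
    fitted = joblib.load(path)
    if not isinstance(fitted, FittedClassifier):
        raise SpecError(f"{path} does not contain a fitted classifier bundle")
    return fitted
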