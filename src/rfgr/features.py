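"""Transfer-feature fusion: forest class probabilities + recurrent features.

The method turns raw 178-sample EEG segments into a compact "transfer"
feature set consumed by downstream classifiers:

* a random forest of T trees is fitted on the segments and its averaged
  per-tree leaf class frequencies

      P_hat(y_j | x_i) = (1/T) * sum_t P_t(y_j | x_i)

  become K probability features per segment;
* a gated recurrent unit reads each segment as a 178-step univariate
  sequence and contributes either its K-class probability head or its
  final hidden state;
* the two blocks are concatenated into columns f1..fd.

Training-set forest probabilities are *cross-fitted*: the train split is
partitioned into ``cross_fit_folds`` stratified folds and each fold is
scored by a forest refitted on its complement, so no row is ever scored
by a forest that saw it.  Features for held-out data come from extractors
fitted on the training split only, and never depend on held-out labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .data import SegmentDataset
from .recurrent import RecurrentClassifier
from .recurrent import count_trainable_parameters as _count_params

FEATURE_MODES = ("rf_probs", "gru_probs", "fused", "fused_hidden")


class DegenerateLabelsError(ValueError):
    """Training data contains fewer than two classes."""


@dataclass(frozen=True)
class RFGRConfig:
    """All knobs of the fusion method."""

    n_trees: int = 100
    max_depth: int = 100
    n_classes: int = 5
    recurrent_units: int = 64
    dropout_rate: float = 0.2
    epochs: int = 10
    batch_size: int = 64
    feature_mode: str = "fused"
    cross_fit_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.cross_fit_folds < 2:
            raise ValueError("cross_fit_folds must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")

    def with_(self, **kw) -> "RFGRConfig":
        return replace(self, **kw)


def _as_xy(data: SegmentDataset | np.ndarray):
    if isinstance(data, SegmentDataset):
        return data.X, data.y
    return np.asarray(data, dtype=float), None


# ---------------------------------------------------------------------------
# Forest probability features
# ---------------------------------------------------------------------------

class ProbabilityFeatureExtractor:
    """Fitted forest whose averaged leaf class frequencies are features."""

    def __init__(self, forest: RandomForestClassifier):
        self.forest = forest
        #: fixed class order of the probability columns (ascending code)
        self.class_order = forest.classes_.astype(int)
        self.n_features_in_ = forest.n_features_in_

    @property
    def trees(self):
        """The individual fitted decision trees (for traversal checks)."""
        return self.forest.estimators_

    def per_tree_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(T, n, K) per-tree leaf class-frequency tables for each row."""
        X = self._check_width(X)
        return np.stack([t.predict_proba(X) for t in self.trees])

    def _check_width(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[-1] if X.ndim else 0} does not match "
                f"training width {self.n_features_in_}"
            )
        return X


def fit_probability_extractor(
    train: SegmentDataset | np.ndarray,
    config: RFGRConfig,
    labels: Sequence[int] | None = None,
) -> ProbabilityFeatureExtractor:
    """Fit a forest of exactly ``n_trees`` bootstrap trees on the train split."""
    X, y = _as_xy(train)
    if labels is not None:
        y = np.asarray(labels)
    if len(X) == 0:
        raise ValueError("training data is empty")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training data contains a single class")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
    )
    forest.fit(X, y)
    return ProbabilityFeatureExtractor(forest)


def probability_features(
    extractor: ProbabilityFeatureExtractor, segments: SegmentDataset | np.ndarray
) -> np.ndarray:
    """n x K matrix of forest-averaged class probabilities (rows sum to 1)."""
    X, _ = _as_xy(segments)
    X = extractor._check_width(X)
    if len(X) == 0:
        return np.empty((0, extractor.class_order.size))
    return extractor.forest.predict_proba(X)


# ---------------------------------------------------------------------------
# Recurrent temporal features
# ---------------------------------------------------------------------------

class TemporalFeatureExtractor:
    """Fitted recurrent network exposing probability and hidden-state heads."""

    def __init__(self, network: RecurrentClassifier):
        self.network = network
        self.class_order = network.classes_.astype(int)

    @property
    def n_features_in_(self) -> int:
        return int(self.network.mean_.shape[0])


def fit_temporal_extractor(
    train: SegmentDataset | np.ndarray,
    config: RFGRConfig,
    labels: Sequence[int] | None = None,
    cell: str = "gru",
) -> TemporalFeatureExtractor:
    """Train the recurrent extractor on the train split only.

    Each segment is a univariate sequence; inputs are z-scored per time
    step by training statistics before entering the recurrence.
    """
    X, y = _as_xy(train)
    if labels is not None:
        y = np.asarray(labels)
    if len(X) == 0:
        raise ValueError("training data is empty")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training data contains a single class")
    net = RecurrentClassifier(
        cell=cell,
        units=config.recurrent_units,
        dropout=config.dropout_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=config.seed,
        standardize=True,
    )
    net.fit(X, y)
    return TemporalFeatureExtractor(net)


def temporal_features(
    extractor: TemporalFeatureExtractor,
    segments: SegmentDataset | np.ndarray,
    head: str = "probs",
) -> np.ndarray:
    """Recurrent features: ``head="probs"`` (n x K) or ``"hidden"`` (n x units)."""
    X, _ = _as_xy(segments)
    if head == "probs":
        return extractor.network.predict_proba(X)
    if head == "hidden":
        return np.asarray(extractor.network.decision_hidden(X), dtype=float)
    raise ValueError(f"unknown head {head!r}")


def count_trainable_parameters(
    config: RFGRConfig, cell: str = "gru", input_dim: int = 1
) -> list[tuple[str, int]]:
    """Per-layer parameter counts of the recurrent extractor architecture."""
    return _count_params(config.recurrent_units, input_dim, config.n_classes, cell)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

@dataclass
class TransferFeatureSet:
    """The n x d fused feature matrix with provenance-tagged columns."""

    X: np.ndarray
    feature_names: list[str]
    provenance: list[str]
    y: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        if self.y is not None:
            df["y"] = self.y
        return df

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def _assemble(
    rf_probs: np.ndarray,
    gru_feats: np.ndarray,
    class_order: np.ndarray,
    mode: str,
    gru_head: str,
    y: np.ndarray | None,
) -> TransferFeatureSet:
    blocks, prov = [], []
    if mode in ("rf_probs", "fused", "fused_hidden"):
        blocks.append(rf_probs)
        prov += [f"rf_prob:{c}" for c in class_order]
    if mode in ("gru_probs", "fused", "fused_hidden"):
        blocks.append(gru_feats)
        if gru_head == "probs":
            prov += [f"gru_prob:{c}" for c in class_order]
        else:
            prov += [f"gru_hidden:{u}" for u in range(gru_feats.shape[1])]
    X = np.concatenate(blocks, axis=1)
    names = [f"f{i + 1}" for i in range(X.shape[1])]
    return TransferFeatureSet(X, names, prov, y)


def crossfit_probability_features(
    X: np.ndarray, y: np.ndarray, config: RFGRConfig
) -> np.ndarray:
    """Out-of-fold forest probabilities for the rows the forest trains on.

    Stratified ``cross_fit_folds``-fold partition; each fold is scored by
    a forest refitted on the complement, so own-row memorization cannot
    leak into the features.
    """
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
    )
    cv = StratifiedKFold(
        n_splits=config.cross_fit_folds, shuffle=True, random_state=config.seed
    )
    return cross_val_predict(clone(forest), X, y, cv=cv, method="predict_proba")


def generate_transfer_features(
    train: SegmentDataset,
    apply_to: SegmentDataset | None,
    config: RFGRConfig,
) -> tuple[TransferFeatureSet, TransferFeatureSet | None, dict]:
    """Fit both extractors on ``train`` and emit fused features.

    Returns ``(train_features, apply_features, extractors)``.  The
    train-side forest block is cross-fitted; ``apply_to`` rows are scored
    by direct application of extractors that never saw them (their labels
    are not consulted at all).
    """
    if len(train) == 0:
        raise ValueError("training data is empty")
    gru_head = "hidden" if config.feature_mode == "fused_hidden" else "probs"

    prob_ext = fit_probability_extractor(train, config)
    need_gru = config.feature_mode != "rf_probs"
    temp_ext = fit_temporal_extractor(train, config) if need_gru else None
    class_order = prob_ext.class_order

    if config.feature_mode == "rf_probs":
        train_rf = crossfit_probability_features(train.X, train.y, config)
        train_gru = np.empty((len(train), 0))
    else:
        train_rf = crossfit_probability_features(train.X, train.y, config)
        train_gru = temporal_features(temp_ext, train, gru_head)
    train_fs = _assemble(
        train_rf, train_gru, class_order, config.feature_mode, gru_head, train.y
    )

    apply_fs = None
    if apply_to is not None:
        apply_rf = probability_features(prob_ext, apply_to)
        apply_gru = (
            temporal_features(temp_ext, apply_to, gru_head)
            if need_gru
            else np.empty((len(apply_to), 0))
        )
        apply_fs = _assemble(
            apply_rf, apply_gru, class_order, config.feature_mode, gru_head,
            apply_to.y if len(apply_to) else None,
        )

    extractors = {"probability": prob_ext, "temporal": temp_ext}
    return train_fs, apply_fs, extractors
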