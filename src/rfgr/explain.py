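"""Post-hoc explanation: feature-importance ranking and tree export.

Two importance methods are provided:

* ``shapley`` — exact Shapley values of the model's probability output
  under the interventional value function, computed by enumerating all
  2^d feature subsets against a background sample.  Exact enumeration is
  feasible because transfer feature sets are narrow (d <= 16 enforced);
  for wide raw-feature inputs use permutation importance instead.
* ``permutation`` — mean held-out accuracy drop over m seeded
  permutations of each column (model-agnostic).

Importance scores aggregate attributions as the mean of |value| over
evaluation rows and classes, reported in descending order.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .features import ProbabilityFeatureExtractor, TransferFeatureSet
from .models import CapabilityError, FittedClassifier, predict, predict_proba

_MAX_EXACT_FEATURES = 16


@dataclass
class ImportanceReport:
    """Ranked (feature, score) pairs, non-increasing in score."""

    entries: list[tuple[str, float]]
    method: str

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(not np.isfinite(s) for s in scores):
            raise ValueError("importance scores must be finite")
        self.entries = sorted(self.entries, key=lambda e: -e[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "importance"])


def exact_shapley_values(
    predict_fn, X_explain: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley values by subset enumeration.

    ``predict_fn`` maps an (m, d) matrix to (m, K) outputs.  Returns
    ``(phi, base)`` with ``phi`` of shape (n, d, K) and ``base`` the
    mean background prediction (K,).  Satisfies the efficiency identity
    ``base + phi.sum(axis=1) == predict_fn(X_explain)``.
    """
    X_explain = np.asarray(X_explain, dtype=float)
    background = np.asarray(background, dtype=float)
    d = X_explain.shape[1]
    if d > _MAX_EXACT_FEATURES:
        raise CapabilityError(
            f"exact Shapley enumeration supports at most {_MAX_EXACT_FEATURES} "
            f"features (got {d}); use method='permutation'"
        )
    n_subsets = 1 << d
    masks = (
        (np.arange(n_subsets)[:, None] >> np.arange(d)[None, :]) & 1
    ).astype(bool)  # (S, d)
    sizes = masks.sum(axis=1)
    # Shapley kernel weight for adding one feature to a subset of given size
    w = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    B = background.shape[0]
    phis = []
    base = None
    for x in X_explain:
        hybrid = np.where(masks[:, None, :], x[None, None, :], background[None, :, :])
        v = predict_fn(hybrid.reshape(n_subsets * B, d)).reshape(n_subsets, B, -1).mean(axis=1)
        if base is None:
            base = v[0]
        phi = np.zeros((d, v.shape[1]))
        for i in range(d):
            without = ~masks[:, i]
            idx_wo = np.nonzero(without)[0]
            idx_wi = idx_wo | (1 << i)
            phi[i] = (w[sizes[idx_wo]][:, None] * (v[idx_wi] - v[idx_wo])).sum(axis=0)
        phis.append(phi)
    return np.stack(phis), base


def _resolve_features(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, TransferFeatureSet):
        return features.X, list(features.feature_names)
    X = np.asarray(features, dtype=float)
    return X, [f"f{i + 1}" for i in range(X.shape[1])]


def transfer_feature_importance(
    fitted: FittedClassifier,
    features,
    labels,
    method: str = "shapley",
    seed: int = 0,
    n_repeats: int = 20,
    n_explain: int = 50,
    n_background: int = 20,
) -> ImportanceReport:
    """Rank features by their contribution to the fitted model's output.

    ``features`` may be a :class:`TransferFeatureSet` or a plain matrix.
    Shapley scores are mean |attribution| over explained rows and
    classes; permutation scores are the mean accuracy drop over
    ``n_repeats`` seeded column permutations.
    """
    X, names = _resolve_features(features)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)

    if method == "shapley":
        if not fitted.supports_proba:
            raise CapabilityError("shapley explanation needs probability output")
        explain_idx = rng.choice(len(X), size=min(n_explain, len(X)), replace=False)
        bg_idx = rng.choice(len(X), size=min(n_background, len(X)), replace=False)
        phi, _ = exact_shapley_values(
            lambda m: predict_proba(fitted, m), X[explain_idx], X[bg_idx]
        )
        scores = np.abs(phi).mean(axis=(0, 2))
    elif method == "permutation":
        base_acc = float((predict(fitted, X) == y).mean())
        scores = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            drops = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(X)), j]
                drops.append(base_acc - float((predict(fitted, Xp) == y).mean()))
            scores[j] = float(np.mean(drops))
    else:
        raise CapabilityError(f"unknown importance method {method!r}")

    return ImportanceReport(list(zip(names, map(float, scores))), method)


# ---------------------------------------------------------------------------
# Decision-tree export
# ---------------------------------------------------------------------------

@dataclass
class TreeExport:
    """Structured description of one decision tree of a fitted forest.

    ``nodes[i]`` holds: feature (name or None at leaves), threshold,
    children ids, training-sample count, and the class-count vector —
    enough to re-derive any sample's leaf by hand.
    """

    nodes: list[dict]
    class_codes: list[int]
    feature_names: list[str]

    def traverse(self, x: np.ndarray) -> int:
        """Walk a sample from the root; returns the leaf node id."""
        x = np.asarray(x, dtype=float)
        i = 0
        while self.nodes[i]["feature"] is not None:
            node = self.nodes[i]
            j = self.feature_names.index(node["feature"])
            i = node["left"] if x[j] <= node["threshold"] else node["right"]
        return i

    def leaf_distribution(self, x: np.ndarray) -> np.ndarray:
        """Class-frequency vector of the leaf the sample lands in."""
        counts = np.asarray(self.nodes[self.traverse(x)]["class_counts"], dtype=float)
        return counts / counts.sum()

    def to_text(self, max_depth: int | None = None) -> str:
        lines: list[str] = []

        def walk(i: int, depth: int) -> None:
            node = self.nodes[i]
            pad = "  " * depth
            if max_depth is not None and depth > max_depth:
                lines.append(f"{pad}...")
                return
            if node["feature"] is None:
                counts = node["class_counts"]
                lines.append(f"{pad}leaf#{i} counts={counts}")
            else:
                lines.append(
                    f"{pad}node#{i} if {node['feature']} <= {node['threshold']:.6g}"
                )
                walk(node["left"], depth + 1)
                lines.append(f"{pad}else  # {node['feature']} > {node['threshold']:.6g}")
                walk(node["right"], depth + 1)

        walk(0, 0)
        return "\n".join(lines)


def export_decision_tree(
    forest,
    tree_index: int = 0,
    feature_names: list[str] | None = None,
) -> TreeExport:
    """Export one tree of a fitted forest as a node/edge structure.

    ``forest`` may be a :class:`ProbabilityFeatureExtractor`, a
    :class:`FittedClassifier` wrapping a random forest, or a bare
    sklearn forest.
    """
    if isinstance(forest, ProbabilityFeatureExtractor):
        rf = forest.forest
    elif isinstance(forest, FittedClassifier):
        rf = forest.model
    else:
        rf = forest
    if not hasattr(rf, "estimators_"):
        raise CapabilityError("tree export needs a fitted forest model")
    if not 0 <= tree_index < len(rf.estimators_):
        raise IndexError(
            f"tree index {tree_index} out of range [0, {len(rf.estimators_)})"
        )
    tree = rf.estimators_[tree_index].tree_
    if feature_names is None:
        feature_names = [f"f{i + 1}" for i in range(rf.n_features_in_)]
    # sklearn stores per-node class distributions normalized; recover counts
    counts = tree.value[:, 0, :] * tree.weighted_n_node_samples[:, None]
    nodes = []
    for i in range(tree.node_count):
        leaf = tree.children_left[i] == -1
        nodes.append(
            {
                "feature": None if leaf else feature_names[tree.feature[i]],
                "threshold": None if leaf else float(tree.threshold[i]),
                "left": int(tree.children_left[i]),
                "right": int(tree.children_right[i]),
                "n_samples": int(tree.n_node_samples[i]),
                "class_counts": [float(c) for c in counts[i]],
            }
        )
    return TreeExport(nodes, [int(c) for c in rf.classes_], list(feature_names))
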