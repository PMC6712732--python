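"""Three-node hierarchical linear-SVM behaviour classifier.

Node 1 separates static from dynamic behaviour using posture and
movement intensity; node 2 splits static windows into vigilance and
resting on posture alone; node 3 splits dynamic windows into foraging
and running using intensity and periodicity.  Each node is a binary
maximum-margin linear separator (hinge loss, penalty C) trained on
z-standardised features; standardisation parameters are estimated from
training windows only and stored with the node.

The SMO solver behind scikit-learn's ``SVC(kernel="linear")`` is
deterministic given the data, so retraining on identical input yields
identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .core import BEHAVIOURS, DYNAMIC_BEHAVIOURS, STATIC_BEHAVIOURS, ValidationError

__all__ = ["NodeModel", "HierarchyModel", "train_node", "train_hierarchy", "predict"]

#: Node wiring: which descriptor feeds which node.
NODE_DESCRIPTORS: dict[int, tuple[str, ...]] = {
    1: ("posture", "intensity"),
    2: ("posture",),
    3: ("intensity", "periodicity"),
}

@dataclass
class NodeModel:
    """One trained binary linear separator of the hierarchy."""

    index: int
    feature_names: tuple[str, ...]
    weights: np.ndarray  # in standardised feature space
    bias: float
    mean: np.ndarray  # per-feature training mean
    sd: np.ndarray  # per-feature training SD
    class_map: dict[int, str]  # {-1: ..., +1: ...}

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Signed distance-like score; positive → ``class_map[+1]``."""
        Z = (np.asarray(X, dtype=float) - self.mean) / self.sd
        return Z @ self.weights + self.bias

    def classify(self, X: np.ndarray) -> np.ndarray:
        d = self.decision(X)
        return np.where(d >= 0, self.class_map[1], self.class_map[-1]).astype(object)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "class_map": {str(k): v for k, v in self.class_map.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "NodeModel":
        return NodeModel(
            index=int(d["index"]),
            feature_names=tuple(d["feature_names"]),
            weights=np.array(d["weights"], dtype=float),
            bias=float(d["bias"]),
            mean=np.array(d["mean"], dtype=float),
            sd=np.array(d["sd"], dtype=float),
            class_map={int(k): v for k, v in d["class_map"].items()},
        )


def train_node(fm: pd.DataFrame, node_index: int, binary_labels: np.ndarray,
               feature_names: tuple[str, ...], C: float = 1.0) -> NodeModel:
    """Train one node's linear max-margin separator.

    ``binary_labels`` holds exactly two label values.  Features are
    z-standardised on the training rows; the learned hyperplane lives in
    that standardised space.
    """
    classes = sorted(set(binary_labels.tolist()))
    if len(classes) != 2:
        raise ValidationError(
            f"node {node_index} needs exactly two classes, got {classes}")
    X = fm.loc[:, list(feature_names)].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - mean) / sd
    clf = SVC(kernel="linear", C=C, tol=1e-6)
    clf.fit(Z, np.asarray(binary_labels, dtype=object).astype(str))
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    if not np.any(w != 0):
        raise ValidationError(f"node {node_index}: degenerate zero weight vector")
    # SVC's positive decision side corresponds to classes_[1]
    pos, neg = clf.classes_[1], clf.classes_[0]
    return NodeModel(index=node_index, feature_names=tuple(feature_names),
                     weights=w, bias=b, mean=mean, sd=sd,
                     class_map={1: str(pos), -1: str(neg)})


@dataclass
class HierarchyModel:
    """Three trained nodes plus the descriptor→feature wiring."""

    nodes: dict[int, NodeModel]
    selected_features: dict[str, str]
    behaviours: tuple[str, ...] = BEHAVIOURS

    def node_features(self, index: int) -> tuple[str, ...]:
        return self.nodes[index].feature_names

    def to_dict(self) -> dict:
        return {
            "nodes": {str(i): n.to_dict() for i, n in self.nodes.items()},
            "selected_features": dict(self.selected_features),
            "behaviours": list(self.behaviours),
        }

    @staticmethod
    def from_dict(d: dict) -> "HierarchyModel":
        return HierarchyModel(
            nodes={int(k): NodeModel.from_dict(v) for k, v in d["nodes"].items()},
            selected_features=dict(d["selected_features"]),
            behaviours=tuple(d["behaviours"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @staticmethod
    def load(path: str | Path) -> "HierarchyModel":
        return HierarchyModel.from_dict(json.loads(Path(path).read_text()))


def train_hierarchy(fm: pd.DataFrame, selected_features: dict[str, str],
                    C: float = 1.0) -> HierarchyModel:
    """Train the full three-node hierarchy on a labelled feature matrix.

    Node 1 sees all windows (static = vigilance ∪ resting vs dynamic =
    foraging ∪ running), node 2 the static windows only, node 3 the
    dynamic windows only.  Raises a :class:`ValidationError` naming the
    node broken by a missing behaviour.
    """
    labels = fm["label"].to_numpy()
    present = set(labels.tolist())
    for node_index, (a, b) in ((2, tuple(sorted(STATIC_BEHAVIOURS))),
                               (3, tuple(sorted(DYNAMIC_BEHAVIOURS)))):
        missing = {a, b} - present
        if missing:
            raise ValidationError(
                f"behaviour(s) {sorted(missing)} absent: cannot train node {node_index}")

    for descriptor in ("posture", "intensity", "periodicity"):
        if descriptor not in selected_features:
            raise ValidationError(f"selected_features missing {descriptor!r}")
        if selected_features[descriptor] not in fm.columns:
            raise ValidationError(
                f"feature column {selected_features[descriptor]!r} not in matrix")

    def feats(node_index: int) -> tuple[str, ...]:
        return tuple(selected_features[d] for d in NODE_DESCRIPTORS[node_index])

    static_mask = np.isin(labels, list(STATIC_BEHAVIOURS))
    node1_y = np.where(static_mask, "static", "dynamic").astype(object)
    nodes = {1: train_node(fm, 1, node1_y, feats(1), C)}
    nodes[2] = train_node(fm.loc[static_mask], 2, labels[static_mask], feats(2), C)
    nodes[3] = train_node(fm.loc[~static_mask], 3, labels[~static_mask], feats(3), C)
    return HierarchyModel(nodes=nodes, selected_features=dict(selected_features))


def predict(model: HierarchyModel, fm: pd.DataFrame) -> np.ndarray:
    """Route every window through the hierarchy; returns one of the four
    behaviour labels per row."""
    for node in model.nodes.values():
        missing = set(node.feature_names) - set(fm.columns)
        if missing:
            raise ValidationError(f"feature matrix lacks columns {sorted(missing)}")

    n1 = model.nodes[1]
    side = n1.classify(fm.loc[:, list(n1.feature_names)].to_numpy(dtype=float))
    out = np.empty(len(fm), dtype=object)
    static_mask = side == "static"
    for mask, node in ((static_mask, model.nodes[2]), (~static_mask, model.nodes[3])):
        if mask.any():
            X = fm.loc[mask, list(node.feature_names)].to_numpy(dtype=float)
            out[mask] = node.classify(X)
    return out
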