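"""Bagged classification-tree ensemble for S2 feature vectors.

The ensemble follows a specific, nonstandard configuration, so the trees
are implemented here rather than delegated to a library:

* 60 trees by default;
* per tree, an in-bag sample drawn *without replacement* as exactly 2/3 of
  the training sounds (a partition into in-bag and out-of-bag thirds, not a
  classical bootstrap; a bootstrap mode is available via ``bootstrap=True``);
* at each node a random subset of ceil(sqrt(d)) features is considered;
* tree growth stops when the number of split (internal) nodes reaches the
  number of retained PCA features d, or when nodes are pure;
* out-of-bag (OOB) error is computed overall and per class from the votes
  of trees that did not see each sample in-bag.

All tie-breaks are deterministic: split ties go to the lowest feature index
then lowest threshold, vote ties to the lowest class index in the fixed
class order (Healthy < CKD < CKD+CAVD).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

CLASS_ORDER = ("Healthy", "CKD", "CKD+CAVD")


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the bagged-tree ensemble."""

    n_trees: int = 60
    in_bag_fraction: float = 2.0 / 3.0
    max_split_nodes_per_tree: Optional[int] = None  # default: retained-feature count d
    features_per_split: Optional[int] = None        # default: ceil(sqrt(d))
    bootstrap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.in_bag_fraction < 1.0:
            raise ValueError("in_bag_fraction must lie in (0, 1)")


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    counts: Optional[np.ndarray] = None  # per-class sample counts at the node

    @property
    def is_leaf(self) -> bool:
        return self.left < 0


@dataclass
class Prediction:
    """Ensemble vote for one feature vector."""

    label: str
    vote_fractions: np.ndarray  # ordered by the ensemble's class list


@dataclass
class TreeEnsemble:
    trees: List[List[_Node]]
    in_bag_masks: np.ndarray  # (n_trees, n_samples) bool
    classes: Tuple[str, ...]
    n_features: int
    oob_error: float
    per_class_oob_error: Dict[str, float]
    n_never_oob: int
    config: EnsembleConfig


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(
    x: np.ndarray, y: np.ndarray, idx: np.ndarray, feat_candidates: np.ndarray, n_classes: int
) -> Optional[Tuple[float, int, float]]:
    """Best (gini-weighted impurity, feature, threshold) over candidate features.

    Ties break to the lowest feature index, then the lowest threshold.
    """
    best: Optional[Tuple[float, int, float]] = None
    n = len(idx)
    for f in np.sort(feat_candidates):
        vals = x[idx, f]
        order = np.argsort(vals, kind="mergesort")
        sv, sy = vals[order], y[idx][order]
        # prefix class counts after each position
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), sy] = 1.0
        left = np.cumsum(onehot, axis=0)[:-1]        # counts left of split i+1
        total = left[-1] + onehot[-1]
        right = total - left
        nl = left.sum(axis=1)
        nr = n - nl
        with np.errstate(divide="ignore", invalid="ignore"):
            gl = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
            gr = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        weighted = (nl * np.nan_to_num(gl) + nr * np.nan_to_num(gr)) / n
        valid = sv[:-1] < sv[1:]  # split only between distinct values
        if not np.any(valid):
            continue
        w = np.where(valid, weighted, np.inf)
        i = int(np.argmin(w))  # argmin takes the first minimum: lowest threshold
        thr = 0.5 * (sv[i] + sv[i + 1])
        cand = (float(w[i]), int(f), float(thr))
        if best is None or cand[0] < best[0]:
            best = cand
    return best


def _grow_tree(
    x: np.ndarray,
    y: np.ndarray,
    in_bag: np.ndarray,
    max_splits: int,
    mtry: int,
    n_classes: int,
    rng: np.random.Generator,
) -> List[_Node]:
    """Grow one tree best-first until the split-node cap or purity."""
    nodes: List[_Node] = []

    def make_node(idx: np.ndarray) -> int:
        counts = np.bincount(y[idx], minlength=n_classes).astype(float)
        nodes.append(_Node(counts=counts))
        return len(nodes) - 1

    root = make_node(in_bag)
    # heap of (impurity-ordered) frontier leaves: (-n*gini, node_id, idx)
    frontier: List[Tuple[float, int]] = []
    idx_map: Dict[int, np.ndarray] = {root: in_bag}

    def push(node_id: int) -> None:
        idx = idx_map[node_id]
        imp = _gini(np.bincount(y[idx], minlength=n_classes).astype(float)) * len(idx)
        if imp > 0 and len(idx) >= 2:
            heapq.heappush(frontier, (-imp, node_id))

    push(root)
    n_splits = 0
    d = x.shape[1]
    while frontier and n_splits < max_splits:
        _, node_id = heapq.heappop(frontier)
        idx = idx_map.pop(node_id)
        feats = rng.choice(d, size=min(mtry, d), replace=False)
        best = _best_split(x, y, idx, feats, n_classes)
        if best is None:
            continue
        _, f, thr = best
        mask = x[idx, f] <= thr
        left_id = make_node(idx[mask])
        right_id = make_node(idx[~mask])
        node = nodes[node_id]
        node.feature, node.threshold = f, thr
        node.left, node.right = left_id, right_id
        idx_map[left_id] = idx[mask]
        idx_map[right_id] = idx[~mask]
        push(left_id)
        push(right_id)
        n_splits += 1
    return nodes


def _tree_apply(nodes: List[_Node], x: np.ndarray) -> np.ndarray:
    """Class votes (argmax of leaf counts, ties to lowest index) per row of x."""
    out = np.empty(len(x), dtype=np.int64)
    for i, row in enumerate(x):
        nid = 0
        while not nodes[nid].is_leaf:
            nd = nodes[nid]
            nid = nd.left if row[nd.feature] <= nd.threshold else nd.right
        out[i] = int(np.argmax(nodes[nid].counts))
    return out


def train_forest(
    features: Sequence, config: Optional[EnsembleConfig] = None
) -> TreeEnsemble:
    """Train the bagged ensemble on a list of FeatureVectors.

    Raises on empty input; single-class data trains but carries an OOB
    error of zero (flagged in the per-class report).
    """
    config = config or EnsembleConfig()
    if len(features) == 0:
        raise ValueError("no training features")
    x = np.stack([np.asarray(f.scores, dtype=float) for f in features])
    labels = [f.label for f in features]
    classes = tuple(c for c in CLASS_ORDER if c in set(labels))
    if not classes:  # labels outside the fixed order: fall back to sorted unique
        classes = tuple(sorted(set(labels)))
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_to_idx[l] for l in labels], dtype=np.int64)
    n, d = x.shape
    n_classes = len(classes)

    max_splits = config.max_split_nodes_per_tree if config.max_split_nodes_per_tree else d
    mtry = config.features_per_split if config.features_per_split else int(np.ceil(np.sqrt(d)))
    in_bag_size = int(round(config.in_bag_fraction * n))
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)

    trees: List[List[_Node]] = []
    masks = np.zeros((config.n_trees, n), dtype=bool)
    for t in range(config.n_trees):
        if config.bootstrap:
            idx = rng.integers(0, n, size=in_bag_size)
        else:
            idx = rng.choice(n, size=in_bag_size, replace=False)
        masks[t, np.unique(idx)] = True
        trees.append(_grow_tree(x, y, np.sort(idx), max_splits, mtry, n_classes, rng))

    # OOB votes: each sample judged only by trees where it was out-of-bag.
    votes = np.zeros((n, n_classes))
    for t, tree in enumerate(trees):
        oob = ~masks[t]
        if np.any(oob):
            pred = _tree_apply(tree, x[oob])
            votes[np.nonzero(oob)[0], pred] += 1
    covered = votes.sum(axis=1) > 0
    n_never = int(np.sum(~covered))
    if np.any(covered):
        oob_pred = np.argmax(votes[covered], axis=1)
        oob_true = y[covered]
        overall = float(np.mean(oob_pred != oob_true))
        per_class = {}
        for c, name in enumerate(classes):
            sel = oob_true == c
            per_class[name] = float(np.mean(oob_pred[sel] != c)) if np.any(sel) else float("nan")
    else:
        overall, per_class = 0.0, {c: float("nan") for c in classes}
    if n_classes == 1:
        overall = 0.0

    return TreeEnsemble(
        trees=trees,
        in_bag_masks=masks,
        classes=classes,
        n_features=d,
        oob_error=overall,
        per_class_oob_error=per_class,
        n_never_oob=n_never,
        config=config,
    )


def predict(ensemble: TreeEnsemble, feature) -> Prediction:
    """Majority vote over trees for one feature vector."""
    return predict_batch(ensemble, [feature])[0]


def predict_batch(ensemble: TreeEnsemble, features: Sequence) -> List[Prediction]:
    """Vectorized majority vote; identical to per-record :func:`predict`."""
    if not features:
        return []
    x = np.stack([np.asarray(f.scores, dtype=float) for f in features])
    if x.shape[1] != ensemble.n_features:
        raise ValueError(
            f"feature length {x.shape[1]} does not match training length {ensemble.n_features}"
        )
    n_classes = len(ensemble.classes)
    votes = np.zeros((len(x), n_classes))
    for tree in ensemble.trees:
        pred = _tree_apply(tree, x)
        votes[np.arange(len(x)), pred] += 1
    fractions = votes / len(ensemble.trees)
    out = []
    for frac in fractions:
        label = ensemble.classes[int(np.argmax(frac))]  # ties -> lowest class index
        out.append(Prediction(label=label, vote_fractions=frac))
    return out


def oob_report(ensemble: TreeEnsemble) -> Dict[str, object]:
    """Overall and per-class OOB misclassification, plus never-OOB count."""
    return {
        "oob_error": ensemble.oob_error,
        "per_class_oob_error": dict(ensemble.per_class_oob_error),
        "n_never_oob": ensemble.n_never_oob,
    }


# ---------------------------------------------------------------------------
# JSON persistence

def ensemble_to_json(ensemble: TreeEnsemble) -> str:
    payload = {
        "classes": list(ensemble.classes),
        "n_features": ensemble.n_features,
        "oob_error": ensemble.oob_error,
        "per_class_oob_error": ensemble.per_class_oob_error,
        "n_never_oob": ensemble.n_never_oob,
        "config": {
            "n_trees": ensemble.config.n_trees,
            "in_bag_fraction": ensemble.config.in_bag_fraction,
            "max_split_nodes_per_tree": ensemble.config.max_split_nodes_per_tree,
            "features_per_split": ensemble.config.features_per_split,
            "bootstrap": ensemble.config.bootstrap,
            "seed": ensemble.config.seed,
        },
        "trees": [
            [
                {
                    "feature": nd.feature,
                    "threshold": nd.threshold,
                    "left": nd.left,
                    "right": nd.right,
                    "counts": list(map(float, nd.counts)),
                }
                for nd in tree
            ]
            for tree in ensemble.trees
        ],
        "in_bag_masks": ensemble.in_bag_masks.astype(int).tolist(),
    }
    return json.dumps(payload)


def ensemble_from_json(text: str) -> TreeEnsemble:
    payload = json.loads(text)
    trees = [
        [
            _Node(
                feature=nd["feature"],
                threshold=nd["threshold"],
                left=nd["left"],
                right=nd["right"],
                counts=np.asarray(nd["counts"]),
            )
            for nd in tree
        ]
        for tree in payload["trees"]
    ]
    cfg = EnsembleConfig(**payload["config"])
    return TreeEnsemble(
        trees=trees,
        in_bag_masks=np.asarray(payload["in_bag_masks"], dtype=bool),
        classes=tuple(payload["classes"]),
        n_features=payload["n_features"],
        oob_error=payload["oob_error"],
        per_class_oob_error=payload["per_class_oob_error"],
        n_never_oob=payload["n_never_oob"],
        config=cfg,
    )
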