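"""Bootstrap-aggregated CART classifier with out-of-bag tree weighting.

The classifier follows the bagged-tree ("TreeBagger") recipe: many CART trees
are each grown on a bootstrap resample of the training samples, with a random
subset of proteins considered at every split (random-forest style). Each
tree is then scored on its own out-of-bag samples; its weight is one minus
its OOB misclassification rate, and only the top-weighted half of the forest
is kept for prediction and for rule extraction. Prediction is a
weight-normalized vote of the selected trees.

All analyses are binary (one disease group, or pooled tumors, against the
benign group).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .npx_core import SampleMetadata

__all__ = [
    "TreeNode",
    "BaggedEnsemble",
    "SplitDataset",
    "split_train_validation",
    "gini_impurity",
    "fit_tree",
    "fit_ensemble",
    "select_trees",
    "predict",
]


def gini_impurity(class_counts: Sequence[float]) -> float:
    """Gini impurity ``1 − Σ (count_c / total)²`` of a node."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot compute impurity of an empty node")
    p = counts / total
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """A CART node: internal (split on one protein at a threshold) or leaf.

    ``impurity_decrease`` is the split's Gini drop weighted by the fraction
    of the tree's training samples reaching the node, so splits near the
    root, acting on many samples, rank above deep ones of equal local gain.
    Samples with value ≤ threshold go left.
    """

    n_train: int
    counts: tuple[int, ...]
    depth: int = 0
    # internal-node fields
    feature: int | None = None
    protein_id: str | None = None
    threshold: float | None = None
    impurity_decrease: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # leaf field (class index; ties resolved to the lower index = negative)
    prediction: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def predict_into(self, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if self.is_leaf:
            out[idx] = self.prediction
            return
        go_left = X[idx, self.feature] <= self.threshold
        self.left.predict_into(X, idx[go_left], out)
        self.right.predict_into(X, idx[~go_left], out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X), dtype=np.int64)
        self.predict_into(X, np.arange(len(X)), out)
        return out

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"n": self.n_train, "counts": list(self.counts), "predict": self.prediction}
        return {
            "n": self.n_train,
            "counts": list(self.counts),
            "protein": self.protein_id,
            "feature": self.feature,
            "threshold": self.threshold,
            "gain": self.impurity_decrease,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict, depth: int = 0) -> "TreeNode":
        if "threshold" not in d:
            return cls(n_train=d["n"], counts=tuple(d["counts"]), depth=depth,
                       prediction=d["predict"])
        return cls(
            n_train=d["n"],
            counts=tuple(d["counts"]),
            depth=depth,
            feature=d["feature"],
            protein_id=d["protein"],
            threshold=d["threshold"],
            impurity_decrease=d["gain"],
            left=cls.from_dict(d["left"], depth + 1),
            right=cls.from_dict(d["right"], depth + 1),
        )


def _best_split_on_feature(x: np.ndarray, y01: np.ndarray, min_leaf: int):
    """Best midpoint threshold on one feature; returns (gain_term, threshold).

    ``gain_term`` is the un-normalized decrease ``n·g_parent − (n_l·g_l +
    n_r·g_r)``; the caller scales by the root size. Returns ``None`` when no
    admissible split exists.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y01[order]
    # prefix counts of the positive class for left blocks of size 1..n-1
    c1 = np.cumsum(ys)[:-1].astype(float)
    nl = np.arange(1, n, dtype=float)
    nr = n - nl
    boundary = xs[:-1] < xs[1:]
    valid = boundary & (nl >= min_leaf) & (nr >= min_leaf)
    if not valid.any():
        return None
    c1r = c1[-1] + ys[-1] - c1
    gl = 1.0 - ((c1 / nl) ** 2 + ((nl - c1) / nl) ** 2)
    gr = 1.0 - ((c1r / nr) ** 2 + ((nr - c1r) / nr) ** 2)
    total1 = c1[-1] + ys[-1]
    g_parent = 1.0 - ((total1 / n) ** 2 + ((n - total1) / n) ** 2)
    gain = n * g_parent - (nl * gl + nr * gr)
    gain[~valid] = -np.inf
    i = int(np.argmax(gain))
    if gain[i] <= 1e-12:
        return None
    return float(gain[i]), float((xs[i] + xs[i + 1]) / 2.0)


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    feature_subsample: int | None = None,
    min_leaf: int = 3,
    rng: np.random.Generator | None = None,
    protein_ids: Sequence[str] | None = None,
) -> TreeNode:
    """Grow one greedy binary CART tree on coded labels ``y ∈ {0, 1}``.

    At each node ``feature_subsample`` candidate proteins are drawn without
    replacement and every midpoint between sorted distinct values is
    evaluated; the split with the largest weighted Gini decrease wins.
    Growth stops at pure nodes, nodes smaller than ``2·min_leaf``, or when no
    split yields positive gain.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y dimensions do not match")
    if X.shape[1] == 0:
        raise ValueError("need at least one feature")
    if min_leaf < 1:
        raise ValueError("min_leaf must be ≥ 1")
    y01 = y.astype(np.int64)
    if not set(np.unique(y01)) <= {0, 1}:
        raise ValueError("fit_tree expects labels coded 0/1")
    rng = rng if rng is not None else np.random.default_rng()
    p = X.shape[1]
    k = feature_subsample if feature_subsample is not None else max(1, int(np.sqrt(p)))
    k = min(k, p)
    n_root = X.shape[0]
    if protein_ids is None:
        protein_ids = [f"f{j}" for j in range(p)]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        ysub = y01[idx]
        n = idx.size
        c1 = int(ysub.sum())
        counts = (n - c1, c1)
        node = TreeNode(n_train=n, counts=counts, depth=depth)
        if c1 == 0 or c1 == n or n < 2 * min_leaf:
            node.prediction = int(c1 > n - c1)
            return node
        feats = rng.choice(p, size=k, replace=False)
        best = None  # (gain_term, feature, threshold)
        for f in feats:
            res = _best_split_on_feature(X[idx, f], ysub, min_leaf)
            if res is not None and (best is None or res[0] > best[0]):
                best = (res[0], int(f), res[1])
        if best is None:
            node.prediction = int(c1 > n - c1)
            return node
        gain_term, f, thr = best
        node.feature = f
        node.protein_id = protein_ids[f]
        node.threshold = thr
        node.impurity_decrease = gain_term / n_root
        go_left = X[idx, f] <= thr
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    return build(np.arange(n_root), 0)


@dataclass
class BaggedEnsemble:
    """A fitted bag of CART trees with per-tree OOB weights.

    ``classes`` is (negative, positive); tree leaves predict class indices
    into it. ``selected`` marks the subset used for prediction and rule
    extraction; ``oob_error`` is the ensemble-level OOB misclassification
    rate (majority weighted vote over each sample's out-of-bag trees).
    """

    trees: list[TreeNode]
    bootstrap_indices: list[np.ndarray]
    oob_error_per_tree: np.ndarray
    tree_weights: np.ndarray
    selected: np.ndarray
    classes: tuple[str, str]
    protein_ids: tuple[str, ...]
    seed: int
    oob_error: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        n = len(self.trees)
        lens = {len(self.bootstrap_indices), self.oob_error_per_tree.size,
                self.tree_weights.size, self.selected.size}
        if lens != {n}:
            raise ValueError("per-tree arrays must all have one entry per tree")
        if np.any(self.tree_weights < 0):
            raise ValueError("tree weights must be non-negative")
        if n and not self.selected.any():
            raise ValueError("at least one tree must be selected")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def positive_class(self) -> str:
        return self.classes[1]

    def selected_trees(self) -> list[TreeNode]:
        return [t for t, s in zip(self.trees, self.selected) if s]

    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes),
            "protein_ids": list(self.protein_ids),
            "seed": self.seed,
            "oob_error": self.oob_error,
            "trees": [
                {
                    "tree": t.to_dict(),
                    "oob_error": float(e),
                    "weight": float(w),
                    "selected": bool(s),
                }
                for t, e, w, s in zip(
                    self.trees, self.oob_error_per_tree, self.tree_weights, self.selected
                )
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "BaggedEnsemble":
        payload = json.loads(Path(path).read_text())
        trees = [TreeNode.from_dict(t["tree"]) for t in payload["trees"]]
        return cls(
            trees=trees,
            bootstrap_indices=[np.array([], dtype=int)] * len(trees),
            oob_error_per_tree=np.array([t["oob_error"] for t in payload["trees"]]),
            tree_weights=np.array([t["weight"] for t in payload["trees"]]),
            selected=np.array([t["selected"] for t in payload["trees"]], dtype=bool),
            classes=tuple(payload["classes"]),
            protein_ids=tuple(payload["protein_ids"]),
            seed=payload["seed"],
            oob_error=payload["oob_error"],
        )


def fit_ensemble(
    X: np.ndarray,
    y: Sequence[str],
    n_trees: int = 5000,
    feature_subsample: int | None = None,
    min_leaf: int = 3,
    seed: int = 0,
    positive_class: str | None = None,
    protein_ids: Sequence[str] | None = None,
    uniform_weights: bool = False,
) -> BaggedEnsemble:
    """Fit the bagged CART ensemble.

    Each tree sees an ``n``-sample bootstrap resample; its OOB error is its
    misclassification rate on the samples left out of that resample, and its
    weight is ``max(0, 1 − OOB error)`` (or 1 for every tree with
    ``uniform_weights``). All trees start selected; see :func:`select_trees`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = [c for c in dict.fromkeys(np.unique(y))]
    if len(classes) != 2:
        raise ValueError(f"ensemble requires exactly two classes, got {classes}")
    if positive_class is not None:
        if positive_class not in classes:
            raise ValueError(f"positive class {positive_class!r} absent from labels")
        classes = [c for c in classes if c != positive_class] + [positive_class]
    classes = tuple(str(c) for c in classes)
    y01 = (y == classes[1]).astype(np.int64)
    n = X.shape[0]
    if protein_ids is None:
        protein_ids = tuple(f"f{j}" for j in range(X.shape[1]))

    rng = np.random.default_rng(seed)
    trees: list[TreeNode] = []
    boots: list[np.ndarray] = []
    oob_err = np.full(n_trees, np.nan)
    # ensemble-level OOB vote accumulators
    vote_pos = np.zeros(n)
    vote_tot = np.zeros(n)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        inbag = np.zeros(n, dtype=bool)
        inbag[boot] = True
        tree = fit_tree(
            X[boot], y01[boot],
            feature_subsample=feature_subsample,
            min_leaf=min_leaf,
            rng=rng,
            protein_ids=protein_ids,
        )
        trees.append(tree)
        boots.append(boot)
        oob_idx = np.flatnonzero(~inbag)
        if oob_idx.size:
            pred = tree.predict(X[oob_idx])
            oob_err[t] = float(np.mean(pred != y01[oob_idx]))
            vote_pos[oob_idx] += pred
            vote_tot[oob_idx] += 1
    weights = np.ones(n_trees) if uniform_weights else np.clip(1.0 - oob_err, 0.0, None)
    weights[np.isnan(weights)] = 0.0
    seen = vote_tot > 0
    ens_oob = float("nan")
    if seen.any():
        agg = (vote_pos[seen] / vote_tot[seen]) > 0.5
        ens_oob = float(np.mean(agg != y01[seen].astype(bool)))
    return BaggedEnsemble(
        trees=trees,
        bootstrap_indices=boots,
        oob_error_per_tree=oob_err,
        tree_weights=weights,
        selected=np.ones(n_trees, dtype=bool),
        classes=classes,
        protein_ids=tuple(protein_ids),
        seed=seed,
        oob_error=ens_oob,
    )


def select_trees(ensemble: BaggedEnsemble, k: int = 2500) -> BaggedEnsemble:
    """Keep the ``k`` highest-weighted trees (ties: lower OOB error, then
    lower tree index); returns a new ensemble with an updated selection."""
    if not 1 <= k <= ensemble.n_trees:
        raise ValueError(f"k must be in [1, {ensemble.n_trees}]")
    oob = np.where(np.isnan(ensemble.oob_error_per_tree), np.inf, ensemble.oob_error_per_tree)
    order = np.lexsort((np.arange(ensemble.n_trees), oob, -ensemble.tree_weights))
    selected = np.zeros(ensemble.n_trees, dtype=bool)
    selected[order[:k]] = True
    return replace(ensemble, selected=selected)


def predict(ensemble: BaggedEnsemble, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-vote prediction of the selected trees.

    Returns ``(labels, scores)`` where ``scores`` is the weight-normalized
    fraction of selected trees voting for the positive class and a sample is
    labelled positive iff its score exceeds 0.5 (exact ties → negative).
    """
    if ensemble.n_trees == 0:
        raise ValueError("ensemble has no trees")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(ensemble.protein_ids):
        raise ValueError("X columns do not match the ensemble's training proteins")
    sel = np.flatnonzero(ensemble.selected)
    w = ensemble.tree_weights[sel]
    wsum = w.sum()
    if wsum <= 0:  # degenerate: every selected tree has weight 0
        w = np.ones_like(w)
        wsum = w.sum()
    score = np.zeros(X.shape[0])
    for t, wt in zip(sel, w):
        if wt > 0:
            score += wt * ensemble.trees[t].predict(X)
    score /= wsum
    labels = np.where(score > 0.5, ensemble.classes[1], ensemble.classes[0])
    return labels, score


@dataclass(frozen=True)
class SplitDataset:
    """Disjoint train/validation index sets over the eligible samples."""

    train_idx: np.ndarray
    val_idx: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.val_idx).size:
            raise ValueError("train and validation sets overlap")


def split_train_validation(
    metadata: SampleMetadata | Sequence[str],
    fraction: float = 0.8,
    stratify_by_group: bool = True,
    seed: int = 0,
) -> SplitDataset:
    """Seeded random 80/20 (by default) train/validation split.

    With stratification the split is drawn within each group so per-group
    training fractions match ``fraction`` to within one sample.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = (
        metadata.groups() if isinstance(metadata, SampleMetadata) else np.asarray(metadata)
    )
    rng = np.random.default_rng(seed)
    n = len(labels)
    if stratify_by_group:
        train_parts, val_parts = [], []
        for cls in dict.fromkeys(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < 2:
                raise ValueError(f"group {cls!r} has fewer than 2 samples")
            perm = rng.permutation(idx)
            n_train = int(np.floor(fraction * idx.size + 0.5))
            n_train = min(max(n_train, 1), idx.size - 1)
            train_parts.append(perm[:n_train])
            val_parts.append(perm[n_train:])
        train = np.sort(np.concatenate(train_parts))
        val = np.sort(np.concatenate(val_parts))
    else:
        perm = rng.permutation(n)
        n_train = int(np.floor(fraction * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        train = np.sort(perm[:n_train])
        val = np.sort(perm[n_train:])
    return SplitDataset(train_idx=train, val_idx=val)
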