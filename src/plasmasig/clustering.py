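"""Unsupervised hierarchical clustering of samples on the full protein panel.

Agglomerative clustering with correlation or Euclidean distance and average
or complete linkage, after optional per-protein z-scoring — the common
defaults for expression-heatmap dendrograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .npx_core import NPXMatrix

__all__ = ["Dendrogram", "hierarchical_cluster", "cluster_label_agreement"]

_DISTANCES = {"correlation", "euclidean"}
_LINKAGES = {"average", "complete"}


@dataclass
class Dendrogram:
    """An agglomeration history in scipy linkage format.

    ``merges[i] = (cluster_a, cluster_b, height, size)``; original samples
    are clusters ``0..n−1`` and merge ``i`` creates cluster ``n+i``.
    """

    merges: np.ndarray
    sample_ids: tuple[str, ...]
    distance: str
    linkage: str

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.merges))

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels for ``k`` clusters."""
        return hierarchy.fcluster(self.merges, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.merges)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        body = walk(tree, tree.dist)
        # strip the root's zero-length suffix
        return body.rsplit(":", 1)[0] + ";"

    def write_merge_table(self, path) -> None:
        df = pd.DataFrame(self.merges, columns=["cluster_a", "cluster_b", "height", "size"])
        df["cluster_a"] = df["cluster_a"].astype(int)
        df["cluster_b"] = df["cluster_b"].astype(int)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def hierarchical_cluster(
    matrix: NPXMatrix | np.ndarray,
    distance: str = "correlation",
    linkage: str = "average",
    standardize: bool = True,
    sample_ids: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomeratively cluster samples over all proteins.

    With ``standardize`` each protein is z-scored before distances are
    computed. Proteins with zero variance are dropped (they carry no
    information and make the correlation distance undefined).
    """
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {sorted(_DISTANCES)}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    if isinstance(matrix, NPXMatrix):
        X = matrix.values
        ids = matrix.sample_ids
    else:
        X = np.asarray(matrix, dtype=float)
        ids = tuple(sample_ids) if sample_ids is not None else tuple(
            f"sample{i}" for i in range(X.shape[0])
        )
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    sd = X.std(axis=0)
    if (standardize or distance == "correlation") and np.any(sd == 0):
        dropped = int(np.sum(sd == 0))
        warnings.warn(f"dropping {dropped} zero-variance protein(s) before clustering",
                      stacklevel=2)
        X = X[:, sd > 0]
        sd = sd[sd > 0]
        if X.shape[1] == 0:
            raise ValueError("no proteins with non-zero variance")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    d = pdist(X, metric=distance)
    Z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(merges=Z, sample_ids=ids, distance=distance, linkage=linkage)


def cluster_label_agreement(dendrogram: Dendrogram, labels: Sequence[str], k: int = 2) -> float:
    """Adjusted Rand index between a k-cluster cut and known group labels."""
    return float(adjusted_rand_score(np.asarray(labels), dendrogram.cut(k)))
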