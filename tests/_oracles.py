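"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — enumeration, permutation, pairwise
counting — and shares no code with the library paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata


def permutation_rank_sum_p(x, y, n_perm: int = 100_000, seed: int = 0) -> float:
    """Two-sided rank-sum p by Monte-Carlo permutation of the pooled ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = x.size
    obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / pooled.size
    rng = np.random.default_rng(seed)
    mat = np.tile(ranks, (n_perm, 1))
    perm_sums = rng.permuted(mat, axis=1)[:, :n1].sum(axis=1)
    return float(np.mean(np.abs(perm_sums - mu) >= abs(obs - mu) - 1e-9))


def bh_stepup_by_hand(p):
    """Literal step-up: sort, scale by m/i, cumulative min from the top, cap."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def auc_by_pair_counting(scores, truth) -> float:
    """Concordant-pair AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos = scores[truth]
    neg = scores[~truth]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (pos.size * neg.size)


def _gini(y01) -> float:
    y01 = np.asarray(y01)
    if y01.size == 0:
        return 0.0
    p1 = y01.mean()
    return 1.0 - (p1**2 + (1 - p1) ** 2)


def brute_force_best_split(X, y01, min_leaf: int = 1):
    """Exhaustive search over every feature and midpoint threshold.

    Returns ``(gain, feature, threshold)`` where gain is the un-normalized
    decrease ``n·g_parent − (n_l·g_l + n_r·g_r)``, or ``None``.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01)
    n = X.shape[0]
    parent = n * _gini(y01)
    best = None
    for f in range(X.shape[1]):
        xs = np.unique(X[:, f])
        for a, b in zip(xs[:-1], xs[1:]):
            thr = (a + b) / 2.0
            left = X[:, f] <= thr
            nl, nr = int(left.sum()), int((~left).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            gain = parent - (nl * _gini(y01[left]) + nr * _gini(y01[~left]))
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, f, thr)
    return best


def naive_agglomeration(X, metric: str = "euclidean", method: str = "average"):
    """Textbook agglomerative clustering; returns merge heights in order.

    Inter-cluster distance is the mean (average linkage) or max (complete
    linkage) over all pairwise original dissimilarities.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = squareform(pdist(X, metric=metric))
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    heights = []
    agg = np.mean if method == "average" else np.max
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = agg([D[p, q] for p in clusters[a] for q in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.asarray(heights)
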