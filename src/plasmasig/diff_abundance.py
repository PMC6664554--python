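"""Group-wise differential abundance of plasma proteins.

Two-sided Wilcoxon rank-sum (Mann-Whitney) tests per protein with
Benjamini-Hochberg FDR adjustment across the panel; an adjusted p-value
below 0.05 is the conventional significance call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .npx_core import NPXMatrix, SampleMetadata

__all__ = ["ComparisonResult", "rank_sum_test", "bh_adjust", "compare_groups", "write_comparison"]

#: Pooled-size bound under which the exact rank-sum null is enumerated
#: (only relevant for tiny oracle problems; cohort groups are far larger).
_EXACT_MAX_POOLED = 12


@dataclass(frozen=True)
class ComparisonResult:
    """Per-protein outcome of a two-group comparison.

    ``direction`` is the sign of ``median(group_a) − median(group_b)`` and
    ``delta_median`` that difference in NPX (log2) units.
    """

    protein_id: str
    p_raw: float
    p_adj: float
    direction: int
    delta_median: float


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` versus ``y``.

    Uses exact enumeration of the Mann-Whitney null when the pooled sample is
    small (≤ 12) and tie-free, otherwise the normal approximation with
    midranks, tie-corrected variance and continuity correction. Returns
    ``(U statistic of x, two-sided p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("rank_sum_test requires finite values")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_POOLED and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Sorted ascending, ``q_(i) = p_(i)·m/i`` with a cumulative minimum applied
    from the largest rank downwards and a cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    matrix: NPXMatrix,
    metadata: SampleMetadata,
    group_a: str,
    group_b: str,
    exclude_inflammatory: bool = False,
) -> list[ComparisonResult]:
    """Per-protein rank-sum comparison of two disease groups with FDR control.

    BH adjustment is applied across all proteins of this comparison only.
    With ``exclude_inflammatory``, benign samples flagged as inflammatory are
    dropped before testing (the benign group mixes inflammatory and
    non-inflammatory conditions). Results are sorted by adjusted p ascending.
    """
    mask_a = metadata.group_mask(group_a)
    mask_b = metadata.group_mask(group_b)
    if exclude_inflammatory:
        inflam = np.array([v is True for v in metadata.df["inflammatory"]])
        mask_a = mask_a & ~inflam
        mask_b = mask_b & ~inflam
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"need ≥2 samples per group, got {int(mask_a.sum())} {group_a} "
            f"and {int(mask_b.sum())} {group_b}"
        )
    p_raw = np.empty(matrix.n_proteins)
    delta = np.empty(matrix.n_proteins)
    for j in range(matrix.n_proteins):
        xa = matrix.values[mask_a, j]
        xb = matrix.values[mask_b, j]
        _, p_raw[j] = rank_sum_test(xa, xb)
        delta[j] = np.median(xa) - np.median(xb)
    p_adj = bh_adjust(p_raw)
    results = [
        ComparisonResult(
            protein_id=matrix.protein_ids[j],
            p_raw=float(p_raw[j]),
            p_adj=float(p_adj[j]),
            direction=int(np.sign(delta[j])),
            delta_median=float(delta[j]),
        )
        for j in range(matrix.n_proteins)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.protein_id))
    return results


def write_comparison(results: Sequence[ComparisonResult], path, comparison: str) -> None:
    """Write comparison results as a TSV with a ``comparison`` label column."""
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "p_raw": [f"{r.p_raw:.6g}" for r in results],
            "p_adj": [f"{r.p_adj:.6g}" for r in results],
            "direction": [r.direction for r in results],
            "delta_median": [f"{r.delta_median:.6g}" for r in results],
            "comparison": comparison,
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
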