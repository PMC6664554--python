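"""Distillation of a bagged-tree classifier into a three-protein threshold
signature.

From every selected tree the three best-discriminating proteins (largest
weighted Gini decrease) and their split thresholds are extracted; across the
forest, proteins are ranked by how often they are extracted, the top three
form the signature, and each protein's consensus cut-off is the median of
its extracted thresholds. The three rules are combined conjunctively: a
sample is called positive only when all three hold (strictly above or below
its cut-off, direction chosen per protein from the class medians).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ensemble import BaggedEnsemble, TreeNode
from .npx_core import NPXMatrix, SampleMetadata
from .single_marker import ClassifierMetrics, ConfusionMatrix, confusion_metrics

__all__ = [
    "SignatureRule",
    "TripleSignature",
    "extract_tree_triple",
    "aggregate_signature",
    "apply_signature",
    "evaluate_signature",
    "refine_cutoffs",
]


@dataclass(frozen=True)
class SignatureRule:
    """One threshold rule: protein strictly above/below an NPX cut-off."""

    protein_id: str
    cutoff: float
    direction: str  # "above" | "below"

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")

    def holds(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return values > self.cutoff if self.direction == "above" else values < self.cutoff


@dataclass
class TripleSignature:
    """Three conjunctive threshold rules with extraction provenance.

    ``provenance`` maps each signature protein to its extraction frequency
    across the selected trees and summary statistics of the extracted
    thresholds.
    """

    rules: tuple[SignatureRule, SignatureRule, SignatureRule]
    positive_class: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rules = tuple(self.rules)
        if len(self.rules) != 3:
            raise ValueError("a triple signature has exactly 3 rules")
        ids = [r.protein_id for r in self.rules]
        if len(set(ids)) != 3:
            raise ValueError("signature proteins must be distinct")

    @property
    def protein_ids(self) -> tuple[str, str, str]:
        return tuple(r.protein_id for r in self.rules)

    def to_json(self, path) -> None:
        payload = {
            "positive_class": self.positive_class,
            "rules": [
                {"protein": r.protein_id, "cutoff": r.cutoff, "direction": r.direction}
                for r in self.rules
            ],
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "TripleSignature":
        payload = json.loads(Path(path).read_text())
        rules = tuple(
            SignatureRule(r["protein"], r["cutoff"], r["direction"]) for r in payload["rules"]
        )
        return cls(rules=rules, positive_class=payload["positive_class"],
                   provenance=payload.get("provenance", {}))


def extract_tree_triple(tree: TreeNode) -> list[tuple[str, float, float, int]]:
    """The tree's up-to-three best-discriminating proteins.

    Internal nodes are ranked by weighted Gini decrease (ties: larger
    training count, then shallower depth); each protein appears once, at its
    highest-ranked threshold. Returns ``(protein_id, threshold,
    impurity_decrease, best_group_size)`` tuples, where ``best_group_size``
    is the training-sample count of the tree's largest pure positive-class
    leaf (0 if none). A leaf-only tree yields an empty list.
    """
    internals = tree.internal_nodes()
    if not internals:
        return []
    internals.sort(key=lambda nd: (-nd.impurity_decrease, -nd.n_train, nd.depth))
    pure_pos = [lf.n_train for lf in tree.leaves() if lf.counts[1] == lf.n_train]
    best_group = max(pure_pos, default=0)
    out: list[tuple[str, float, float, int]] = []
    seen: set[str] = set()
    for nd in internals:
        if nd.protein_id in seen:
            continue
        seen.add(nd.protein_id)
        out.append((nd.protein_id, float(nd.threshold), float(nd.impurity_decrease), best_group))
        if len(out) == 3:
            break
    return out


def aggregate_signature(
    ensemble: BaggedEnsemble,
    X: np.ndarray,
    y: Sequence[str],
    positive_class: str,
) -> TripleSignature:
    """Distill the selected trees into a consensus three-protein signature.

    Proteins are ranked by extraction frequency over the selected trees'
    triples (ties by mean impurity decrease); the consensus cut-off is the
    median of each protein's extracted thresholds, and the rule direction is
    "above" where the positive class's median NPX exceeds the other class's.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if positive_class not in set(y):
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    thresholds: dict[str, list[float]] = {}
    gains: dict[str, list[float]] = {}
    for tree in ensemble.selected_trees():
        for pid, thr, gain, _size in extract_tree_triple(tree):
            thresholds.setdefault(pid, []).append(thr)
            gains.setdefault(pid, []).append(gain)
    if len(thresholds) < 3:
        raise ValueError(
            f"cannot form a 3-protein signature: only {len(thresholds)} distinct "
            f"proteins were ever extracted ({sorted(thresholds)})"
        )
    ranked = sorted(
        thresholds,
        key=lambda pid: (-len(thresholds[pid]), -float(np.mean(gains[pid])), pid),
    )
    top3 = ranked[:3]
    col = {pid: j for j, pid in enumerate(ensemble.protein_ids)}
    pos_mask = y == positive_class
    rules = []
    provenance = {}
    for pid in top3:
        cutoff = float(np.median(thresholds[pid]))
        med_pos = float(np.median(X[pos_mask, col[pid]]))
        med_neg = float(np.median(X[~pos_mask, col[pid]]))
        direction = "above" if med_pos > med_neg else "below"
        rules.append(SignatureRule(pid, cutoff, direction))
        thr = np.asarray(thresholds[pid])
        provenance[pid] = {
            "frequency": int(thr.size),
            "n_selected_trees": int(ensemble.selected.sum()),
            "threshold_median": cutoff,
            "threshold_min": float(thr.min()),
            "threshold_max": float(thr.max()),
            "mean_impurity_decrease": float(np.mean(gains[pid])),
        }
    return TripleSignature(tuple(rules), positive_class=positive_class, provenance=provenance)


def apply_signature(sig: TripleSignature, matrix: NPXMatrix | np.ndarray,
                    protein_ids: Sequence[str] | None = None) -> np.ndarray:
    """Boolean positive-calls of the conjunctive signature on each sample."""
    if isinstance(matrix, NPXMatrix):
        cols = {pid: matrix.column(pid) for pid in sig.protein_ids}
    else:
        if protein_ids is None:
            raise ValueError("protein_ids required with a raw array")
        lookup = {pid: j for j, pid in enumerate(protein_ids)}
        missing = [p for p in sig.protein_ids if p not in lookup]
        if missing:
            raise KeyError(f"matrix lacks signature proteins: {missing}")
        arr = np.asarray(matrix, dtype=float)
        cols = {pid: arr[:, lookup[pid]] for pid in sig.protein_ids}
    calls = np.ones(len(next(iter(cols.values()))), dtype=bool)
    for rule in sig.rules:
        calls &= rule.holds(cols[rule.protein_id])
    return calls


def evaluate_signature(
    sig: TripleSignature,
    matrix: NPXMatrix,
    metadata: SampleMetadata,
    positive_group: str,
    negative_group: str,
) -> tuple[ConfusionMatrix, ClassifierMetrics]:
    """Confusion matrix and metrics of the signature on two disease groups."""
    mask = metadata.group_mask(positive_group) | metadata.group_mask(negative_group)
    if not metadata.group_mask(positive_group).any() or not metadata.group_mask(negative_group).any():
        raise ValueError("both groups must be present")
    sub = matrix.subset_samples(mask)
    truth = metadata.subset(mask).groups() == positive_group
    pred = apply_signature(sig, sub)
    cm = ConfusionMatrix.from_predictions(pred, truth, positive_group)
    return cm, confusion_metrics(cm)


def refine_cutoffs(
    sig: TripleSignature,
    X: np.ndarray,
    y: Sequence[str],
    protein_ids: Sequence[str],
    require_perfect_specificity: bool = True,
) -> TripleSignature:
    """Coordinate-wise grid refinement of the consensus cut-offs.

    Each rule's cut-off is searched over the midpoints of that protein's
    observed values to maximize training accuracy, optionally subject to
    perfect specificity (no negative-class sample called positive) —
    mirroring the convention of reporting cut-offs "chosen to best separate"
    the groups.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    truth = y == sig.positive_class
    lookup = {pid: j for j, pid in enumerate(protein_ids)}
    rules = list(sig.rules)

    def score(rules_now) -> tuple[int, int]:
        trial = TripleSignature(tuple(rules_now), sig.positive_class, {})
        pred = apply_signature(trial, X, protein_ids)
        fp = int(np.sum(pred & ~truth))
        acc = int(np.sum(pred == truth))
        return fp, acc

    for i, rule in enumerate(rules):
        xcol = np.sort(np.unique(X[:, lookup[rule.protein_id]]))
        candidates = np.concatenate(
            [[xcol[0] - 1.0], (xcol[:-1] + xcol[1:]) / 2.0, [xcol[-1] + 1.0]]
        )
        best = rules[i]
        best_fp, best_acc = score(rules)
        for c in candidates:
            rules[i] = SignatureRule(rule.protein_id, float(c), rule.direction)
            fp, acc = score(rules)
            ok = (fp == 0) if require_perfect_specificity else True
            cur_ok = (best_fp == 0) if require_perfect_specificity else True
            if (ok and not cur_ok) or (ok == cur_ok and acc > best_acc):
                best, best_fp, best_acc = rules[i], fp, acc
        rules[i] = best
    if require_perfect_specificity and best_fp > 0:
        warnings.warn("could not reach perfect specificity during refinement", stacklevel=2)
    return TripleSignature(tuple(rules), sig.positive_class, dict(sig.provenance))
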