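"""Reproducible benchmark experiments.

Two families:

* exact re-computation of diagnostic metrics from the published benchmark
  confusion matrices (:mod:`plasmasig.benchmarks`) — deterministic arithmetic;
* multi-seed recovery experiments on synthetic cohorts — marker power of the
  rank-sum/FDR stage, validated sensitivity of the weighted bagged-tree
  classifier, recovery of an injected three-protein signature, and null-cohort
  calibration (false-positive control and chance-level validation AUC).

All stochastic experiments derive their per-replicate seeds from one base
seed and report summary statistics across replicates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import benchmarks
from .diff_abundance import compare_groups
from .ensemble import fit_ensemble, predict, select_trees, split_train_validation
from .npx_core import qc_detection
from .signature import aggregate_signature
from .single_marker import ConfusionMatrix, confusion_metrics, roc_curve
from .synthetic import CohortConfig, EffectSpec, generate_cohort, study_like_config

__all__ = [
    "published_metric_values",
    "qc_percentages",
    "marker_power",
    "ensemble_validation",
    "signature_recovery",
    "null_false_positives",
    "null_ensemble_auc",
]

#: The four markers injected into the LAC group of the study-like cohort.
LAC_MARKERS = ("CXCL17", "CEACAM5", "VEGFR2", "ERBB3")

#: Signature-recovery cohort: exactly three proteins carry signal.
SIGNATURE_PROTEINS = ("CEACAM5", "WFDC2", "TCL1A")
SIGNATURE_SHIFT = 2.0


def _replicate_seed(base_seed: int, i: int) -> int:
    return int((base_seed * 100_003 + 7919 * i + 1) % 2**31)


def published_metric_values() -> dict[str, float]:
    """Diagnostic metrics recomputed from the published benchmark matrices.

    Keys are ``<analysis>_<metric>``; values are 2-decimal proportions as
    printed in diagnostic tables.
    """
    out: dict[str, float] = {}

    def add(prefix: str, cm: ConfusionMatrix, keys: Sequence[str]) -> None:
        m = dataclasses.asdict(confusion_metrics(cm, round_to=2))
        for k in keys:
            out[f"{prefix}_{k}"] = m[k]

    allm = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
    for pid, cm in benchmarks.SINGLE_MARKER_MATRICES.items():
        add(f"{pid.lower()}_cutoff", cm, allm)
    add("signature_vs_benign", benchmarks.SIGNATURE_VS_BENIGN, allm)
    add("signature_vs_crcmet", benchmarks.SIGNATURE_VS_CRC_MET, allm)
    add("stage1_vs_benign", benchmarks.STAGE1_VS_BENIGN, allm)
    add("stage1_vs_noninflammatory", benchmarks.STAGE1_VS_NONINFLAMMATORY, allm)
    add("tumors_vs_benign", benchmarks.TUMORS_VS_BENIGN, allm)
    return out


def qc_percentages(seed: int = 0) -> dict[str, float]:
    """Detection QC on a default synthetic cohort (5 of 92 proteins censored)."""
    matrix, _, panel, _ = generate_cohort(study_like_config(seed=seed))
    qc = qc_detection(matrix, panel)
    return {
        "pct_proteins_fully_detected": float(qc.pct_proteins_fully_detected),
        "n_proteins_fully_detected": float(qc.n_proteins_fully_detected),
    }


def marker_power(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Fraction of seeds in which all four injected LAC markers reach
    adjusted p < 0.05 in the LAC-vs-benign comparison."""
    hits = 0
    per_marker = {p: 0 for p in LAC_MARKERS}
    for i in range(n_seeds):
        cfg = study_like_config(seed=_replicate_seed(base_seed, i))
        matrix, metadata, _, _ = generate_cohort(cfg)
        results = compare_groups(matrix, metadata, "LAC", "benign")
        sig = {r.protein_id for r in results if r.p_adj < 0.05}
        for p in LAC_MARKERS:
            per_marker[p] += p in sig
        hits += all(p in sig for p in LAC_MARKERS)
    return {
        "all_markers_rate": hits / n_seeds,
        "per_marker_rate": {p: c / n_seeds for p, c in per_marker.items()},
        "n_seeds": n_seeds,
    }


def _lac_benign_cohort(cfg: CohortConfig):
    matrix, metadata, _, _ = generate_cohort(cfg)
    mask = metadata.group_mask("LAC") | metadata.group_mask("benign")
    sub = matrix.subset_samples(mask)
    return sub, metadata.subset(mask).groups()


def ensemble_validation(
    n_seeds: int = 20, base_seed: int = 0, n_trees: int = 500, select_k: int | None = None
) -> dict:
    """80/20-validated performance of the weighted bagged-tree classifier on
    study-like cohorts; per-seed sensitivity/specificity/AUC plus summaries."""
    sens, spec, auc = [], [], []
    n_val = 0
    for i in range(n_seeds):
        s = _replicate_seed(base_seed, i)
        sub, labels = _lac_benign_cohort(study_like_config(seed=s))
        split = split_train_validation(labels, fraction=0.8, seed=s + 1)
        ens = fit_ensemble(
            sub.values[split.train_idx], labels[split.train_idx],
            n_trees=n_trees, seed=s + 2, positive_class="LAC",
            protein_ids=sub.protein_ids,
        )
        ens = select_trees(ens, k=select_k or max(1, n_trees // 2))
        pred, score = predict(ens, sub.values[split.val_idx])
        yval = labels[split.val_idx]
        cm = ConfusionMatrix.from_predictions(pred == "LAC", yval == "LAC", "LAC")
        m = confusion_metrics(cm)
        sens.append(m.sensitivity)
        spec.append(m.specificity)
        auc.append(roc_curve(score, yval, "LAC").auc)
        n_val = int(split.val_idx.size)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "auc": auc,
        "median_sensitivity": float(np.median(sens)),
        "mean_sensitivity": float(np.mean(sens)),
        "mean_specificity": float(np.mean(spec)),
        "mean_auc": float(np.mean(auc)),
        "n_validation": n_val,
        "n_seeds": n_seeds,
    }


def signature_recovery(
    n_seeds: int = 50, base_seed: int = 0, n_trees: int = 200, select_k: int = 100
) -> dict:
    """Recovery of an injected three-protein signature.

    Cohorts carry signal in exactly three proteins (+2 NPX in LAC at unit
    SD); a seed counts as recovered when the aggregated signature names
    exactly those proteins. Consensus cut-offs falling between the two group
    means are counted separately.
    """
    recovered = 0
    cutoffs_between = 0
    n_cutoffs = 0
    for i in range(n_seeds):
        s = _replicate_seed(base_seed, i)
        cfg = CohortConfig(
            group_sizes={"LAC": 144, "benign": 68},
            effects=tuple(EffectSpec(p, "LAC", SIGNATURE_SHIFT) for p in SIGNATURE_PROTEINS),
            seed=s,
        )
        sub, labels = _lac_benign_cohort(cfg)
        ens = fit_ensemble(
            sub.values, labels, n_trees=n_trees, seed=s + 2,
            positive_class="LAC", protein_ids=sub.protein_ids,
        )
        ens = select_trees(ens, k=select_k)
        sig = aggregate_signature(ens, sub.values, labels, positive_class="LAC")
        if set(sig.protein_ids) == set(SIGNATURE_PROTEINS):
            recovered += 1
            for rule in sig.rules:
                lo = float(np.mean(sub.values[labels == "benign",
                                              sub.protein_ids.index(rule.protein_id)]))
                hi = float(np.mean(sub.values[labels == "LAC",
                                              sub.protein_ids.index(rule.protein_id)]))
                n_cutoffs += 1
                cutoffs_between += lo < rule.cutoff < hi
    return {
        "recovery_rate": recovered / n_seeds,
        "cutoffs_between_group_means_rate": (cutoffs_between / n_cutoffs) if n_cutoffs else 0.0,
        "n_seeds": n_seeds,
    }


def null_false_positives(n_seeds: int = 200, base_seed: int = 0) -> dict:
    """Zero-effect cohorts: fraction of seeds with no adjusted-significant
    protein, and the mean raw-p<0.05 fraction (should sit near 5%)."""
    clean = 0
    raw_rates = []
    for i in range(n_seeds):
        cfg = CohortConfig(
            group_sizes={"LAC": 144, "benign": 68}, seed=_replicate_seed(base_seed, i)
        )
        matrix, metadata, _, _ = generate_cohort(cfg)
        results = compare_groups(matrix, metadata, "LAC", "benign")
        clean += not any(r.p_adj < 0.05 for r in results)
        raw_rates.append(np.mean([r.p_raw < 0.05 for r in results]))
    return {
        "zero_adjusted_significant_rate": clean / n_seeds,
        "mean_raw_significant_fraction": float(np.mean(raw_rates)),
        "n_seeds": n_seeds,
    }


def null_ensemble_auc(n_seeds: int = 50, base_seed: int = 0, n_trees: int = 100) -> dict:
    """Validation AUC of the classifier on cohorts with no injected effects
    (leakage check: should be at chance level)."""
    aucs = []
    for i in range(n_seeds):
        s = _replicate_seed(base_seed, i)
        cfg = CohortConfig(group_sizes={"LAC": 144, "benign": 68}, seed=s)
        sub, labels = _lac_benign_cohort(cfg)
        split = split_train_validation(labels, fraction=0.8, seed=s + 1)
        ens = fit_ensemble(
            sub.values[split.train_idx], labels[split.train_idx],
            n_trees=n_trees, seed=s + 2, positive_class="LAC",
            protein_ids=sub.protein_ids,
        )
        ens = select_trees(ens, k=max(1, n_trees // 2))
        _, score = predict(ens, sub.values[split.val_idx])
        aucs.append(roc_curve(score, labels[split.val_idx], "LAC").auc)
    return {
        "aucs": aucs,
        "mean_auc": float(np.mean(aucs)),
        "n_seeds": n_seeds,
    }
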