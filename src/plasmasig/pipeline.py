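"""End-to-end orchestration: QC → differential abundance → single-marker
tables and ROC → bagged-tree training/validation per analysis variant →
signature extraction/evaluation → hierarchical clustering.

All randomness flows from one top-level seed through named substreams
(`numpy.random.SeedSequence.spawn`), so re-running an identical config
reproduces every output byte-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_label_agreement, hierarchical_cluster
from .diff_abundance import compare_groups, write_comparison
from .ensemble import fit_ensemble, predict, select_trees, split_train_validation
from .npx_core import (
    NPXMatrix,
    PanelDefinition,
    SampleMetadata,
    qc_detection,
    read_cohort,
    write_cohort,
)
from .signature import aggregate_signature, apply_signature
from .single_marker import (
    ConfusionMatrix,
    combine_markers,
    confusion_metrics,
    median_cutoff_classify,
    roc_curve,
)
from .synthetic import CohortConfig, generate_cohort, study_like_config

__all__ = ["PipelineConfig", "VARIANTS", "run_pipeline", "variant_subset"]

#: Named binary analysis variants (positive group vs benign controls).
VARIANTS = (
    "all_LAC_vs_benign",
    "stageI_vs_benign",
    "stageI_vs_noninflammatory_benign",
    "pooled_tumors_vs_benign",
)

_STAGE_I = ("IA", "IB")


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs; every output records the seed."""

    out_dir: str = "plasmasig_out"
    # input: either paths to an existing cohort, or a synthetic config
    npx_path: str | None = None
    metadata_path: str | None = None
    panel_path: str | None = None
    synthetic: CohortConfig | None = None
    # analyses
    comparisons: tuple[tuple[str, str], ...] = (
        ("LAC", "benign"),
        ("LAC", "CRC_met"),
        ("LAC", "carcinoid"),
    )
    variants: tuple[str, ...] = ("all_LAC_vs_benign",)
    n_trees: int = 500
    select_k: int | None = None  # default: half the trees
    min_leaf: int = 3
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown analysis variants: {sorted(unknown)}")
        has_paths = all(p is not None for p in (self.npx_path, self.metadata_path, self.panel_path))
        if not has_paths and self.synthetic is None:
            self.synthetic = study_like_config(seed=self.seed)


def variant_subset(variant: str, metadata: SampleMetadata) -> tuple[np.ndarray, np.ndarray, str]:
    """Sample mask, binary labels, and positive class for an analysis variant."""
    groups = metadata.groups()
    benign = metadata.group_mask("benign")
    inflam = np.array([v is True for v in metadata.df["inflammatory"]])
    stage = metadata.df["stage"]
    if variant == "all_LAC_vs_benign":
        pos = metadata.group_mask("LAC")
        neg = benign
        positive = "LAC"
    elif variant == "stageI_vs_benign":
        pos = metadata.group_mask("LAC") & stage.isin(_STAGE_I).to_numpy()
        neg = benign
        positive = "LAC"
    elif variant == "stageI_vs_noninflammatory_benign":
        pos = metadata.group_mask("LAC") & stage.isin(_STAGE_I).to_numpy()
        neg = benign & ~inflam
        positive = "LAC"
    elif variant == "pooled_tumors_vs_benign":
        pos = ~benign
        neg = benign
        positive = "tumor"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    mask = pos | neg
    labels = np.where(pos, positive, "benign")[mask]
    return mask, labels, positive


def _metrics_row(name: str, cm: ConfusionMatrix, extra: dict | None = None) -> dict:
    m = confusion_metrics(cm, round_to=2)
    row = {
        "analysis": name,
        "positive_class": cm.positive_class,
        "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
        "sensitivity": m.sensitivity, "specificity": m.specificity,
        "ppv": m.ppv, "npv": m.npv, "accuracy": m.accuracy,
    }
    if extra:
        row.update(extra)
    return row


def _check_self_consistency(rows: Sequence[dict]) -> None:
    """Every reported metric must be recomputable from its own counts."""
    for row in rows:
        cm = ConfusionMatrix(tp=row["tp"], fp=row["fp"], tn=row["tn"], fn=row["fn"],
                             positive_class=row["positive_class"])
        m = confusion_metrics(cm, round_to=2)
        for key in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            got, want = row[key], getattr(m, key)
            if not (np.isnan(want) and np.isnan(got)) and got != want:
                raise AssertionError(
                    f"self-consistency failure in {row['analysis']}: {key} {got} != {want}"
                )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a report dict and writes all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"plasmasig {__version__}", f"seed {config.seed}"]
    streams = np.random.SeedSequence(config.seed).spawn(4)
    split_seed, ensemble_seed = (int(s.generate_state(1)[0] % 2**31) for s in streams[:2])

    # ------------------------------------------------------------------ load
    if config.npx_path is not None:
        matrix, metadata, panel = read_cohort(
            config.npx_path, config.metadata_path, config.panel_path
        )
        log_lines.append(f"loaded cohort from {config.npx_path}")
    else:
        matrix, metadata, panel, truth = generate_cohort(config.synthetic)
        write_cohort(matrix, metadata, panel, out / "cohort")
        truth.to_csv(out / "cohort" / "truth.tsv", sep="\t", index=False)
        log_lines.append(f"generated synthetic cohort (seed {config.synthetic.seed})")
    log_lines.append(f"{matrix.n_samples} samples × {matrix.n_proteins} proteins")

    report: dict = {"seed": config.seed, "version": __version__}

    # -------------------------------------------------------------------- qc
    qc = qc_detection(matrix, panel)
    report["qc"] = dataclasses.asdict(qc)
    (out / "qc.json").write_text(json.dumps(report["qc"], indent=2))

    # ------------------------------------------------- differential abundance
    diff_top: dict[str, list[str]] = {}
    for a, b in config.comparisons:
        results = compare_groups(matrix, metadata, a, b)
        write_comparison(results, out / f"diff_{a}_vs_{b}.tsv", f"{a}_vs_{b}")
        diff_top[f"{a}_vs_{b}"] = [r.protein_id for r in results if r.p_adj < 0.05]
        if a == "LAC" and b == "benign":
            results_ni = compare_groups(matrix, metadata, a, b, exclude_inflammatory=True)
            write_comparison(
                results_ni, out / "diff_LAC_vs_benign_noninflammatory.tsv",
                "LAC_vs_noninflammatory_benign",
            )
    report["significant_proteins"] = diff_top

    # ------------------------------------------------------- single markers
    lac_vs_benign = compare_groups(matrix, metadata, "LAC", "benign")
    top4 = [r.protein_id for r in lac_vs_benign[:4]]
    two_group = metadata.group_mask("LAC") | metadata.group_mask("benign")
    sub = matrix.subset_samples(two_group)
    sub_meta = metadata.subset(two_group)
    labels = sub_meta.groups()
    marker_rows = []
    metric_rows = []
    for pid in top4:
        vals = sub.column(pid)
        cm = median_cutoff_classify(vals, labels, positive_class="LAC")
        roc = roc_curve(vals, labels, positive_class="LAC")
        marker_rows.append(_metrics_row(f"median_cutoff_{pid}", cm, {"auc": round(roc.auc, 3)}))
    scores = combine_markers(sub, top4, labels, positive_class="LAC")
    roc4 = roc_curve(scores, labels, positive_class="LAC")
    report["single_marker"] = {"proteins": top4, "combined_auc": round(roc4.auc, 3)}
    metric_rows.extend(marker_rows)

    # --------------------------------------------- ensemble + signature per variant
    select_k = config.select_k if config.select_k is not None else max(1, config.n_trees // 2)
    report["variants"] = {}
    for variant in config.variants:
        mask, vlabels, positive = variant_subset(variant, metadata)
        vmatrix = matrix.subset_samples(mask)
        split = split_train_validation(
            vlabels, fraction=config.split_fraction, stratify_by_group=True, seed=split_seed
        )
        Xtr, ytr = vmatrix.values[split.train_idx], vlabels[split.train_idx]
        Xval, yval = vmatrix.values[split.val_idx], vlabels[split.val_idx]
        ens = fit_ensemble(
            Xtr, ytr,
            n_trees=config.n_trees,
            min_leaf=config.min_leaf,
            seed=ensemble_seed,
            positive_class=positive,
            protein_ids=vmatrix.protein_ids,
        )
        ens = select_trees(ens, k=min(select_k, ens.n_trees))
        pred_labels, scores = predict(ens, Xval)
        cm = ConfusionMatrix.from_predictions(
            pred_labels == positive, yval == positive, positive
        )
        roc = roc_curve(scores, yval, positive_class=positive)
        metric_rows.append(_metrics_row(f"ensemble_{variant}", cm, {"auc": round(roc.auc, 3)}))
        sig = aggregate_signature(ens, Xtr, ytr, positive_class=positive)
        sig.to_json(out / f"signature_{variant}.json")
        cm_sig = ConfusionMatrix.from_predictions(
            apply_signature(sig, vmatrix.values, vmatrix.protein_ids),
            vlabels == positive,
            positive,
        )
        metric_rows.append(_metrics_row(f"signature_{variant}", cm_sig))
        ens.to_json(out / f"ensemble_{variant}.json")
        report["variants"][variant] = {
            "n_train": int(split.train_idx.size),
            "n_validation": int(split.val_idx.size),
            "validation_auc": round(roc.auc, 3),
            "oob_error": None if np.isnan(ens.oob_error) else round(ens.oob_error, 4),
            "signature_proteins": list(sig.protein_ids),
        }

    _check_self_consistency(metric_rows)
    pd.DataFrame(metric_rows).to_csv(out / "metrics.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- clustering
    lac_benign = matrix.subset_samples(two_group)
    dend = hierarchical_cluster(lac_benign)
    (out / "dendrogram.newick").write_text(dend.to_newick())
    dend.write_merge_table(out / "dendrogram_merges.tsv")
    ari = cluster_label_agreement(dend, sub_meta.groups(), k=2)
    report["clustering"] = {"adjusted_rand_vs_groups": round(ari, 4)}

    log_lines.append("pipeline complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
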